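# Methods

This note records the models, conventions and design choices behind
`angiosprout`, in the spirit of the methods documentation of mature
scientific packages: what each stage assumes, which parameters matter and
why their defaults are what they are, what the synthetic generator does and
does not emulate, and where the genuinely open design decisions were made.

## 1. Acquisition model and maximal projection

The assay images 3-lane microfluidic chips as two-channel confocal
z-stacks — 40 planes at a 5 µm step, spanning the full 200 µm chip depth —
with a nuclear (Hoechst) and an F-actin (phalloidin) channel.  All analysis
operates on per-channel maximal projections (pixel-wise maximum over z).
Consequences embraced by the design:

* No volumetric analysis, deconvolution or flat-field correction is
  attempted; the projection is the unit of analysis.
* Physical calibration (`pixel_size_um`, `z_step_um`) is **mandatory
  configuration**, never read from TIFF tags by default: tag dialects vary
  between acquisition systems, and the 10× objective's effective pixel size
  depends on camera and binning.  If resolution tags are present and
  disagree with the config by more than 1 %, a warning is logged and the
  config wins.
* Channel roles are assigned by an explicit label→role map, never guessed
  from intensity statistics.
* Intensities stay in native integer depth until a detection operator needs
  floating point.

## 2. Chip geometry from phase-guide autofluorescence

The phase guides — the ridge structures separating the three channels —
autofluoresce in the nuclear channel and serve as the geometric landmark.
The mask chain is:

1. **Inclusive threshold** `[threshold_lo, threshold_hi]`.  The defaults are
   `lo` = Otsu's threshold of the projection and `hi` = ∞: the guides are
   the brightest *extended* structures, and bright nuclei that also clear
   the threshold are eliminated by the next two stages.  Both bounds are
   overridable with absolute values for plates where autofluorescence and
   nuclear staining overlap differently.
2. **Artefact-clearing erosion** by a disk of radius `shrink_px` (default
   5 px).  The erosion exists to delete small artefacts, not to thin the
   guides: components that survive the subsequent area filter are restored
   by exactly `shrink_px` geodesic dilation steps *inside the thresholded
   mask*.  This undoes the erosion of the guide bar itself while annexing at
   most a `shrink_px`-deep sliver of any bright structure (a nucleus) that
   merely touches the guide.  Whether the original proprietary "shrink"
   used a Euclidean disk or a square kernel is not determinable; disk
   semantics (radius, not diameter) are used and documented here.
3. **Object-area band** `[area_min_px, area_max_px]` keeps the two guide
   bars.  Connected components use 8-connectivity.  If more than two
   components survive, the two largest are kept (tie-break: area
   descending, then centroid-Y ascending) with a logged warning; fewer than
   two is a detection failure naming the stage that emptied the mask.
4. **Centroid-Y split** assigns top vs bottom guide.  The analysis
   convention is tube at image top, gel below; a `flip_y` config flag
   handles plates scanned inverted.
5. **Hole filling** of the top guide by morphological closing with radius
   `fill_radius_px` (default 5 px) — the dilation-then-shrink-of-equal-value
   sequence.  Holes arise from heterogeneous autofluorescence and from cell
   nuclei sitting on the guide.
6. **Guide straightening**: opening with a 1×`straighten_len_px`
   (default 45 px) horizontal line.  Nuclei lying directly on a guide bulge
   the thresholded mask locally by up to their own diameter, which would
   push the derived interface several pixels into the gel at those columns;
   the opening removes any vertical protrusion narrower than the line while
   leaving a width-spanning (possibly tilted) bar essentially unchanged.
7. **Inversion** of the straightened top-guide mask.  The complement's
   component with smallest centroid-Y is the tube region (rejected); the
   component directly below the guide is the ECM-gel mask, clipped
   per-column to rows above the bottom guide.  A guide that does not span
   the image width makes tube and gel connected; this raises a geometry
   error advising a larger `fill_radius_px`.
8. **Reference line**: dilation of the top guide by `ref_dilation_px`
   (default 3 px) AND the ECM mask — a thin band at the tube–gel interface.
   The magnitude of the "slight" dilation is a calibration parameter; 3 px
   keeps the band thin while guaranteeing overlap.  The scalar
   `reference_y_px` is the per-column mean of the line's uppermost row,
   rounded half-up; the per-column reduction matters only for tilted chips,
   for which no established convention exists.

All masks, and therefore every downstream statistic, are equivariant under
integer image translation — the property that motivates computing the
reference line per chip instead of assuming a fixed interface position.

## 3. Sprout-network detection and metrics

The actin channel inside the ECM mask is segmented by an open analog of a
proprietary "find fibers" operator:

* Pixels outside the gel are first replaced by the gel's median intensity,
  so tube or guide signal cannot bleed across the boundary through the
  filters — detection provably depends on gel pixels only.
* **Enhancement**: Gaussian smoothing (σ = 1 px) followed by a white top-hat
  whose disk footprint is several fiber widths across
  (radius `6 × ridge_scale_px`, default 12 px).  The top-hat removes broad
  background; the footprint is deliberately larger than a single fiber so
  bundles of crossing sprouts are not suppressed along with the background.
* **Threshold** at half the ridge amplitude, where the amplitude is the
  `intensity_percentile`-th percentile (default 99.9) of the enhanced gel
  pixels.  Cutting at the half-maximum contour makes the segmented width
  track the true fiber width instead of the arbitrary noise-tail position.
  The threshold never drops below a robust noise floor
  (median + `noise_nsigmas` × 1.4826·MAD, default 6σ), so a signal-free gel
  yields zero detections rather than spurious top-percentile pixels.
* **Small-object removal** below `min_object_area_px` (default 40 px), then
  classification of each component as fibrous or nonfibrous by its
  skeleton-length-to-mean-width ratio (`fibrous_aspect_min`, default 3).
  The two classes are merged into the sprout-network mask; the split is
  retained for QC only.

Metrics, in physical units:

* **Area** = pixel count × pixel_size².
* **Height** = (deepest network row − `reference_y_px`) × pixel_size,
  clamped at 0.  Measuring from the reference line (not the image top)
  keeps the metric translation-invariant and consistent with the nuclei
  statistic.
* **Length** = skeleton arc length: the network mask is skeletonized and
  the 8-connected neighbour graph's edges are summed (1 per axial step,
  √2 per diagonal), skipping diagonals whose corner pixel is itself on the
  skeleton (shortcuts across an axial path).  "Length" has no canonical
  definition in the emulated software; this convention is exact on
  axis-aligned and diagonal paths.

Zero detections are a valid all-zero result, not an error.  No per-sprout
instance segmentation or branch statistics are computed — only the three
aggregate metrics.  Actin-based metrics remain sensitive to ECM
stiffness/quality; no correction is attempted, which is precisely the
motivation for the nuclei statistic below.

## 4. Nuclei detection and the Nuclei Centroid Y Sum

Nuclei are detected with an open analog of a "find round objects" operator:

* Gaussian smoothing (σ = 1 px), then a threshold — `percentile` mode
  (default, 95th percentile of the smoothed *gel* pixels, i.e. of the
  analysis domain) or `absolute` mode.  In percentile mode the threshold is
  floored at median + 5σ (robust MAD scale) of the gel, so a gel with no
  nuclei yields no blobs.
* The phase guides (plus a 2 px halo covering their smoothing fringe) are
  excluded from the binary mask: they are known non-nuclear structures that
  clear any threshold, and excluding them keeps interface-hugging nuclei
  from merging into the guide plateau.
* **Touching-blob separation** (`split_touching`, default on): the
  watershed is seeded from local maxima of a Laplacian-of-Gaussian response
  matched to the small end of the diameter band
  (σ = `diameter_min_um`/2.355).  Round nuclei give one sharp LoG peak
  each, which separates neighbours well below the spacing that raw
  intensity peaks or the distance transform resolve.
* **Size gate** on the FWHM equivalent diameter — the diameter of the
  region above half peak height over background — in
  `[diameter_min_um, diameter_max_um]` (default 7–20 µm, typical HUVEC
  nuclei; flagged for per-lot recalibration).  Measuring at half-height
  decouples the gate from the global threshold.  Objects up to twice the
  band maximum are retained as unresolved clusters and counted once:
  dropping them loses more signal than miscounting them; anything larger is
  rejected as non-nuclear.
* **Centroids** are intensity-weighted (sub-pixel); mask membership is
  looked up at the nearest pixel.  Whether the emulated software used
  sub-pixel centroids is unknown; the choice is documented, not asserted as
  equivalent.

Only nuclei whose centroid lies in the ECM mask count.  Each contributes a
migration distance `(y − reference_y_px) × pixel_size`, clamped at zero:
boundary-straddling nuclei with centroids marginally above the line are
physically "at" the interface, and migration distance is non-negative by
definition.  The **Nuclei Centroid Y Sum** is the sum of these distances
over all gel nuclei — equivalently count × mean migration — additive over
disjoint sets, strictly increased by any nucleus inside the gel, and
translation-invariant.  It deliberately uses *all* nuclei rather than the
ten furthest-migrating ones.  The legacy statistic (subtract a constant
400 µm from each nuclear y-coordinate, clamp, sum) is provided solely as
the comparison baseline: a whole-chip shift of Δ changes it by Δ × count
while leaving the refined statistic unchanged.

## 5. The synthetic chip generator

The generator renders what the detection operators need and nothing more —
no PSF or optics simulation:

* **Geometry**: 400×400 px at 2.0 µm/px (a ≈0.8 mm field, consistent with a
  10× objective with binning).  The nominal tube–gel interface sits at
  400 µm from the image top (row 200), guides are 40 µm thick, the gel
  240 µm deep.  The 2 µm/px choice makes the 400 µm legacy interface an
  exact integer row, so the aligned-chip agreement between legacy and
  refined statistics is an exact, not approximate, check.  `tilt_deg`
  rotates the interface line; `y_jitter_um` shifts the whole chip per draw,
  emulating scanner misalignment.
* **Nuclear channel**: background 100 + Gaussian noise (SD 20, 16-bit),
  guide bands at +1500, nuclei as Gaussian blobs (amplitude 2000, FWHM
  12 µm).  Tube nuclei are placed uniformly in a 100 µm band above the top
  guide at 1500 /mm²; gel nuclei are placed at uniform arc-length positions
  along sprouts (Poisson mean 4 per sprout) — uniformity gives an analytic
  expected statistic.  Gel nuclei enforce a minimum centre separation of
  0.9 FWHM: nuclei are solid objects and cannot physically overlap almost
  completely, and rendering near-coincident Gaussians would create
  unresolvable fixtures that say nothing about real data.
* **Actin channel**: background + noise, a tube band above the guide at
  +600, and wavy sprout polylines (default 10 sprouts, length 150 ± 40 µm,
  width 8 µm, sinusoidal waviness 0.15) rasterized, clipped to the gel, and
  lightly blurred for anti-aliasing at +1000.
* **Ground truth** records exactly what was rasterized: guide masks, the
  analytic interface line, per-sprout polylines and the union sprout mask,
  the per-nucleus table with true migration distances, and the true metric
  values.  True sprout length is the sum of analytic polyline lengths, so
  it double-counts crossings that a detected skeleton merges — recovered
  length is expected to read a few percent low on dense chips.
* **Dose series**: each dilution factor scales the Poisson mean of the
  sprout count *and* scales mean sprout length by √factor — a diluted
  angiogenic stimulus produces both fewer and shorter sprouts, and without
  the length effect the maximal-extent height metric would not respond to
  dilution at all.  Per-chip sub-seeds derive deterministically from the
  plate seed and chip index, so plates are reproducible chip-wise.
* Optional z-stack rendering spreads both channels over a Gaussian z-profile
  (peak weight 1) across 40 planes at 5 µm, so the maximal projection
  recovers the 2-D images exactly and exercises the projection path
  end-to-end.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: optical blur and depth attenuation, uneven
illumination, ECM texture and autofluorescence, nuclei of heterogeneous
brightness/shape, apoptotic debris, and tube-boundary irregularity.  The
synthetic results validate the pipeline's logic and its robustness to the
modelled effects (noise, misalignment, tilt, density); real plates will
still need threshold and diameter-band calibration.

## 6. Numerical and degenerate-input conventions

* Structuring elements are Euclidean disks (radius semantics); component
  labelling is 8-connected throughout.
* `reference_y_px` rounds half-up; CSV floats are written with a fixed
  4-decimal format so repeated runs are byte-identical.
* Empty gels, zero detections, and nuclei-free chips are valid zero-valued
  results; empty masks where geometry is impossible (no guides, gapped
  guide, non-adjacent guide and gel) raise typed errors naming the failing
  stage, which the plate runner converts to QC flags rather than crashes.
* QC-flagged chips are excluded from aggregates but retained in the
  per-chip table so replicate attrition is visible.
* Normalization uses the control condition's **mean** (not median) as the
  100 % denominator, matching the assay's mean ± SD reporting convention;
  SD is reported only for n ≥ 2, and conditions with fewer than four usable
  replicates trigger a warning (chip-to-chip variability makes four the
  recommended minimum).  Normalization is per-plate; pooling controls
  across experiments is left to the user.

## 7. Validation problem sizes

The bundled validation suite and `scripts/acceptance.py` use: 20 seeded
chips (every fifth tilted 1°) for geometry recovery; 20 chips cycling
density factors 1.0/0.5/0.25 for statistic recovery; a 100-chip plate with
±30 µm jitter for the misalignment comparison; a 3-dilution × 4-replicate
series plus a 10- vs 20-sprout twofold contrast (4 replicates each) for
dose–response; and a two-chip plate analysed twice for byte-level
determinism.  These sizes give stable worst-case estimates while keeping a
full validation run around a minute on one CPU.

## 8. Known limitations

* Only the 3-lane, two-phase-guide chip layout is supported.
* The fibrous/nonfibrous split is a heuristic aspect-ratio rule; it does
  not affect the merged network metrics.
* Sub-pixel tilt is handled by the per-column reference line, but metrics
  use the scalar `reference_y_px`; for tilts ≫1° a per-column distance
  would be more faithful.
* The generator's statistical contracts (e.g. expected statistic under
  uniform placement) assume the defaults above; exotic parameter choices
  (sprouts longer than the gel, nuclei larger than guides) are rejected by
  validation rather than supported.
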