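# angiosprout

Open, tested quantification pipeline for the OrganoPlate® 3-lane
angiogenesis-on-chip sprouting assay.

In this assay, endothelial cells (HUVECs) form a perfused tube in the top
channel of a 3-lane microfluidic chip and sprout into a collagen-I ECM gel
in the middle channel under an angiogenic growth-factor gradient.  Chips
are imaged as two-channel confocal z-stacks (Hoechst/nuclei and
phalloidin/F-actin), collapsed to maximal projections, and quantified.
`angiosprout` reimplements this quantification with documented open
operators in place of proprietary high-content-screening software, for
screening labs that want a reproducible, scriptable version of the
analysis — and bundles a synthetic chip-image generator with exact ground
truth so the whole pipeline is testable without a microscope.

## What it computes

Per chip field:

1. **Chip geometry** from phase-guide autofluorescence in the nuclear
   channel: an inclusive intensity band isolates the two guide bars, a 5 px
   "shrink" erosion plus an object-area filter rejects artefacts, a
   dilation-then-shrink closing fills holes, and inverting the top-guide
   mask yields the tube and ECM-gel masks.
2. **The per-chip reference line** — the tube–gel interface — as the
   logical AND of the slightly dilated top-guide mask with the ECM mask.
   Its row coordinate `y_ref` is the per-chip origin for all migration
   distances, making every statistic invariant to chip misalignment in the
   scanner.
3. **Sprout metrics** from the actin channel inside the gel: the sprout
   network mask (ridge enhancement → half-maximum threshold → small-object
   removal → fibrous/nonfibrous merge) and its **area** (µm²), **height**
   (deepest extent below the reference line, µm) and **length** (skeleton
   arc length, µm).
4. **The Nuclei Centroid Y Sum**, the nuclei-based angiogenesis statistic:

   S = Σᵢ max(0, yᵢ − y_ref) · pixel_size,

   summed over *all* nuclei whose centroid lies in the ECM gel — robust to
   ECM stiffness/quality variation that affects actin-based metrics, and to
   chip-to-chip misalignment thanks to the per-chip reference line.  The
   legacy alternative (subtracting a constant 400 µm) is included for
   comparison.

Per plate: metrics are normalized to a designated control condition
(control mean = 100 %) and aggregated as mean ± SD with n per condition.

## Worked example

Simulate a small plate (undiluted "control" vs a 0.5-density dilution, two
replicates each), analyse it, and render QC overlays:

```bash
angiosprout simulate --out fixtures --seed 5 --density-factors 1.0,0.5 --replicates 2
angiosprout run --input fixtures --layout fixtures/layout.csv \
    --control control --out results
angiosprout qc --input fixtures --layout fixtures/layout.csv --out results/qc
```

`results/chips.csv` then contains per-chip rows such as:

```
chip_id,condition,sprout_area_um2,sprout_length_um,nuclei_centroid_y_sum_um,max_migration_um
control_r0,control,23808.0000,2720.5710,4335.4187,218.6112
control_r1,control,21680.0000,2515.7771,3663.8977,212.8147
density_0.5_r0,density_0.5,10644.0000,1216.5870,2102.5893,124.3293
density_0.5_r1,density_0.5,7700.0000,843.5433,1219.9169,129.4278
```

and `results/conditions.csv` the per-condition aggregates:

```
  condition  n  nuclei_centroid_y_sum_um_mean  nuclei_centroid_y_sum_um_pct_control_mean
    control  2                      3999.6582                                   100.0000
density_0.5  2                      1661.2531                                    41.5349
```

Reading this: the control chips accumulate ≈4000 µm of summed nuclear
migration below the tube–gel interface; halving the sprouting density
roughly halves the number of migrated nuclei *and* shortens sprouts, so
the statistic drops to ≈42 % of control.  `max_migration_um` ≈ 219 µm says
the furthest nucleus reached 219 µm into the gel.  QC-flagged chips (e.g.
failed guide detection) stay listed in `chips.csv` but are excluded from
the aggregates.

The library mirrors the CLI: `generate_chip` / `generate_dose_series`
produce synthetic chips with ground truth, `run_chip` executes the
pipeline on a stack or projection pair, and `normalize_and_aggregate`
builds the plate report.  All tunables live in a YAML config (see
`AnalysisConfig`); CLI flag > YAML > built-in default, and the effective
config is written next to the results.

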