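"""Nuclei detection in the gel and the Nuclei Centroid Y Sum statistic.

Actin-based sprout quantification is sensitive to ECM stiffness and quality,
which vary between experiments.  The robust alternative quantifies
angiogenic sprouting from the nuclear stain: every nucleus whose centroid
lies in the ECM gel contributes its distance below the per-chip reference
line, and the statistic is the sum of those migration distances over *all*
gel nuclei (not just the furthest-migrating few).  Because the reference
line is recomputed per chip, the statistic is invariant to whole-image
translation — chips need not be aligned in the scanner.

The legacy alternative, subtracting a constant 400 µm from every nuclear
y-coordinate, is provided for method comparison only: it inflates or
deflates with any chip misalignment.

Detection is an open analog of a proprietary "find round objects" operator:
smoothing, thresholding, optional watershed splitting of touching blobs, an
intensity-weighted (sub-pixel) centroid per object, and a size gate on the
FWHM equivalent diameter (measured at half peak height above background so
the gate does not depend on the global threshold level).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import feature, morphology, segmentation

from .chip_geometry import ChipMasks

_EIGHT = np.ones((3, 3), bool)


class PipelineOrderError(RuntimeError):
    """Geometry (reference line) must be computed before nuclei quantification."""


@dataclass(frozen=True)
class NucleiParams:
    """Tunables of the nuclear blob detector.

    The diameter band defaults to 7-20 µm (typical HUVEC nuclei); different
    cell types or HUVEC lots may require recalibration.  ``threshold_mode``
    is ``"percentile"`` (percentile of the smoothed ECM-region intensities,
    the analysis domain) or ``"absolute"``.
    """

    diameter_min_um: float = 7.0
    diameter_max_um: float = 20.0
    intensity_threshold_mode: str = "percentile"
    intensity_threshold_value: float = 95.0
    split_touching: bool = True
    smoothing_sigma_px: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.diameter_min_um < self.diameter_max_um:
            raise ValueError("need 0 < diameter_min_um < diameter_max_um")
        if self.intensity_threshold_mode not in ("percentile", "absolute"):
            raise ValueError("intensity_threshold_mode must be 'percentile' or 'absolute'")


@dataclass(frozen=True)
class NucleiSet:
    """Detected gel nuclei with per-nucleus migration distances (µm)."""

    centroids: np.ndarray  # (n, 2) sub-pixel (x_px, y_px)
    areas_px: np.ndarray  # (n,) thresholded footprint areas
    migration_um: np.ndarray  # (n,) distance below the reference line, >= 0
    chip_id: str = ""

    def __post_init__(self) -> None:
        n = len(self.centroids)
        if len(self.areas_px) != n or len(self.migration_um) != n:
            raise ValueError("centroids, areas_px, migration_um must align")
        if n and np.any(self.migration_um < 0):
            raise ValueError("migration distances must be non-negative")

    def __len__(self) -> int:
        return len(self.centroids)


def find_nuclei(
    nuclear_image: np.ndarray,
    masks: ChipMasks,
    params: NucleiParams,
    pixel_size_um: float,
    chip_id: str = "",
) -> NucleiSet:
    """Detect nuclei and keep those whose centroid lies in the ECM gel.

    Centroids are intensity-weighted (sub-pixel); mask membership is looked
    up at the nearest pixel.  Nuclei on the boundary band whose centroid
    falls at or above the reference line contribute a migration distance of
    zero (migration is physically non-negative); zero detections yield a
    valid empty set.
    """
    if masks.reference_line is None or not masks.reference_line.any():
        raise PipelineOrderError("reference line missing: run chip geometry first")
    img = np.asarray(nuclear_image, dtype=np.float64)
    smoothed = ndi.gaussian_filter(img, sigma=params.smoothing_sigma_px)

    gel_vals = smoothed[masks.ecm_mask]
    if params.intensity_threshold_mode == "percentile":
        thr = float(np.percentile(gel_vals, params.intensity_threshold_value))
        # guard against a signal-free gel where the percentile sits in noise
        med = float(np.median(gel_vals))
        mad_sigma = 1.4826 * float(np.median(np.abs(gel_vals - med)))
        thr = max(thr, med + 5.0 * mad_sigma)
    else:
        thr = params.intensity_threshold_value

    binary = smoothed > thr
    # The phase guides are known non-nuclear structures that clear any
    # intensity threshold; excluding them (plus a 2 px halo covering their
    # smoothing fringe) keeps interface nuclei from merging into the guide
    # plateau and suppresses spurious edge detections along the guides.
    guides = morphology.dilation(
        masks.top_guide | masks.bottom_guide, morphology.disk(2)
    )
    binary &= ~guides
    labels = _label_blobs(img, binary, params, pixel_size_um)

    bg = float(np.median(gel_vals))
    centroids: list[tuple[float, float]] = []
    areas: list[int] = []
    ref_y = masks.reference_y_px
    for lab in range(1, labels.max() + 1):
        obj = labels == lab
        area = int(obj.sum())
        if area == 0:
            continue
        if not _diameter_in_band(smoothed, obj, bg, params, pixel_size_um):
            continue
        cy, cx = _weighted_centroid(img, obj)
        iy, ix = int(round(cy)), int(round(cx))
        if not (
            0 <= iy < masks.ecm_mask.shape[0]
            and 0 <= ix < masks.ecm_mask.shape[1]
            and masks.ecm_mask[iy, ix]
        ):
            continue
        centroids.append((cx, cy))
        areas.append(area)

    if not centroids:
        return NucleiSet(
            centroids=np.empty((0, 2)),
            areas_px=np.empty(0, int),
            migration_um=np.empty(0),
            chip_id=chip_id,
        )
    cents = np.asarray(centroids)
    migration = np.maximum(0.0, (cents[:, 1] - ref_y) * pixel_size_um)
    return NucleiSet(
        centroids=cents,
        areas_px=np.asarray(areas, int),
        migration_um=migration,
        chip_id=chip_id,
    )


def nuclei_centroid_y_sum(nuclei: NucleiSet) -> float:
    """Sum of migration distances (µm) over all gel nuclei; 0 for an empty set.

    Equals count × mean migration distance, and is additive over disjoint
    nuclei sets.
    """
    return float(np.sum(nuclei.migration_um))


def legacy_constant_offset_sum(
    nuclei_raw_y_px: np.ndarray,
    pixel_size_um: float,
    offset_um: float = 400.0,
) -> float:
    """Migration sum against a fixed 400 µm offset (comparison baseline only).

    The legacy convention assumed the tube-gel interface at a constant
    400 µm from the image origin; any chip misalignment shifts this
    statistic by (shift × nucleus count), which the per-chip reference line
    avoids.
    """
    y_um = np.asarray(nuclei_raw_y_px, dtype=float) * pixel_size_um
    return float(np.sum(np.maximum(0.0, y_um - offset_um)))


def _label_blobs(
    img: np.ndarray,
    binary: np.ndarray,
    params: NucleiParams,
    pixel_size_um: float,
) -> np.ndarray:
    """Label thresholded blobs, optionally watershed-splitting touching ones.

    Splitting seeds the watershed from maxima of a Laplacian-of-Gaussian
    response matched to the *small* end of the diameter band: round nuclei
    give one sharp LoG peak each, which separates touching blobs well below
    the separation either raw intensity peaks or the distance transform can
    resolve.
    """
    min_area = max(2, int(np.pi * (params.diameter_min_um / (4 * pixel_size_um)) ** 2))
    binary = morphology.remove_small_objects(binary, max_size=min_area - 1, connectivity=2)
    if not binary.any():
        return np.zeros(binary.shape, int)
    if not params.split_touching:
        labels, _ = ndi.label(binary, structure=_EIGHT)
        return labels
    sigma_px = params.diameter_min_um / (2.355 * pixel_size_um)
    log_resp = -ndi.gaussian_laplace(img, sigma=sigma_px)
    peaks = feature.peak_local_max(
        log_resp, min_distance=2, labels=binary, exclude_border=False
    )
    if len(peaks) == 0:
        labels, _ = ndi.label(binary, structure=_EIGHT)
        return labels
    markers = np.zeros(binary.shape, int)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    return segmentation.watershed(-log_resp, markers, mask=binary)


def _weighted_centroid(img: np.ndarray, obj: np.ndarray) -> tuple[float, float]:
    ys, xs = np.nonzero(obj)
    w = img[ys, xs].astype(float)
    tot = w.sum()
    if tot <= 0:
        return float(ys.mean()), float(xs.mean())
    return float((ys * w).sum() / tot), float((xs * w).sum() / tot)


def _diameter_in_band(
    smoothed: np.ndarray,
    obj: np.ndarray,
    background: float,
    params: NucleiParams,
    pixel_size_um: float,
) -> bool:
    """Gate an object on its FWHM equivalent diameter in µm.

    Measuring at half peak height above background decouples the gate from
    the global threshold level.  Objects up to twice the band maximum are
    retained: they are unresolved clusters of touching nuclei the watershed
    could not split, and counting them once loses less signal than dropping
    them.  Anything larger is a non-nuclear structure.
    """
    peak = float(smoothed[obj].max())
    half = background + 0.5 * (peak - background)
    fwhm_area = int(np.count_nonzero(obj & (smoothed >= half)))
    d_um = 2.0 * np.sqrt(fwhm_area / np.pi) * pixel_size_um
    return params.diameter_min_um <= d_um <= 2.0 * params.diameter_max_um
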