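"""Chip-geometry reconstruction from nuclear-channel autofluorescence.

The OrganoPlate 3-lane chip has two horizontal phase guides that separate the
endothelial-tube channel (top), the ECM-gel channel (middle) and the
gradient channel (bottom).  The guides autofluoresce in the Hoechst channel,
which makes them the geometric landmark of every chip field:

1. an inclusive intensity band isolates the autofluorescent guides;
2. a 5 px erosion clears small artefacts, an object-area band rejects the
   rest, and the two guides are told apart by centroid-Y;
3. holes in the top guide (cell nuclei sitting on it, heterogeneous
   autofluorescence) are closed by a dilation-then-shrink of equal radius;
4. the complement of the closed top guide yields the tube mask (above) and
   the ECM-gel mask (below);
5. the reference line at the tube-gel interface is the intersection of the
   slightly dilated top guide with the ECM mask.

The reference line is recomputed per chip because chips are not always
aligned in the plate scanner; all migration distances are measured from it,
which makes every downstream statistic invariant to whole-image translation.

Conventions: image y increases downward (tube at top, gel below; a
``flip_y`` config flag handles plates scanned inverted); structuring
elements are Euclidean disks with *radius* semantics; connected components
use 8-connectivity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, morphology

logger = logging.getLogger(__name__)

_EIGHT = np.ones((3, 3), bool)  # 8-connectivity structuring element


class GuideDetectionError(RuntimeError):
    """Guide detection emptied out; the message names the failing stage."""


class GeometryError(RuntimeError):
    """Derived geometry is inconsistent (e.g. guide does not span the image)."""


@dataclass(frozen=True)
class GuideDetectionParams:
    """Tunables of the phase-guide mask pipeline.

    ``threshold_lo``/``threshold_hi`` bound the inclusive autofluorescence
    band; when ``threshold_lo`` is None it defaults to Otsu's threshold of
    the nuclear projection (the guides are the brightest *extended*
    structures, and the erosion + area filter reject bright nuclei that also
    clear the threshold) and ``threshold_hi`` None means no upper bound.
    ``shrink_px`` is the artefact-clearing erosion radius (default 5 px,
    matching the acquisition software's "shrink objects" value).
    """

    threshold_lo: float | None = None
    threshold_hi: float | None = None
    shrink_px: int = 5
    area_min_px: int = 1000
    area_max_px: int = 10_000_000
    fill_radius_px: int = 5
    ref_dilation_px: int = 3
    straighten_len_px: int = 45

    def __post_init__(self) -> None:
        if (
            self.threshold_lo is not None
            and self.threshold_hi is not None
            and self.threshold_lo > self.threshold_hi
        ):
            raise ValueError("threshold_lo must be <= threshold_hi")
        if min(self.shrink_px, self.fill_radius_px, self.ref_dilation_px) < 0:
            raise ValueError("all radii must be >= 0")
        if self.straighten_len_px < 0:
            raise ValueError("straighten_len_px must be >= 0")
        if self.area_min_px >= self.area_max_px:
            raise ValueError("area_min_px must be < area_max_px")


@dataclass(frozen=True)
class ChipMasks:
    """The derived binary masks of one chip field."""

    top_guide: np.ndarray
    bottom_guide: np.ndarray
    tube_mask: np.ndarray
    ecm_mask: np.ndarray
    reference_line: np.ndarray
    reference_y_px: int


def detect_guides(
    nuclear_image: np.ndarray, params: GuideDetectionParams
) -> tuple[np.ndarray, np.ndarray]:
    """Segment both phase guides from the nuclear-channel projection.

    Returns ``(top_guide, bottom_guide)`` split by component centroid-Y.
    The erosion exists only to reject small artefacts: components that
    survive the area filter are restored by exactly ``shrink_px`` geodesic
    dilation steps inside the thresholded band, which undoes the erosion of
    the guide bar itself without annexing bright structures (nuclei) that
    merely touch it.
    """
    img = np.asarray(nuclear_image)
    if img.size == 0:
        raise GuideDetectionError("empty nuclear projection")
    lo = (
        params.threshold_lo
        if params.threshold_lo is not None
        else float(filters.threshold_otsu(img))
    )
    hi = params.threshold_hi if params.threshold_hi is not None else np.inf

    band = (img >= lo) & (img <= hi)
    if not band.any():
        raise GuideDetectionError(
            f"threshold stage: no pixels in intensity band [{lo:g}, {hi:g}]"
        )

    eroded = morphology.erosion(band, morphology.disk(params.shrink_px))
    if not eroded.any():
        raise GuideDetectionError(
            f"erosion stage: shrink by {params.shrink_px} px removed every object"
        )

    labels, n = ndi.label(eroded, structure=_EIGHT)
    areas = ndi.sum_labels(eroded, labels, index=np.arange(1, n + 1))
    keep = [
        i + 1
        for i, a in enumerate(areas)
        if params.area_min_px <= a <= params.area_max_px
    ]
    if len(keep) < 2:
        raise GuideDetectionError(
            f"area-filter stage: {len(keep)} component(s) in "
            f"[{params.area_min_px}, {params.area_max_px}] px; need 2 guides"
        )
    if len(keep) > 2:
        logger.warning(
            "area filter kept %d components; keeping the two largest", len(keep)
        )
        order = sorted(
            keep,
            key=lambda lab: (-areas[lab - 1], ndi.center_of_mass(labels == lab)[0]),
        )
        keep = order[:2]

    # Undo the erosion for the survivors: shrink_px geodesic steps in the band.
    restored = np.isin(labels, keep)
    disk1 = morphology.disk(1)
    for _ in range(params.shrink_px):
        restored = morphology.dilation(restored, disk1) & band

    rlabels, _ = ndi.label(restored, structure=_EIGHT)
    comps: dict[int, np.ndarray] = {}
    for lab in keep:
        rlab = int(rlabels[labels == lab][0])
        comps[rlab] = rlabels == rlab
    ordered = sorted(
        ((ndi.center_of_mass(m)[0], m) for m in comps.values()), key=lambda t: t[0]
    )
    if len(ordered) != 2:
        raise GuideDetectionError("centroid-split stage: could not isolate two guides")
    return ordered[0][1], ordered[1][1]


def fill_top_guide(top_guide: np.ndarray, params: GuideDetectionParams) -> np.ndarray:
    """Close holes in the top-guide mask (dilation then shrink of equal radius).

    Holes of diameter below ``2 * fill_radius_px`` are closed; the output is
    always a superset of the input, and a solid guide passes through
    unchanged.
    """
    if not top_guide.any():
        raise GeometryError("fill_top_guide: empty top-guide mask")
    if params.fill_radius_px == 0:
        return top_guide.copy()
    selem = morphology.disk(params.fill_radius_px)
    closed = morphology.closing(top_guide, selem)
    return closed | top_guide


def derive_ecm_mask(
    filled_top_guide: np.ndarray,
    image_shape: tuple[int, int],
    bottom_guide: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Invert the closed top-guide mask into the tube and ECM-gel masks.

    The complement of a width-spanning guide falls into (at least) a
    component above the guide — the endothelial-tube region — and one below
    it — the ECM gel.  The tube component is identified by smallest
    centroid-Y and rejected; the component adjacent below the guide is the
    gel.  When a bottom-guide mask is supplied, the gel is additionally
    clipped to rows above it.
    """
    if not filled_top_guide.any():
        raise GeometryError("derive_ecm_mask: empty top-guide mask")
    cols_covered = filled_top_guide.any(axis=0)
    if not cols_covered.all():
        raise GeometryError(
            "top guide does not span the full image width; increase "
            "fill_radius_px so the closing bridges the gap"
        )

    complement = ~filled_top_guide
    labels, n = ndi.label(complement, structure=_EIGHT)
    if n < 2:
        raise GeometryError(
            "complement of the top guide is connected; the guide must split "
            "the image into tube and gel regions"
        )
    centroids = ndi.center_of_mass(complement, labels, index=np.arange(1, n + 1))
    order = np.argsort([c[0] for c in centroids])
    tube_mask = labels == order[0] + 1
    ecm_mask = labels == order[1] + 1

    if bottom_guide is not None and bottom_guide.any():
        ecm_mask = ecm_mask & ~bottom_guide
        # clip per column at the bottom guide's top row (tilt-aware)
        rows = np.arange(image_shape[0])[:, None]
        top_of_bottom = np.where(
            bottom_guide.any(axis=0),
            np.argmax(bottom_guide, axis=0),
            image_shape[0],
        )
        ecm_mask = ecm_mask & (rows < top_of_bottom[None, :])
    return tube_mask, ecm_mask


def compute_reference_line(
    filled_top_guide: np.ndarray,
    ecm_mask: np.ndarray,
    params: GuideDetectionParams,
) -> tuple[np.ndarray, int]:
    """Locate the tube-gel interface: dilated top guide AND gel mask.

    Returns the thin reference-line mask plus ``reference_y_px``, the
    per-column mean of the line's uppermost row rounded half-up.  This is the
    per-chip origin from which all nuclear migration distances are measured.
    """
    if not filled_top_guide.any() or not ecm_mask.any():
        raise GeometryError("compute_reference_line: empty input mask")
    dilated = morphology.dilation(
        filled_top_guide, morphology.disk(params.ref_dilation_px)
    )
    line = dilated & ecm_mask
    if not line.any():
        raise GeometryError(
            "reference line is empty: top guide and ECM gel are not adjacent"
        )
    cols = line.any(axis=0)
    top_rows = np.argmax(line, axis=0)[cols]
    reference_y_px = int(np.floor(top_rows.mean() + 0.5))  # round half-up
    return line, reference_y_px


def straighten_guide(guide: np.ndarray, params: GuideDetectionParams) -> np.ndarray:
    """Shave off vertical protrusions from a guide mask.

    Cell nuclei sitting directly on a phase guide clear the autofluorescence
    threshold and bulge the guide mask locally, which would push the derived
    interface several pixels into the gel at those columns.  Opening with a
    horizontal line of ``straighten_len_px`` removes any protrusion narrower
    than the line while leaving a width-spanning bar (tilted or not)
    essentially untouched.
    """
    if params.straighten_len_px <= 1 or not guide.any():
        return guide
    footprint = np.ones((1, params.straighten_len_px), dtype=bool)
    return morphology.opening(guide, footprint)


def build_chip_masks(
    nuclear_image: np.ndarray, params: GuideDetectionParams
) -> ChipMasks:
    """Run the full geometry chain on one nuclear-channel projection."""
    top, bottom = detect_guides(nuclear_image, params)
    filled = straighten_guide(fill_top_guide(top, params), params)
    bottom = straighten_guide(bottom, params)
    tube, ecm = derive_ecm_mask(filled, nuclear_image.shape, bottom_guide=bottom)
    line, ref_y = compute_reference_line(filled, ecm, params)
    return ChipMasks(
        top_guide=filled,
        bottom_guide=bottom,
        tube_mask=tube,
        ecm_mask=ecm,
        reference_line=line,
        reference_y_px=ref_y,
    )
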