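"""Synthetic chip-image generator with exact ground truth.

Emulates the signal structure of the OrganoPlate 3-lane angiogenesis assay
so every analysis module is testable without microscopy data:

* nuclear channel — two horizontal autofluorescent phase-guide bars, a dense
  band of tube nuclei above the top guide, round Gaussian nuclear blobs
  along the sprouts in the gel, plus Gaussian read noise;
* actin channel — a bright tube band above the top guide and curvilinear
  sprout polylines of configurable width extending from the tube-gel
  interface into the gel, plus noise.

The generator records exactly what it rasterised: guide masks, the analytic
interface line, per-sprout polylines and the rasterised sprout mask,
per-nucleus positions with true migration distances, and the resulting true
metric values.  Chip misalignment (``y_jitter_um``) shifts the whole chip
vertically per draw — the fixture that makes the benefit of a per-chip
reference line measurable.  No optics/PSF simulation is attempted; the
signal model only needs to exercise the detection operators.

Default dimensions: 400×400 px at 2.0 µm/px (a ≈0.8 mm field as from a 10×
objective with binning), nominal tube-gel interface at 400 µm from the image
top, 40 µm-thick guides, a 240 µm-deep gel.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import draw, morphology

from .image_io import ChipStack, Projection


@dataclass(frozen=True)
class SyntheticChipSpec:
    """Full parameterisation of one synthetic chip; ``seed`` fixes the output."""

    image_shape_px: tuple[int, int] = (400, 400)
    pixel_size_um: float = 2.0
    interface_y_um: float = 400.0  # nominal tube-gel interface (lower edge of top guide)
    guide_thickness_um: float = 40.0
    gel_depth_um: float = 240.0
    guide_autofluorescence_level: float = 1500.0
    tilt_deg: float = 0.0
    y_jitter_um: float = 0.0
    n_sprouts: int = 10
    sprout_length_um_mean: float = 150.0
    sprout_length_um_sd: float = 40.0
    sprout_width_um: float = 8.0
    sprout_waviness: float = 0.15
    nuclei_per_sprout_mean: float = 4.0
    tube_nuclei_density_per_mm2: float = 1500.0
    tube_band_um: float = 100.0
    nuclei_fwhm_um: float = 12.0
    nuclei_level: float = 2000.0
    actin_level: float = 1000.0
    noise_sd: float = 20.0
    background_level: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        h_um = self.image_shape_px[0] * self.pixel_size_um
        if not 0 < self.guide_thickness_um < self.interface_y_um:
            raise ValueError("top guide must fit above the interface")
        if self.interface_y_um + self.gel_depth_um + self.guide_thickness_um > h_um:
            raise ValueError("guides and gel do not fit inside the image")
        if self.sprout_length_um_mean > self.gel_depth_um:
            raise ValueError("mean sprout length exceeds gel depth")
        for name in (
            "pixel_size_um",
            "gel_depth_um",
            "sprout_width_um",
            "nuclei_fwhm_um",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """Exact description of what one synthetic chip contains."""

    interface_y_um: float  # actual (jittered) interface at image centre
    tilt_deg: float
    top_guide_mask: np.ndarray
    bottom_guide_mask: np.ndarray
    sprout_polylines_px: list  # list of (n, 2) arrays of (x, y) pixel coords
    sprout_mask: np.ndarray  # rasterised gel-clipped sprout network
    nuclei: pd.DataFrame  # columns x_um, y_um, x_px, y_px, in_gel, true_migration_um
    true_centroid_y_sum_um: float
    true_sprout_area_um2: float
    true_sprout_height_um: float
    true_sprout_length_um: float

    def interface_row_px(self, x_px: np.ndarray | float, pixel_size_um: float) -> np.ndarray:
        """Analytic interface row (float px) at the given column(s)."""
        x = np.asarray(x_px, dtype=float)
        w = self.top_guide_mask.shape[1]
        slope = np.tan(np.deg2rad(self.tilt_deg))
        return self.interface_y_um / pixel_size_um + slope * (x - w / 2)


def generate_chip(
    spec: SyntheticChipSpec, as_stack: bool = False, n_planes: int = 40, z_step_um: float = 5.0
) -> tuple[dict, GroundTruth]:
    """Render one chip.

    Returns ``(channels, truth)`` where ``channels`` maps ``"nuclear"`` and
    ``"actin"`` to :class:`~angiosprout.image_io.Projection` objects, or — with
    ``as_stack=True`` — contains a single ``"stack"`` entry whose intensities
    are spread over a Gaussian z-profile so the maximal projection recovers
    the 2-D images.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_shape_px
    px = spec.pixel_size_um

    jitter = rng.uniform(-spec.y_jitter_um, spec.y_jitter_um) if spec.y_jitter_um else 0.0
    interface_um = spec.interface_y_um + jitter
    slope = np.tan(np.deg2rad(spec.tilt_deg))

    cols = np.arange(w, dtype=float)
    interface_row = interface_um / px + slope * (cols - w / 2)  # per-column float row

    top_guide = _band_mask(h, w, interface_row - spec.guide_thickness_um / px, interface_row)
    bot_top = interface_row + spec.gel_depth_um / px
    bottom_guide = _band_mask(h, w, bot_top, bot_top + spec.guide_thickness_um / px)

    nuclear = np.full((h, w), spec.background_level, dtype=np.float64)
    actin = np.full((h, w), spec.background_level, dtype=np.float64)
    nuclear[top_guide] += spec.guide_autofluorescence_level
    nuclear[bottom_guide] += spec.guide_autofluorescence_level

    # endothelial tube: actin-rich band hugging the top guide from above
    tube_top = interface_row - (spec.guide_thickness_um + spec.tube_band_um) / px
    tube_band = _band_mask(h, w, tube_top, interface_row - spec.guide_thickness_um / px)
    actin[tube_band] += 0.6 * spec.actin_level

    sprout_mask = np.zeros((h, w), dtype=bool)
    polylines: list[np.ndarray] = []
    nuclei_rows: list[dict] = []

    for _ in range(spec.n_sprouts):
        poly = _sample_sprout(rng, spec, w, interface_row)
        polylines.append(poly)
        sprout_mask |= _rasterize_polyline(poly, spec.sprout_width_um / (2 * px), (h, w))
        n_nuc = rng.poisson(spec.nuclei_per_sprout_mean)
        arc = _cumulative_arc(poly)
        # Nuclei are solid ~12 µm objects: enforce a minimum centre-to-centre
        # separation (0.9 FWHM) so the rendered blobs stay physically plausible.
        min_sep_px = 0.9 * spec.nuclei_fwhm_um / px
        placed = [(r["x_px"], r["y_px"]) for r in nuclei_rows if r["in_gel"]]
        for _ in range(n_nuc):
            for _attempt in range(30):
                t = rng.uniform(0.05, 1.0)
                x_px_, y_px_ = _point_at_arc(poly, arc, t * arc[-1])
                x_px_ += rng.normal(0, spec.sprout_width_um / (4 * px))
                x_px_ = float(np.clip(x_px_, 0, w - 1))
                if all(
                    (x_px_ - qx) ** 2 + (y_px_ - qy) ** 2 >= min_sep_px**2
                    for qx, qy in placed
                ):
                    placed.append((x_px_, y_px_))
                    nuclei_rows.append({"x_px": x_px_, "y_px": float(y_px_), "in_gel": True})
                    break

    # keep sprout pixels strictly in the gel (never above the interface)
    rows = np.arange(h, dtype=float)[:, None]
    gel_region = (rows >= interface_row[None, :]) & (rows < bot_top[None, :])
    sprout_mask &= gel_region

    # tube nuclei strictly above the interface (inside the tube band)
    tube_area_mm2 = (spec.tube_band_um / 1000.0) * (w * px / 1000.0)
    n_tube = rng.poisson(spec.tube_nuclei_density_per_mm2 * tube_area_mm2)
    for _ in range(n_tube):
        x_px_ = rng.uniform(0, w - 1)
        local_if = interface_um / px + slope * (x_px_ - w / 2)
        y_px_ = rng.uniform(
            local_if - (spec.guide_thickness_um + spec.tube_band_um) / px,
            local_if - spec.guide_thickness_um / px - 1,
        )
        nuclei_rows.append({"x_px": x_px_, "y_px": y_px_, "in_gel": False})

    nuclei = pd.DataFrame(nuclei_rows, columns=["x_px", "y_px", "in_gel"])
    nuclei["x_um"] = nuclei["x_px"] * px
    nuclei["y_um"] = nuclei["y_px"] * px
    local_if_um = interface_um + slope * (nuclei["x_px"] - w / 2) * px
    nuclei["true_migration_um"] = np.where(
        nuclei["in_gel"], np.maximum(0.0, nuclei["y_um"] - local_if_um), 0.0
    )

    sigma_px = spec.nuclei_fwhm_um / (2.355 * px)
    for _, row in nuclei.iterrows():
        _add_gaussian_blob(nuclear, row["x_px"], row["y_px"], sigma_px, spec.nuclei_level)

    actin_sprouts = np.zeros((h, w))
    actin_sprouts[sprout_mask] = spec.actin_level
    actin += ndi.gaussian_filter(actin_sprouts, sigma=0.7)  # anti-aliasing

    if spec.noise_sd > 0:
        nuclear += rng.normal(0, spec.noise_sd, size=(h, w))
        actin += rng.normal(0, spec.noise_sd, size=(h, w))
    nuclear_u16 = np.clip(nuclear, 0, 65535).astype(np.uint16)
    actin_u16 = np.clip(actin, 0, 65535).astype(np.uint16)

    truth = _make_truth(
        spec, interface_um, top_guide, bottom_guide, polylines, sprout_mask, nuclei
    )

    chip_id = f"chip_seed{spec.seed}"
    if as_stack:
        stack = _render_stack(nuclear_u16, actin_u16, spec, rng, n_planes, z_step_um, chip_id)
        return {"stack": stack}, truth
    channels = {
        "nuclear": Projection(nuclear_u16, "nuclear", px, chip_id),
        "actin": Projection(actin_u16, "actin", px, chip_id),
    }
    return channels, truth


def generate_dose_series(
    base_spec: SyntheticChipSpec,
    density_factors: list[float],
    n_replicates: int,
    seed: int,
    condition_labels: list[str] | None = None,
) -> tuple[list[dict], pd.DataFrame]:
    """Generate a plate emulating an angiogenic-cocktail dilution series.

    Sprout counts (and with them gel-nucleus counts) scale with each density
    factor, and mean sprout length scales with the square root of the
    factor — diluting the angiogenic stimulus yields both fewer and shorter
    sprouts, which is what makes the maximal-extent height metric respond to
    dilution at all.  Returns per-chip records
    ``{chip_id, condition, spec, channels, truth}`` and a layout table; the
    factor-1.0 group is the designated control.  Per-chip sub-seeds are
    derived deterministically from ``seed`` and the chip index.
    """
    if any(not 0 < f <= 1 for f in density_factors):
        raise ValueError("density_factors must lie in (0, 1]")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if condition_labels is None:
        condition_labels = [
            "control" if f == 1.0 else f"density_{f:g}" for f in density_factors
        ]
    chips: list[dict] = []
    layout: list[dict] = []
    idx = 0
    for factor, label in zip(density_factors, condition_labels):
        for rep in range(n_replicates):
            sub_seed = int(np.random.SeedSequence([seed, idx]).generate_state(1)[0] % 2**31)
            rng = np.random.default_rng(sub_seed)
            n_spr = int(rng.poisson(base_spec.n_sprouts * factor))
            length_scale = float(np.sqrt(factor))
            spec = replace(
                base_spec,
                n_sprouts=n_spr,
                sprout_length_um_mean=base_spec.sprout_length_um_mean * length_scale,
                sprout_length_um_sd=base_spec.sprout_length_um_sd * length_scale,
                seed=sub_seed,
            )
            channels, truth = generate_chip(spec)
            chip_id = f"{label}_r{rep}"
            channels = {
                role: replace(p, chip_id=chip_id) for role, p in channels.items()
            }
            chips.append(
                {
                    "chip_id": chip_id,
                    "condition": label,
                    "spec": spec,
                    "channels": channels,
                    "truth": truth,
                }
            )
            layout.append({"chip_id": chip_id, "condition": label, "density_factor": factor})
            idx += 1
    return chips, pd.DataFrame(layout)


def write_chip_tiffs(channels: dict, out_dir: str | Path) -> list[Path]:
    """Write one 2-D TIFF per channel using the <chip_id>_<role>.tif convention."""
    import tifffile

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for role, proj in channels.items():
        p = out_dir / f"{proj.chip_id}_{role}.tif"
        tifffile.imwrite(p, proj.image)
        paths.append(p)
    return paths


# ---------------------------------------------------------------- internals


def _band_mask(h: int, w: int, top_row: np.ndarray, bottom_row: np.ndarray) -> np.ndarray:
    """Pixels whose row lies in [top_row(col), bottom_row(col))."""
    rows = np.arange(h, dtype=float)[:, None]
    return (rows >= np.asarray(top_row)[None, :]) & (rows < np.asarray(bottom_row)[None, :])


def _sample_sprout(
    rng: np.random.Generator,
    spec: SyntheticChipSpec,
    w: int,
    interface_row: np.ndarray,
) -> np.ndarray:
    """Sample one wavy sprout polyline in pixel coordinates (x, y)."""
    px = spec.pixel_size_um
    margin = max(8, int(0.05 * w))
    x0 = rng.uniform(margin, w - margin)
    length_um = np.clip(
        rng.normal(spec.sprout_length_um_mean, spec.sprout_length_um_sd),
        0.2 * spec.sprout_length_um_mean,
        spec.gel_depth_um - spec.sprout_width_um,
    )
    length_px = length_um / px
    y_start = float(np.interp(x0, np.arange(w), interface_row))
    t = np.linspace(0, 1, 32)
    amp = spec.sprout_waviness * length_px
    phase = rng.uniform(0, 2 * np.pi)
    freq = rng.uniform(1.0, 2.5)
    xs = x0 + amp * np.sin(2 * np.pi * freq * t + phase) - amp * np.sin(phase)
    ys = y_start + t * length_px
    xs = np.clip(xs, 1, w - 2)
    return np.column_stack([xs, ys])


def _rasterize_polyline(poly: np.ndarray, radius_px: float, shape: tuple[int, int]) -> np.ndarray:
    canvas = np.zeros(shape, dtype=bool)
    pts = np.round(poly).astype(int)
    for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
        rr, cc = draw.line(y0, x0, y1, x1)
        ok = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
        canvas[rr[ok], cc[ok]] = True
    r = max(1, int(round(radius_px)))
    return morphology.dilation(canvas, morphology.disk(r))


def _cumulative_arc(poly: np.ndarray) -> np.ndarray:
    seg = np.sqrt(np.sum(np.diff(poly, axis=0) ** 2, axis=1))
    return np.concatenate([[0.0], np.cumsum(seg)])


def _point_at_arc(poly: np.ndarray, arc: np.ndarray, s: float) -> tuple[float, float]:
    i = int(np.searchsorted(arc, s, side="right") - 1)
    i = min(i, len(poly) - 2)
    seg = arc[i + 1] - arc[i]
    f = 0.0 if seg == 0 else (s - arc[i]) / seg
    x = poly[i, 0] + f * (poly[i + 1, 0] - poly[i, 0])
    y = poly[i, 1] + f * (poly[i + 1, 1] - poly[i, 1])
    return float(x), float(y)


def _add_gaussian_blob(
    img: np.ndarray, x: float, y: float, sigma_px: float, amplitude: float
) -> None:
    h, w = img.shape
    r = int(np.ceil(4 * sigma_px))
    y0, y1 = max(0, int(y) - r), min(h, int(y) + r + 1)
    x0, x1 = max(0, int(x) - r), min(w, int(x) + r + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    img[y0:y1, x0:x1] += amplitude * np.exp(
        -((yy - y) ** 2 + (xx - x) ** 2) / (2 * sigma_px**2)
    )


def _make_truth(
    spec: SyntheticChipSpec,
    interface_um: float,
    top_guide: np.ndarray,
    bottom_guide: np.ndarray,
    polylines: list[np.ndarray],
    sprout_mask: np.ndarray,
    nuclei: pd.DataFrame,
) -> GroundTruth:
    px = spec.pixel_size_um
    in_gel = nuclei[nuclei["in_gel"]] if len(nuclei) else nuclei
    true_sum = float(in_gel["true_migration_um"].sum()) if len(in_gel) else 0.0
    area = float(sprout_mask.sum()) * px**2
    if sprout_mask.any():
        max_row = int(np.max(np.nonzero(sprout_mask.any(axis=1))[0]))
        height = max(0.0, max_row * px - interface_um)
    else:
        height = 0.0
    length = float(sum(_cumulative_arc(p)[-1] for p in polylines)) * px
    return GroundTruth(
        interface_y_um=interface_um,
        tilt_deg=spec.tilt_deg,
        top_guide_mask=top_guide,
        bottom_guide_mask=bottom_guide,
        sprout_polylines_px=polylines,
        sprout_mask=sprout_mask,
        nuclei=nuclei,
        true_centroid_y_sum_um=true_sum,
        true_sprout_area_um2=area,
        true_sprout_height_um=height,
        true_sprout_length_um=length,
    )


def _render_stack(
    nuclear: np.ndarray,
    actin: np.ndarray,
    spec: SyntheticChipSpec,
    rng: np.random.Generator,
    n_planes: int,
    z_step_um: float,
    chip_id: str,
) -> ChipStack:
    """Spread the 2-D images over a Gaussian z-profile (peak weight 1).

    The per-plane weight profile has maximum 1 at the focal plane so the
    maximal projection over z recovers the 2-D image (up to integer
    truncation of the dimmer planes).
    """
    z = np.arange(n_planes)
    z_focus = rng.uniform(0.3, 0.7) * n_planes
    profile = np.exp(-((z - z_focus) ** 2) / (2 * (n_planes / 6) ** 2))
    profile /= profile.max()
    planes = np.empty((n_planes, 2, *nuclear.shape), dtype=np.uint16)
    for k in range(n_planes):
        planes[k, 0] = (nuclear.astype(np.float64) * profile[k]).astype(np.uint16)
        planes[k, 1] = (actin.astype(np.float64) * profile[k]).astype(np.uint16)
    return ChipStack(
        pixels=planes,
        channel_roles=("nuclear", "actin"),
        pixel_size_um=spec.pixel_size_um,
        z_step_um=z_step_um,
        chip_id=chip_id,
    )
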