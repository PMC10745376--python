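"""End-to-end benchmark runs on synthetic plates.

Each function generates a seeded synthetic data set, runs the full analysis
pipeline on it, and measures recovery against the generator's ground truth.
They back both the validation test suite and the reproduction script, and
are the quantitative record of what the pipeline achieves on data whose
truth is known exactly.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy import ndimage as ndi

from . import nuclei_quant, reporting
from .chip_geometry import build_chip_masks
from .config import AnalysisConfig
from .image_io import planes_for_depth
from .synthetic import SyntheticChipSpec, generate_chip, generate_dose_series

#: Chip depth and z-step of the acquisition geometry being emulated (µm).
CHIP_DEPTH_UM = 200.0
Z_STEP_UM = 5.0


def _sub_seed(seed: int, index: int) -> int:
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0] % 2**31)


def acquisition_planes() -> int:
    """Planes needed to span the full chip depth at the acquisition z-step."""
    return planes_for_depth(CHIP_DEPTH_UM, Z_STEP_UM)


def mask_pipeline_accuracy(
    seed: int, n_chips: int = 20, config: AnalysisConfig | None = None
) -> dict:
    """Chip-geometry recovery on seeded chips, a fifth of them tilted by 1°.

    Returns worst-case guide-centroid error (px), worst per-column
    reference-line error (px), minimum gel coverage and maximum tube leakage
    of the ECM mask (fractions of ground-truth region pixels).
    """
    cfg = config or AnalysisConfig()
    px = cfg.pixel_size_um
    cen_errs, line_errs, coverages, leakages = [], [], [], []
    for i in range(n_chips):
        tilt = 1.0 if i % 5 == 4 else 0.0
        spec = SyntheticChipSpec(seed=_sub_seed(seed, i), tilt_deg=tilt)
        channels, truth = generate_chip(spec)
        masks = build_chip_masks(channels["nuclear"].image, cfg.geometry)

        for det, tru in (
            (masks.top_guide, truth.top_guide_mask),
            (masks.bottom_guide, truth.bottom_guide_mask),
        ):
            cd, ct = ndi.center_of_mass(det), ndi.center_of_mass(tru)
            cen_errs.append(float(np.hypot(cd[0] - ct[0], cd[1] - ct[1])))

        line = masks.reference_line
        cols = np.nonzero(line.any(axis=0))[0]
        top_rows = np.argmax(line[:, cols], axis=0)
        line_errs.append(float(np.abs(top_rows - truth.interface_row_px(cols, px)).max()))

        h, w = truth.top_guide_mask.shape
        rows = np.arange(h)[:, None]
        if_row = truth.interface_row_px(np.arange(w), px)
        gel_true = (rows >= if_row[None, :]) & (
            rows < if_row[None, :] + spec.gel_depth_um / px
        )
        tube_true = rows < (if_row[None, :] - spec.guide_thickness_um / px)
        coverages.append(float((masks.ecm_mask & gel_true).sum() / gel_true.sum()))
        leakages.append(float((masks.ecm_mask & tube_true).sum() / tube_true.sum()))
    return {
        "n_chips": n_chips,
        "max_guide_centroid_err_px": max(cen_errs),
        "max_reference_line_err_px": max(line_errs),
        "min_gel_coverage": min(coverages),
        "max_tube_leakage": max(leakages),
    }


def statistic_recovery(
    seed: int, n_chips: int = 20, config: AnalysisConfig | None = None
) -> dict:
    """Nuclei Centroid Y Sum recovery across sprout densities.

    Chips cycle through density factors 1.0 / 0.5 / 0.25; the pipeline's
    statistic is compared with the generator's true per-chip sum.  A chip
    with no gel nuclei must yield exactly zero.
    """
    cfg = config or AnalysisConfig()
    factors = (1.0, 0.5, 0.25)
    errs = []
    for i in range(n_chips):
        f = factors[i % len(factors)]
        spec = SyntheticChipSpec(
            seed=_sub_seed(seed, 1000 + i), n_sprouts=max(1, round(10 * f))
        )
        channels, truth = generate_chip(spec)
        res = reporting.run_chip(channels, cfg)
        est = res.metrics["nuclei_centroid_y_sum_um"]
        errs.append(100.0 * (est / truth.true_centroid_y_sum_um - 1.0))

    empty_spec = SyntheticChipSpec(
        seed=_sub_seed(seed, 1999), n_sprouts=0, nuclei_per_sprout_mean=0.0
    )
    channels, _ = generate_chip(empty_spec)
    zero_stat = reporting.run_chip(channels, cfg).metrics["nuclei_centroid_y_sum_um"]
    return {
        "n_chips": n_chips,
        "max_abs_err_pct": max(abs(e) for e in errs),
        "mean_err_pct": float(np.mean(errs)),
        "zero_gel_nuclei_statistic_um": zero_stat,
    }


def misalignment_robustness(
    seed: int,
    n_chips: int = 100,
    y_jitter_um: float = 30.0,
    config: AnalysisConfig | None = None,
) -> dict:
    """Refined vs legacy statistic on a misaligned plate.

    Simulates chips whose true interface jitters by ±``y_jitter_um`` around
    the nominal 400 µm, then compares the across-chip coefficient of
    variation of the per-chip-reference-line statistic with the legacy
    constant-400 µm-offset statistic computed on the same detected nuclei.
    Also verifies exact agreement of the two on one perfectly aligned chip.
    """
    cfg = config or AnalysisConfig()
    px = cfg.pixel_size_um
    refined, legacy = [], []
    for i in range(n_chips):
        spec = SyntheticChipSpec(seed=_sub_seed(seed, 2000 + i), y_jitter_um=y_jitter_um)
        channels, _ = generate_chip(spec)
        masks = build_chip_masks(channels["nuclear"].image, cfg.geometry)
        nuclei = nuclei_quant.find_nuclei(channels["nuclear"].image, masks, cfg.nuclei, px)
        refined.append(nuclei_quant.nuclei_centroid_y_sum(nuclei))
        legacy.append(
            nuclei_quant.legacy_constant_offset_sum(nuclei.centroids[:, 1], px, 400.0)
        )
    refined_a, legacy_a = np.asarray(refined), np.asarray(legacy)

    def cv(x: np.ndarray) -> float:
        return float(x.std(ddof=1) / x.mean() * 100.0)

    channels, _ = generate_chip(SyntheticChipSpec(seed=_sub_seed(seed, 2999)))
    masks = build_chip_masks(channels["nuclear"].image, cfg.geometry)
    nuclei = nuclei_quant.find_nuclei(channels["nuclear"].image, masks, cfg.nuclei, px)
    agree = np.isclose(
        nuclei_quant.nuclei_centroid_y_sum(nuclei),
        nuclei_quant.legacy_constant_offset_sum(nuclei.centroids[:, 1], px, 400.0),
        rtol=0,
        atol=1e-9,
    )
    return {
        "n_chips": n_chips,
        "cv_reference_line_pct": cv(refined_a),
        "cv_legacy_400um_pct": cv(legacy_a),
        "aligned_chip_exact_agreement": bool(agree),
    }


def dose_response(seed: int, config: AnalysisConfig | None = None) -> dict:
    """Dilution-series ordering and twofold-effect recovery.

    A 1.0/0.5/0.25 density series (4 replicates each) is analysed end to
    end; all four metrics must decrease strictly with density.  A separate
    treated group at exactly twice the control sprout density measures how
    well a twofold effect is recovered in % of control.
    """
    cfg = config or AnalysisConfig()
    base = SyntheticChipSpec()
    chips, _ = generate_dose_series(base, [1.0, 0.5, 0.25], 4, seed=_sub_seed(seed, 3000))
    results = [
        reporting.run_chip(c["channels"], cfg, condition=c["condition"]) for c in chips
    ]
    report = reporting.normalize_and_aggregate(results, control_label="control")
    r = report.conditions.set_index("condition")
    order = ["control", "density_0.5", "density_0.25"]
    metrics = (
        "sprout_area_um2",
        "sprout_height_um",
        "sprout_length_um",
        "nuclei_centroid_y_sum_um",
    )
    violations = 0
    for col in metrics:
        vals = [float(r.loc[c, f"{col}_mean"]) for c in order]
        if not (vals[0] > vals[1] > vals[2]):
            violations += 1

    results2 = []
    for i in range(4):
        channels, _ = generate_chip(
            replace(base, n_sprouts=10, seed=_sub_seed(seed, 3100 + i))
        )
        results2.append(reporting.run_chip(channels, cfg, condition="control"))
    for i in range(4):
        channels, _ = generate_chip(
            replace(base, n_sprouts=20, seed=_sub_seed(seed, 3200 + i))
        )
        results2.append(reporting.run_chip(channels, cfg, condition="treated"))
    rep2 = reporting.normalize_and_aggregate(results2, control_label="control")
    twofold = float(
        rep2.conditions.set_index("condition").loc[
            "treated", "nuclei_centroid_y_sum_um_pct_control_mean"
        ]
    )
    return {
        "ordering_violations": violations,
        "twofold_recovery_pct_of_control": twofold,
    }


def determinism_check(seed: int, config: AnalysisConfig | None = None) -> dict:
    """Analyse the same two-chip plate twice; reports are compared byte-wise."""
    import tempfile
    from pathlib import Path

    from .cli import write_report

    cfg = config or AnalysisConfig()
    chips, _ = generate_dose_series(
        SyntheticChipSpec(), [1.0, 0.5], 1, seed=_sub_seed(seed, 4000)
    )
    blobs = []
    for run in range(2):
        results = [
            reporting.run_chip(c["channels"], cfg, condition=c["condition"])
            for c in chips
        ]
        report = reporting.normalize_and_aggregate(results, control_label="control")
        with tempfile.TemporaryDirectory() as d:
            write_report(report, cfg, Path(d))
            blobs.append((Path(d) / "chips.csv").read_bytes())
    return {"identical_chip_tables": bool(blobs[0] == blobs[1])}
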