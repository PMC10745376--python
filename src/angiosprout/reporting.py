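"""Per-chip pipeline orchestration, control normalization and aggregation.

``run_chip`` composes the stages in order — maximal projection → chip
geometry → sprout network → nuclei → metrics — and converts any stage
failure into a QC flag on the result rather than a crash, so a bad chip
never takes down a plate run.  ``normalize_and_aggregate`` then expresses
every metric as % of the designated control condition's mean and reports
mean ± SD with n per condition, the convention of the assay's figures.
QC-flagged chips are excluded from aggregates but kept in the per-chip
table so replicate attrition stays visible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import chip_geometry, image_io, nuclei_quant, sprout_quant
from .config import AnalysisConfig

logger = logging.getLogger(__name__)

METRIC_COLUMNS = (
    "sprout_area_um2",
    "sprout_height_um",
    "sprout_length_um",
    "n_nuclei_gel",
    "nuclei_centroid_y_sum_um",
    "mean_migration_um",
    "max_migration_um",
)


class AnalysisError(RuntimeError):
    """Plate-level analysis cannot proceed (e.g. no usable control chips)."""


@dataclass
class ChipResult:
    """All metrics of one chip, or QC flags when a stage failed."""

    chip_id: str
    condition: str = ""
    metrics: dict = field(default_factory=dict)
    qc_flags: list = field(default_factory=list)
    reference_y_px: int | None = None

    @property
    def ok(self) -> bool:
        return not self.qc_flags

    def to_row(self) -> dict:
        row: dict = {"chip_id": self.chip_id, "condition": self.condition}
        for col in METRIC_COLUMNS:
            row[col] = self.metrics.get(col, np.nan)
        row["reference_y_px"] = self.reference_y_px
        row["qc_flags"] = ";".join(self.qc_flags)
        return row


@dataclass(frozen=True)
class PlateReport:
    """Per-chip table plus per-condition aggregates normalized to control."""

    chips: pd.DataFrame
    conditions: pd.DataFrame
    control_label: str


def run_chip(
    inputs: image_io.ChipStack | dict,
    config: AnalysisConfig,
    condition: str = "",
) -> ChipResult:
    """Run the full per-chip pipeline; stage failures become QC flags.

    ``inputs`` is either a :class:`~angiosprout.image_io.ChipStack` or a dict
    of pre-computed projections ``{"nuclear": Projection, "actin": Projection}``.
    """
    if isinstance(inputs, image_io.ChipStack):
        nuclear = image_io.max_project(inputs, "nuclear")
        actin = image_io.max_project(inputs, "actin")
        chip_id = inputs.chip_id
    else:
        nuclear, actin = inputs["nuclear"], inputs["actin"]
        chip_id = nuclear.chip_id
    result = ChipResult(chip_id=chip_id, condition=condition)

    nuc_img = nuclear.image[::-1] if config.flip_y else nuclear.image
    act_img = actin.image[::-1] if config.flip_y else actin.image

    try:
        masks = chip_geometry.build_chip_masks(nuc_img, config.geometry)
    except (chip_geometry.GuideDetectionError, chip_geometry.GeometryError) as exc:
        logger.warning("%s: guide detection failed: %s", chip_id, exc)
        result.qc_flags.append("guide_detection_failed")
        return result
    result.reference_y_px = masks.reference_y_px
    logger.info(
        "%s: geometry ok (reference_y_px=%d, ecm_px=%d)",
        chip_id,
        masks.reference_y_px,
        int(masks.ecm_mask.sum()),
    )

    try:
        network = sprout_quant.find_sprouts(
            act_img, masks, config.sprouts, config.pixel_size_um
        )
        nuclei = nuclei_quant.find_nuclei(
            nuc_img, masks, config.nuclei, config.pixel_size_um, chip_id=chip_id
        )
    except chip_geometry.GeometryError as exc:
        logger.warning("%s: quantification failed: %s", chip_id, exc)
        result.qc_flags.append("quantification_failed")
        return result

    migration = nuclei.migration_um
    result.metrics = {
        "sprout_area_um2": network.sprout_area_um2,
        "sprout_height_um": network.sprout_height_um,
        "sprout_length_um": network.sprout_length_um,
        "n_nuclei_gel": len(nuclei),
        "nuclei_centroid_y_sum_um": nuclei_quant.nuclei_centroid_y_sum(nuclei),
        "mean_migration_um": float(migration.mean()) if len(migration) else 0.0,
        "max_migration_um": float(migration.max()) if len(migration) else 0.0,
    }
    logger.info(
        "%s: %d gel nuclei, centroid-Y sum %.1f um",
        chip_id,
        len(nuclei),
        result.metrics["nuclei_centroid_y_sum_um"],
    )
    return result


def normalize_and_aggregate(
    results: list[ChipResult], control_label: str
) -> PlateReport:
    """Normalize every metric to the control-condition mean (=100 %).

    Per condition: mean, SD (n >= 2 only) and n over non-QC-flagged chips.
    A warning is logged for conditions with fewer than four usable
    replicates — the recommended minimum given chip-to-chip variability.
    """
    chips = pd.DataFrame([r.to_row() for r in results])
    usable = chips[chips["qc_flags"] == ""]
    control = usable[usable["condition"] == control_label]
    if control.empty:
        raise AnalysisError(
            f"no usable chips in control condition {control_label!r}"
        )
    control_means = control[list(METRIC_COLUMNS)].mean()

    for col in METRIC_COLUMNS:
        denom = control_means[col]
        chips[f"{col}_pct_control"] = (
            chips[col] / denom * 100.0 if denom else np.nan
        )

    rows = []
    for cond, grp in usable.groupby("condition", sort=True):
        n = len(grp)
        if n < 4:
            logger.warning(
                "condition %r has only %d usable replicate(s); at least four "
                "technical replicates are recommended",
                cond,
                n,
            )
        row: dict = {"condition": cond, "n": n}
        for col in METRIC_COLUMNS:
            denom = control_means[col]
            vals = grp[col]
            row[f"{col}_mean"] = vals.mean()
            row[f"{col}_sd"] = vals.std(ddof=1) if n >= 2 else np.nan
            row[f"{col}_pct_control_mean"] = (
                vals.mean() / denom * 100.0 if denom else np.nan
            )
            row[f"{col}_pct_control_sd"] = (
                vals.std(ddof=1) / denom * 100.0 if (denom and n >= 2) else np.nan
            )
        rows.append(row)
    conditions = pd.DataFrame(rows)
    return PlateReport(chips=chips, conditions=conditions, control_label=control_label)
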