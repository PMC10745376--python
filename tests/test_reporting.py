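import numpy as np
import pytest

from angiosprout import SyntheticChipSpec, generate_chip
from angiosprout.config import AnalysisConfig, ConfigError, load_config
from angiosprout.reporting import (
    AnalysisError,
    ChipResult,
    normalize_and_aggregate,
    run_chip,
)


def result(chip_id, condition, stat, flags=()):
    metrics = (
        {}
        if flags
        else {
            "sprout_area_um2": stat * 3,
            "sprout_height_um": 100.0,
            "sprout_length_um": stat * 2,
            "n_nuclei_gel": 10,
            "nuclei_centroid_y_sum_um": stat,
            "mean_migration_um": stat / 10,
            "max_migration_um": stat / 5,
        }
    )
    return ChipResult(
        chip_id=chip_id, condition=condition, metrics=metrics, qc_flags=list(flags)
    )


class TestRunChip:
    def test_control_chip_fully_populated(self, default_chip, config):
        channels, _ = default_chip
        res = run_chip(channels, config, condition="control")
        assert res.ok
        assert res.reference_y_px is not None
        assert res.metrics["n_nuclei_gel"] > 0
        assert res.metrics["nuclei_centroid_y_sum_um"] > 0
        assert res.metrics["sprout_area_um2"] > 0

    def test_blank_chip_is_qc_flagged_not_crashed(self, config):
        from angiosprout.image_io import Projection

        blank = {
            role: Projection(np.zeros((200, 200), np.uint16), role, 2.0, "blank")
            for role in ("nuclear", "actin")
        }
        res = run_chip(blank, config)
        assert res.qc_flags == ["guide_detection_failed"]
        assert res.metrics == {}

    def test_guides_but_empty_gel_gives_zero_metrics(self, config):
        channels, _ = generate_chip(
            SyntheticChipSpec(seed=6, n_sprouts=0, nuclei_per_sprout_mean=0.0)
        )
        res = run_chip(channels, config)
        assert res.ok
        assert res.metrics["sprout_area_um2"] == 0.0
        assert res.metrics["nuclei_centroid_y_sum_um"] == 0.0

    def test_stack_input(self, config):
        stacked, _ = generate_chip(SyntheticChipSpec(seed=1), as_stack=True)
        res = run_chip(stacked["stack"], config)
        assert res.ok
        assert res.metrics["n_nuclei_gel"] > 0


class TestNormalizeAndAggregate:
    def test_treated_normalized_mean(self):
        results = [
            result("c1", "DMSO", 100.0),
            result("c2", "DMSO", 120.0),
            result("c3", "DMSO", 80.0),
            result("t1", "drug", 200.0),
            result("t2", "drug", 220.0),
            result("t3", "drug", 180.0),
        ]
        rep = normalize_and_aggregate(results, control_label="DMSO")
        r = rep.conditions.set_index("condition")
        assert r.loc["drug", "nuclei_centroid_y_sum_um_pct_control_mean"] == pytest.approx(200.0)
        assert r.loc["DMSO", "nuclei_centroid_y_sum_um_pct_control_mean"] == pytest.approx(100.0)
        assert r.loc["DMSO", "n"] == 3

    def test_control_only_plate(self):
        results = [result("c1", "DMSO", 90.0), result("c2", "DMSO", 110.0)]
        rep = normalize_and_aggregate(results, control_label="DMSO")
        r = rep.conditions.set_index("condition")
        assert r.loc["DMSO", "nuclei_centroid_y_sum_um_pct_control_mean"] == pytest.approx(100.0)
        assert r.loc["DMSO", "nuclei_centroid_y_sum_um_sd"] == pytest.approx(
            np.std([90, 110], ddof=1)
        )

    def test_scale_invariance(self):
        base = [result(f"c{i}", "DMSO", v) for i, v in enumerate([100, 120, 80])]
        base += [result(f"t{i}", "drug", v) for i, v in enumerate([150, 170, 160])]
        scaled = [
            result(r.chip_id, r.condition, r.metrics["nuclei_centroid_y_sum_um"] * 7.5)
            for r in base
        ]
        a = normalize_and_aggregate(base, "DMSO").conditions
        b = normalize_and_aggregate(scaled, "DMSO").conditions
        cols = [c for c in a.columns if c.endswith("pct_control_mean")]
        np.testing.assert_allclose(a[cols].values, b[cols].values)

    def test_permutation_invariance(self):
        results = [result(f"c{i}", "DMSO", 100 + i) for i in range(3)]
        results += [result(f"t{i}", "drug", 180 + i) for i in range(3)]
        a = normalize_and_aggregate(results, "DMSO").conditions
        b = normalize_and_aggregate(results[::-1], "DMSO").conditions
        np.testing.assert_allclose(
            a.drop(columns="condition").values, b.drop(columns="condition").values
        )

    def test_qc_flagged_chips_listed_but_excluded(self):
        results = [
            result("c1", "DMSO", 100.0),
            result("c2", "DMSO", 120.0),
            result("bad", "DMSO", 0.0, flags=("guide_detection_failed",)),
        ]
        rep = normalize_and_aggregate(results, "DMSO")
        assert len(rep.chips) == 3
        assert rep.conditions.set_index("condition").loc["DMSO", "n"] == 2

    def test_fully_flagged_control_is_analysis_error(self):
        results = [result("bad", "DMSO", 0.0, flags=("guide_detection_failed",))]
        with pytest.raises(AnalysisError):
            normalize_and_aggregate(results, "DMSO")


class TestConfig:
    def test_yaml_roundtrip(self, tmp_path):
        cfg = AnalysisConfig()
        p = tmp_path / "cfg.yaml"
        cfg.dump_yaml(p)
        loaded = load_config(p)
        assert loaded == cfg

    def test_overrides_take_precedence(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("pixel_size_um: 1.5\ngeometry:\n  shrink_px: 4\n")
        cfg = load_config(p, overrides={"pixel_size_um": 3.0})
        assert cfg.pixel_size_um == 3.0
        assert cfg.geometry.shrink_px == 4

    def test_unknown_key_names_path(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("geometry:\n  shrink_pixels: 4\n")
        with pytest.raises(ConfigError, match="geometry.shrink_pixels"):
            load_config(p)

    def test_invalid_parameter_value(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("geometry:\n  area_min_px: 500\n  area_max_px: 100\n")
        with pytest.raises(ConfigError, match="geometry"):
            load_config(p)
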