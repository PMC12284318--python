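import dataclasses

import numpy as np
import pandas as pd
import pytest

from rwemri.regstatus import StatusConfig, assign_all
from rwemri.synthdata import (
    ROIS,
    SchemaError,
    SimConfig,
    read_tables,
    simulate_analysis_rows,
    simulate_cohort,
    write_tables,
)

SMALL = dict(cohorts={"OSTPRE": 80, "ADNI": 40})


# ---------------------------------------------------------------------------
# config validation


class TestConfigValidation:
    @pytest.mark.parametrize("field,value", [
        ("outlier_rate", 1.5),
        ("subquality_rate", -0.1),
        ("residual_sd", -1.0),
        ("quality_threshold", 0.0),
    ])
    def test_bad_values_rejected_naming_field(self, field, value):
        with pytest.raises(ValueError, match=field):
            SimConfig(**{field: value})

    def test_inconsistent_participant_total_rejected(self):
        with pytest.raises(ValueError, match="n_participants"):
            SimConfig(cohorts={"A": 10}, n_participants=11)

    def test_missing_transition_rejected(self):
        with pytest.raises(ValueError, match="MCI>D"):
            SimConfig(status_transition_rates={"NMC>SMC": 0.1, "SMC>MCI": 0.1})


# ---------------------------------------------------------------------------
# generation contracts


class TestSimulate:
    def test_zero_outlier_rate_gives_no_outliers(self):
        sim = simulate_cohort(SimConfig(**SMALL, outlier_rate=0.0, seed=1))
        assert not sim.truth.per_scan["true_outlier"].any()

    def test_deterministic_given_seed(self):
        cfg = SimConfig(**SMALL, seed=7)
        a, b = simulate_cohort(cfg), simulate_cohort(cfg)
        for name in a.tables():
            pd.testing.assert_frame_equal(a.tables()[name], b.tables()[name])

    def test_every_scan_appears_once_in_ground_truth(self):
        sim = simulate_cohort(SimConfig(**SMALL, seed=2))
        assert sim.truth.per_scan["scan_id"].is_unique
        assert set(sim.truth.per_scan["scan_id"]) == set(sim.scans["scan_id"])
        assert sim.participants["participant_id"].is_unique

    def test_null_model_equalises_status_means(self):
        """With all systematic terms off, per-ROI mean volumes are equal
        across status categories up to simulation error."""
        zero = {r: {"NMC": 0.0, "SMC": 0.0, "MCI": 0.0, "D": 0.0} for r in ROIS}
        cfg = SimConfig(
            cohorts={"OSTPRE": 700},
            effect_sizes=zero,
            random_intercept_sd=0.0,
            scanner_offsets={"Siemens": 0, "Philips": 0, "GE": 0, "Toshiba": 0},
            field_offsets={1.5: 0, 3.0: 0},
            age_slope_ml={r: 0.0 for r in ROIS},
            tiv_slope={r: 0.0 for r in ROIS},
            seed=3,
        )
        sim = simulate_cohort(cfg)
        df = sim.volumes.merge(sim.truth.per_scan[["scan_id", "true_status"]], on="scan_id")
        for roi, col in (("gm", "gm_a"),):
            groups = df.groupby("true_status")[col]
            means, counts = groups.mean(), groups.count()
            sd = df[col].std(ddof=1)
            grand = df[col].mean()
            for status, m in means.items():
                tol = 4 * sd / np.sqrt(counts[status])
                assert abs(m - grand) < tol, (roi, status)

    def test_configured_effects_recovered_on_large_simulation(self):
        """Per-status means of the noise-standardized volume component match
        the configured standardized shifts within 3 Monte-Carlo SEs."""
        cfg = SimConfig(
            cohorts={"OSTPRE": 1800},
            scanner_offsets={"Siemens": 0, "Philips": 0, "GE": 0, "Toshiba": 0},
            field_offsets={1.5: 0, 3.0: 0},
            seed=4,
        )
        sim = simulate_cohort(cfg)
        assert len(sim.volumes) >= 5000
        scans = sim.scans.merge(
            sim.participants[["participant_id", "birth_date"]], on="participant_id"
        )
        age = (scans["acquisition_date"] - scans["birth_date"]).dt.days / 365.25
        df = sim.volumes.merge(sim.truth.per_scan[["scan_id", "true_status"]], on="scan_id")
        for roi, col in (("gm", "gm_a"), ("ventricles", None)):
            total = (
                df[col]
                if col
                else df[["vent_llat_a", "vent_rlat_a", "vent_linf_a", "vent_rinf_a"]].sum(axis=1)
            )
            da = age.to_numpy() - cfg.age_center
            z = (
                total.to_numpy()
                - cfg.roi_baseline_ml[roi]
                - cfg.tiv_slope[roi] * (df["tiv"].to_numpy() - cfg.tiv_mean_sd[0])
                - cfg.age_slope_ml[roi] * da
            ) / cfg.roi_scale_ml[roi]
            zs = pd.Series(z).groupby(df["true_status"])
            n_part = df.merge(sim.scans[["scan_id", "participant_id"]], on="scan_id")
            for status, m in zs.mean().items():
                grp_sd = zs.std().loc[status]
                n_clusters = n_part.loc[
                    df["true_status"] == status, "participant_id"
                ].nunique()
                se = grp_sd / np.sqrt(n_clusters)
                assert abs(m - cfg.effect_sizes[roi][status]) < 3 * se, (roi, status)

    def test_subquality_fraction_converges_to_rate(self):
        cfg = SimConfig(cohorts={"OSTPRE": 800}, subquality_rate=0.1, seed=5)
        sim = simulate_cohort(cfg)
        frac = (sim.volumes["quality_pct"] < cfg.quality_threshold).mean()
        n = len(sim.volumes)
        assert abs(frac - 0.1) < 4 * np.sqrt(0.1 * 0.9 / n)
        # truth flag agrees exactly with the generated percentage
        truth = sim.truth.per_scan.set_index("scan_id")["true_subquality"]
        below = sim.volumes.set_index("scan_id")["quality_pct"] < cfg.quality_threshold
        assert (truth.sort_index() == below.sort_index()).all()

    def test_zero_reporting_delay_classification_equals_latent_truth(self):
        """With no recording lag (and no repeat events), register-derived
        baseline status reproduces the latent truth at every scan date."""
        cfg = SimConfig(
            **SMALL,
            reporting_delay_days={"shape": 2.0, "scale": 0.0},
            repeat_event_rate=0.0,
            seed=6,
        )
        sim = simulate_cohort(cfg)
        out = assign_all(
            sim.scans, sim.events, config=StatusConfig(upgrade_policy="none")
        )
        merged = out.merge(
            sim.truth.per_scan[["scan_id", "true_status"]], on="scan_id"
        )
        assert (merged["status"] == merged["true_status"]).all()

    def test_pipeline_b_is_a_plus_noise_except_outliers(self):
        cfg = SimConfig(**SMALL, outlier_rate=0.05, seed=8)
        sim = simulate_cohort(cfg)
        truth = sim.truth.per_scan.set_index("scan_id")
        v = sim.volumes.set_index("scan_id")
        clean = truth.loc[~truth["true_outlier"]].index
        resid = (v.loc[clean, "gm_b"] - v.loc[clean, "gm_a"]).abs()
        assert resid.max() < 6 * cfg.interpipeline_noise_sd["gm"]
        out_gm = truth.loc[truth["true_outlier"] & (truth["outlier_roi"] == "gm")].index
        if len(out_gm):
            d = (v.loc[out_gm, "gm_b"] - v.loc[out_gm, "gm_a"]).abs()
            assert (d > 0.5 * cfg.outlier_displacement["gm"]).all()


# ---------------------------------------------------------------------------
# analysis-row generator


class TestAnalysisRows:
    def test_requested_size_and_clustering(self):
        rows = simulate_analysis_rows(
            500, {"NMC": 0, "SMC": 0, "MCI": 0, "D": 0}, dup_rate=0.3, seed=1
        )
        assert len(rows) == 500
        sizes = rows.groupby("participant_id").size()
        assert sizes.max() <= 2 and (sizes == 2).any()

    def test_effects_shift_group_means(self):
        rows = simulate_analysis_rows(
            4000, {"NMC": 0.0, "D": -1.0}, status_probs={"NMC": 0.5, "D": 0.5},
            intercept_sd=0.0, residual_sd=0.5, seed=2,
        )
        diff = rows.groupby("status")["y"].mean()
        assert diff["NMC"] - diff["D"] == pytest.approx(1.0, abs=0.1)


# ---------------------------------------------------------------------------
# table I/O


class TestTableIO:
    def test_round_trip_lossless(self, tmp_path, small_cohort):
        _, sim = small_cohort
        tables = sim.tables()
        write_tables(tables, tmp_path)
        back = read_tables(tmp_path)
        for name, df in tables.items():
            pd.testing.assert_frame_equal(back[name], df, check_dtype=True)

    def test_missing_column_schema_error(self, tmp_path, small_cohort):
        _, sim = small_cohort
        broken = sim.scans.drop(columns=["slice_count"])
        with pytest.raises(SchemaError, match="slice_count"):
            write_tables({"scan_metadata": broken}, tmp_path)

    def test_extra_column_schema_error_on_read(self, tmp_path, small_cohort):
        _, sim = small_cohort
        write_tables({"scan_metadata": sim.scans}, tmp_path)
        path = tmp_path / "scan_metadata.csv"
        df = pd.read_csv(path)
        df["rogue"] = 1
        df.to_csv(path, index=False)
        with pytest.raises(SchemaError, match="rogue"):
            read_tables(tmp_path, ["scan_metadata"])

    def test_empty_table_with_header_accepted(self, tmp_path):
        sim = simulate_cohort(SimConfig(cohorts={"OSTPRE": 0, "ADNI": 0}))
        write_tables(sim.tables(), tmp_path)
        back = read_tables(tmp_path)
        assert len(back["scan_metadata"]) == 0
        assert list(back["scan_metadata"].columns) == list(sim.scans.columns)
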