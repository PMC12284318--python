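import numpy as np
import pandas as pd
import pytest

from rwemri.synthdata import simulate_analysis_rows
from rwemri.volmodel import (
    ModelConfig,
    VolumetricContrastModel,
    build_spline,
    standardize,
)

NULL_EFFECTS = {"NMC": 0.0, "SMC": 0.0, "MCI": 0.0, "D": 0.0}


def rows_fixture(n=200, seed=0, effects=None, **kw):
    return simulate_analysis_rows(n, effects or NULL_EFFECTS, seed=seed, **kw)


# ---------------------------------------------------------------------------
# standardization


class TestStandardize:
    def test_known_values(self):
        z, mean, sd = standardize([2, 4, 6])
        assert np.allclose(z, [-1, 0, 1])
        assert (mean, sd) == (4.0, 2.0)

    def test_idempotent(self):
        x = np.random.default_rng(0).normal(3, 7, 100)
        z1, _, _ = standardize(x)
        z2, m, s = standardize(z1)
        assert np.allclose(z1, z2, atol=1e-12)
        assert abs(m) < 1e-12 and abs(s - 1) < 1e-12

    def test_inverse_round_trip(self):
        x = np.random.default_rng(1).normal(-4, 0.3, 50)
        z, m, s = standardize(x)
        assert np.allclose(z * s + m, x, atol=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError):
            standardize([3.0, 3.0, 3.0])
        with pytest.raises(ValueError):
            standardize([1.0])


# ---------------------------------------------------------------------------
# splines


class TestSpline:
    @pytest.mark.parametrize("n_knots", [0, 1, 3, 5])
    def test_partition_of_unity(self, n_knots):
        rng = np.random.default_rng(2)
        x = rng.uniform(60, 90, 300)
        basis, M = build_spline(x, n_knots)
        assert np.allclose(M.sum(axis=1), 1.0, atol=1e-10)
        # also at fresh points inside the range, including both boundaries
        xs = np.concatenate([[x.min(), x.max()], rng.uniform(x.min(), x.max(), 500)])
        assert np.allclose(basis.design(xs).sum(axis=1), 1.0, atol=1e-10)

    def test_cubic_polynomial_reproduction_zero_knots(self):
        x = np.linspace(1, 5, 60)
        y = x**3 - 2 * x**2 + 4
        _, M = build_spline(x, 0)
        coef, *_ = np.linalg.lstsq(M, y, rcond=None)
        assert np.max(np.abs(M @ coef - y)) < 1e-8

    def test_no_extrapolation(self):
        basis, _ = build_spline(np.linspace(0, 1, 30), 2)
        with pytest.raises(ValueError, match="boundary"):
            basis.design([1.5])

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="at least"):
            build_spline(np.arange(4.0), 3)

    def test_basis_column_count(self):
        basis, M = build_spline(np.linspace(0, 1, 50), 3)
        assert basis.n_columns == 3 + 3 + 1 == M.shape[1]


# ---------------------------------------------------------------------------
# sandwich covariance


def hand_sandwich(X, y, groups, cov_type="CR1"):
    """The clustered sandwich written out as plain matrix arithmetic."""
    n, k = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    e = y - X @ beta
    labels = pd.unique(groups)
    meat = np.zeros((k, k))
    for g in labels:
        Xg = X[groups == g]
        eg = e[groups == g]
        s = Xg.T @ eg
        meat += np.outer(s, s)
    G = len(labels)
    c = (G / (G - 1)) * ((n - 1) / (n - k)) if cov_type == "CR1" else 1.0
    return c * XtX_inv @ meat @ XtX_inv, beta


class TestSandwich:
    def ten_row_fixture(self):
        # 10 observations, 3 participant clusters, two status groups
        return pd.DataFrame(
            {
                "participant_id": ["a"] * 4 + ["b"] * 3 + ["c"] * 3,
                "status": ["NMC", "NMC", "D", "D", "NMC", "D", "D", "NMC", "NMC", "D"],
                "cohort": ["OSTPRE"] * 10,
                "age": [70, 71, 72, 73, 74, 75, 76, 77, 78, 79.0],
                "tiv_std": [0.1, -0.2, 0.3, 0.0, -0.1, 0.2, -0.3, 0.1, 0.0, -0.2],
                "manufacturer": ["S", "S", "P", "P", "S", "S", "P", "S", "P", "S"],
                "field_strength": [1.5, 1.5, 3.0, 3.0, 1.5, 1.5, 3.0, 1.5, 3.0, 1.5],
                "y": [0.3, -0.1, -0.8, -1.2, 0.5, -0.9, -1.1, 0.2, 0.4, -1.0],
            }
        )

    @pytest.mark.parametrize("cov_type", ["CR0", "CR1"])
    def test_matches_hand_computation(self, cov_type):
        data = self.ten_row_fixture()
        cfg = ModelConfig(include_covariates=False, cov_type=cov_type)
        res = VolumetricContrastModel(data, config=cfg).fit()
        X = res.model._X
        V, beta = hand_sandwich(
            X, data["y"].to_numpy(), data["participant_id"].to_numpy(), cov_type
        )
        assert np.max(np.abs(res.cov_params.to_numpy() - V)) < 1e-10
        assert np.max(np.abs(res.params.to_numpy() - beta)) < 1e-12

    def test_matches_statsmodels_cluster(self):
        sm = pytest.importorskip("statsmodels.api")
        data = rows_fixture(n=150, seed=4)
        res = VolumetricContrastModel(data).fit()
        X, y = res.model._X, data["y"].to_numpy()
        ref = sm.OLS(y, X).fit(
            cov_type="cluster",
            cov_kwds={"groups": pd.factorize(data["participant_id"])[0]},
        )
        assert np.max(np.abs(res.cov_params.to_numpy() - ref.cov_params())) < 1e-10

    def test_singleton_clusters_equal_hc1(self):
        """With one row per cluster the CR1 covariance is exactly the
        heteroskedasticity-robust HC1 covariance."""
        sm = pytest.importorskip("statsmodels.api")
        data = rows_fixture(n=120, seed=5, dup_rate=0.0)
        assert data["participant_id"].nunique() == len(data)
        res = VolumetricContrastModel(data).fit()
        ref = sm.OLS(data["y"].to_numpy(), res.model._X).fit(cov_type="HC1")
        assert np.max(np.abs(res.cov_params.to_numpy() - ref.cov_params())) < 1e-12

    def test_sandwich_close_to_classical_under_independence(self):
        """On independent homoskedastic data the mean sandwich SE tracks the
        empirical sampling SD of the NMC-D contrast (simulation oracle)."""
        ests, ses = [], []
        for rep in range(250):
            data = rows_fixture(n=150, seed=1000 + rep, dup_rate=0.0, intercept_sd=0.0)
            res = VolumetricContrastModel(data).fit()
            c = res.contrast("NMC", "D", "OSTPRE")
            ests.append(c["estimate"]); ses.append(c["se"])
        assert np.mean(ses) == pytest.approx(np.std(ests, ddof=1), rel=0.12)

    def test_rank_deficiency_and_single_cluster_errors(self):
        data = self.ten_row_fixture()
        # manufacturer perfectly aliased with field strength -> rank deficient
        data["manufacturer"] = np.where(data["field_strength"] == 1.5, "S", "P")
        with pytest.raises(ValueError, match="rank-deficient"):
            VolumetricContrastModel(
                data, config=ModelConfig(n_knots_age=0, n_knots_tiv=0)
            ).fit()
        one = self.ten_row_fixture().assign(participant_id="a")
        with pytest.raises(ValueError, match="cluster"):
            VolumetricContrastModel(one, config=ModelConfig(include_covariates=False)).fit()


# ---------------------------------------------------------------------------
# margins


class TestMargins:
    def test_unadjusted_margin_equals_cell_mean(self):
        data = rows_fixture(n=120, seed=6)
        res = VolumetricContrastModel(
            data, config=ModelConfig(include_covariates=False)
        ).fit()
        for status in ("NMC", "D"):
            cell = data.loc[(data["status"] == status)]
            est, _ = res.predictive_margin(status, "OSTPRE")
            assert est == pytest.approx(cell["y"].mean(), abs=1e-10)

    def test_margins_invariant_to_row_order(self):
        data = rows_fixture(n=150, seed=7)
        a = VolumetricContrastModel(data).fit().margins()
        shuffled = data.sample(frac=1, random_state=1).reset_index(drop=True)
        b = VolumetricContrastModel(shuffled).fit().margins()
        pd.testing.assert_frame_equal(
            a.sort_values(["status", "cohort"]).reset_index(drop=True),
            b.sort_values(["status", "cohort"]).reset_index(drop=True),
            atol=1e-10, rtol=0,
        )

    def test_frequency_weighted_margins_equal_mean_fitted(self):
        data = rows_fixture(n=180, seed=8)
        res = VolumetricContrastModel(data).fit()
        total = 0.0
        for s, c in res.model.cells:
            w = ((data["status"] == s) & (data["cohort"] == c)).mean()
            total += w * res.predictive_margin(s, c)[0]
        fitted_mean = float(np.mean(res.model._X @ res.params.to_numpy()))
        assert total == pytest.approx(fitted_mean, abs=1e-10)

    def test_unknown_level_raises(self):
        res = VolumetricContrastModel(rows_fixture(seed=9)).fit()
        with pytest.raises(ValueError, match="cell"):
            res.predictive_margin("NMC", "nope")


# ---------------------------------------------------------------------------
# contrasts


class TestContrasts:
    def test_antisymmetry(self):
        res = VolumetricContrastModel(rows_fixture(seed=10)).fit()
        ab = res.contrast("NMC", "D", "OSTPRE")
        ba = res.contrast("D", "NMC", "OSTPRE")
        assert ab["estimate"] == pytest.approx(-ba["estimate"], abs=1e-12)
        assert ab["se"] == pytest.approx(ba["se"], abs=1e-12)

    def test_between_cohort_difference_is_linear_combination(self):
        rng = np.random.default_rng(11)
        a = rows_fixture(n=150, seed=11, cohort="OSTPRE")
        b = rows_fixture(n=150, seed=12, cohort="ADNI")
        b["participant_id"] = "B" + b["participant_id"]
        b["scan_id"] = "B" + b["scan_id"]
        data = pd.concat([a, b], ignore_index=True)
        res = VolumetricContrastModel(data).fit()
        table = res.contrasts().set_index(["contrast", "scope"])
        for pair in ("NMC-SMC", "NMC-D"):
            dod = table.loc[(pair, "ADNI-OSTPRE"), "estimate"]
            within = (
                table.loc[(pair, "ADNI"), "estimate"]
                - table.loc[(pair, "OSTPRE"), "estimate"]
            )
            assert dod == pytest.approx(within, abs=1e-12)

    def test_missing_cell_reported_as_nan(self):
        data = rows_fixture(n=120, seed=13, status_probs={"NMC": 0.5, "D": 0.5})
        res = VolumetricContrastModel(data).fit()
        table = res.contrasts().set_index("contrast")
        assert np.isnan(table.loc["NMC-SMC", "estimate"])
        assert not np.isnan(table.loc["NMC-D", "estimate"])

    def test_p_value_consistent_with_t_distribution(self):
        from scipy import stats

        res = VolumetricContrastModel(rows_fixture(seed=14)).fit()
        c = res.contrast("NMC", "D", "OSTPRE")
        z = c["estimate"] / c["se"]
        assert c["p_value"] == pytest.approx(
            2 * stats.t.sf(abs(z), res.n_clusters - 1), abs=1e-12
        )


# ---------------------------------------------------------------------------
# trajectories


class TestTrajectory:
    def test_curve_equals_pinned_average_prediction(self):
        data = rows_fixture(n=150, seed=15)
        res = VolumetricContrastModel(data).fit()
        g = float(data["age"].median())
        curve = res.trajectory("age", [g])
        pinned = data.copy()
        pinned["age"] = g
        X2, _ = res.model._design(pinned)
        expected = float(X2.mean(axis=0) @ res.params.to_numpy())
        assert curve["estimate"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_linear_truth_recovered_within_ci(self):
        data = rows_fixture(
            n=800, seed=16, age_fn=lambda a: -0.05 * (a - 75.0), residual_sd=0.4
        )
        res = VolumetricContrastModel(data).fit()
        lo, hi = res.model.age_basis.boundary
        grid = np.linspace(lo + 0.1, hi - 0.1, 9)
        curve = res.trajectory("age", grid)
        # compare slope over the grid against the configured truth
        est_slope = np.polyfit(curve["age"], curve["estimate"], 1)[0]
        assert est_slope == pytest.approx(-0.05, abs=0.02)

    def test_band_width_shrinks_with_n(self):
        widths = []
        for n in (150, 1200):
            data = rows_fixture(n=n, seed=17)
            res = VolumetricContrastModel(data).fit()
            lo, hi = res.model.age_basis.boundary
            grid = np.linspace(lo + 1, hi - 1, 5)
            c = res.trajectory("age", grid)
            widths.append(float((c["ci_high"] - c["ci_low"]).mean()))
        assert widths[1] < widths[0]

    def test_grid_outside_range_raises(self):
        res = VolumetricContrastModel(rows_fixture(seed=18)).fit()
        with pytest.raises(ValueError, match="boundary"):
            res.trajectory("age", [200.0])


def test_summary_contains_key_figures():
    res = VolumetricContrastModel(rows_fixture(seed=19)).fit()
    text = res.summary()
    assert "clusters" in text and "Predictive margins" in text


def test_complete_case_drop_counted():
    data = rows_fixture(n=100, seed=20)
    data.loc[3, "age"] = np.nan
    model = VolumetricContrastModel(data)
    assert model.n_dropped == 1 and len(model.data) == 99
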