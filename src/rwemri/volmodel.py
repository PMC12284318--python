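"""Adjusted volumetric group contrasts with cluster-robust inference.

The model is an ordinary-least-squares regression of a standardized brain
volume (mean 0, SD 1) on a cell-means parameterization of the cognitive
status × cohort cross, adjusted for cubic B-spline terms in age and
standardized total intracranial volume (TIV) and for scanner manufacturer and
field-strength indicators:

    y_ij = mu[status_ij, cohort_ij] + f_age(age_ij) + f_tiv(tiv_ij)
           + gamma' scanner_ij + e_ij

Repeated scans of one participant are correlated, so the covariance of the
coefficient estimates uses the clustered sandwich estimator

    V = c (X'X)^-1 [ sum_g X_g' e_g e_g' X_g ] (X'X)^-1,

with the CR1 small-sample correction c = G/(G-1) * (n-1)/(n-k) over G
participant clusters (CR0, c = 1, available). Group comparisons are
predictive margins — the average model prediction over the analysis sample
with the status×cohort cell pinned and each observation's own covariates
retained — and their contrasts: within-cohort between-status differences and
between-cohort differences of those differences. Margins and contrasts are
linear in the coefficients, so delta-method standard errors a'Va are exact.

The public surface follows the Model/Results convention:

>>> model = VolumetricContrastModel(rows, response="y")   # doctest: +SKIP
>>> res = model.fit()                                     # doctest: +SKIP
>>> res.contrasts()                                       # doctest: +SKIP
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import stats
from scipy.interpolate import BSpline

from .regstatus import CATEGORY_ORDER

__all__ = [
    "standardize",
    "SplineBasis",
    "build_spline",
    "VolumetricContrastModel",
    "VolumetricContrastResults",
    "fit_model",
    "predictive_margin",
    "contrast_table",
    "trajectory",
]


# ---------------------------------------------------------------------------
# standardization


def standardize(values) -> tuple[np.ndarray, float, float]:
    """Center and scale to mean 0, sample SD 1 (n-1 denominator).

    Returns ``(z, mean, sd)`` so the transform can be inverted
    (``x = z * sd + mean``). Constant or length-<2 input raises.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D vector")
    if x.size < 2:
        raise ValueError(f"need at least 2 values to standardize, got {x.size}")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        raise ValueError("cannot standardize a constant vector")
    return (x - mean) / sd, mean, sd


# ---------------------------------------------------------------------------
# B-spline basis


@dataclass(frozen=True)
class SplineBasis:
    """Cubic B-spline basis frozen to a training range.

    Interior knots sit at equally spaced quantiles of the training values;
    boundary knots at the min/max. The full basis satisfies the partition of
    unity (rows sum to 1) on the closed boundary interval; evaluation outside
    it raises (no extrapolation).
    """

    interior_knots: tuple[float, ...]
    boundary: tuple[float, float]
    degree: int = 3

    @property
    def n_columns(self) -> int:
        return len(self.interior_knots) + self.degree + 1

    @property
    def knot_vector(self) -> np.ndarray:
        lo, hi = self.boundary
        return np.concatenate(
            [
                np.repeat(lo, self.degree + 1),
                np.asarray(self.interior_knots, dtype=float),
                np.repeat(hi, self.degree + 1),
            ]
        )

    def design(self, x) -> np.ndarray:
        """Basis matrix at ``x`` (shape ``(len(x), n_columns)``)."""
        x = np.asarray(x, dtype=float)
        lo, hi = self.boundary
        if np.any(x < lo) or np.any(x > hi):
            raise ValueError(
                f"values outside the boundary knots [{lo}, {hi}]; "
                "no extrapolation"
            )
        t = self.knot_vector
        # design_matrix is strict about the half-open last interval; clip the
        # right boundary point into it.
        xc = np.minimum(x, np.nextafter(hi, lo)) if hi > lo else x
        M = BSpline.design_matrix(xc, t, self.degree, extrapolate=False).toarray()
        return M


def build_spline(x, n_interior_knots: int = 3, degree: int = 3) -> tuple[SplineBasis, np.ndarray]:
    """Cubic B-spline basis with interior knots at equally spaced quantiles.

    Returns the frozen :class:`SplineBasis` and the basis matrix evaluated at
    the training points. With 0 interior knots the basis spans cubic
    polynomials on the range exactly.
    """
    x = np.asarray(x, dtype=float)
    if n_interior_knots < 0:
        raise ValueError("n_interior_knots must be >= 0")
    if x.size < n_interior_knots + degree + 1:
        raise ValueError(
            f"need at least {n_interior_knots + degree + 1} points for "
            f"{n_interior_knots} interior knots, got {x.size}"
        )
    lo, hi = float(np.min(x)), float(np.max(x))
    if lo == hi:
        raise ValueError("x spans a degenerate range")
    if n_interior_knots:
        qs = np.linspace(0, 1, n_interior_knots + 2)[1:-1]
        interior = tuple(float(q) for q in np.quantile(x, qs))
    else:
        interior = ()
    basis = SplineBasis(interior_knots=interior, boundary=(lo, hi), degree=degree)
    return basis, basis.design(x)


# ---------------------------------------------------------------------------
# model


@dataclass(frozen=True)
class ModelConfig:
    n_knots_age: int = 3
    n_knots_tiv: int = 3
    cov_type: str = "CR1"  # CR0, or "classical" (naive, ignores clustering)
    inference: str = "t"  # t with G-1 df, or "normal"
    include_covariates: bool = True  # False: cell means only (unadjusted)

    def __post_init__(self) -> None:
        if self.cov_type not in ("CR0", "CR1", "classical"):
            raise ValueError(
                f"cov_type must be CR0, CR1 or classical, got {self.cov_type!r}"
            )
        if self.inference not in ("t", "normal"):
            raise ValueError(f"inference must be 't' or 'normal', got {self.inference!r}")


class VolumetricContrastModel:
    """OLS model of a standardized volume on status×cohort cells plus
    spline/scanner adjustments, fitted with cluster-robust covariance.

    Parameters
    ----------
    data
        One row per analysis observation with columns ``response``,
        ``status``, ``cohort``, ``age``, ``tiv_std``, ``manufacturer``,
        ``field_strength`` and the cluster id (participant).
    response
        Name of the dependent-variable column (should already be
        standardized; see :func:`standardize`).
    config
        Spline and covariance options.

    Rows with a missing value in any model variable are dropped
    (complete-case) and counted in ``n_dropped``.
    """

    REQUIRED = ("status", "cohort", "age", "tiv_std", "manufacturer", "field_strength")

    def __init__(
        self,
        data: pd.DataFrame,
        response: str = "y",
        cluster: str = "participant_id",
        config: ModelConfig = ModelConfig(),
    ) -> None:
        cols = [response, cluster, *self.REQUIRED]
        missing_cols = [c for c in cols if c not in data.columns]
        if missing_cols:
            raise ValueError(f"missing model columns: {missing_cols}")
        complete = data[cols].notna().all(axis=1)
        self.n_dropped = int((~complete).sum())
        self.data = data.loc[complete].reset_index(drop=True)
        if self.data.empty:
            raise ValueError("no complete-case rows to fit")
        self.response = response
        self.cluster = cluster
        self.config = config

        self.statuses = [s for s in CATEGORY_ORDER if s in set(self.data["status"])]
        extra = sorted(set(self.data["status"]) - set(CATEGORY_ORDER))
        if extra:
            raise ValueError(f"unknown status levels: {extra}")
        self.cohorts = sorted(set(self.data["cohort"]))
        self.cells = [
            (s, c)
            for s in self.statuses
            for c in self.cohorts
            if ((self.data["status"] == s) & (self.data["cohort"] == c)).any()
        ]

        if config.include_covariates:
            self.age_basis, age_M = build_spline(self.data["age"], config.n_knots_age)
            self.tiv_basis, tiv_M = build_spline(self.data["tiv_std"], config.n_knots_tiv)
        else:
            self.age_basis = self.tiv_basis = None
            age_M = tiv_M = None
        self.manufacturers = sorted(set(self.data["manufacturer"].astype(str)))
        self.field_strengths = sorted(set(self.data["field_strength"].astype(float)))
        self._X, self.exog_names = self._design(self.data, age_M=age_M, tiv_M=tiv_M)

    # -- design ------------------------------------------------------------

    def _design(
        self,
        data: pd.DataFrame,
        cell: Optional[tuple[str, str]] = None,
        pin: Optional[tuple[str, float]] = None,
        age_M: Optional[np.ndarray] = None,
        tiv_M: Optional[np.ndarray] = None,
    ) -> tuple[np.ndarray, list[str]]:
        """Design matrix: cell dummies (cell means, no intercept), spline
        columns for age and TIV with the first basis column dropped (the
        dummies absorb the level), and baseline-dropped scanner indicators.

        ``cell`` pins every row to one status×cohort cell; ``pin`` sets a
        focal continuous variable to one value for every row.
        """
        n = len(data)
        cols: list[np.ndarray] = []
        names: list[str] = []
        status = data["status"].to_numpy()
        cohort = data["cohort"].to_numpy()
        for s, c in self.cells:
            if cell is not None:
                d = np.full(n, 1.0 if (s, c) == cell else 0.0)
            else:
                d = ((status == s) & (cohort == c)).astype(float)
            cols.append(d)
            names.append(f"cell[{s}:{c}]")
        if not self.config.include_covariates:
            return np.column_stack(cols), names
        age = data["age"].to_numpy(dtype=float)
        tiv = data["tiv_std"].to_numpy(dtype=float)
        if pin is not None:
            if pin[0] == "age":
                age = np.full(n, float(pin[1]))
            elif pin[0] == "tiv_std":
                tiv = np.full(n, float(pin[1]))
            else:
                raise ValueError(f"unknown pinned variable {pin[0]!r}")
        if age_M is None:
            age_M = self.age_basis.design(age)
        if tiv_M is None:
            tiv_M = self.tiv_basis.design(tiv)
        # drop the first basis column of each spline: the basis rows sum to 1
        # and would be collinear with the cell dummies
        for j in range(1, age_M.shape[1]):
            cols.append(age_M[:, j])
            names.append(f"age_spline[{j}]")
        for j in range(1, tiv_M.shape[1]):
            cols.append(tiv_M[:, j])
            names.append(f"tiv_spline[{j}]")
        manu = data["manufacturer"].astype(str).to_numpy()
        for level in self.manufacturers[1:]:
            cols.append((manu == level).astype(float))
            names.append(f"manufacturer[{level}]")
        fs = data["field_strength"].astype(float).to_numpy()
        for level in self.field_strengths[1:]:
            cols.append((fs == level).astype(float))
            names.append(f"field_strength[{level}]")
        return np.column_stack(cols), names

    # -- fitting -----------------------------------------------------------

    def fit(self) -> "VolumetricContrastResults":
        X = self._X
        y = self.data[self.response].to_numpy(dtype=float)
        n, k = X.shape
        groups = self.data[self.cluster].to_numpy()
        uniq, gidx = np.unique(groups, return_inverse=True)
        G = uniq.size
        if G < 2:
            raise ValueError("cluster-robust inference needs >= 2 clusters")
        rank = np.linalg.matrix_rank(X)
        if rank < k:
            raise ValueError(
                f"rank-deficient design (rank {rank} < {k} columns); "
                f"aliased columns among: {self._aliased_columns()}"
            )
        XtX = X.T @ X
        XtX_inv = np.linalg.inv(XtX)
        beta = XtX_inv @ (X.T @ y)
        resid = y - X @ beta
        # cluster score sums: S_g = X_g' e_g, meat = sum_g S_g S_g'
        Xe = X * resid[:, None]
        S = np.zeros((G, k))
        np.add.at(S, gidx, Xe)
        meat = S.T @ S
        if self.config.cov_type == "CR1":
            c = (G / (G - 1)) * ((n - 1) / (n - k))
        else:
            c = 1.0
        V_cluster = c * XtX_inv @ meat @ XtX_inv
        V_cluster = (V_cluster + V_cluster.T) / 2
        sigma2 = float(resid @ resid) / (n - k)
        V_classical = sigma2 * XtX_inv
        V = V_classical if self.config.cov_type == "classical" else V_cluster
        names = self.exog_names
        return VolumetricContrastResults(
            model=self,
            params=pd.Series(beta, index=names),
            cov_params=pd.DataFrame(V, index=names, columns=names),
            nobs=n,
            n_clusters=G,
            resid=resid,
            cov_params_classical=pd.DataFrame(V_classical, index=names, columns=names),
        )

    def _aliased_columns(self) -> list[str]:
        # name columns whose removal restores full rank (greedy QR-based scan)
        X = self._X
        _, R, piv = sla.qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        bad = piv[diag < tol] if diag.size else []
        return [self.exog_names[j] for j in np.atleast_1d(bad)]


WITHIN_PAIRS = (("NMC", "SMC"), ("NMC", "MCI"), ("NMC", "D"), ("MCI", "D"))


class VolumetricContrastResults:
    """Fitted coefficients, cluster-robust covariance, and the derived
    margins/contrast/trajectory machinery."""

    def __init__(self, model, params, cov_params, nobs, n_clusters, resid,
                 cov_params_classical=None):
        self.model = model
        self.params = params
        self.cov_params = cov_params
        self.nobs = nobs
        self.n_clusters = n_clusters
        self.resid = resid
        #: naive OLS covariance, kept alongside for calibration comparisons
        self.cov_params_classical = cov_params_classical

    # -- inference helpers -------------------------------------------------

    def _crit(self) -> float:
        if self.model.config.inference == "t":
            return float(stats.t.ppf(0.975, self.n_clusters - 1))
        return float(stats.norm.ppf(0.975))

    def _pvalue(self, z: float) -> float:
        if self.model.config.inference == "t":
            return float(2 * stats.t.sf(abs(z), self.n_clusters - 1))
        return float(2 * stats.norm.sf(abs(z)))

    def _linear(self, a: np.ndarray) -> tuple[float, float]:
        est = float(a @ self.params.to_numpy())
        se = float(np.sqrt(a @ self.cov_params.to_numpy() @ a))
        return est, se

    # -- margins -----------------------------------------------------------

    def _margin_vector(self, status: str, cohort: str) -> np.ndarray:
        if (status, cohort) not in self.model.cells:
            raise ValueError(f"no analysis rows in cell ({status}, {cohort})")
        Xc, _ = self.model._design(self.model.data, cell=(status, cohort))
        return Xc.mean(axis=0)

    def predictive_margin(self, status: str, cohort: str) -> tuple[float, float]:
        """Average prediction with every row's cell pinned to
        ``(status, cohort)`` and its own covariates retained."""
        return self._linear(self._margin_vector(status, cohort))

    def margins(self) -> pd.DataFrame:
        """Predictive margin, SE and 95% CI for every observed cell."""
        crit = self._crit()
        rows = []
        for s, c in self.model.cells:
            est, se = self.predictive_margin(s, c)
            rows.append(
                {
                    "status": s,
                    "cohort": c,
                    "margin": est,
                    "se": se,
                    "ci_low": est - crit * se,
                    "ci_high": est + crit * se,
                }
            )
        return pd.DataFrame(rows)

    # -- contrasts ---------------------------------------------------------

    def contrast(self, status_a: str, status_b: str, cohort: str) -> dict:
        """Within-cohort margin difference ``status_a - status_b``."""
        a = self._margin_vector(status_a, cohort) - self._margin_vector(status_b, cohort)
        est, se = self._linear(a)
        crit = self._crit()
        return {
            "estimate": est,
            "se": se,
            "ci_low": est - crit * se,
            "ci_high": est + crit * se,
            "p_value": self._pvalue(est / se) if se > 0 else np.nan,
        }

    def contrasts(self) -> pd.DataFrame:
        """Within-cohort between-status contrasts and, when two cohorts are
        present, the between-cohort differences of those contrasts.

        A contrast whose cells are unobserved is reported as a row of NaNs,
        not fabricated.
        """
        crit = self._crit()
        rows = []
        cohorts = self.model.cohorts
        for cohort in cohorts:
            for sa, sb in WITHIN_PAIRS:
                label = f"{sa}-{sb}"
                try:
                    a = self._margin_vector(sa, cohort) - self._margin_vector(sb, cohort)
                except ValueError:
                    rows.append(
                        {"contrast": label, "scope": cohort, "estimate": np.nan,
                         "se": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                         "p_value": np.nan}
                    )
                    continue
                est, se = self._linear(a)
                rows.append(
                    {"contrast": label, "scope": cohort, "estimate": est, "se": se,
                     "ci_low": est - crit * se, "ci_high": est + crit * se,
                     "p_value": self._pvalue(est / se) if se > 0 else np.nan}
                )
        if len(cohorts) == 2:
            c1, c2 = cohorts
            scope = f"{c1}-{c2}"
            for sa, sb in WITHIN_PAIRS:
                label = f"{sa}-{sb}"
                try:
                    a = (
                        self._margin_vector(sa, c1)
                        - self._margin_vector(sb, c1)
                        - self._margin_vector(sa, c2)
                        + self._margin_vector(sb, c2)
                    )
                except ValueError:
                    rows.append(
                        {"contrast": label, "scope": scope, "estimate": np.nan,
                         "se": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                         "p_value": np.nan}
                    )
                    continue
                est, se = self._linear(a)
                rows.append(
                    {"contrast": label, "scope": scope, "estimate": est, "se": se,
                     "ci_low": est - crit * se, "ci_high": est + crit * se,
                     "p_value": self._pvalue(est / se) if se > 0 else np.nan}
                )
        return pd.DataFrame(rows)

    # -- trajectories ------------------------------------------------------

    def trajectory(self, variable: str, grid) -> pd.DataFrame:
        """Adjusted prediction curve over a grid of one continuous variable.

        At each grid value the focal variable is pinned for every row
        (covariates and cells retained) and predictions averaged; the 95%
        band is the exact delta-method ``a'Va`` interval. Grid values outside
        the training boundary knots raise.
        """
        if variable not in ("age", "tiv_std"):
            raise ValueError("variable must be 'age' or 'tiv_std'")
        if self.model.age_basis is None:
            raise ValueError("trajectories require a covariate-adjusted model")
        crit = self._crit()
        rows = []
        for g in np.asarray(grid, dtype=float):
            Xg, _ = self.model._design(self.model.data, pin=(variable, g))
            a = Xg.mean(axis=0)
            est, se = self._linear(a)
            rows.append(
                {variable: g, "estimate": est, "se": se,
                 "ci_low": est - crit * se, "ci_high": est + crit * se}
            )
        return pd.DataFrame(rows)

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Volumetric contrast model (OLS, cluster-robust covariance)",
            f"  n_obs: {self.nobs}   clusters: {self.n_clusters}   "
            f"cov: {cfg.cov_type}   inference: {cfg.inference}",
            f"  dropped (incomplete rows): {self.model.n_dropped}",
            "",
            f"{'coef':<28}{'estimate':>12}{'se':>12}",
        ]
        se = np.sqrt(np.diag(self.cov_params.to_numpy()))
        for name, b, s in zip(self.params.index, self.params.to_numpy(), se):
            lines.append(f"{name:<28}{b:>12.4f}{s:>12.4f}")
        lines.append("")
        lines.append("Predictive margins:")
        for row in self.margins().itertuples(index=False):
            lines.append(
                f"  {row.status:<4} {row.cohort:<8} {row.margin:>8.3f} "
                f"({row.ci_low:.3f} to {row.ci_high:.3f})"
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# thin functional wrappers


def fit_model(rows: pd.DataFrame, config: ModelConfig = ModelConfig(), response: str = "y",
              cluster: str = "participant_id") -> VolumetricContrastResults:
    return VolumetricContrastModel(rows, response=response, cluster=cluster, config=config).fit()


def predictive_margin(fit: VolumetricContrastResults, status: str, cohort: str):
    return fit.predictive_margin(status, cohort)


def contrast_table(fit: VolumetricContrastResults) -> pd.DataFrame:
    return fit.contrasts()


def trajectory(fit: VolumetricContrastResults, variable: str, grid) -> pd.DataFrame:
    return fit.trajectory(variable, grid)
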