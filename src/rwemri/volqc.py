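"""Two-stage quality control of pipeline-derived brain volumes.

Stage 1 gates each scan on the segmentation tool's image-quality percentage
(default threshold 68%, inclusive). Stage 2 flags scans whose volumes
disagree between two independent segmentation pipelines: for each region of
interest (total gray matter, hippocampus L+R, ventricles as the sum of the
four lateral/inferior-lateral parts) pipeline-A volumes predict pipeline-B
volumes in a robust univariate regression (iteratively reweighted least
squares with a Tukey bisquare weight function, scale re-estimated each
iteration from the MAD of the residuals), and a scan is a potential outlier
when, for any ROI, the absolute residual exceeds ``mad_multiplier`` (default
8) times the MAD-based estimate of the residual SD. Flagged scans default to
a "review" disposition — mirroring a human visual-inspection step — with an
optional automatic exclusion mode for unattended runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

#: ROI pairs checked for concordance: name -> (pipeline-A cols, pipeline-B cols).
ROI_PAIRS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "gm": (("gm_a",), ("gm_b",)),
    "hippocampus": (
        ("hip_left_a", "hip_right_a"),
        ("hip_left_b", "hip_right_b"),
    ),
    "ventricles": (
        ("vent_llat_a", "vent_rlat_a", "vent_linf_a", "vent_rinf_a"),
        ("vent_llat_b", "vent_rlat_b", "vent_linf_b", "vent_rinf_b"),
    ),
}

ROI_NAMES = tuple(ROI_PAIRS)


@dataclass(frozen=True)
class QCConfig:
    quality_threshold: float = 68.0
    mad_multiplier: float = 8.0
    mad_to_sd: float = 1.4826  # Gaussian consistency constant
    tuning_constant: float = 4.685  # bisquare, 95% Gaussian efficiency
    max_iter: int = 50
    tol: float = 1e-8
    auto_exclude: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.quality_threshold <= 100):
            raise ValueError(
                f"quality_threshold must be in (0, 100], got {self.quality_threshold}"
            )
        if self.mad_multiplier <= 0:
            raise ValueError(f"mad_multiplier must be > 0, got {self.mad_multiplier}")


@dataclass
class RobustFit:
    """IRLS bisquare regression fit of y on x (with intercept)."""

    intercept: float
    slope: float
    residuals: np.ndarray
    weights: np.ndarray
    scale: float
    n_iter: int
    converged: bool


def quality_gate(volumes: pd.DataFrame, config: QCConfig = QCConfig()) -> pd.Series:
    """Boolean pass/fail per scan on the quality percentage (inclusive)."""
    q = volumes["quality_pct"].astype(float)
    bad = q[(q < 0) | (q > 100) | q.isna()]
    if not bad.empty:
        raise ValueError(
            f"quality_pct outside [0, 100] for scans "
            f"{volumes.loc[bad.index, 'scan_id'].tolist()}"
        )
    passed = q >= config.quality_threshold
    passed.name = "pass_quality"
    return passed


def _mad_scale(resid: np.ndarray, mad_to_sd: float) -> float:
    # MAD of median-centred residuals, scaled to estimate the residual SD.
    return mad_to_sd * float(np.median(np.abs(resid - np.median(resid))))


def robust_fit(x, y, config: QCConfig = QCConfig()) -> RobustFit:
    """Robust univariate regression of ``y`` on ``x`` with Tukey bisquare
    weights.

    Iteratively reweighted least squares: starting from ordinary least
    squares, each iteration re-estimates the residual scale as the
    MAD-derived SD, computes bisquare weights
    ``w = (1 - u^2)^2`` for ``|u| < 1`` (0 beyond), with
    ``u = r / (tuning_constant * scale)``, and solves the weighted normal
    equations; iteration stops when the largest coefficient change falls
    below ``tol`` or ``max_iter`` is reached. Residuals are returned on the
    original scale.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 5:
        raise ValueError(f"insufficient data: need >= 5 points, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictor: x is constant")

    X = np.column_stack([np.ones(n), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    weights = np.ones(n)
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        resid = y - X @ beta
        scale = _mad_scale(resid, config.mad_to_sd)
        if scale <= 0:
            # (near-)perfect fit; weights are irrelevant
            weights = np.ones(n)
            converged = True
            break
        u = resid / (config.tuning_constant * scale)
        weights = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
        sw = np.sqrt(weights)
        beta_new, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
        if np.max(np.abs(beta_new - beta)) < config.tol:
            beta = beta_new
            converged = True
            break
        beta = beta_new
    resid = y - X @ beta
    return RobustFit(
        intercept=float(beta[0]),
        slope=float(beta[1]),
        residuals=resid,
        weights=weights,
        scale=_mad_scale(resid, config.mad_to_sd),
        n_iter=it,
        converged=converged,
    )


def threshold_flags(residuals, config: QCConfig = QCConfig()) -> tuple[np.ndarray, float]:
    """MAD-based outlier flags for one ROI's residual vector.

    ``sigma_mad`` is the consistency-scaled MAD of the median-centred
    residuals; a residual is flagged when strictly larger in magnitude than
    ``mad_multiplier * sigma_mad`` (two-sided, strict: a residual exactly at
    the threshold is not an outlier). Returns ``(flags, sigma_mad)``.
    """
    residuals = np.asarray(residuals, dtype=float)
    sigma = _mad_scale(residuals, config.mad_to_sd)
    return np.abs(residuals) > config.mad_multiplier * sigma, sigma


def roi_totals(volumes: pd.DataFrame) -> pd.DataFrame:
    """Aggregate component columns into the three checked ROI totals for
    both pipelines (columns ``<roi>_a`` / ``<roi>_b``)."""
    out = pd.DataFrame(index=volumes.index)
    out["scan_id"] = volumes["scan_id"]
    for roi, (cols_a, cols_b) in ROI_PAIRS.items():
        out[f"{roi}_a"] = volumes[list(cols_a)].sum(axis=1)
        out[f"{roi}_b"] = volumes[list(cols_b)].sum(axis=1)
    return out


def flag_outliers(volumes: pd.DataFrame, config: QCConfig = QCConfig()) -> pd.DataFrame:
    """Cross-pipeline concordance outlier flags for quality-passed scans.

    For each ROI, residuals come from the robust fit of pipeline-B totals on
    pipeline-A totals; ``sigma_mad`` is the MAD-based residual-SD estimate,
    and a scan is flagged when ``|residual| > mad_multiplier * sigma_mad``
    for any ROI (strict inequality, two-sided).

    Returns one row per scan with per-ROI residuals and thresholds,
    ``flagged``, and ``flag_rois`` (pipe-joined ROI names, empty string when
    unflagged).
    """
    if len(volumes) < 5:
        raise ValueError(
            f"insufficient data: need >= 5 usable scans, got {len(volumes)}"
        )
    totals = roi_totals(volumes)
    out = pd.DataFrame({"scan_id": totals["scan_id"]}, index=totals.index)
    flagged = np.zeros(len(totals), dtype=bool)
    rois_hit: list[list[str]] = [[] for _ in range(len(totals))]
    for roi in ROI_NAMES:
        fit = robust_fit(totals[f"{roi}_a"], totals[f"{roi}_b"], config)
        hit, sigma = threshold_flags(fit.residuals, config)
        out[f"resid_{roi}"] = fit.residuals
        out[f"sigma_mad_{roi}"] = sigma
        flagged |= hit
        for i in np.flatnonzero(hit):
            rois_hit[i].append(roi)
    out["flagged"] = flagged
    out["flag_rois"] = ["|".join(r) for r in rois_hit]
    return out


def run_qc(volumes: pd.DataFrame, config: QCConfig = QCConfig()) -> pd.DataFrame:
    """Both QC stages: quality gate, then concordance flags on the passers.

    Dispositions: ``excluded`` for quality failures (and for flagged scans
    when ``auto_exclude`` is set), ``review`` for flagged passers otherwise,
    ``pass`` for the rest.
    """
    passed = quality_gate(volumes, config)
    report = pd.DataFrame(
        {"scan_id": volumes["scan_id"], "pass_quality": passed}, index=volumes.index
    )
    passers = volumes.loc[passed]
    if len(passers) >= 5:
        flags = flag_outliers(passers, config)
    else:
        # too few passers for a concordance fit; nothing can be flagged
        flags = pd.DataFrame(
            {"scan_id": passers["scan_id"], "flagged": False, "flag_rois": ""}
        )
    report = report.merge(flags, on="scan_id", how="left")
    report["flagged"] = report["flagged"].eq(True)  # NaN (quality-failed) -> False
    report["flag_rois"] = report["flag_rois"].astype(object).where(
        report["flag_rois"].notna(), ""
    )
    disposition = np.where(
        ~report["pass_quality"],
        "excluded",
        np.where(
            report["flagged"],
            "excluded" if config.auto_exclude else "review",
            "pass",
        ),
    )
    report["disposition"] = disposition
    return report
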