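"""Synthetic cohort generator with known ground truth.

Emulates the data structure of a register-linked real-world MRI study plus a
single-visit research reference cohort: participants (women born in a fixed
window), a latent progressive cognitive process (NMC -> SMC -> MCI -> dementia
with exponential waiting times), examination visits carrying several scan
series with realistic free-text protocol names, two-pipeline volumetric
outputs with configurable concordance noise and injected gross outliers,
sub-threshold-quality scans, and register events recorded with a reporting
delay after each latent transition (so register-derived status can lag
truth). Every generated artefact is accompanied by its ground truth, making
each downstream stage testable without any external data.

All randomness flows from a single seed; identical config + seed yields
byte-identical tables.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .regstatus import CATEGORY_ORDER

ROIS = ("gm", "hippocampus", "ventricles")

#: fixed component shares of the ROI totals (left/right hippocampus; the four
#: ventricular parts: left/right lateral, left/right inferior lateral)
HIP_SPLIT = (0.5, 0.5)
VENT_SPLIT = (0.42, 0.42, 0.08, 0.08)

REGISTERS = (
    "hospital-discharge",
    "primary-care",
    "causes-of-death",
    "reimbursement",
    "drug-purchase",
)

#: codes recognised by the default code map in :mod:`rwemri.regstatus`
CATEGORY_CODES = {
    "SMC": ("R418", "SMC001"),
    "MCI": ("F06.7", "MCI001"),
    "D": ("F00.9", "G30.1", "DEM001"),
}


@dataclass(frozen=True)
class ProtocolSpec:
    """One protocol-name entry of the scanner vocabulary."""

    name: str
    is_t1: bool
    has_contrast: bool
    slice_range: tuple[int, int]
    weight: float


#: Vocabulary covering every branch of the metadata filter: eligible 3-D T1s,
#: a 2-D T1 failing the slice rule, a contrast-enhanced T1, a 2-D FLAIR whose
#: name contains "tra" but fails on slices, a 3-D T2 that passes the loose
#: pattern (the documented false-positive channel), and an unmatched DWI.
DEFAULT_VOCABULARY: tuple[ProtocolSpec, ...] = (
    ProtocolSpec("mprage", True, False, (140, 192), 3.0),
    ProtocolSpec("t1_se_sag", True, False, (90, 130), 2.0),
    ProtocolSpec("t1_se_tra", True, False, (20, 40), 1.0),
    ProtocolSpec("mprage_gd", True, True, (140, 192), 1.0),
    ProtocolSpec("t2_tra_flair", False, False, (20, 45), 2.0),
    ProtocolSpec("t2_space_tra", False, False, (100, 176), 0.5),
    ProtocolSpec("dwi_ax", False, False, (20, 35), 1.0),
)


def _dd(d: Mapping) -> dict:
    return dict(d)


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters.

    Defaults are chosen to resemble a two-decade regional real-world cohort
    of older women plus a research reference cohort: birth years 1932-1941,
    scans acquired 2003-2022, ~1.3 scans per real-world participant vs one
    baseline scan per reference participant, cohort-specific scanner mixes,
    and status effect sizes (standardized mean shifts per category) matching
    published adjusted between-group differences for gray matter,
    hippocampus and ventricle volumes.
    """

    cohorts: Mapping[str, int] = field(default_factory=lambda: {"OSTPRE": 300, "ADNI": 160})
    n_participants: Optional[int] = None
    birth_year_range: tuple[int, int] = (1932, 1941)
    study_period: tuple[str, str] = ("2003-01-01", "2022-12-31")
    status_onset_age: float = 60.0
    status_transition_rates: Mapping[str, float] = field(
        default_factory=lambda: {"NMC>SMC": 0.07, "SMC>MCI": 0.12, "MCI>D": 0.35}
    )
    reporting_delay_days: Mapping[str, float] = field(
        default_factory=lambda: {"shape": 2.0, "scale": 45.0}
    )
    visits_per_participant: Mapping[str, float] = field(
        default_factory=lambda: {"OSTPRE": 0.3, "ADNI": 0.0}
    )
    scans_per_visit_extra: float = 1.2
    protocol_vocabulary: tuple[ProtocolSpec, ...] = DEFAULT_VOCABULARY
    nonhead_rate: float = 0.05
    nonhead_code: str = "NA1AG"
    head_codes: tuple[str, ...] = ("AA1BG", "AA1CG", "AA1DG")
    manufacturer_mix: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "OSTPRE": {"Siemens": 0.81, "Philips": 0.18, "Toshiba": 0.01},
            "ADNI": {"Siemens": 0.56, "Philips": 0.167, "GE": 0.273},
        }
    )
    field_mix: Mapping[str, Mapping[float, float]] = field(
        default_factory=lambda: {
            "OSTPRE": {1.5: 0.825, 3.0: 0.175},
            "ADNI": {1.5: 0.294, 3.0: 0.706},
        }
    )
    effect_sizes: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "gm": {"NMC": 0.0, "SMC": -0.19, "MCI": -0.59, "D": -0.66},
            "hippocampus": {"NMC": 0.0, "SMC": -0.17, "MCI": -0.59, "D": -1.01},
            "ventricles": {"NMC": 0.0, "SMC": 0.09, "MCI": 0.26, "D": 0.44},
        }
    )
    roi_baseline_ml: Mapping[str, float] = field(
        default_factory=lambda: {"gm": 620.0, "hippocampus": 7.4, "ventricles": 28.0}
    )
    roi_scale_ml: Mapping[str, float] = field(
        default_factory=lambda: {"gm": 55.0, "hippocampus": 0.9, "ventricles": 14.0}
    )
    age_slope_ml: Mapping[str, float] = field(
        default_factory=lambda: {"gm": -3.5, "hippocampus": -0.05, "ventricles": 1.2}
    )
    age_quad_ml: Mapping[str, float] = field(
        default_factory=lambda: {"gm": 0.0, "hippocampus": 0.0, "ventricles": 0.0}
    )
    age_center: float = 75.0
    tiv_mean_sd: tuple[float, float] = (1450.0, 130.0)
    tiv_slope: Mapping[str, float] = field(
        default_factory=lambda: {"gm": 0.25, "hippocampus": 0.0025, "ventricles": 0.015}
    )
    random_intercept_sd: float = 0.5
    residual_sd: float = 0.7
    scanner_offsets: Mapping[str, float] = field(
        default_factory=lambda: {"Siemens": 0.0, "Philips": 0.05, "GE": -0.05, "Toshiba": 0.1}
    )
    field_offsets: Mapping[float, float] = field(
        default_factory=lambda: {1.5: 0.0, 3.0: 0.08}
    )
    interpipeline_noise_sd: Mapping[str, float] = field(
        default_factory=lambda: {"gm": 5.0, "hippocampus": 0.1, "ventricles": 0.8}
    )
    outlier_rate: float = 0.01
    outlier_displacement: Mapping[str, float] = field(
        default_factory=lambda: {"gm": 100.0, "hippocampus": 2.0, "ventricles": 16.0}
    )
    subquality_rate: float = 0.08
    quality_threshold: float = 68.0
    repeat_event_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("nonhead_rate", "outlier_rate", "subquality_rate", "repeat_event_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("random_intercept_sd", "residual_sd", "scans_per_visit_extra"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        for key, v in self.status_transition_rates.items():
            if v < 0:
                raise ValueError(f"status_transition_rates[{key}] must be >= 0, got {v}")
        for key in ("NMC>SMC", "SMC>MCI", "MCI>D"):
            if key not in self.status_transition_rates:
                raise ValueError(f"status_transition_rates missing transition {key!r}")
        if any(n < 0 for n in self.cohorts.values()):
            raise ValueError("cohorts sizes must be >= 0")
        if self.n_participants is not None and self.n_participants != sum(self.cohorts.values()):
            raise ValueError(
                f"n_participants ({self.n_participants}) inconsistent with cohort "
                f"sizes (sum {sum(self.cohorts.values())})"
            )
        if self.birth_year_range[0] > self.birth_year_range[1]:
            raise ValueError(f"birth_year_range reversed: {self.birth_year_range}")
        for roi in ROIS:
            for mapping_name in (
                "effect_sizes", "roi_baseline_ml", "roi_scale_ml", "age_slope_ml",
                "age_quad_ml", "tiv_slope", "interpipeline_noise_sd", "outlier_displacement",
            ):
                if roi not in getattr(self, mapping_name):
                    raise ValueError(f"{mapping_name} missing ROI {roi!r}")
            if self.interpipeline_noise_sd[roi] < 0:
                raise ValueError(f"interpipeline_noise_sd[{roi}] must be >= 0")
        for p in self.protocol_vocabulary:
            if p.slice_range[0] > p.slice_range[1] or p.slice_range[0] < 0:
                raise ValueError(f"protocol_vocabulary[{p.name}] has bad slice_range {p.slice_range}")
            if p.weight < 0:
                raise ValueError(f"protocol_vocabulary[{p.name}] has negative weight")
        if not (0 < self.quality_threshold <= 100):
            raise ValueError(f"quality_threshold must be in (0, 100], got {self.quality_threshold}")
        if self.reporting_delay_days.get("shape", 1.0) <= 0 or self.reporting_delay_days.get("scale", 0.0) < 0:
            raise ValueError(f"reporting_delay_days invalid: {dict(self.reporting_delay_days)}")

    @property
    def total_participants(self) -> int:
        return sum(self.cohorts.values())


@dataclass
class GroundTruth:
    """Test oracle accompanying a simulated cohort.

    ``per_scan`` carries one row per generated scan (truth flags for T1
    weighting, contrast, injected outliers, sub-threshold quality and the
    latent status on the acquisition date); ``transitions`` the latent
    transition dates; ``true_effects`` the configured standardized shifts.
    """

    per_scan: pd.DataFrame
    transitions: pd.DataFrame
    true_effects: dict


@dataclass
class SimulatedCohort:
    scans: pd.DataFrame
    volumes: pd.DataFrame
    events: pd.DataFrame
    participants: pd.DataFrame
    truth: GroundTruth

    def tables(self) -> dict:
        return {
            "scan_metadata": self.scans,
            "volumes": self.volumes,
            "register_events": self.events,
            "participants": self.participants,
            "ground_truth": self.truth.per_scan,
            "ground_truth_transitions": self.truth.transitions,
        }


def _choice(rng: np.random.Generator, mix: Mapping, size: int) -> np.ndarray:
    keys = list(mix.keys())
    p = np.asarray([mix[k] for k in keys], dtype=float)
    p = p / p.sum()
    idx = rng.choice(len(keys), size=size, p=p)
    return np.asarray(keys, dtype=object)[idx]


def latent_status_at(transitions: pd.DataFrame, participant_id, date) -> str:
    """Latent (truth) category of one participant at a date."""
    rows = transitions[transitions["participant_id"] == participant_id]
    date = pd.Timestamp(date)
    status = "NMC"
    for row in rows.itertuples(index=False):
        if pd.Timestamp(row.transition_date) <= date:
            status = row.category
    return status


def simulate_cohort(config: SimConfig = SimConfig()) -> SimulatedCohort:
    """Generate the four input tables plus ground truth.

    Volumes are built as baseline + TIV term + age term + status effect +
    participant random intercept + scanner offset + residual noise; the
    second pipeline's values equal the first's plus concordance noise, except
    injected outlier scans where one ROI is displaced by the configured
    gross amount. Register events fire at latent transition time plus a
    reporting delay.
    """
    rng = np.random.default_rng(config.seed)
    start = pd.Timestamp(config.study_period[0])
    end = pd.Timestamp(config.study_period[1])
    n_days = (end - start).days

    # --- participants ----------------------------------------------------
    pids, cohorts_col = [], []
    for label in sorted(config.cohorts):
        n = config.cohorts[label]
        pids.extend(f"{label[:2].upper()}{i:05d}" for i in range(n))
        cohorts_col.extend([label] * n)
    n_p = len(pids)
    y0, y1 = config.birth_year_range
    birth_offsets = rng.integers(0, (y1 - y0 + 1) * 365, size=n_p)
    birth_dates = pd.Timestamp(f"{y0}-01-01") + pd.to_timedelta(birth_offsets, unit="D")
    participants = pd.DataFrame(
        {
            "participant_id": pids,
            "birth_date": birth_dates,
            "sex": "F",
            "cohort": cohorts_col,
        }
    )

    # --- latent progressive status process --------------------------------
    rates = config.status_transition_rates
    waits = np.column_stack(
        [
            rng.exponential(1.0 / rates[k], size=n_p) if rates[k] > 0 else np.full(n_p, np.inf)
            for k in ("NMC>SMC", "SMC>MCI", "MCI>D")
        ]
    )
    trans_ages = config.status_onset_age + np.cumsum(waits, axis=1)
    trans_rows = []
    for i, pid in enumerate(pids):
        for j, cat in enumerate(("SMC", "MCI", "D")):
            age = trans_ages[i, j]
            if np.isfinite(age) and age < 120:
                date = birth_dates[i] + pd.Timedelta(days=round(age * 365.25))
                trans_rows.append(
                    {"participant_id": pid, "category": cat, "transition_date": date}
                )
    transitions = pd.DataFrame(
        trans_rows, columns=["participant_id", "category", "transition_date"]
    )

    # --- register events (transition + reporting delay) -------------------
    shape = config.reporting_delay_days.get("shape", 2.0)
    scale = config.reporting_delay_days.get("scale", 45.0)
    ev_rows = []
    for row in transitions.itertuples(index=False):
        delay = float(rng.gamma(shape, scale)) if scale > 0 else 0.0
        date = pd.Timestamp(row.transition_date) + pd.Timedelta(days=round(delay))
        code = str(rng.choice(CATEGORY_CODES[row.category]))
        source = str(rng.choice(REGISTERS))
        ev_rows.append(
            {"participant_id": row.participant_id, "event_date": date,
             "source": source, "code": code}
        )
        if rng.random() < config.repeat_event_rate:
            extra = date + pd.Timedelta(days=int(rng.integers(30, 400)))
            ev_rows.append(
                {"participant_id": row.participant_id, "event_date": extra,
                 "source": str(rng.choice(REGISTERS)),
                 "code": str(rng.choice(CATEGORY_CODES[row.category]))}
            )
    events = pd.DataFrame(
        ev_rows, columns=["participant_id", "event_date", "source", "code"]
    ).sort_values(["participant_id", "event_date"], kind="stable").reset_index(drop=True)

    # --- visits and scan series ------------------------------------------
    tiv_by_p = rng.normal(config.tiv_mean_sd[0], config.tiv_mean_sd[1], size=n_p)
    b_by_p = rng.normal(0.0, config.random_intercept_sd, size=(n_p, len(ROIS)))
    vocab = config.protocol_vocabulary
    vocab_w = np.asarray([p.weight for p in vocab], dtype=float)
    vocab_w = vocab_w / vocab_w.sum()

    trans_dates_by_p: dict[str, list[tuple[pd.Timestamp, str]]] = {}
    for row in transitions.itertuples(index=False):
        trans_dates_by_p.setdefault(row.participant_id, []).append(
            (pd.Timestamp(row.transition_date), row.category)
        )

    scan_rows, vol_rows, truth_rows = [], [], []
    for i, pid in enumerate(pids):
        cohort = cohorts_col[i]
        mean_extra = config.visits_per_participant.get(cohort, 0.0)
        n_visits = 1 + (int(rng.poisson(mean_extra)) if mean_extra > 0 else 0)
        offsets = np.sort(rng.integers(0, n_days + 1, size=n_visits))
        for v, off in enumerate(offsets, start=1):
            vdate = start + pd.Timedelta(days=int(off))
            visit_id = f"v{v}"
            manufacturer = str(_choice(rng, config.manufacturer_mix[cohort], 1)[0])
            fstrength = float(_choice(rng, config.field_mix[cohort], 1)[0])
            age = (vdate - birth_dates[i]).days / 365.25
            true_status = "NMC"
            for tdate, cat in trans_dates_by_p.get(pid, []):
                if tdate <= vdate:
                    true_status = cat
            n_series = 1 + int(rng.poisson(config.scans_per_visit_extra))
            for s in range(1, n_series + 1):
                scan_id = f"{pid}_{visit_id}_s{s}"
                proto = vocab[int(rng.choice(len(vocab), p=vocab_w))]
                slices = int(rng.integers(proto.slice_range[0], proto.slice_range[1] + 1))
                nonhead = rng.random() < config.nonhead_rate
                code = config.nonhead_code if nonhead else str(rng.choice(config.head_codes))
                scan_rows.append(
                    {"scan_id": scan_id, "participant_id": pid, "visit_id": visit_id,
                     "acquisition_date": vdate, "procedure_code": code,
                     "protocol_name": proto.name, "slice_count": slices,
                     "manufacturer": manufacturer, "field_strength": fstrength}
                )

                # volumetric model (totals, ml)
                totals_a, totals_b = {}, {}
                is_outlier = rng.random() < config.outlier_rate
                outlier_roi = str(rng.choice(ROIS)) if is_outlier else ""
                outlier_sign = float(rng.choice([-1.0, 1.0])) if is_outlier else 0.0
                for r, roi in enumerate(ROIS):
                    z = (
                        config.effect_sizes[roi][true_status]
                        + config.scanner_offsets.get(manufacturer, 0.0)
                        + config.field_offsets.get(fstrength, 0.0)
                        + b_by_p[i, r]
                        + rng.normal(0.0, config.residual_sd)
                    )
                    da = age - config.age_center
                    total = (
                        config.roi_baseline_ml[roi]
                        + config.tiv_slope[roi] * (tiv_by_p[i] - config.tiv_mean_sd[0])
                        + config.age_slope_ml[roi] * da
                        + config.age_quad_ml[roi] * da**2
                        + config.roi_scale_ml[roi] * z
                    )
                    totals_a[roi] = max(total, 0.0)
                    noise = rng.normal(0.0, config.interpipeline_noise_sd[roi])
                    b_total = totals_a[roi] + noise
                    if is_outlier and roi == outlier_roi:
                        b_total += outlier_sign * config.outlier_displacement[roi]
                    totals_b[roi] = max(b_total, 0.0)

                subq = rng.random() < config.subquality_rate
                if subq:
                    quality = float(rng.uniform(20.0, config.quality_threshold - 0.01))
                else:
                    quality = float(rng.uniform(config.quality_threshold, 99.9))

                vol = {"scan_id": scan_id}
                for suffix, totals in (("a", totals_a), ("b", totals_b)):
                    vol[f"gm_{suffix}"] = totals["gm"]
                    vol[f"hip_left_{suffix}"] = totals["hippocampus"] * HIP_SPLIT[0]
                    vol[f"hip_right_{suffix}"] = totals["hippocampus"] * HIP_SPLIT[1]
                    for part, frac in zip(("llat", "rlat", "linf", "rinf"), VENT_SPLIT):
                        vol[f"vent_{part}_{suffix}"] = totals["ventricles"] * frac
                vol["tiv"] = tiv_by_p[i]
                vol["quality_pct"] = quality
                vol_rows.append(vol)

                truth_rows.append(
                    {"scan_id": scan_id, "participant_id": pid, "visit_id": visit_id,
                     "true_is_t1": proto.is_t1, "true_has_contrast": proto.has_contrast,
                     "true_outlier": is_outlier, "outlier_roi": outlier_roi,
                     "true_subquality": subq, "true_status": true_status}
                )

    scans = pd.DataFrame.from_records(scan_rows, columns=TABLE_SCHEMAS["scan_metadata"])
    volumes = pd.DataFrame.from_records(vol_rows, columns=TABLE_SCHEMAS["volumes"])
    # normalise dtypes so a CSV round trip is lossless
    scans["acquisition_date"] = pd.to_datetime(scans["acquisition_date"])
    scans["slice_count"] = scans["slice_count"].astype("int64")
    scans["field_strength"] = scans["field_strength"].astype(float)
    events["event_date"] = pd.to_datetime(events["event_date"])
    participants["participant_id"] = participants["participant_id"].astype(str)
    participants["birth_date"] = pd.to_datetime(participants["birth_date"])
    transitions["transition_date"] = pd.to_datetime(transitions["transition_date"])
    truth = GroundTruth(
        per_scan=pd.DataFrame.from_records(truth_rows, columns=TABLE_SCHEMAS["ground_truth"]),
        transitions=transitions,
        true_effects={roi: _dd(config.effect_sizes[roi]) for roi in ROIS},
    )
    return SimulatedCohort(scans, volumes, events, participants, truth)


# ---------------------------------------------------------------------------
# lightweight analysis-row generator for calibration studies


def simulate_analysis_rows(
    n_scans: int,
    effect_by_status: Mapping[str, Mapping[str, float]] | Mapping[str, float],
    status_probs: Mapping[str, float] | None = None,
    intercept_sd: float = 0.5,
    residual_sd: float = 0.7,
    dup_rate: float = 0.3,
    cohort: str = "OSTPRE",
    age_fn=None,
    tiv_fn=None,
    seed: int = 0,
) -> pd.DataFrame:
    """Directly simulate modelling observations on the standardized scale.

    One cluster per participant; a fraction ``dup_rate`` of participants
    contribute two scans (~1.3 scans/participant at the default), each
    participant keeps one status across scans, and

        y = effect[status] + age_fn(age) + tiv_fn(tiv_std) + b_i + eps,

    with ``b_i ~ N(0, intercept_sd^2)`` shared within participant and
    ``eps ~ N(0, residual_sd^2)`` per scan. ``effect_by_status`` may be one
    mapping status->shift (single response returned in column ``y``) and the
    returned frame is truncated to exactly ``n_scans`` rows.

    This generator feeds calibration studies of the modelling stage (type-I
    error, effect recovery, ordering); the full four-table structure comes
    from :func:`simulate_cohort`.
    """
    rng = np.random.default_rng(seed)
    if status_probs is None:
        status_probs = {"NMC": 0.40, "SMC": 0.20, "MCI": 0.08, "D": 0.32}
    cats = [c for c in CATEGORY_ORDER if status_probs.get(c, 0) > 0]
    p = np.asarray([status_probs[c] for c in cats], dtype=float)
    p /= p.sum()
    if age_fn is None:
        age_fn = lambda a: -0.03 * (a - 75.0)
    if tiv_fn is None:
        tiv_fn = lambda t: 0.2 * t

    n_pid = n_scans  # upper bound; truncated below
    statuses = np.asarray(cats, dtype=object)[rng.choice(len(cats), size=n_pid, p=p)]
    dup = rng.random(n_pid) < dup_rate
    n_scans_per = 1 + dup.astype(int)
    cum = np.cumsum(n_scans_per)
    n_keep = int(np.searchsorted(cum, n_scans) + 1)
    statuses, n_scans_per = statuses[:n_keep], n_scans_per[:n_keep]
    b = rng.normal(0.0, intercept_sd, size=n_keep)

    pid = np.repeat([f"P{i:06d}" for i in range(n_keep)], n_scans_per)
    status = np.repeat(statuses, n_scans_per)
    b_rep = np.repeat(b, n_scans_per)
    n = pid.size
    age = rng.uniform(62.0, 90.0, size=n)
    tiv = rng.normal(0.0, 1.0, size=n)
    manufacturer = np.asarray(["Siemens", "Philips"], dtype=object)[
        rng.choice(2, size=n, p=[0.8, 0.2])
    ]
    fstrength = np.asarray([1.5, 3.0])[rng.choice(2, size=n, p=[0.8, 0.2])]
    eff = np.asarray([float(effect_by_status[s]) for s in status])
    y = eff + age_fn(age) + tiv_fn(tiv) + b_rep + rng.normal(0.0, residual_sd, size=n)
    rows = pd.DataFrame(
        {
            "scan_id": [f"S{i:06d}" for i in range(n)],
            "participant_id": pid,
            "status": status,
            "cohort": cohort,
            "age": age,
            "tiv_std": tiv,
            "manufacturer": manufacturer,
            "field_strength": fstrength,
            "y": y,
        }
    )
    return rows.iloc[:n_scans].reset_index(drop=True)


# ---------------------------------------------------------------------------
# table I/O (CSV, ISO-8601 dates, schema-checked round trip)


class SchemaError(ValueError):
    """Raised when a table's columns do not match the documented schema."""


DATE_COLUMNS = {
    "scan_metadata": ["acquisition_date"],
    "volumes": [],
    "register_events": ["event_date"],
    "participants": ["birth_date"],
    "ground_truth": [],
    "ground_truth_transitions": ["transition_date"],
}

TABLE_SCHEMAS = {
    "scan_metadata": [
        "scan_id", "participant_id", "visit_id", "acquisition_date",
        "procedure_code", "protocol_name", "slice_count", "manufacturer",
        "field_strength",
    ],
    "volumes": [
        "scan_id",
        "gm_a", "hip_left_a", "hip_right_a",
        "vent_llat_a", "vent_rlat_a", "vent_linf_a", "vent_rinf_a",
        "gm_b", "hip_left_b", "hip_right_b",
        "vent_llat_b", "vent_rlat_b", "vent_linf_b", "vent_rinf_b",
        "tiv", "quality_pct",
    ],
    "register_events": ["participant_id", "event_date", "source", "code"],
    "participants": ["participant_id", "birth_date", "sex", "cohort"],
    "ground_truth": [
        "scan_id", "participant_id", "visit_id", "true_is_t1",
        "true_has_contrast", "true_outlier", "outlier_roi", "true_subquality",
        "true_status",
    ],
    "ground_truth_transitions": ["participant_id", "category", "transition_date"],
}

BOOL_COLUMNS = {
    "ground_truth": ["true_is_t1", "true_has_contrast", "true_outlier", "true_subquality"],
}


def _check_schema(name: str, columns: Sequence[str]) -> None:
    expected = TABLE_SCHEMAS[name]
    missing = [c for c in expected if c not in columns]
    extra = [c for c in columns if c not in expected]
    if missing or extra:
        raise SchemaError(
            f"table {name!r}: missing columns {missing}, unexpected columns {extra}"
        )


def write_tables(tables: Mapping[str, pd.DataFrame], directory) -> dict:
    """Write tables as CSV with ISO-8601 dates; returns name -> path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in tables.items():
        if name not in TABLE_SCHEMAS:
            raise SchemaError(f"unknown table {name!r}")
        _check_schema(name, df.columns)
        out = df[TABLE_SCHEMAS[name]].copy()
        for col in DATE_COLUMNS[name]:
            out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
        path = directory / f"{name}.csv"
        out.to_csv(path, index=False)
        paths[name] = path
    return paths


def read_tables(directory, names: Sequence[str] | None = None) -> dict:
    """Read CSV tables back; dates parsed, schema enforced."""
    directory = Path(directory)
    if names is None:
        names = [n for n in TABLE_SCHEMAS if (directory / f"{n}.csv").exists()]
    tables = {}
    for name in names:
        path = directory / f"{name}.csv"
        df = pd.read_csv(path, dtype={"visit_id": str, "participant_id": str})
        _check_schema(name, df.columns)
        for col in DATE_COLUMNS[name]:
            df[col] = pd.to_datetime(df[col], format="%Y-%m-%d")
        for col in BOOL_COLUMNS.get(name, []):
            df[col] = df[col].astype(bool)
        if name == "ground_truth" and "outlier_roi" in df:
            df["outlier_roi"] = df["outlier_roi"].fillna("")
        tables[name] = df
    return tables
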