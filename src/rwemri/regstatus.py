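"""Register-based cognitive-status assignment.

Each MRI visit is classified into one of four ordered categories — no memory
complaints (NMC) < subjective memory complaints (SMC) < mild cognitive
impairment (MCI) < dementia (D) — from dated, coded events drawn from
administrative health registers (hospital discharge, primary care, causes of
death, special reimbursement, drug purchases).

The rule has two steps:

1. *Baseline*: the most severe category among events dated on or before the
   visit date; NMC when no relevant code exists.
2. *Upgrade*: a milder baseline is promoted when the next more severe category
   is recorded within a window (default 365 days) after the visit — SMC
   followed by MCI becomes MCI, MCI followed by dementia becomes dementia.
   Under the default ``printed_pairs`` policy only these one-step promotions
   apply; ``max_within_window`` instead takes the maximum category observed in
   the window (NMC baselines are never upgraded under either policy, and a
   dementia baseline cannot increase).

Register codes are mapped to categories through a configurable
:class:`CodeMap` (regex patterns), since concrete national code lists are
register-specific.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: Ordered cognitive-status categories, mildest first.
CATEGORY_ORDER: tuple[str, ...] = ("NMC", "SMC", "MCI", "D")

#: Rank of each category (NMC=0 ... D=3).
CATEGORY_RANK: Mapping[str, int] = {c: i for i, c in enumerate(CATEGORY_ORDER)}

#: Categories a register event can carry (NMC is the absence of events).
EVENT_CATEGORIES: tuple[str, ...] = ("SMC", "MCI", "D")

UPGRADE_POLICIES = ("printed_pairs", "max_within_window", "none")


class CodeMapError(ValueError):
    """Raised for an inconsistent code→category mapping."""


@dataclass(frozen=True)
class CodeMap:
    """Mapping from register-code regex patterns to status categories.

    Parameters
    ----------
    patterns
        Sequence of ``(pattern, category)`` pairs. Patterns are matched with
        unanchored :func:`re.search` against the event's code string. A code
        matching no pattern maps to no category (the event is dropped).
    """

    patterns: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for pattern, category in self.patterns:
            if category not in EVENT_CATEGORIES:
                raise CodeMapError(
                    f"pattern {pattern!r} maps to unknown category {category!r}; "
                    f"expected one of {EVENT_CATEGORIES}"
                )
            if pattern in seen and seen[pattern] != category:
                raise CodeMapError(
                    f"pattern {pattern!r} maps to both {seen[pattern]!r} and "
                    f"{category!r}"
                )
            seen[pattern] = category
            re.compile(pattern)  # surface bad regexes at construction

    @classmethod
    def from_dict(cls, mapping: Mapping[str, str]) -> "CodeMap":
        return cls(tuple(mapping.items()))

    @classmethod
    def from_yaml(cls, path) -> "CodeMap":
        """Load a codemap from a YAML file of ``pattern: category`` entries
        (or a list of ``{pattern:, category:}`` mappings)."""
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if isinstance(data, dict):
            return cls.from_dict(data)
        pairs = [(item["pattern"], item["category"]) for item in data]
        return cls(tuple(pairs))

    def categorize(self, code: str) -> Optional[str]:
        """Category of a single code, or ``None`` when no pattern matches.

        When several patterns match, the most severe category wins.
        """
        best: Optional[str] = None
        for pattern, category in self.patterns:
            if re.search(pattern, code):
                if best is None or CATEGORY_RANK[category] > CATEGORY_RANK[best]:
                    best = category
        return best


#: Synthetic default mapping used by the simulator and demo pipeline. Real
#: deployments supply their register-specific lists via YAML.
DEFAULT_CODEMAP = CodeMap(
    (
        (r"^R41", "SMC"),
        (r"^SMC", "SMC"),
        (r"^F06\.7", "MCI"),
        (r"^MCI", "MCI"),
        (r"^F0[0-3]", "D"),
        (r"^G30", "D"),
        (r"^DEM", "D"),
    )
)


@dataclass(frozen=True)
class StatusConfig:
    """Rules for turning dated events into a per-visit status."""

    upgrade_window_days: int = 365
    upgrade_policy: str = "printed_pairs"

    def __post_init__(self) -> None:
        if self.upgrade_window_days < 0:
            raise ValueError(
                f"upgrade_window_days must be >= 0, got {self.upgrade_window_days}"
            )
        if self.upgrade_policy not in UPGRADE_POLICIES:
            raise ValueError(
                f"upgrade_policy must be one of {UPGRADE_POLICIES}, "
                f"got {self.upgrade_policy!r}"
            )


@dataclass(frozen=True)
class StatusAssignment:
    """Status of one scan: baseline, final after the upgrade rule, and the
    event that triggered an upgrade (if any)."""

    scan_id: str
    baseline_category: str
    final_category: str
    upgrade_applied: bool
    triggering_event: Optional[pd.Timestamp] = None

    def __post_init__(self) -> None:
        assert CATEGORY_RANK[self.final_category] >= CATEGORY_RANK[self.baseline_category]
        assert self.upgrade_applied == (
            self.final_category != self.baseline_category
        )


def map_events(events: pd.DataFrame, codemap: CodeMap) -> pd.DataFrame:
    """Attach a ``category`` column to register events; drop unmapped codes.

    The number of dropped (unrecognised-code) events is logged. Events from
    different register sources carrying the same code are all retained.
    """
    if events.empty:
        out = events.copy()
        out["category"] = pd.Series(dtype=object)
        return out
    categories = events["code"].astype(str).map(codemap.categorize)
    n_dropped = int(categories.isna().sum())
    if n_dropped:
        logger.info("map_events: dropped %d events with unmapped codes", n_dropped)
    out = events.loc[categories.notna()].copy()
    out["category"] = categories[categories.notna()]
    return out


def _as_timestamp(d) -> pd.Timestamp:
    return pd.Timestamp(d)


def baseline_status(events: pd.DataFrame, visit_date) -> str:
    """Most severe category recorded on or before the visit date; NMC if none.

    ``events`` must already carry a ``category`` column (see
    :func:`map_events`) and belong to a single participant. An event dated
    exactly on the visit date counts toward the baseline.
    """
    visit_date = _as_timestamp(visit_date)
    if events.empty:
        return "NMC"
    prior = events.loc[pd.to_datetime(events["event_date"]) <= visit_date]
    if prior.empty:
        return "NMC"
    return max(prior["category"], key=CATEGORY_RANK.__getitem__)


def apply_upgrade(
    baseline: str,
    events: pd.DataFrame,
    visit_date,
    config: StatusConfig = StatusConfig(),
    scan_id: str = "",
) -> StatusAssignment:
    """Apply the post-visit upgrade rule to a baseline category.

    The window is half-open: ``(visit_date, visit_date + window_days]`` in
    calendar days. Under ``printed_pairs`` an SMC baseline is promoted to MCI
    by an MCI event in the window and an MCI baseline to dementia by a
    dementia event; NMC and dementia baselines never change. Under
    ``max_within_window`` the final status is the maximum of the baseline and
    any in-window event category, except that an NMC baseline is unchanged.
    """
    visit_date = _as_timestamp(visit_date)
    final = baseline
    trigger: Optional[pd.Timestamp] = None
    if config.upgrade_policy != "none" and baseline not in ("NMC", "D") and not events.empty:
        lo = visit_date
        hi = visit_date + pd.Timedelta(days=config.upgrade_window_days)
        dates = pd.to_datetime(events["event_date"])
        in_window = events.loc[(dates > lo) & (dates <= hi)]
        if not in_window.empty:
            if config.upgrade_policy == "printed_pairs":
                target = CATEGORY_ORDER[CATEGORY_RANK[baseline] + 1]
                hits = in_window.loc[in_window["category"] == target]
                if not hits.empty:
                    final = target
                    trigger = pd.to_datetime(hits["event_date"]).min()
            else:  # max_within_window
                best = max(in_window["category"], key=CATEGORY_RANK.__getitem__)
                if CATEGORY_RANK[best] > CATEGORY_RANK[baseline]:
                    final = best
                    mask = in_window["category"] == best
                    trigger = pd.to_datetime(in_window.loc[mask, "event_date"]).min()
    return StatusAssignment(
        scan_id=scan_id,
        baseline_category=baseline,
        final_category=final,
        upgrade_applied=final != baseline,
        triggering_event=trigger,
    )


def assign_status(
    events: pd.DataFrame,
    visit_date,
    config: StatusConfig = StatusConfig(),
    scan_id: str = "",
) -> StatusAssignment:
    """Baseline + upgrade in one step for a single participant's events."""
    base = baseline_status(events, visit_date)
    return apply_upgrade(base, events, visit_date, config, scan_id=scan_id)


def assign_all(
    scans: pd.DataFrame,
    events: pd.DataFrame,
    codemap: CodeMap = DEFAULT_CODEMAP,
    config: StatusConfig = StatusConfig(),
    participants: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Assign a status to every scan.

    Parameters
    ----------
    scans
        Table with ``scan_id``, ``participant_id`` and ``acquisition_date``.
    events
        Raw register events (``participant_id``, ``event_date``, ``code``).
    codemap, config
        Mapping and rule parameters.
    participants
        Optional participant table; when given, scans whose participant is
        absent raise a ``ValueError`` listing the missing ids.

    Returns
    -------
    DataFrame with one row per scan: ``scan_id``, ``participant_id``,
    ``baseline_category``, ``final_category`` (as ``status``),
    ``upgrade_applied``.
    """
    if participants is not None:
        known = set(participants["participant_id"])
        missing = sorted(set(scans["participant_id"]) - known)
        if missing:
            raise ValueError(
                f"scans reference participants absent from the participant "
                f"table: {missing}"
            )
    mapped = map_events(events, codemap)
    by_pid = {pid: grp for pid, grp in mapped.groupby("participant_id")} if not mapped.empty else {}
    empty = mapped.iloc[0:0]
    records = []
    for row in scans.itertuples(index=False):
        pevents = by_pid.get(row.participant_id, empty)
        a = assign_status(pevents, row.acquisition_date, config, scan_id=row.scan_id)
        records.append(
            {
                "scan_id": row.scan_id,
                "participant_id": row.participant_id,
                "acquisition_date": pd.Timestamp(row.acquisition_date),
                "baseline_category": a.baseline_category,
                "status": a.final_category,
                "upgrade_applied": a.upgrade_applied,
            }
        )
    columns = [
        "scan_id",
        "participant_id",
        "acquisition_date",
        "baseline_category",
        "status",
        "upgrade_applied",
    ]
    return pd.DataFrame.from_records(records, columns=columns)
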