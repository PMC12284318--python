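"""Head-exam filtering and T1-weighted scan selection from acquisition metadata.

Clinical PACS exports mix organs, sequences and contrast states; structural
volumetry needs exactly one non-contrast T1-weighted scan per examination
visit. Selection proceeds in three metadata-only steps:

1. keep examinations whose radiologic procedure code marks a head exam
   (defaults AA1BG/AA1CG/AA1DG);
2. keep scans whose free-text protocol name matches an inclusion substring
   alternation (default ``mpr|mprage|t1_se|sag|tra|T1|TFE``), does not match
   an exclusion pattern (default ``gd``, gadolinium contrast), and has enough
   slices to cover the brain in 3-D (default >= 90);
3. when a visit retains several eligible scans, pick one uniformly at random,
   with a per-visit random stream so the choice is reproducible and stable
   under row reordering.

The inclusion alternation is deliberately loose (fragments such as ``tra`` or
``sag`` also occur in non-T1 protocol names); misclassified scans are caught
downstream by segmentation quality control, not here.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

#: Rejection reason labels, in the order the filters apply.
REASONS = (
    "not_head_exam",
    "pattern_no_match",
    "contrast_excluded",
    "too_few_slices",
    "not_selected_random",
)


@dataclass(frozen=True)
class SelectionConfig:
    """Parameters of the metadata filter.

    ``inclusion_pattern`` / ``exclusion_pattern`` are regex alternations
    applied unanchored to the protocol name. Matching is case-sensitive by
    default because the printed inclusion list distinguishes ``t1_se`` from
    ``T1``; set ``case_sensitive=False`` for lenient matching.
    """

    head_procedure_codes: frozenset = frozenset({"AA1BG", "AA1CG", "AA1DG"})
    inclusion_pattern: str = "mpr|mprage|t1_se|sag|tra|T1|TFE"
    exclusion_pattern: str = "gd"
    min_slices: int = 90
    case_sensitive: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_slices < 1:
            raise ValueError(f"min_slices must be >= 1, got {self.min_slices}")
        if not self.inclusion_pattern or not self.exclusion_pattern:
            raise ValueError("inclusion_pattern and exclusion_pattern must be non-empty")

    def _flags(self) -> int:
        return 0 if self.case_sensitive else re.IGNORECASE


@dataclass
class SelectionResult:
    """Outcome of per-visit selection.

    Attributes
    ----------
    selected
        visit key -> chosen scan_id.
    eligible_per_visit
        visit key -> list of eligible scan_ids (sorted).
    rejection_reason
        scan_id -> reason, for every scan not selected.
    """

    selected: dict
    eligible_per_visit: dict
    rejection_reason: dict

    def selected_ids(self) -> list:
        return sorted(self.selected.values())


def filter_head_exams(scans: pd.DataFrame, config: SelectionConfig = SelectionConfig()) -> pd.DataFrame:
    """Rows whose procedure code is a head-exam code; original order kept."""
    if scans.empty:
        return scans.copy()
    mask = scans["procedure_code"].astype(str).isin(config.head_procedure_codes)
    return scans.loc[mask].copy()


def is_eligible_t1(record, config: SelectionConfig = SelectionConfig()):
    """Eligibility of one scan record.

    Returns ``(eligible, reason)`` where ``reason`` is ``None`` for eligible
    scans and one of ``pattern_no_match`` / ``contrast_excluded`` /
    ``too_few_slices`` otherwise. A missing protocol name is treated as a
    non-match, not an error.
    """
    name = record.get("protocol_name") if isinstance(record, Mapping) else record["protocol_name"]
    flags = config._flags()
    if name is None or (isinstance(name, float) and np.isnan(name)):
        return False, "pattern_no_match"
    name = str(name)
    if not re.search(config.inclusion_pattern, name, flags):
        return False, "pattern_no_match"
    if re.search(config.exclusion_pattern, name, flags):
        return False, "contrast_excluded"
    if int(record["slice_count"]) < config.min_slices:
        return False, "too_few_slices"
    return True, None


def classify_scans(scans: pd.DataFrame, config: SelectionConfig = SelectionConfig()) -> pd.DataFrame:
    """Vectorised eligibility over a head-exam table.

    Adds ``eligible`` (bool) and ``reason`` (None for eligible rows).
    """
    out = scans.copy()
    if out.empty:
        out["eligible"] = pd.Series(dtype=bool)
        out["reason"] = pd.Series(dtype=object)
        return out
    flags = config._flags()
    names = out["protocol_name"].astype(str)
    inc = names.str.contains(config.inclusion_pattern, regex=True, flags=flags, na=False)
    exc = names.str.contains(config.exclusion_pattern, regex=True, flags=flags, na=False)
    enough = out["slice_count"].astype(int) >= config.min_slices
    reason = np.full(len(out), None, dtype=object)
    reason[~inc.to_numpy()] = "pattern_no_match"
    reason[(inc & exc).to_numpy()] = "contrast_excluded"
    reason[(inc & ~exc & ~enough).to_numpy()] = "too_few_slices"
    out["eligible"] = (inc & ~exc & enough).to_numpy()
    out["reason"] = reason
    return out


def _visit_rng(seed: int, participant_id, visit_id) -> np.random.Generator:
    # Stable per-visit stream: the choice for a visit depends only on
    # (seed, participant, visit), not on row order or other visits.
    key = f"{participant_id}\x1f{visit_id}".encode()
    digest = int.from_bytes(hashlib.blake2b(key, digest_size=8).digest(), "big")
    return np.random.default_rng(np.random.SeedSequence([seed, digest]))


def select_one_per_visit(eligible: pd.DataFrame, seed: int = 0) -> SelectionResult:
    """Choose one scan uniformly at random per (participant, visit).

    ``eligible`` must contain only eligible rows (see :func:`classify_scans`).
    Deterministic given ``seed``; a visit with a single eligible scan keeps it
    with probability 1.
    """
    selected: dict = {}
    eligible_per_visit: dict = {}
    rejection: dict = {}
    if eligible.empty:
        return SelectionResult(selected, eligible_per_visit, rejection)
    for (pid, vid), grp in eligible.groupby(["participant_id", "visit_id"], sort=True):
        ids = sorted(grp["scan_id"].astype(str))
        eligible_per_visit[(pid, vid)] = ids
        if len(ids) == 1:
            choice = ids[0]
        else:
            rng = _visit_rng(seed, pid, vid)
            choice = ids[int(rng.integers(len(ids)))]
        selected[(pid, vid)] = choice
        for sid in ids:
            if sid != choice:
                rejection[sid] = "not_selected_random"
    return SelectionResult(selected, eligible_per_visit, rejection)


def select_scans(scans: pd.DataFrame, config: SelectionConfig = SelectionConfig()) -> pd.DataFrame:
    """Full selection pass: head filter -> T1 eligibility -> per-visit choice.

    Returns the input table with ``eligible``, ``reason`` and ``selected``
    columns; every non-selected scan carries a rejection reason.
    """
    out = scans.copy()
    if out.empty:
        for col, dtype in (("eligible", bool), ("selected", bool), ("reason", object)):
            out[col] = pd.Series(dtype=dtype)
        return out
    head = out["procedure_code"].astype(str).isin(config.head_procedure_codes)
    classified = classify_scans(out, config)
    eligible = classified["eligible"] & head
    reason = classified["reason"].to_numpy(dtype=object, copy=True)
    reason[~head.to_numpy()] = "not_head_exam"
    result = select_one_per_visit(out.loc[eligible], seed=config.seed)
    chosen = set(result.selected.values())
    sel = out["scan_id"].astype(str).isin(chosen) & eligible
    reason[(eligible & ~sel).to_numpy()] = "not_selected_random"
    out["eligible"] = eligible.to_numpy()
    out["reason"] = reason
    out["selected"] = sel.to_numpy()
    return out


_SANITIZE = re.compile(r"[^A-Za-z0-9]")


def bids_name(record) -> str:
    """BIDS-style file stem ``sub-<participant>_ses-<visit>_T1w``.

    Identifiers are sanitised to alphanumerics; empty identifiers raise.
    """
    pid = _SANITIZE.sub("", str(record["participant_id"]))
    vid = _SANITIZE.sub("", str(record["visit_id"]))
    if not pid:
        raise ValueError("participant_id empty after sanitisation")
    if not vid:
        raise ValueError("visit_id empty after sanitisation")
    return f"sub-{pid}_ses-{vid}_T1w"


def bids_names(scans: pd.DataFrame) -> pd.Series:
    """Vectorised :func:`bids_name` that refuses identifier collisions.

    A collision is two distinct (participant, visit) pairs mapping to one
    sanitised name; repeated scans of the same visit share a name legally.
    """
    names = scans.apply(bids_name, axis=1)
    pairs = pd.DataFrame(
        {
            "name": names,
            "pid": scans["participant_id"].astype(str),
            "vid": scans["visit_id"].astype(str),
        }
    )
    per_name = pairs.groupby("name")[["pid", "vid"]].nunique()
    bad = per_name[(per_name["pid"] > 1) | (per_name["vid"] > 1)].index.tolist()
    if bad:
        raise ValueError(f"sanitised BIDS name collision: {bad}")
    return names
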