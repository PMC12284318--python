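"""End-to-end orchestration: simulate -> select -> qc -> status -> model -> report.

Each stage writes an immutable CSV under the run directory and the next stage
reads only those files (no hidden state), so any run can be audited or
resumed from its intermediates. Dropped-row counts with reasons are logged at
every stage boundary, mirroring a curation flowchart. A single global seed
deterministically derives per-stage seeds; rerunning with the same config and
seed reproduces every output byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from . import regstatus, scanselect, synthdata, volmodel, volqc
from .regstatus import CodeMap, StatusConfig, DEFAULT_CODEMAP
from .scanselect import SelectionConfig
from .synthdata import SimConfig, SimulatedCohort
from .volmodel import ModelConfig, VolumetricContrastModel
from .volqc import QCConfig, ROI_PAIRS

logger = logging.getLogger(__name__)

ROIS = synthdata.ROIS


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class RunConfig:
    sim: SimConfig = SimConfig()
    selection: SelectionConfig = SelectionConfig()
    qc: QCConfig = QCConfig()
    status: StatusConfig = StatusConfig()
    model: ModelConfig = ModelConfig()
    codemap: CodeMap = DEFAULT_CODEMAP
    cohort_matching: Mapping[str, object] = field(default_factory=lambda: {"sex": "F"})
    seed: int = 0
    n_trajectory_points: int = 25

    def stage_seeds(self) -> dict:
        """Deterministic per-stage seeds derived from the global seed."""
        state = np.random.SeedSequence(self.seed).generate_state(4)
        return {
            "sim": int(state[0] & 0x7FFFFFFF),
            "selection": int(state[1] & 0x7FFFFFFF),
        }

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "sim": dataclasses.asdict(self.sim),
                "selection": {
                    **dataclasses.asdict(self.selection),
                    "head_procedure_codes": sorted(self.selection.head_procedure_codes),
                },
                "qc": dataclasses.asdict(self.qc),
                "status": dataclasses.asdict(self.status),
                "model": dataclasses.asdict(self.model),
                "codemap": list(self.codemap.patterns),
                "cohort_matching": dict(self.cohort_matching),
                "seed": self.seed,
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "sim" in raw:
            kwargs["sim"] = SimConfig(**raw["sim"])
        if "selection" in raw:
            sel = dict(raw["selection"])
            if "head_procedure_codes" in sel:
                sel["head_procedure_codes"] = frozenset(sel["head_procedure_codes"])
            kwargs["selection"] = SelectionConfig(**sel)
        if "qc" in raw:
            kwargs["qc"] = QCConfig(**raw["qc"])
        if "status" in raw:
            kwargs["status"] = StatusConfig(**raw["status"])
        if "model" in raw:
            kwargs["model"] = ModelConfig(**raw["model"])
        if "codemap" in raw:
            kwargs["codemap"] = CodeMap.from_dict(raw["codemap"])
        for key in ("cohort_matching", "seed", "n_trajectory_points"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)


@dataclass
class RunReport:
    counts: dict
    characteristics: pd.DataFrame
    contrasts: pd.DataFrame
    config_hash: str
    seed: int
    timestamp: Optional[str] = None  # in-memory only; never written to disk

    def markdown(self) -> str:
        lines = ["# Pipeline run report", ""]
        lines.append(f"- config hash: `{self.config_hash}`")
        lines.append(f"- seed: {self.seed}")
        lines.append("")
        lines.append("## Flowchart counts")
        lines.append("")
        for key, val in self.counts.items():
            lines.append(f"- {key}: {val}")
        lines.append("")
        lines.append("## Characteristics by cohort")
        lines.append("")
        lines.append(self.characteristics.to_csv(index=False).rstrip())
        lines.append("")
        lines.append("## Adjusted contrasts")
        lines.append("")
        lines.append(self.contrasts.to_csv(index=False).rstrip())
        lines.append("")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# analysis-row construction


def build_analysis_rows(
    scans: pd.DataFrame,
    volumes: pd.DataFrame,
    statuses: pd.DataFrame,
    participants: pd.DataFrame,
    cohort_matching: Mapping[str, object] | None = None,
) -> pd.DataFrame:
    """Join the curated intermediates into one modelling table.

    One row per analyzed scan with ROI totals from pipeline A, their
    standardized versions (``z_gm``, ``z_hippocampus``, ``z_ventricles``,
    standardized over the full analysis sample), standardized TIV, age at
    scan, scanner covariates, status and cohort. ``cohort_matching`` filters
    the participant table (equality on each given column) before joining.
    """
    parts = participants.copy()
    for col, val in (cohort_matching or {}).items():
        parts = parts.loc[parts[col] == val]
    totals = volqc.roi_totals(volumes)
    df = (
        scans[["scan_id", "participant_id", "visit_id", "acquisition_date",
               "manufacturer", "field_strength"]]
        .merge(totals[["scan_id"] + [f"{r}_a" for r in ROIS]], on="scan_id")
        .merge(volumes[["scan_id", "tiv"]], on="scan_id")
        .merge(statuses[["scan_id", "status"]], on="scan_id")
        .merge(parts[["participant_id", "birth_date", "cohort"]], on="participant_id")
    )
    if df.empty:
        for col in ["age", "tiv_std"] + [f"z_{r}" for r in ROIS]:
            df[col] = pd.Series(dtype=float)
        return df
    df["age"] = (
        pd.to_datetime(df["acquisition_date"]) - pd.to_datetime(df["birth_date"])
    ).dt.days / 365.25
    df["tiv_std"], _, _ = volmodel.standardize(df["tiv"])
    for roi in ROIS:
        df[f"z_{roi}"], _, _ = volmodel.standardize(df[f"{roi}_a"])
    return df


def characteristics_table(rows: pd.DataFrame) -> pd.DataFrame:
    """Population-characteristics summary by cohort: scan and participant
    counts, age mean (SD), field-strength / manufacturer / status
    percentages."""
    records = []
    for cohort, grp in rows.groupby("cohort"):
        n_scans = len(grp)
        records.append({"cohort": cohort, "block": "counts", "item": "scans",
                        "value": f"{n_scans}"})
        records.append({"cohort": cohort, "block": "counts", "item": "participants",
                        "value": f"{grp['participant_id'].nunique()}"})
        records.append(
            {"cohort": cohort, "block": "age", "item": "mean (SD), years",
             "value": f"{grp['age'].mean():.1f} ({grp['age'].std(ddof=1):.1f})"}
        )
        for block, col in (("field_strength", "field_strength"),
                           ("manufacturer", "manufacturer"),
                           ("status", "status")):
            counts = grp[col].value_counts().sort_index()
            for level, n in counts.items():
                records.append(
                    {"cohort": cohort, "block": block, "item": str(level),
                     "value": f"{n} ({100 * n / n_scans:.1f}%)"}
                )
    return pd.DataFrame.from_records(
        records, columns=["cohort", "block", "item", "value"]
    )


# ---------------------------------------------------------------------------
# run_all


def _write(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def run_all(config: RunConfig, out_dir) -> RunReport:
    """Run every stage, writing intermediates and a report under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = config.stage_seeds()

    # --- stage: simulate --------------------------------------------------
    try:
        sim_cfg = dataclasses.replace(config.sim, seed=seeds["sim"])
        cohort = synthdata.simulate_cohort(sim_cfg)
        synthdata.write_tables(cohort.tables(), out / "tables")
    except Exception as exc:  # pragma: no cover - defensive
        raise StageError(f"stage 'simulate' failed: {exc}") from exc

    # --- stage: select ----------------------------------------------------
    try:
        sel_cfg = dataclasses.replace(config.selection, seed=seeds["selection"])
        selection = scanselect.select_scans(cohort.scans, sel_cfg)
        _write(selection, out / "selection.csv")
    except Exception as exc:
        raise StageError(f"stage 'select' failed: {exc}") from exc
    selected = selection.loc[selection["selected"]]
    logger.info(
        "select: %d of %d scans selected", len(selected), len(selection)
    )

    # --- stage: qc --------------------------------------------------------
    try:
        sel_volumes = cohort.volumes.loc[
            cohort.volumes["scan_id"].isin(selected["scan_id"])
        ].reset_index(drop=True)
        qc_report = volqc.run_qc(sel_volumes, config.qc)
        _write(qc_report, out / "qc_report.csv")
    except Exception as exc:
        raise StageError(f"stage 'qc' failed: {exc}") from exc
    usable_ids = set(qc_report.loc[qc_report["disposition"] == "pass", "scan_id"])

    # --- stage: status ----------------------------------------------------
    try:
        statuses = regstatus.assign_all(
            selected, cohort.events, config.codemap, config.status,
            participants=cohort.participants,
        )
        _write(statuses, out / "status.csv")
    except Exception as exc:
        raise StageError(f"stage 'status' failed: {exc}") from exc

    # --- stage: analysis rows --------------------------------------------
    try:
        analyzed_scans = selected.loc[selected["scan_id"].isin(usable_ids)]
        rows = build_analysis_rows(
            analyzed_scans, sel_volumes, statuses, cohort.participants,
            config.cohort_matching,
        )
        _write(rows, out / "analysis_rows.csv")
    except Exception as exc:
        raise StageError(f"stage 'analysis_rows' failed: {exc}") from exc

    # --- stage: model -----------------------------------------------------
    margins_all, contrasts_all, traj_all = [], [], []
    fit_possible = (
        len(rows) >= 30
        and rows["participant_id"].nunique() >= 2
        and rows["status"].nunique() >= 2
    )
    if fit_possible:
        try:
            for roi in ROIS:
                res = VolumetricContrastModel(
                    rows, response=f"z_{roi}", config=config.model
                ).fit()
                m = res.margins(); m.insert(0, "roi", roi); margins_all.append(m)
                c = res.contrasts(); c.insert(0, "roi", roi); contrasts_all.append(c)
                lo, hi = res.model.age_basis.boundary
                grid = np.linspace(lo, hi, config.n_trajectory_points)
                t = res.trajectory("age", grid); t.insert(0, "roi", roi)
                t = t.rename(columns={"age": "grid"}); t["variable"] = "age"
                traj_all.append(t)
                lo, hi = res.model.tiv_basis.boundary
                grid = np.linspace(lo, hi, config.n_trajectory_points)
                t = res.trajectory("tiv_std", grid); t.insert(0, "roi", roi)
                t = t.rename(columns={"tiv_std": "grid"}); t["variable"] = "tiv_std"
                traj_all.append(t)
        except Exception as exc:
            raise StageError(f"stage 'model' failed: {exc}") from exc
    empty_contrast = pd.DataFrame(
        columns=["roi", "contrast", "scope", "estimate", "se", "ci_low", "ci_high", "p_value"]
    )
    margins = pd.concat(margins_all, ignore_index=True) if margins_all else pd.DataFrame(
        columns=["roi", "status", "cohort", "margin", "se", "ci_low", "ci_high"]
    )
    contrasts = pd.concat(contrasts_all, ignore_index=True) if contrasts_all else empty_contrast
    trajectories = pd.concat(traj_all, ignore_index=True) if traj_all else pd.DataFrame(
        columns=["roi", "grid", "estimate", "se", "ci_low", "ci_high", "variable"]
    )
    _write(margins, out / "margins.csv")
    _write(contrasts, out / "contrasts.csv")
    _write(trajectories, out / "trajectories.csv")

    # --- stage: report ----------------------------------------------------
    counts = {
        "scans_in": int(len(cohort.scans)),
        "head_exams": int(len(scanselect.filter_head_exams(cohort.scans, sel_cfg))),
        "eligible": int(selection["eligible"].sum()),
        "selected": int(selection["selected"].sum()),
        "quality_passed": int(qc_report["pass_quality"].sum()),
        "flagged": int(qc_report["flagged"].sum()),
        "excluded": int((qc_report["disposition"] == "excluded").sum()),
        "analyzed": int(len(rows)),
    }
    chars = characteristics_table(rows)
    _write(pd.DataFrame([counts]), out / "counts.csv")
    _write(chars, out / "characteristics.csv")
    (out / "provenance.json").write_text(
        json.dumps({"config_hash": config.config_hash(), "seed": config.seed}, indent=2)
        + "\n"
    )
    # the report is rendered from the saved intermediates so that
    # regenerating it later reproduces report.md exactly
    report = make_report(out)
    (out / "report.md").write_text(report.markdown())
    return report


def make_report(run_dir, config_hash: str = "", seed: int = 0) -> RunReport:
    """Regenerate the report purely from saved intermediates."""
    run_dir = Path(run_dir)
    required = ["counts.csv", "characteristics.csv", "contrasts.csv", "analysis_rows.csv"]
    for name in required:
        if not (run_dir / name).exists():
            raise FileNotFoundError(f"missing intermediate: {name}")
    counts = pd.read_csv(run_dir / "counts.csv").iloc[0].to_dict()
    counts = {k: int(v) for k, v in counts.items()}
    chars = pd.read_csv(run_dir / "characteristics.csv", dtype=str)
    contrasts = pd.read_csv(run_dir / "contrasts.csv")
    prov_path = run_dir / "provenance.json"
    if prov_path.exists():
        prov = json.loads(prov_path.read_text())
        config_hash = config_hash or prov.get("config_hash", "")
        seed = seed or prov.get("seed", 0)
    return RunReport(
        counts=counts, characteristics=chars, contrasts=contrasts,
        config_hash=config_hash, seed=seed,
    )
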