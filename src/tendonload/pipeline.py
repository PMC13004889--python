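"""Pipeline orchestration: ingest -> QC -> estimation -> metrics -> reports.

The analysis is deterministic given its inputs; all randomness lives in the
synthetic-data generator. ``analyze_cohort`` is the in-memory workhorse;
the ``stage_*`` functions mirror it on serialized inputs/outputs so each
stage can be run independently from the CLI, and ``run_pipeline`` chains
them into the full report bundle with a run manifest.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigError, DependencyError, DomainError
from .io import (
    DEFAULT_DIALECT,
    FunctionalMeasures,
    InsoleRecording,
    ParticipantProfile,
    assemble_dataset,
    read_recording,
    write_recording,
)
from .load import DEFAULT_GEOMETRY, SensorGeometry, TendonLoadTrace, estimate_trace
from .metrics import (
    THR_HIGH,
    THR_OVERALL,
    DayLoad,
    summary_from_day_loads,
    trace_day_load,
)
from .qc import (
    DEFAULT_RULES,
    QCReport,
    QCRules,
    STATUS_EXCLUDED,
    correct_baseline_drift,
    screen_recording,
)
from .reliability import DESIGN_DAYS, reliability_analysis
from .stats import DEFAULT_ROSTER, correlation_table
from .synth import Cohort, ScenarioConfig, generate_cohort

log = logging.getLogger("tendonload")


@dataclass(frozen=True)
class PipelineConfig:
    geometry: SensorGeometry = DEFAULT_GEOMETRY
    qc_rules: QCRules = DEFAULT_RULES
    thr_overall: float = THR_OVERALL
    thr_high: float = THR_HIGH
    roster: tuple[str, ...] = DEFAULT_ROSTER

    def __post_init__(self) -> None:
        if not (0 < self.thr_overall < self.thr_high):
            raise ConfigError(
                f"thresholds must satisfy 0 < overall < high, got "
                f"{self.thr_overall}, {self.thr_high}"
            )

    def sha256(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()


DEFAULT_CONFIG = PipelineConfig()


@dataclass
class PipelineResult:
    qc_reports: dict[str, QCReport]
    day_loads: pd.DataFrame  # participant_id, day_index, 4 raw columns
    summaries: pd.DataFrame  # one row per participant
    reliability: pd.DataFrame
    correlations: pd.DataFrame
    exclusions: pd.DataFrame  # session- and participant-level exclusion log
    manifest: dict


def qc_recording(
    rec: InsoleRecording, profile: ParticipantProfile, rules: QCRules = DEFAULT_RULES
) -> tuple[InsoleRecording, QCReport]:
    """Drift-correct then screen one recording."""
    corrected, drift_report = correct_baseline_drift(rec, rules=rules)
    report = screen_recording(corrected, profile, rules, drift_report)
    return corrected, report


def analyze_cohort(
    recordings: Iterable[InsoleRecording],
    profiles: Mapping[str, ParticipantProfile],
    outcomes: pd.DataFrame | None = None,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> PipelineResult:
    """Run the full analysis in memory.

    Participants whose sessions are all excluded by QC are dropped from the
    summaries and logged, mirroring field studies that must discard
    participants with predominantly erroneous recordings.
    """
    by_pid: dict[str, list[InsoleRecording]] = {}
    for rec in recordings:
        by_pid.setdefault(rec.participant_id, []).append(rec)
    unknown = sorted(set(by_pid) - set(profiles))
    if unknown:
        raise DomainError(f"recordings reference unknown participants {unknown}")

    qc_reports: dict[str, QCReport] = {}
    excl_rows: list[dict] = []
    day_load_rows: list[dict] = []
    day_loads_by_pid: dict[str, dict[int, DayLoad]] = {}
    summary_rows: list[dict] = []

    for pid in sorted(by_pid):
        profile = profiles[pid]
        dataset = assemble_dataset(by_pid[pid], profile)
        per_day: dict[int, DayLoad] = {}
        n_valid = 0
        for rec in dataset.recordings:
            corrected, report = qc_recording(rec, profile, config.qc_rules)
            qc_reports[rec.session_id] = report
            if report.status == STATUS_EXCLUDED:
                log.info(
                    "excluded session %s (%s)", rec.session_id, report.exclusion_reason
                )
                excl_rows.append(
                    {
                        "level": "session",
                        "participant_id": pid,
                        "session_id": rec.session_id,
                        "reason": report.exclusion_reason,
                    }
                )
                continue
            n_valid += 1
            trace = estimate_trace(
                corrected, config.geometry, profile, qc_report=report
            )
            dl = trace_day_load(trace, config.thr_overall, config.thr_high)
            per_day[rec.day_index] = per_day.get(rec.day_index, DayLoad()) + dl
        if n_valid == 0:
            log.warning("participant %s has no valid recordings; excluded", pid)
            excl_rows.append(
                {
                    "level": "participant",
                    "participant_id": pid,
                    "session_id": "",
                    "reason": "no-valid-recordings",
                }
            )
            continue
        day_loads_by_pid[pid] = per_day
        for d in sorted(per_day):
            dl = per_day[d]
            day_load_rows.append(
                {
                    "participant_id": pid,
                    "day_index": d,
                    "loading_time_h": dl.loading_time_h,
                    "high_time_h": dl.high_time_h,
                    "overall_impulse_bwh": dl.overall_impulse_bwh,
                    "high_impulse_bwh": dl.high_impulse_bwh,
                }
            )
        summary = summary_from_day_loads(pid, per_day)
        summary_rows.append(summary.as_dict())

    summaries = pd.DataFrame(summary_rows)
    if not summaries.empty:
        summaries = summaries.set_index("participant_id")
        summaries["days_included"] = summaries["days_included"].map(
            lambda v: ",".join(map(str, v))
        )
    day_loads = pd.DataFrame(day_load_rows)

    eligible = {
        pid: loads for pid, loads in day_loads_by_pid.items() if len(loads) >= DESIGN_DAYS
    }
    if len(eligible) >= 2:
        reliability = reliability_analysis(eligible)
    else:
        log.warning("fewer than 2 participants with >= %d days; reliability skipped", DESIGN_DAYS)
        reliability = pd.DataFrame()

    if outcomes is not None and not summaries.empty:
        loads_df = summaries[["norm_overall_bw", "norm_high_bw"]]
        correlations = correlation_table(loads_df, outcomes, roster=config.roster)
    else:
        correlations = pd.DataFrame()

    manifest = {
        "software": "tendonload",
        "version": __version__,
        "config_sha256": config.sha256(),
        "n_participants_in": len(by_pid),
        "n_participants_analyzed": int(len(summary_rows)),
        "n_sessions": sum(len(v) for v in by_pid.values()),
        "n_sessions_excluded": sum(1 for r in excl_rows if r["level"] == "session"),
    }
    return PipelineResult(
        qc_reports=qc_reports,
        day_loads=day_loads,
        summaries=summaries,
        reliability=reliability,
        correlations=correlations,
        exclusions=pd.DataFrame(
            excl_rows, columns=["level", "participant_id", "session_id", "reason"]
        ),
        manifest=manifest,
    )


# ---------------------------------------------------------------------------
# File-based stages (CLI backends)
# ---------------------------------------------------------------------------

SESSIONS_DIR = "sessions"
PROFILES_FILE = "profiles.json"
OUTCOMES_FILE = "outcomes.csv"
GROUND_TRUTH_FILE = "ground_truth.json"
CORRECTED_DIR = "corrected"
QC_REPORTS_FILE = "qc_reports.json"
TRACES_DIR = "traces"
TRACES_INDEX = "traces_index.csv"
DAY_LOADS_FILE = "day_loads.csv"
SUMMARIES_FILE = "summaries.csv"
RELIABILITY_FILE = "reliability.csv"
CORRELATIONS_FILE = "correlations.csv"
EXCLUSIONS_FILE = "exclusions.csv"
MANIFEST_FILE = "manifest.json"


def _require(path: Path, stage: str, needed_by: str) -> Path:
    if not path.exists():
        raise DependencyError(
            f"stage {needed_by!r} requires outputs of stage {stage!r} "
            f"(missing {path}); run `tendonload {stage}` first"
        )
    return path


def write_profiles(profiles: Mapping[str, ParticipantProfile], path: Path) -> None:
    payload = {pid: dataclasses.asdict(p) for pid, p in sorted(profiles.items())}
    path.write_text(json.dumps(payload, indent=1, default=str))


def read_profiles(path: Path) -> dict[str, ParticipantProfile]:
    payload = json.loads(path.read_text())
    return {pid: ParticipantProfile(**kw) for pid, kw in payload.items()}


def write_cohort(cohort: Cohort, input_dir: Path) -> None:
    """Serialize a synthetic cohort in the recording_io dialect."""
    input_dir = Path(input_dir)
    sess_dir = input_dir / SESSIONS_DIR
    sess_dir.mkdir(parents=True, exist_ok=True)
    for rec in cohort.recordings:
        write_recording(rec, sess_dir / f"{rec.session_id}.csv")
    write_profiles(cohort.profiles, input_dir / PROFILES_FILE)
    cohort.outcomes_frame().rename_axis("participant_id").to_csv(
        input_dir / OUTCOMES_FILE
    )
    gt = cohort.ground_truth
    payload = {
        "per_participant": gt.per_participant.to_dict(orient="index"),
        "targets": gt.targets,
        "excluded_sessions": list(gt.excluded_sessions),
    }
    (input_dir / GROUND_TRUTH_FILE).write_text(json.dumps(payload, indent=1))


def read_sessions(input_dir: Path) -> list[InsoleRecording]:
    sess_dir = _require(Path(input_dir) / SESSIONS_DIR, "simulate", "qc")
    return [read_recording(p) for p in sorted(sess_dir.glob("*.csv"))]


def stage_simulate(input_dir: Path, scenario: ScenarioConfig) -> Cohort:
    cohort = generate_cohort(scenario)
    write_cohort(cohort, Path(input_dir))
    return cohort


def stage_qc(input_dir: Path, output_dir: Path, config: PipelineConfig = DEFAULT_CONFIG) -> None:
    input_dir, output_dir = Path(input_dir), Path(output_dir)
    profiles = read_profiles(_require(input_dir / PROFILES_FILE, "simulate", "qc"))
    recs = read_sessions(input_dir)
    corr_dir = output_dir / CORRECTED_DIR
    corr_dir.mkdir(parents=True, exist_ok=True)
    reports = {}
    for rec in recs:
        corrected, report = qc_recording(rec, profiles[rec.participant_id], config.qc_rules)
        reports[rec.session_id] = {**report.to_dict(), "participant_id": rec.participant_id}
        if report.status != STATUS_EXCLUDED:
            write_recording(corrected, corr_dir / f"{rec.session_id}.csv")
    (output_dir / QC_REPORTS_FILE).write_text(json.dumps(reports, indent=1, sort_keys=True))


def stage_estimate(input_dir: Path, output_dir: Path, config: PipelineConfig = DEFAULT_CONFIG) -> None:
    input_dir, output_dir = Path(input_dir), Path(output_dir)
    _require(output_dir / QC_REPORTS_FILE, "qc", "estimate")
    profiles = read_profiles(input_dir / PROFILES_FILE)
    corr_dir = _require(output_dir / CORRECTED_DIR, "qc", "estimate")
    traces_dir = output_dir / TRACES_DIR
    traces_dir.mkdir(parents=True, exist_ok=True)
    index_rows = []
    for p in sorted(corr_dir.glob("*.csv")):
        rec = read_recording(p)
        trace = estimate_trace(rec, config.geometry, profiles[rec.participant_id])
        pd.DataFrame({"time_s": trace.t, "load_bw": trace.load}).to_csv(
            traces_dir / f"{rec.session_id}.csv", index=False
        )
        index_rows.append(
            {
                "session_id": rec.session_id,
                "participant_id": rec.participant_id,
                "day_index": rec.day_index,
                "sample_rate": rec.sample_rate,
            }
        )
    pd.DataFrame(index_rows).to_csv(output_dir / TRACES_INDEX, index=False)


def stage_summarize(output_dir: Path, config: PipelineConfig = DEFAULT_CONFIG) -> None:
    output_dir = Path(output_dir)
    index = pd.read_csv(_require(output_dir / TRACES_INDEX, "estimate", "summarize"))
    traces_dir = _require(output_dir / TRACES_DIR, "estimate", "summarize")
    day_rows = []
    per_pid: dict[str, dict[int, DayLoad]] = {}
    for row in index.itertuples():
        df = pd.read_csv(traces_dir / f"{row.session_id}.csv")
        trace = TendonLoadTrace(
            participant_id=row.participant_id,
            session_id=row.session_id,
            day_index=int(row.day_index),
            sample_rate=float(row.sample_rate),
            load=df["load_bw"].to_numpy(),
        )
        dl = trace_day_load(trace, config.thr_overall, config.thr_high)
        loads = per_pid.setdefault(row.participant_id, {})
        loads[int(row.day_index)] = loads.get(int(row.day_index), DayLoad()) + dl
    summary_rows = []
    for pid in sorted(per_pid):
        for d in sorted(per_pid[pid]):
            dl = per_pid[pid][d]
            day_rows.append(
                {
                    "participant_id": pid,
                    "day_index": d,
                    "loading_time_h": dl.loading_time_h,
                    "high_time_h": dl.high_time_h,
                    "overall_impulse_bwh": dl.overall_impulse_bwh,
                    "high_impulse_bwh": dl.high_impulse_bwh,
                }
            )
        s = summary_from_day_loads(pid, per_pid[pid]).as_dict()
        s["days_included"] = ",".join(map(str, s["days_included"]))
        summary_rows.append(s)
    pd.DataFrame(day_rows).to_csv(output_dir / DAY_LOADS_FILE, index=False)
    pd.DataFrame(summary_rows).to_csv(output_dir / SUMMARIES_FILE, index=False)


def stage_reliability(output_dir: Path) -> None:
    output_dir = Path(output_dir)
    day_loads = pd.read_csv(_require(output_dir / DAY_LOADS_FILE, "summarize", "reliability"))
    by_pid: dict[str, dict[int, DayLoad]] = {}
    for row in day_loads.itertuples():
        by_pid.setdefault(row.participant_id, {})[int(row.day_index)] = DayLoad(
            row.loading_time_h,
            row.high_time_h,
            row.overall_impulse_bwh,
            row.high_impulse_bwh,
        )
    eligible = {pid: v for pid, v in by_pid.items() if len(v) >= DESIGN_DAYS}
    report = reliability_analysis(eligible) if len(eligible) >= 2 else pd.DataFrame()
    report.to_csv(output_dir / RELIABILITY_FILE, index=False)


def stage_correlate(input_dir: Path, output_dir: Path, config: PipelineConfig = DEFAULT_CONFIG) -> None:
    input_dir, output_dir = Path(input_dir), Path(output_dir)
    summaries = pd.read_csv(
        _require(output_dir / SUMMARIES_FILE, "summarize", "correlate"),
        index_col="participant_id",
    )
    outcomes = pd.read_csv(
        _require(input_dir / OUTCOMES_FILE, "simulate", "correlate"),
        index_col="participant_id",
    )
    table = correlation_table(
        summaries[["norm_overall_bw", "norm_high_bw"]], outcomes, roster=config.roster
    )
    table.to_csv(output_dir / CORRELATIONS_FILE, index=False)


def run_pipeline(
    input_dir: Path, output_dir: Path, config: PipelineConfig = DEFAULT_CONFIG
) -> None:
    """Chain all analysis stages and write the run manifest.

    Built from the same stage functions the CLI exposes, so stagewise and
    monolithic runs produce identical outputs.
    """
    input_dir, output_dir = Path(input_dir), Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    stage_qc(input_dir, output_dir, config)
    stage_estimate(input_dir, output_dir, config)
    stage_summarize(output_dir, config)
    stage_reliability(output_dir)
    stage_correlate(input_dir, output_dir, config)

    reports = json.loads((output_dir / QC_REPORTS_FILE).read_text())
    summaries = pd.read_csv(output_dir / SUMMARIES_FILE)
    excl_rows = [
        {
            "level": "session",
            "participant_id": rep["participant_id"],
            "session_id": sid,
            "reason": rep["exclusion_reason"],
        }
        for sid, rep in reports.items()
        if rep["status"] == STATUS_EXCLUDED
    ]
    analyzed = set(summaries["participant_id"]) if not summaries.empty else set()
    all_pids = {rep["participant_id"] for rep in reports.values()}
    for pid in sorted(all_pids - analyzed):
        excl_rows.append(
            {
                "level": "participant",
                "participant_id": pid,
                "session_id": "",
                "reason": "no-valid-recordings",
            }
        )
    pd.DataFrame(
        excl_rows, columns=["level", "participant_id", "session_id", "reason"]
    ).to_csv(output_dir / EXCLUSIONS_FILE, index=False)
    manifest = {
        "software": "tendonload",
        "version": __version__,
        "config_sha256": config.sha256(),
        "input_dir": str(input_dir),
        "n_sessions": len(reports),
        "n_sessions_excluded": len([r for r in excl_rows if r["level"] == "session"]),
    }
    (output_dir / MANIFEST_FILE).write_text(json.dumps(manifest, indent=1, sort_keys=True))
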