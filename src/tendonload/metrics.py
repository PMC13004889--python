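"""Cumulative Achilles tendon load biomarkers.

Two magnitude thresholds delineate loading levels: 0.3xBW, the load of the
lowest-loading tendon exercise (seated heel raise), defines *overall*
loading and doubles as the wear/activity gate — time above it is the
participant's total loading time; 3.0xBW, approximately the peak tendon
load of walking, defines *high-level* loading attributable to dynamic
exercise. For each threshold we accumulate (i) time above and (ii) the
impulse, i.e. the trapezoidal integral of the full load magnitude over
supra-threshold samples (area down to zero, not just the excess above the
line), summed over all sessions and days. Dividing both impulses by the
*overall* loading time yields wear-time-normalized loads per hour (xBW).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import DomainError, IntegrityError
from .load import TendonLoadTrace

#: Default loading-level thresholds (xBW).
THR_OVERALL = 0.3
THR_HIGH = 3.0


def time_above(trace: TendonLoadTrace, thr: float) -> float:
    """Hours with load >= ``thr`` (samplewise indicator, no interpolation)."""
    if thr < 0:
        raise DomainError(f"threshold must be >= 0, got {thr}")
    if trace.n_samples == 0:
        return 0.0
    n_above = int(np.count_nonzero(trace.load >= thr))
    return n_above / trace.sample_rate / 3600.0


def impulse_above(trace: TendonLoadTrace, thr: float) -> float:
    """Impulse (xBW x hour): trapezoidal integral of the supra-threshold load.

    The load is masked to zero where it is below ``thr`` and the *full*
    magnitude is integrated over the remaining samples.
    """
    if thr < 0:
        raise DomainError(f"threshold must be >= 0, got {thr}")
    if trace.n_samples < 2:
        return 0.0
    masked = np.where(trace.load >= thr, trace.load, 0.0)
    return float(np.trapezoid(masked, dx=1.0 / trace.sample_rate)) / 3600.0


@dataclass(frozen=True)
class DayLoad:
    """Raw (un-normalized) per-day accumulation; additive across days."""

    loading_time_h: float = 0.0
    high_time_h: float = 0.0
    overall_impulse_bwh: float = 0.0
    high_impulse_bwh: float = 0.0

    def __add__(self, other: "DayLoad") -> "DayLoad":
        return DayLoad(
            self.loading_time_h + other.loading_time_h,
            self.high_time_h + other.high_time_h,
            self.overall_impulse_bwh + other.overall_impulse_bwh,
            self.high_impulse_bwh + other.high_impulse_bwh,
        )


def trace_day_load(
    trace: TendonLoadTrace, thr_overall: float = THR_OVERALL, thr_high: float = THR_HIGH
) -> DayLoad:
    return DayLoad(
        loading_time_h=time_above(trace, thr_overall),
        high_time_h=time_above(trace, thr_high),
        overall_impulse_bwh=impulse_above(trace, thr_overall),
        high_impulse_bwh=impulse_above(trace, thr_high),
    )


@dataclass(frozen=True)
class CumulativeLoadSummary:
    """Loading time, impulses and per-hour normalized loads for a day set.

    When ``loading_time_h`` is zero the normalized values are undefined and
    reported as NaN with ``norms_defined=False`` (never 0 or infinity).
    """

    participant_id: str
    days_included: tuple[int, ...]
    loading_time_h: float
    high_time_h: float
    overall_impulse_bwh: float
    high_impulse_bwh: float
    norm_overall_bw: float
    norm_high_bw: float
    thresholds: tuple[float, float] = (THR_OVERALL, THR_HIGH)
    norms_defined: bool = True

    def __post_init__(self) -> None:
        tol = 1e-9
        if not (-tol <= self.high_time_h <= self.loading_time_h + tol):
            raise IntegrityError(
                f"high_time_h {self.high_time_h} outside [0, loading_time_h="
                f"{self.loading_time_h}]"
            )
        if not (-tol <= self.high_impulse_bwh <= self.overall_impulse_bwh + tol):
            raise IntegrityError(
                f"high_impulse_bwh {self.high_impulse_bwh} outside "
                f"[0, overall_impulse_bwh={self.overall_impulse_bwh}]"
            )
        if self.norms_defined:
            if self.loading_time_h <= 0:
                raise IntegrityError("norms_defined requires loading_time_h > 0")
            for name in ("norm_overall_bw", "norm_high_bw"):
                v = getattr(self, name)
                if not math.isfinite(v):
                    raise IntegrityError(f"{name} must be finite when defined")

    def as_dict(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "days_included": list(self.days_included),
            "loading_time_h": self.loading_time_h,
            "high_time_h": self.high_time_h,
            "overall_impulse_bwh": self.overall_impulse_bwh,
            "high_impulse_bwh": self.high_impulse_bwh,
            "norm_overall_bw": self.norm_overall_bw,
            "norm_high_bw": self.norm_high_bw,
        }


def summarize(
    traces: Iterable[TendonLoadTrace],
    days: Iterable[int] | None = None,
    thr_overall: float = THR_OVERALL,
    thr_high: float = THR_HIGH,
) -> CumulativeLoadSummary:
    """Accumulate times and impulses across sessions in the selected days.

    Sessions are combined without bridging the gaps between them: time not
    recorded contributes nothing. Both normalized loads divide by the
    *overall* loading time.
    """
    if not thr_overall < thr_high:
        raise DomainError(
            f"thr_overall ({thr_overall}) must be below thr_high ({thr_high})"
        )
    traces = list(traces)
    pids = {t.participant_id for t in traces}
    if len(pids) > 1:
        raise IntegrityError(f"traces from multiple participants: {sorted(pids)}")
    pid = pids.pop() if pids else ""
    available = {t.day_index for t in traces}
    if days is None:
        selected = available
    else:
        selected = set(days)
        extra = selected - available
        if extra:
            raise DomainError(f"requested days {sorted(extra)} have no traces")
    total = DayLoad()
    for tr in traces:
        if tr.day_index in selected:
            total = total + trace_day_load(tr, thr_overall, thr_high)

    if total.loading_time_h > 0:
        norm_overall = total.overall_impulse_bwh / total.loading_time_h
        norm_high = total.high_impulse_bwh / total.loading_time_h
        defined = True
    else:
        warnings.warn(
            f"participant {pid!r}: zero loading time in selected days; "
            "normalized loads are undefined",
            stacklevel=2,
        )
        norm_overall = norm_high = float("nan")
        defined = False

    return CumulativeLoadSummary(
        participant_id=pid,
        days_included=tuple(sorted(selected)),
        loading_time_h=total.loading_time_h,
        high_time_h=total.high_time_h,
        overall_impulse_bwh=total.overall_impulse_bwh,
        high_impulse_bwh=total.high_impulse_bwh,
        norm_overall_bw=norm_overall,
        norm_high_bw=norm_high,
        thresholds=(thr_overall, thr_high),
        norms_defined=defined,
    )


def summary_from_day_loads(
    participant_id: str, day_loads: Mapping[int, DayLoad], days: Iterable[int] | None = None
) -> CumulativeLoadSummary:
    """Like :func:`summarize`, but from pre-accumulated per-day loads."""
    selected = set(day_loads) if days is None else set(days)
    total = DayLoad()
    for d in selected:
        total = total + day_loads[d]
    if total.loading_time_h > 0:
        norm_overall = total.overall_impulse_bwh / total.loading_time_h
        norm_high = total.high_impulse_bwh / total.loading_time_h
        defined = True
    else:
        norm_overall = norm_high = float("nan")
        defined = False
    return CumulativeLoadSummary(
        participant_id=participant_id,
        days_included=tuple(sorted(selected)),
        loading_time_h=total.loading_time_h,
        high_time_h=total.high_time_h,
        overall_impulse_bwh=total.overall_impulse_bwh,
        high_impulse_bwh=total.high_impulse_bwh,
        norm_overall_bw=norm_overall,
        norm_high_bw=norm_high,
        norms_defined=defined,
    )
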