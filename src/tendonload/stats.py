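"""Correlations between cumulative tendon load and clinical measures.

Pearson correlations are computed between the two normalized cumulative
loads (overall and high-level, xBW per hour) and a roster of participant
measures: seven dynamometer-based plantar-flexor capacity measures, three
motion-capture-based dynamic-function measures, and three survey measures
(age, VISA-A, PAS). Correlation strength is classified descriptively:
|r| >= 0.6 strong, 0.4 <= |r| < 0.6 moderate, |r| < 0.4 weak; the
significance flag (two-sided alpha = 0.05, no multiplicity correction) is
ancillary.
"""
from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .errors import DomainError

STRONG = "strong"
MODERATE = "moderate"
WEAK = "weak"

#: Default outcome roster (Table-2-style measure names).
CAPACITY_MEASURES = (
    "peak_moment_isometric",
    "peak_moment_30",
    "peak_moment_150",
    "peak_power_30",
    "peak_power_150",
    "work_30",
    "work_150",
)
DYNAMIC_MEASURES = ("heel_raise_height", "cmj_height", "incline_reps")
SURVEY_MEASURES = ("age", "visa_a", "pas")
DEFAULT_ROSTER = CAPACITY_MEASURES + DYNAMIC_MEASURES + SURVEY_MEASURES

LOAD_MEASURES = ("norm_overall_bw", "norm_high_bw")


def classify_strength(r: float) -> str:
    """Descriptive strength category of a Pearson correlation."""
    if not np.isfinite(r) or abs(r) > 1 + 1e-12:
        raise DomainError(f"correlation must satisfy |r| <= 1, got {r}")
    a = min(abs(r), 1.0)
    if a >= 0.6:
        return STRONG
    if a >= 0.4:
        return MODERATE
    return WEAK


def correlation_table(
    loads: pd.DataFrame,
    outcomes: pd.DataFrame,
    roster: Sequence[str] = DEFAULT_ROSTER,
    load_measures: Sequence[str] = LOAD_MEASURES,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One row per (load measure, outcome measure) pair.

    ``loads`` and ``outcomes`` are participant-indexed DataFrames; pairs are
    formed on the index intersection with pairwise-complete cases. Rows with
    fewer than 3 complete pairs or a zero-variance vector are flagged in the
    ``flag`` column rather than silently dropped.
    """
    missing = [c for c in load_measures if c not in loads.columns]
    if missing:
        raise DomainError(f"loads table missing columns {missing}")
    rows = []
    common = loads.index.intersection(outcomes.index)
    for x_name in load_measures:
        for y_name in roster:
            if y_name not in outcomes.columns:
                rows.append(_flagged_row(x_name, y_name, 0, "missing-measure"))
                continue
            x = loads.loc[common, x_name].to_numpy(dtype=float)
            y = outcomes.loc[common, y_name].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            n = int(ok.sum())
            if n < 3:
                rows.append(_flagged_row(x_name, y_name, n, "insufficient-n"))
                continue
            xs, ys = x[ok], y[ok]
            if np.std(xs) == 0 or np.std(ys) == 0:
                rows.append(_flagged_row(x_name, y_name, n, "zero-variance"))
                continue
            res = scipy.stats.pearsonr(xs, ys)
            r, p = float(res.statistic), float(res.pvalue)
            rows.append(
                {
                    "x_name": x_name,
                    "y_name": y_name,
                    "n": n,
                    "r": r,
                    "p": p,
                    "strength": classify_strength(r),
                    "significant": bool(p < alpha),
                    "flag": "ok",
                }
            )
    return pd.DataFrame(rows)


def _flagged_row(x_name: str, y_name: str, n: int, flag: str) -> dict:
    warnings.warn(f"correlation {x_name} vs {y_name}: {flag}", stacklevel=3)
    return {
        "x_name": x_name,
        "y_name": y_name,
        "n": n,
        "r": float("nan"),
        "p": float("nan"),
        "strength": "",
        "significant": False,
        "flag": flag,
    }


def capacity_measures(
    torque: np.ndarray,
    t: np.ndarray,
    ang_velocity,
    height: float,
    weight: float,
) -> dict:
    """Normalized capacity scalars from one dynamometer contraction.

    peak moment = max torque / (H x W) x 100          (%HxW)
    peak power  = max(torque x omega) / (H x W) x 100 (%HxW x rad/s)
    work        = integral of power dt / (H x W) x 100 (%HxW x rad)

    ``ang_velocity`` (rad/s) may be a scalar (isokinetic) or a trace.
    """
    if not height > 0 or not weight > 0:
        raise DomainError(f"height and weight must be > 0, got {height}, {weight}")
    torque = np.asarray(torque, dtype=float)
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(torque)):
        raise DomainError("torque trace must be finite")
    omega = np.broadcast_to(np.asarray(ang_velocity, dtype=float), torque.shape)
    hw = height * weight
    power = torque * omega
    return {
        "peak_moment": float(torque.max(initial=0.0)) / hw * 100.0,
        "peak_power": float(power.max(initial=0.0)) / hw * 100.0,
        "work": float(np.trapezoid(power, t)) / hw * 100.0,
    }


def mean_capacity(reps: Sequence[Mapping[str, float]]) -> dict:
    """Average capacity measures across contraction repetitions."""
    if not reps:
        raise DomainError("at least one repetition is required")
    keys = reps[0].keys()
    return {k: float(np.mean([r[k] for r in reps])) for k in keys}


def normalize_height(measure_m: float, height: float) -> float:
    """Express a jump/raise height as percent of body height (%BH)."""
    if not height > 0:
        raise DomainError(f"height must be > 0, got {height}")
    return measure_m / height * 100.0
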