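"""Day-subsampling reliability of cumulative-load estimates.

How many monitoring days are enough? Using each participant's full set of
recorded days as reference, cumulative loads are re-estimated from every
combination of k of the participant's *first six* recorded days
(k = 6: one subset; k = 5: leave-one-day-out; ...; k = 1: single days) and
compared to the reference by mean absolute percent error (MAPE), Pearson
correlation of per-participant subset means against the reference, and the
intraclass correlation ICC(2,1) (two-way random effects, absolute
agreement, single measures) across day-aligned subsets.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pingouin as pg
import scipy.stats

from .errors import DomainError
from .metrics import DayLoad

#: Number of leading recorded days the subsampling design draws from.
DESIGN_DAYS = 6

METRIC_OVERALL = "overall"
METRIC_HIGH = "high"


@dataclass(frozen=True)
class SubsampleDesign:
    """All size-k combinations of a participant's first six recorded days."""

    k: int
    subsets: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        if any(len(s) != self.k for s in self.subsets):
            raise DomainError("every subset must have size k")
        if len(set(self.subsets)) != len(self.subsets):
            raise DomainError("subsets must be unique")


def enumerate_subsets(recorded_days: Sequence[int], k: int) -> SubsampleDesign:
    """All C(6, k) combinations of the first six recorded days, in day order."""
    if not 1 <= k <= DESIGN_DAYS:
        raise DomainError(f"k must be in 1..{DESIGN_DAYS}, got {k}")
    if len(recorded_days) < DESIGN_DAYS:
        raise DomainError(
            f"participant has only {len(recorded_days)} recorded days; "
            f"subsampling needs at least {DESIGN_DAYS}"
        )
    first6 = tuple(recorded_days[:DESIGN_DAYS])
    return SubsampleDesign(k=k, subsets=tuple(itertools.combinations(first6, k)))


def percent_errors(
    estimates: Mapping[str, Sequence[float]], reference: Mapping[str, float]
) -> np.ndarray:
    """Pooled absolute percent errors over participants and subsets.

    Participants with a zero reference are dropped with a warning (the
    percent difference is undefined); NaN subset estimates are ignored.
    """
    pooled: list[np.ndarray] = []
    for pid, est in estimates.items():
        ref = reference[pid]
        est = np.asarray(est, dtype=float)
        if ref == 0:
            warnings.warn(
                f"participant {pid!r} has zero reference; dropped from MAPE",
                stacklevel=2,
            )
            continue
        ape = np.abs(est - ref) / abs(ref) * 100.0
        pooled.append(ape[np.isfinite(ape)])
    return np.concatenate(pooled) if pooled else np.array([])


def mape(
    estimates: Mapping[str, Sequence[float]], reference: Mapping[str, float]
) -> float:
    """Mean absolute percent error over all participants and subsets."""
    ape = percent_errors(estimates, reference)
    return float(ape.mean()) if ape.size else float("nan")


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson r and two-sided p (t transform, n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise DomainError("pearson requires two equal-length vectors, n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("zero variance; Pearson correlation undefined", stacklevel=2)
        return float("nan"), float("nan")
    res = scipy.stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def icc(matrix) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    ``matrix`` is participants x subsets with columns aligned across
    participants. Rows containing missing cells are dropped (complete-case)
    with a warning.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise DomainError("icc requires a 2-D matrix with >= 2 columns")
    complete = ~np.isnan(m).any(axis=1)
    if not complete.all():
        warnings.warn(
            f"dropping {int((~complete).sum())} participant(s) with missing cells",
            stacklevel=2,
        )
        m = m[complete]
    if m.shape[0] < 2:
        raise DomainError("icc requires >= 2 complete participants")
    n, k = m.shape
    long = pd.DataFrame(
        {
            "target": np.repeat(np.arange(n), k),
            "rater": np.tile(np.arange(k), n),
            "score": m.ravel(),
        }
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = pg.intraclass_corr(
            data=long, targets="target", raters="rater", ratings="score"
        )
    # absolute-agreement single-measures row; label varies across pingouin versions
    sel = res["Type"].isin(["ICC2", "ICC(A,1)"])
    return float(res.loc[sel, "ICC"].iloc[0])


def reliability_analysis(
    day_loads_by_pid: Mapping[str, Mapping[int, DayLoad]],
    metrics: Sequence[str] = (METRIC_OVERALL, METRIC_HIGH),
) -> pd.DataFrame:
    """Fig.-4-style reliability table over k = 1..6 day subsamples.

    ``day_loads_by_pid`` maps participant -> {day_index: DayLoad}. The
    reference is the participant's *all* recorded days. Participants with
    fewer than six recorded days are excluded with a warning. Returns one
    row per (metric, k) with MAPE mean/SD (pooled across participants and
    subsets), Pearson r of per-participant subset means vs reference, and
    ICC(2,1) across day-aligned subsets.
    """
    eligible: dict[str, Mapping[int, DayLoad]] = {}
    for pid, loads in day_loads_by_pid.items():
        if len(loads) < DESIGN_DAYS:
            warnings.warn(
                f"participant {pid!r} has {len(loads)} recorded days (< "
                f"{DESIGN_DAYS}); excluded from subsampling analysis",
                stacklevel=2,
            )
            continue
        eligible[pid] = loads
    if len(eligible) < 2:
        raise DomainError("subsampling analysis needs >= 2 eligible participants")

    def norm(loads: Mapping[int, DayLoad], days: Sequence[int], metric: str) -> float:
        time = sum(loads[d].loading_time_h for d in days)
        if time <= 0:
            return float("nan")
        if metric == METRIC_OVERALL:
            imp = sum(loads[d].overall_impulse_bwh for d in days)
        else:
            imp = sum(loads[d].high_impulse_bwh for d in days)
        return imp / time

    reference = {
        metric: {
            pid: norm(loads, sorted(loads), metric) for pid, loads in eligible.items()
        }
        for metric in metrics
    }

    rows = []
    pids = sorted(eligible)
    for k in range(1, DESIGN_DAYS + 1):
        designs = {
            pid: enumerate_subsets(sorted(eligible[pid]), k) for pid in pids
        }
        for metric in metrics:
            est = {
                pid: [norm(eligible[pid], s, metric) for s in designs[pid].subsets]
                for pid in pids
            }
            ape = percent_errors(est, reference[metric])
            mat = np.array([est[pid] for pid in pids])
            subset_means = np.nanmean(mat, axis=1)
            ref_vec = np.array([reference[metric][pid] for pid in pids])
            ok = np.isfinite(subset_means) & np.isfinite(ref_vec)
            if ok.sum() >= 3 and np.std(subset_means[ok]) > 0 and np.std(ref_vec[ok]) > 0:
                r, p = pearson(subset_means[ok], ref_vec[ok])
            else:
                r, p = float("nan"), float("nan")
            icc_val = icc(mat) if mat.shape[1] >= 2 else float("nan")
            rows.append(
                {
                    "metric": metric,
                    "k": k,
                    "n_subsets": mat.shape[1],
                    "n_participants": len(pids),
                    "mape_mean_pct": float(ape.mean()) if ape.size else float("nan"),
                    "mape_sd_pct": float(ape.std(ddof=1)) if ape.size > 1 else float("nan"),
                    "pearson_r": r,
                    "pearson_p": p,
                    "icc": icc_val,
                }
            )
    return pd.DataFrame(rows)
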