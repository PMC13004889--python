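"""Synthetic multi-day insole cohorts with exact ground truth.

The generator builds each participant's days from parametric *pulse trains*:
periodic raised-cosine load pulses standing in for the stance phases of
light ambulation (peak ~0.6xBW), walking (peak ~3xBW, the typical peak
Achilles tendon load of gait), running and dynamic exercises (heel raises,
jumps; peaks 4-6xBW). Pulse-parametric waveforms keep the ground truth
analytic: time above a threshold and the supra-threshold impulse of a
raised-cosine pulse have closed forms, so per-participant cumulative-load
bookkeeping is exact for the continuous waveform, independent of the 20 Hz
sampling the pipeline sees.

Load waveforms (xBW) are inverted through the same moment-arm model the
estimator uses — forces are distributed over the three pads with a
heel-to-forefoot stance progression — so estimation recovers the input
trace. Artifact injection then adds sensor noise, constant initialization
offsets, stepwise baseline drifts and, rarely, a whole-session
initialization failure (a wandering baseline that never goes quiet, which
screening must exclude; such sessions are also excluded from the ground
truth because their content is unusable by construction).

Participant-level outcome measures are drawn with a configurable Pearson
correlation to the ground-truth normalized high-level load.
"""
from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DomainError
from .io import G, InsoleRecording, ParticipantProfile, FunctionalMeasures
from .load import DEFAULT_GEOMETRY, SensorGeometry
from .metrics import THR_HIGH, THR_OVERALL, DayLoad

# ---------------------------------------------------------------------------
# Pulse trains and closed-form bookkeeping
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PulseTrainSpec:
    """A periodic train of identical load pulses.

    peak_bw: pulse peak (xBW); pulse_s: pulse (stance) duration; period_s:
    pulse repetition period. Shapes: ``raised-cosine`` (smooth stance pulse)
    or ``rect`` (test primitive). Periods are deliberately incommensurate
    with the 20 Hz sample grid so sampling phases self-average.
    """

    peak_bw: float
    pulse_s: float
    period_s: float
    shape: str = "raised-cosine"

    def __post_init__(self) -> None:
        if self.peak_bw < 0:
            raise DomainError(f"peak_bw must be >= 0, got {self.peak_bw}")
        if not 0 < self.pulse_s <= self.period_s:
            raise DomainError(
                f"need 0 < pulse_s <= period_s, got {self.pulse_s}, {self.period_s}"
            )
        if self.shape not in ("raised-cosine", "rect"):
            raise DomainError(f"unknown pulse shape {self.shape!r}")


#: Default activity archetypes (peaks anchored to the 0.3/3.0xBW rationale).
LIGHT_ACTIVITY = PulseTrainSpec(peak_bw=0.6, pulse_s=0.79, period_s=1.57)
WALKING = PulseTrainSpec(peak_bw=3.0, pulse_s=0.654, period_s=1.091)
RUNNING = PulseTrainSpec(peak_bw=4.2, pulse_s=0.35, period_s=0.757)
HEEL_RAISE = PulseTrainSpec(peak_bw=4.5, pulse_s=1.51, period_s=2.53)
JUMP = PulseTrainSpec(peak_bw=5.5, pulse_s=0.53, period_s=1.47)


def pulse_time_above(peak: float, dur: float, thr: float, shape: str = "raised-cosine") -> float:
    """Seconds one pulse spends at or above ``thr`` (closed form)."""
    if peak <= thr or dur <= 0:
        return 0.0
    if shape == "rect":
        return dur
    a = math.acos(1.0 - 2.0 * thr / peak) / (2.0 * math.pi)
    return dur * (1.0 - 2.0 * a)


def pulse_impulse_above(peak: float, dur: float, thr: float, shape: str = "raised-cosine") -> float:
    """BW*seconds of full-magnitude impulse while one pulse is >= ``thr``."""
    if peak <= thr or dur <= 0:
        return 0.0
    if shape == "rect":
        return peak * dur
    a = math.acos(1.0 - 2.0 * thr / peak) / (2.0 * math.pi)
    return peak * dur / 2.0 * ((1.0 - 2.0 * a) + math.sin(2.0 * math.pi * a) / math.pi)


@dataclass(frozen=True)
class Bout:
    """A pulse train placed at ``start_s`` with ``n_pulses`` repetitions."""

    spec: PulseTrainSpec
    start_s: float
    n_pulses: int

    @property
    def span_s(self) -> float:
        if self.n_pulses == 0:
            return 0.0
        return (self.n_pulses - 1) * self.spec.period_s + self.spec.pulse_s

    @property
    def end_s(self) -> float:
        return self.start_s + self.span_s

    def bookkeeping(
        self, thr_overall: float = THR_OVERALL, thr_high: float = THR_HIGH
    ) -> DayLoad:
        """Exact cumulative-load contribution of this bout (hours, BW*h)."""
        s = self.spec
        n = self.n_pulses
        return DayLoad(
            loading_time_h=n * pulse_time_above(s.peak_bw, s.pulse_s, thr_overall, s.shape) / 3600.0,
            high_time_h=n * pulse_time_above(s.peak_bw, s.pulse_s, thr_high, s.shape) / 3600.0,
            overall_impulse_bwh=n * pulse_impulse_above(s.peak_bw, s.pulse_s, thr_overall, s.shape) / 3600.0,
            high_impulse_bwh=n * pulse_impulse_above(s.peak_bw, s.pulse_s, thr_high, s.shape) / 3600.0,
        )


def bout_from_duration(spec: PulseTrainSpec, start_s: float, duration_s: float) -> Bout:
    """Largest whole-pulse bout fitting in ``duration_s``."""
    if duration_s < spec.pulse_s:
        return Bout(spec=spec, start_s=start_s, n_pulses=0)
    n = int((duration_s - spec.pulse_s) // spec.period_s) + 1
    return Bout(spec=spec, start_s=start_s, n_pulses=n)


def generate_load_waveform(
    bouts: Sequence[Bout],
    duration_s: float,
    sample_rate: float,
    thr_overall: float = THR_OVERALL,
    thr_high: float = THR_HIGH,
) -> tuple[np.ndarray, DayLoad]:
    """Sample a session's load waveform and return exact bookkeeping.

    Bouts must not overlap. The returned array has ``round(duration_s *
    sample_rate)`` samples; the bookkeeping is the closed-form sum over
    pulses and therefore refers to the continuous waveform.
    """
    n = int(round(duration_s * sample_rate))
    load = np.zeros(n)
    total = DayLoad()
    for bout in sorted(bouts, key=lambda b: b.start_s):
        if bout.n_pulses == 0:
            continue
        if bout.end_s > duration_s + 1e-9:
            raise DomainError(
                f"bout ending at {bout.end_s:.1f}s exceeds session duration {duration_s}s"
            )
        s = bout.spec
        i0 = max(int(math.ceil(bout.start_s * sample_rate)), 0)
        i1 = min(int(math.floor(bout.end_s * sample_rate)), n - 1)
        if i1 >= i0:
            t_rel = np.arange(i0, i1 + 1) / sample_rate - bout.start_s
            pulse_idx = np.floor(t_rel / s.period_s)
            phase = t_rel - pulse_idx * s.period_s
            active = (phase <= s.pulse_s) & (pulse_idx < bout.n_pulses)
            if s.shape == "rect":
                seg = np.where(active, s.peak_bw, 0.0)
            else:
                seg = np.where(
                    active,
                    s.peak_bw * 0.5 * (1.0 - np.cos(2.0 * np.pi * phase / s.pulse_s)),
                    0.0,
                )
            if np.any(load[i0 : i1 + 1][seg > 0] > 0):
                raise DomainError("overlapping bouts are not supported")
            load[i0 : i1 + 1] += seg
        total = total + bout.bookkeeping(thr_overall, thr_high)
    return load, total


# ---------------------------------------------------------------------------
# Model inversion: load waveform -> sensor forces
# ---------------------------------------------------------------------------

#: Pad weight distribution at the start (heel-dominant) and end
#: (forefoot-dominant) of a loaded segment; linear blend in between.
_W_EARLY = np.array([0.30, 0.50, 0.20])
_W_LATE = np.array([0.00, 0.20, 0.80])


def waveform_to_forces(
    load_bw: np.ndarray,
    sample_rate: float,
    geom: SensorGeometry = DEFAULT_GEOMETRY,
    body_weight: float = 700.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Distribute a tendon-load waveform over the three sensor pads.

    Within each contiguous loaded segment the pad weights progress linearly
    from a heel-dominant to a forefoot-dominant mix (stance progression).
    The total force is chosen so that the moment-arm model applied to the
    output reproduces the input load exactly:
    ``F_total = load * BW * r_AT / (w(u) . r)``.
    """
    load = np.asarray(load_bw, dtype=float)
    if load.size and load.min() < 0:
        raise DomainError("load waveform must be non-negative")
    n = len(load)
    f = np.zeros((3, n))
    loaded = load > 0
    if loaded.any():
        idx = np.arange(n)
        start_mark = loaded & np.concatenate(([True], ~loaded[:-1]))
        end_mark = loaded & np.concatenate((~loaded[1:], [True]))
        run_start = np.maximum.accumulate(np.where(start_mark, idx, 0))
        run_end = np.minimum.accumulate(np.where(end_mark, idx, n - 1)[::-1])[::-1]
        length = run_end - run_start
        u = np.where(length > 0, (idx - run_start) / np.maximum(length, 1), 0.5)
        w = _W_EARLY[:, None] + u[None, :] * (_W_LATE - _W_EARLY)[:, None]
        r_eff = (w * geom.arms[:, None]).sum(axis=0)
        if np.any(r_eff[loaded] <= 0):
            raise DomainError(
                "pad weight progression yields a non-positive effective moment "
                f"arm for geometry {geom}"
            )
        f_total = np.where(loaded, load * body_weight * geom.r_at / np.where(r_eff > 0, r_eff, 1.0), 0.0)
        f = w * f_total[None, :]
    return f[0], f[1], f[2]


# ---------------------------------------------------------------------------
# Artifact injection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ArtifactSpec:
    """Magnitudes and rates of the injected sensor artifacts."""

    noise_sd_n: float = 0.5
    offset_prob: float = 0.2  # constant initialization offset, one channel
    offset_range_n: tuple[float, float] = (5.0, 40.0)
    drift_prob: float = 0.3  # stepwise baseline drift, one channel
    drift_range_n: tuple[float, float] = (10.0, 60.0)
    init_failure_prob: float = 0.03  # whole-session wandering baseline
    failure_step_sd_n: float = 5.0

    def __post_init__(self) -> None:
        for p in (self.offset_prob, self.drift_prob, self.init_failure_prob):
            if not 0 <= p <= 1:
                raise ConfigError(f"artifact probabilities must be in [0,1], got {p}")
        if self.noise_sd_n < 0:
            raise ConfigError("noise_sd_n must be >= 0")

    @classmethod
    def none(cls) -> "ArtifactSpec":
        return cls(
            noise_sd_n=0.0,
            offset_prob=0.0,
            drift_prob=0.0,
            init_failure_prob=0.0,
        )


@dataclass(frozen=True)
class ArtifactLog:
    """What was injected into one session."""

    session_id: str
    init_failure: bool = False
    offset: tuple[str, float] | None = None
    drift: tuple[str, float, float] | None = None  # (channel, onset_s, magnitude_n)


_CHANNELS = ("f_heel", "f_mid", "f_fore")


def inject_artifacts(
    rec: InsoleRecording, spec: ArtifactSpec, seed_or_rng
) -> tuple[InsoleRecording, ArtifactLog]:
    """Deterministically corrupt a recording according to ``spec``.

    With all magnitudes/probabilities zero the recording is returned
    unchanged (bitwise).
    """
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    n = rec.n_samples
    channels = {ch: getattr(rec, ch) for ch in _CHANNELS}

    failure = rng.uniform() < spec.init_failure_prob
    offset_info = None
    drift_info = None

    if spec.noise_sd_n > 0:
        for ch in _CHANNELS:
            channels[ch] = channels[ch] + rng.normal(0.0, spec.noise_sd_n, n)
    if failure:
        # wandering baseline: every epoch keeps moving, so range-based
        # unloaded detection never fires
        walk = np.cumsum(rng.normal(0.0, spec.failure_step_sd_n, n))
        walk = walk - walk.min() + 50.0
        for ch, share in zip(_CHANNELS, (0.5, 0.8, 1.0)):
            channels[ch] = channels[ch] + share * walk
    else:
        if rng.uniform() < spec.offset_prob:
            ch = _CHANNELS[rng.integers(3)]
            mag = rng.uniform(*spec.offset_range_n)
            channels[ch] = channels[ch] + mag
            offset_info = (ch, float(mag))
        if rng.uniform() < spec.drift_prob:
            ch = _CHANNELS[rng.integers(3)]
            onset = rng.uniform(0.1, 0.9) * rec.duration_s
            mag = rng.uniform(*spec.drift_range_n)
            i0 = int(onset * rec.sample_rate)
            shifted = channels[ch].copy()
            shifted[i0:] += mag
            channels[ch] = shifted
            drift_info = (ch, float(onset), float(mag))

    changed = any(channels[ch] is not getattr(rec, ch) for ch in _CHANNELS)
    if changed:
        for ch in _CHANNELS:
            channels[ch] = np.maximum(channels[ch], 0.0)
        rec = rec.replace(**channels)
    log = ArtifactLog(
        session_id=rec.session_id,
        init_failure=failure,
        offset=offset_info,
        drift=drift_info,
    )
    return rec, log


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

#: Outcome marginals: name -> (mean, sd, lower, upper, integer-valued).
OUTCOME_MARGINALS: dict[str, tuple[float, float, float | None, float | None, bool]] = {
    "age": (46.7, 12.0, 18.0, 70.0, False),
    "visa_a": (54.2, 26.1, 0.0, 100.0, False),
    "pas": (3.8, 1.6, 1.0, 6.0, True),
    "peak_moment_isometric": (9.0, 3.0, 0.0, None, False),
    "peak_moment_30": (8.0, 2.5, 0.0, None, False),
    "peak_moment_150": (5.0, 2.0, 0.0, None, False),
    "peak_power_30": (4.2, 1.5, 0.0, None, False),
    "peak_power_150": (13.0, 4.5, 0.0, None, False),
    "work_30": (6.0, 2.0, 0.0, None, False),
    "work_150": (4.0, 1.2, 0.0, None, False),
    "heel_raise_height": (5.8, 1.5, 0.0, None, False),
    "cmj_height": (8.0, 3.0, 0.0, None, False),
    "incline_reps": (20.0, 8.0, 0.0, 30.0, True),
}

#: Default target Pearson correlations between each outcome and the
#: ground-truth normalized high-level load.
DEFAULT_TARGETS: dict[str, float] = {
    "peak_moment_isometric": 0.48,
    "peak_moment_30": 0.52,
    "peak_moment_150": 0.625,
    "peak_power_30": 0.50,
    "peak_power_150": 0.55,
    "work_30": 0.50,
    "work_150": 0.55,
    "heel_raise_height": 0.60,
    "cmj_height": 0.55,
    "incline_reps": 0.50,
    "age": -0.33,
    "visa_a": 0.436,
    "pas": 0.617,
}

_FUNCTIONAL_FIELDS = (
    "peak_moment_isometric",
    "peak_moment_30",
    "peak_moment_150",
    "peak_power_30",
    "peak_power_150",
    "work_30",
    "work_150",
    "heel_raise_height",
    "cmj_height",
    "incline_reps",
)


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for a synthetic cohort."""

    n_participants: int = 15
    days_min: int = 6
    days_max: int = 14
    sessions_per_day: tuple[int, int] = (1, 3)
    session_hours: tuple[float, float] = (1.0, 1.5)
    sample_rate: float = 20.0
    light_fraction: float = 0.65  # share of ambulatory bouts that are light
    peak_cv: float = 0.07  # per-bout coefficient of variation of pulse peaks
    exercise_day_prob: float = 0.35  # scaled by participant activity level
    exercise_one_of_first6: bool = False  # exactly one exercise day in days 1-6
    light: PulseTrainSpec = LIGHT_ACTIVITY
    walking: PulseTrainSpec = WALKING
    run: PulseTrainSpec = RUNNING
    heel_raise: PulseTrainSpec = HEEL_RAISE
    jump: PulseTrainSpec = JUMP
    geometry: SensorGeometry = DEFAULT_GEOMETRY
    artifacts: ArtifactSpec = field(default_factory=ArtifactSpec)
    outcome_targets: tuple[tuple[str, float], ...] = tuple(DEFAULT_TARGETS.items())
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ConfigError("n_participants must be >= 1")
        if not 1 <= self.days_min <= self.days_max:
            raise ConfigError(f"bad day range {self.days_min}..{self.days_max}")
        if not 0 <= self.exercise_day_prob <= 1 or not 0 <= self.light_fraction <= 1:
            raise ConfigError("probabilities must be in [0, 1]")
        for name, rho in self.outcome_targets:
            if abs(rho) > 1:
                raise ConfigError(f"infeasible target correlation {name}={rho}")
            if name not in OUTCOME_MARGINALS:
                raise ConfigError(f"unknown outcome measure {name!r}")

    @property
    def targets(self) -> dict[str, float]:
        return dict(self.outcome_targets)


@dataclass
class GroundTruth:
    """Exact bookkeeping the pipeline is expected to recover."""

    per_participant: pd.DataFrame
    day_loads: dict[str, dict[int, DayLoad]]
    outcomes: pd.DataFrame
    targets: dict[str, float]
    excluded_sessions: tuple[str, ...]


@dataclass
class Cohort:
    recordings: list[InsoleRecording]
    profiles: dict[str, ParticipantProfile]
    functional: dict[str, FunctionalMeasures]
    ground_truth: GroundTruth

    def functional_frame(self) -> pd.DataFrame:
        rows = {
            pid: {f: getattr(fm, f) for f in _FUNCTIONAL_FIELDS}
            for pid, fm in self.functional.items()
        }
        return pd.DataFrame.from_dict(rows, orient="index")

    def outcomes_frame(self) -> pd.DataFrame:
        """All 13 outcome measures (functional + survey) per participant."""
        df = self.functional_frame()
        for pid, prof in self.profiles.items():
            df.loc[pid, "age"] = prof.age
            df.loc[pid, "visa_a"] = prof.visa_a
            df.loc[pid, "pas"] = prof.pas
        return df


def _vary_peak(spec: PulseTrainSpec, rng: np.random.Generator, cv: float) -> PulseTrainSpec:
    """Per-bout peak variability: real gait does not hit one exact peak.

    Keeping every walking pulse at exactly the high-level threshold would be
    degenerate (any residual artifact flips the whole bout across the line);
    a truncated-normal multiplier spreads bout peaks around the archetype.
    """
    if cv <= 0:
        return spec
    factor = float(np.clip(rng.normal(1.0, cv), 1.0 - 2.5 * cv, 1.0 + 2.5 * cv))
    return dataclasses.replace(spec, peak_bw=spec.peak_bw * factor)


def _schedule_session(
    rng: np.random.Generator,
    duration_s: float,
    cfg: ScenarioConfig,
    include_exercise: bool,
    activity: float,
) -> list[Bout]:
    """Alternate rest gaps with ambulatory bouts; optionally one exercise block."""
    bouts: list[Bout] = []
    t = rng.uniform(20.0, 60.0)  # leading rest anchors QC
    end = duration_s - 60.0  # trailing rest anchors QC
    exercise_pending = include_exercise

    while t < end - 90.0:
        if exercise_pending and t > 0.25 * duration_s:
            exercise_pending = False
            reps = int(rng.integers(40, 81))
            spec = _vary_peak(cfg.heel_raise, rng, cfg.peak_cv)
            b = Bout(spec, t, reps)
            if b.end_s > end:
                b = bout_from_duration(spec, t, end - t)
            bouts.append(b)
            t = b.end_s + rng.uniform(30.0, 60.0)
            if activity > 0.6 and t < end - 120.0:
                run_dur = min(rng.uniform(420.0, 900.0), end - t)
                b = bout_from_duration(_vary_peak(cfg.run, rng, cfg.peak_cv), t, run_dur)
                bouts.append(b)
                t = b.end_s + rng.uniform(30.0, 60.0)
            if rng.uniform() < 0.5 and t < end - 90.0:
                reps = int(rng.integers(20, 41))
                spec = _vary_peak(cfg.jump, rng, cfg.peak_cv)
                b = Bout(spec, t, reps)
                if b.end_s > end:
                    b = bout_from_duration(spec, t, end - t)
                bouts.append(b)
                t = b.end_s + rng.uniform(30.0, 60.0)
            continue
        spec = _vary_peak(
            cfg.light if rng.uniform() < cfg.light_fraction else cfg.walking,
            rng,
            cfg.peak_cv,
        )
        dur = min(rng.uniform(120.0, 480.0), end - t)
        b = bout_from_duration(spec, t, dur)
        if b.n_pulses == 0:
            break
        bouts.append(b)
        t = b.end_s + rng.uniform(60.0, 240.0)
    return [b for b in bouts if b.n_pulses > 0]


def draw_outcomes(
    norm_high: pd.Series,
    targets: Mapping[str, float],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Outcomes with target Pearson correlation to the high-level load.

    Each outcome is ``mean + sd * (rho * z + sqrt(1 - rho^2) * eps)`` where
    ``z`` is the standardized ground-truth norm_high; a target of +/-1 gives
    an exact affine (comonotone) relation. Values are clipped to physical
    bounds and integer-valued scales are rounded, which attenuates the
    realized correlation slightly.
    """
    x = norm_high.to_numpy(dtype=float)
    sd = x.std()
    if sd > 0:
        z = (x - x.mean()) / sd
    else:
        warnings.warn(
            "ground-truth high-level load has zero variance; outcomes are "
            "uncorrelated noise",
            stacklevel=2,
        )
        z = np.zeros_like(x)
    out = {}
    for name, rho in targets.items():
        if abs(rho) > 1:
            raise ConfigError(f"infeasible target correlation {name}={rho}")
        mean, msd, lo, hi, as_int = OUTCOME_MARGINALS[name]
        eps = rng.standard_normal(len(x))
        y = mean + msd * (rho * z + math.sqrt(max(1.0 - rho * rho, 0.0)) * eps)
        if lo is not None or hi is not None:
            y = np.clip(y, lo if lo is not None else -np.inf, hi if hi is not None else np.inf)
        if as_int:
            y = np.round(y)
        out[name] = y
    return pd.DataFrame(out, index=norm_high.index)


def generate_cohort(config: ScenarioConfig = ScenarioConfig()) -> Cohort:
    """Generate recordings, profiles, functional measures and ground truth.

    Deterministic: the global seed fans out into one substream per
    participant (plus one for the outcome draw), so extending the cohort
    does not perturb existing participants.
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_participants + 1)
    base_date = datetime(2025, 3, 1)

    recordings: list[InsoleRecording] = []
    body: dict[str, tuple[float, float, str, str]] = {}  # mass, height, sex, side
    gt_day_loads: dict[str, dict[int, DayLoad]] = {}
    activity_level: dict[str, float] = {}
    n_days: dict[str, int] = {}
    excluded: list[str] = []

    for i in range(config.n_participants):
        rng = np.random.default_rng(children[i])
        pid = f"P{i + 1:02d}"
        mass = float(np.clip(rng.normal(95.6, 24.9), 55.0, 145.0))
        height = float(np.clip(rng.normal(1.72, 0.12), 1.50, 1.95))
        sex = str(rng.choice(["F", "M"]))
        side = str(rng.choice(["left", "right"]))
        body[pid] = (mass, height, sex, side)
        bw = mass * G

        days = int(rng.integers(config.days_min, config.days_max + 1))
        n_days[pid] = days
        activity = float(rng.uniform())
        activity_level[pid] = activity
        if config.exercise_one_of_first6:
            exercise_days = {int(rng.integers(1, min(6, days) + 1))}
        else:
            p_ex = min(config.exercise_day_prob * (0.25 + 1.5 * activity), 0.95)
            exercise_days = {d for d in range(1, days + 1) if rng.uniform() < p_ex}

        day_loads: dict[int, DayLoad] = {}
        for d in range(1, days + 1):
            n_sess = int(rng.integers(config.sessions_per_day[0], config.sessions_per_day[1] + 1))
            ex_session = int(rng.integers(n_sess)) if d in exercise_days else -1
            day_total = DayLoad()
            for j in range(n_sess):
                dur = float(rng.uniform(*config.session_hours)) * 3600.0
                start_h = 8.0 + j * (11.0 / n_sess) + float(rng.uniform(0.0, 1.0))
                bouts = _schedule_session(rng, dur, config, j == ex_session, activity)
                load, book = generate_load_waveform(bouts, dur, config.sample_rate)
                fh, fm, ff = waveform_to_forces(load, config.sample_rate, config.geometry, bw)
                sid = f"{pid}-d{d:02d}s{j + 1}"
                rec = InsoleRecording(
                    participant_id=pid,
                    session_id=sid,
                    start_time=base_date
                    + timedelta(days=d - 1, hours=start_h),
                    sample_rate=config.sample_rate,
                    f_heel=fh,
                    f_mid=fm,
                    f_fore=ff,
                    day_index=d,
                )
                rec, log = inject_artifacts(rec, config.artifacts, rng)
                recordings.append(rec)
                if log.init_failure:
                    excluded.append(sid)
                else:
                    day_total = day_total + book
            day_loads[d] = day_total
        gt_day_loads[pid] = day_loads

    pids = sorted(gt_day_loads)
    rows = {}
    for pid in pids:
        total = DayLoad()
        for dl in gt_day_loads[pid].values():
            total = total + dl
        rows[pid] = {
            "loading_time_h": total.loading_time_h,
            "high_time_h": total.high_time_h,
            "overall_impulse_bwh": total.overall_impulse_bwh,
            "high_impulse_bwh": total.high_impulse_bwh,
            "norm_overall_bw": total.overall_impulse_bwh / total.loading_time_h
            if total.loading_time_h > 0
            else float("nan"),
            "norm_high_bw": total.high_impulse_bwh / total.loading_time_h
            if total.loading_time_h > 0
            else float("nan"),
            "n_days": n_days[pid],
            "activity": activity_level[pid],
        }
    per_participant = pd.DataFrame.from_dict(rows, orient="index")

    rng_out = np.random.default_rng(children[-1])
    outcomes = draw_outcomes(per_participant["norm_high_bw"], config.targets, rng_out)

    profiles = {}
    functional = {}
    for pid in pids:
        mass, height, sex, side = body[pid]
        profiles[pid] = ParticipantProfile(
            participant_id=pid,
            mass=mass,
            height=height,
            age=float(outcomes.loc[pid, "age"]) if "age" in outcomes else 45.0,
            sex=sex,
            symptomatic_side=side,
            visa_a=float(outcomes.loc[pid, "visa_a"]) if "visa_a" in outcomes else float("nan"),
            pas=float(outcomes.loc[pid, "pas"]) if "pas" in outcomes else float("nan"),
        )
        functional[pid] = FunctionalMeasures(
            participant_id=pid,
            **{
                f: float(outcomes.loc[pid, f]) if f in outcomes else 0.0
                for f in _FUNCTIONAL_FIELDS
            },
        )

    gt = GroundTruth(
        per_participant=per_participant,
        day_loads=gt_day_loads,
        outcomes=outcomes,
        targets=config.targets,
        excluded_sessions=tuple(excluded),
    )
    return Cohort(
        recordings=recordings, profiles=profiles, functional=functional, ground_truth=gt
    )
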