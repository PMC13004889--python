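"""On-disk data model for insole recordings and participant metadata.

A recording session is stored as a CSV file in SI units (seconds, Newtons)
with columns ``time_s, f_heel_n, f_mid_n, f_fore_n`` plus a JSON sidecar
(``<name>.meta.json``) carrying ``participant_id``, ``session_id``,
``start_time`` (ISO-8601), ``sample_rate`` and optionally ``day_index``.
The insole logs three plantar contact forces (heel, midfoot, forefoot pads)
at a nominal 20 Hz.
"""
from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyInputError, FormatError, IntegrityError, NumericError

#: Standard gravitational acceleration used for body-weight conversion (m/s^2).
G = 9.80665

#: Nominal logger sample rate (Hz).
NOMINAL_SAMPLE_RATE = 20.0


@dataclass(frozen=True)
class CsvDialect:
    """Column names and sidecar naming of the project CSV dialect."""

    time_col: str = "time_s"
    heel_col: str = "f_heel_n"
    mid_col: str = "f_mid_n"
    fore_col: str = "f_fore_n"
    sidecar_suffix: str = ".meta.json"

    @property
    def force_cols(self) -> tuple[str, str, str]:
        return (self.heel_col, self.mid_col, self.fore_col)


DEFAULT_DIALECT = CsvDialect()


@dataclass(frozen=True)
class InsoleRecording:
    """One continuous 3-channel plantar-force session.

    Timestamps are implicit: sample ``i`` occurs at ``i / sample_rate``
    seconds after ``start_time``, so uniform spacing holds by construction.
    """

    participant_id: str
    session_id: str
    start_time: datetime
    sample_rate: float
    f_heel: np.ndarray
    f_mid: np.ndarray
    f_fore: np.ndarray
    day_index: int = 1

    def __post_init__(self) -> None:
        for name in ("f_heel", "f_mid", "f_fore"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
        n = len(self.f_heel)
        if len(self.f_mid) != n or len(self.f_fore) != n:
            raise IntegrityError(
                f"channel lengths differ in session {self.session_id!r}: "
                f"{len(self.f_heel)}/{len(self.f_mid)}/{len(self.f_fore)}"
            )
        for name in ("f_heel", "f_mid", "f_fore"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise NumericError(f"non-finite force values in channel {name}")
        if not self.sample_rate > 0:
            raise IntegrityError(f"sample_rate must be > 0, got {self.sample_rate}")
        if self.day_index < 1:
            raise IntegrityError(f"day_index must be >= 1, got {self.day_index}")

    @property
    def n_samples(self) -> int:
        return len(self.f_heel)

    @property
    def t(self) -> np.ndarray:
        """Seconds since session start, uniformly spaced."""
        return np.arange(self.n_samples) / self.sample_rate

    @property
    def duration_s(self) -> float:
        """Time span between first and last sample."""
        return max(self.n_samples - 1, 0) / self.sample_rate

    @property
    def total_force(self) -> np.ndarray:
        """Sum of the three sensor channels (N)."""
        return self.f_heel + self.f_mid + self.f_fore

    def replace(self, **changes) -> "InsoleRecording":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class ParticipantProfile:
    """Anthropometrics and survey scores for one participant.

    ``body_weight`` (N) defaults to ``mass * g``; if given explicitly it must
    agree with that product. VISA-A is scored 0-100 (100 = asymptomatic);
    PAS is a single 1-6 activity item.
    """

    participant_id: str
    mass: float
    height: float
    age: float
    sex: str = "unspecified"
    symptomatic_side: str = "unspecified"
    visa_a: float = float("nan")
    pas: float = float("nan")
    body_weight: float | None = None

    def __post_init__(self) -> None:
        if not self.mass > 0:
            raise IntegrityError(f"mass must be > 0, got {self.mass}")
        if not self.height > 0:
            raise IntegrityError(f"height must be > 0, got {self.height}")
        expected_bw = self.mass * G
        if self.body_weight is None:
            object.__setattr__(self, "body_weight", expected_bw)
        elif abs(self.body_weight - expected_bw) > 1e-9 * expected_bw:
            raise IntegrityError(
                f"body_weight {self.body_weight} inconsistent with mass*g {expected_bw}"
            )
        if np.isfinite(self.visa_a) and not 0 <= self.visa_a <= 100:
            raise IntegrityError(f"visa_a must be in [0, 100], got {self.visa_a}")
        if np.isfinite(self.pas) and (self.pas != int(self.pas) or not 1 <= self.pas <= 6):
            raise IntegrityError(f"pas must be an integer in 1..6, got {self.pas}")


@dataclass(frozen=True)
class FunctionalMeasures:
    """Plantar-flexor capacity and dynamic-function scalars for one participant.

    Capacity measures come from dynamometer testing, normalized by body
    height x weight; dynamic-function measures come from motion capture,
    heights normalized by body height (%BH).
    """

    participant_id: str
    peak_moment_isometric: float  # %HxW
    peak_moment_30: float  # %HxW, 30 deg/s isokinetic
    peak_moment_150: float  # %HxW, 150 deg/s isokinetic
    peak_power_30: float  # %HxW x rad/s
    peak_power_150: float  # %HxW x rad/s
    work_30: float  # %HxW x rad
    work_150: float  # %HxW x rad
    heel_raise_height: float  # %BH
    cmj_height: float  # %BH
    incline_reps: float  # count

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if f.name == "participant_id":
                continue
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise NumericError(f"{f.name} must be finite, got {v}")
        if self.incline_reps < 0:
            raise IntegrityError(f"incline_reps must be >= 0, got {self.incline_reps}")


@dataclass(frozen=True)
class ParticipantDataset:
    """All sessions of one participant, grouped by calendar day."""

    profile: ParticipantProfile
    recordings: tuple[InsoleRecording, ...] = ()

    @property
    def wear_day_count(self) -> int:
        """Number of calendar days with at least one recording."""
        return len({r.day_index for r in self.recordings})

    @property
    def days_present(self) -> tuple[int, ...]:
        return tuple(sorted({r.day_index for r in self.recordings}))

    def by_day(self) -> dict[int, list[InsoleRecording]]:
        out: dict[int, list[InsoleRecording]] = {}
        for rec in self.recordings:
            out.setdefault(rec.day_index, []).append(rec)
        return out


def _sidecar_path(path: Path, dialect: CsvDialect) -> Path:
    return path.with_suffix("").with_name(path.stem + dialect.sidecar_suffix)


def read_recording(path, dialect: CsvDialect = DEFAULT_DIALECT) -> InsoleRecording:
    """Read one session from CSV + JSON sidecar and validate it.

    Timestamps are checked for strict monotonicity and uniform spacing at
    the sidecar's sample rate (relative tolerance 1e-9), then regularized
    to the nominal grid ``i / sample_rate``.
    """
    path = Path(path)
    sidecar = _sidecar_path(path, dialect)
    if not sidecar.exists():
        raise FormatError(f"missing sidecar metadata file {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in ("participant_id", "session_id", "start_time", "sample_rate"):
        if key not in meta:
            raise FormatError(f"sidecar {sidecar} missing required key {key!r}")

    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"recording file {path} is empty") from None
    if df.empty:
        raise EmptyInputError(f"recording file {path} contains no samples")
    for col in (dialect.time_col, *dialect.force_cols):
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {path}")

    t = df[dialect.time_col].to_numpy(dtype=float)
    fs = float(meta["sample_rate"])
    if fs <= 0:
        raise FormatError(f"sample_rate must be > 0, got {fs}")
    if len(t) > 1:
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise IntegrityError(f"non-monotonic time column in {path}")
        step = 1.0 / fs
        if np.max(np.abs(dt - step)) > 1e-9 * max(step, abs(t[-1])):
            raise IntegrityError(
                f"time column in {path} is not uniform at {fs} Hz"
            )

    return InsoleRecording(
        participant_id=str(meta["participant_id"]),
        session_id=str(meta["session_id"]),
        start_time=datetime.fromisoformat(meta["start_time"]),
        sample_rate=fs,
        f_heel=df[dialect.heel_col].to_numpy(dtype=float),
        f_mid=df[dialect.mid_col].to_numpy(dtype=float),
        f_fore=df[dialect.fore_col].to_numpy(dtype=float),
        day_index=int(meta.get("day_index", 1)),
    )


def write_recording(rec: InsoleRecording, path, dialect: CsvDialect = DEFAULT_DIALECT) -> Path:
    """Write a session as CSV + JSON sidecar (lossless float round-trip)."""
    path = Path(path)
    df = pd.DataFrame(
        {
            dialect.time_col: rec.t,
            dialect.heel_col: rec.f_heel,
            dialect.mid_col: rec.f_mid,
            dialect.fore_col: rec.f_fore,
        }
    )
    # %.17g guarantees bit-exact float64 round-trips through text
    df.to_csv(path, index=False, float_format="%.17g")
    meta = {
        "participant_id": rec.participant_id,
        "session_id": rec.session_id,
        "start_time": rec.start_time.isoformat(),
        "sample_rate": rec.sample_rate,
        "day_index": rec.day_index,
    }
    _sidecar_path(path, dialect).write_text(json.dumps(meta, indent=1))
    return path


def assemble_dataset(
    recordings: Iterable[InsoleRecording], profile: ParticipantProfile
) -> ParticipantDataset:
    """Group a participant's sessions by calendar day.

    Day 1 is the calendar date of the earliest recording; a session keeps the
    day of its ``start_time`` even if it spans midnight. Ordering is by
    ``start_time`` and therefore invariant to input order.
    """
    recs = list(recordings)
    if not recs:
        return ParticipantDataset(profile=profile)
    pids = {r.participant_id for r in recs}
    if pids != {profile.participant_id}:
        raise IntegrityError(
            f"mixed participant ids {sorted(pids)} for profile {profile.participant_id!r}"
        )
    sids = [r.session_id for r in recs]
    if len(set(sids)) != len(sids):
        dup = sorted({s for s in sids if sids.count(s) > 1})
        raise IntegrityError(f"duplicate session ids {dup}")
    first_date = min(r.start_time.date() for r in recs)
    recs = [
        r.replace(day_index=(r.start_time.date() - first_date).days + 1) for r in recs
    ]
    recs.sort(key=lambda r: r.start_time)
    return ParticipantDataset(profile=profile, recordings=tuple(recs))
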