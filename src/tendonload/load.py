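"""Achilles tendon load estimation from 3-sensor plantar forces.

Each sensor force is assumed perpendicular to the sole and applied at a
fixed per-sensor center of pressure, so the net ankle plantarflexion moment
is the sum of three force-by-moment-arm products,

    M_PF = F_heel * r_heel + F_mid * r_mid + F_fore * r_fore,

with moment arms signed anterior-positive about the ankle joint axis (the
heel pad may sit posterior to the axis, hence a negative arm). Dividing the
moment by the Achilles tendon moment arm r_AT (default 5 cm) gives a proxy
tendon force, which is clamped at zero — the tendon cannot transmit
compression, so net dorsiflexion moments map to zero load — and normalized
by body weight (unit: xBW).

The default pad moment arms are this package's calibration (chosen so that
synthetic walking reproduces the ~3xBW tendon-load peaks typical of gait);
insole-size-specific values can be supplied via :func:`geometry_for_size`.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, IntegrityError, NumericError
from .io import InsoleRecording, ParticipantProfile
from .qc import QCReport, STATUS_EXCLUDED


@dataclass(frozen=True)
class SensorGeometry:
    """Signed anterior moment arms (m) of the 3 pads and the tendon arm."""

    r_heel: float = -0.02
    r_mid: float = 0.05
    r_fore: float = 0.12
    r_at: float = 0.05

    def __post_init__(self) -> None:
        arms = (self.r_heel, self.r_mid, self.r_fore, self.r_at)
        if not all(np.isfinite(arms)):
            raise DomainError(f"moment arms must be finite, got {arms}")
        if not self.r_at > 0:
            raise DomainError(f"r_at must be > 0, got {self.r_at}")
        if not (self.r_fore > self.r_mid > self.r_heel):
            raise DomainError(
                f"expected r_fore > r_mid > r_heel, got {arms[:3]}"
            )

    @property
    def arms(self) -> np.ndarray:
        return np.array([self.r_heel, self.r_mid, self.r_fore])


DEFAULT_GEOMETRY = SensorGeometry()

#: Per-insole-size geometry presets (arms scale with foot length).
GEOMETRY_BY_SIZE = {
    "S": SensorGeometry(r_heel=-0.018, r_mid=0.045, r_fore=0.108),
    "M": DEFAULT_GEOMETRY,
    "L": SensorGeometry(r_heel=-0.022, r_mid=0.055, r_fore=0.132),
}


def geometry_for_size(size: str) -> SensorGeometry:
    try:
        return GEOMETRY_BY_SIZE[size]
    except KeyError:
        raise DomainError(
            f"unknown insole size {size!r}; known sizes: {sorted(GEOMETRY_BY_SIZE)}"
        ) from None


@dataclass(frozen=True)
class TendonLoadTrace:
    """Body-weight-normalized Achilles tendon load time series."""

    participant_id: str
    session_id: str
    day_index: int
    sample_rate: float
    load: np.ndarray  # xBW, non-negative

    def __post_init__(self) -> None:
        arr = np.asarray(self.load, dtype=float)
        object.__setattr__(self, "load", arr)
        if arr.size and arr.min() < 0:
            raise IntegrityError("tendon load must be non-negative everywhere")
        if not self.sample_rate > 0:
            raise IntegrityError(f"sample_rate must be > 0, got {self.sample_rate}")

    @property
    def n_samples(self) -> int:
        return len(self.load)

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate


def plantarflexion_moment(f_heel, f_mid, f_fore, geom: SensorGeometry = DEFAULT_GEOMETRY):
    """Net ankle plantarflexion moment (N*m), positive = plantarflexion."""
    f_heel = np.asarray(f_heel, dtype=float)
    f_mid = np.asarray(f_mid, dtype=float)
    f_fore = np.asarray(f_fore, dtype=float)
    for name, f in (("f_heel", f_heel), ("f_mid", f_mid), ("f_fore", f_fore)):
        if not np.all(np.isfinite(f)):
            raise NumericError(f"non-finite values in {name}")
    return f_heel * geom.r_heel + f_mid * geom.r_mid + f_fore * geom.r_fore


def tendon_load(m_pf, geom: SensorGeometry, body_weight: float):
    """Achilles tendon load in xBW: max(0, M_PF / r_AT) / BW."""
    if not body_weight > 0:
        raise DomainError(f"body_weight must be > 0, got {body_weight}")
    m_pf = np.asarray(m_pf, dtype=float)
    return np.maximum(m_pf / geom.r_at, 0.0) / body_weight


def estimate_trace(
    rec: InsoleRecording,
    geom: SensorGeometry = DEFAULT_GEOMETRY,
    profile: ParticipantProfile | None = None,
    qc_report: QCReport | None = None,
    body_weight: float | None = None,
) -> TendonLoadTrace:
    """Samplewise tendon-load trace for a QC-passed recording.

    Either ``profile`` or an explicit ``body_weight`` (N) must be given.
    Recordings excluded by screening are refused.
    """
    if qc_report is not None and qc_report.status == STATUS_EXCLUDED:
        raise IntegrityError(
            f"session {rec.session_id!r} was excluded by QC "
            f"({qc_report.exclusion_reason}); refusing to estimate tendon load"
        )
    if body_weight is None:
        if profile is None:
            raise DomainError("either profile or body_weight is required")
        body_weight = profile.body_weight
    m_pf = plantarflexion_moment(rec.f_heel, rec.f_mid, rec.f_fore, geom)
    return TendonLoadTrace(
        participant_id=rec.participant_id,
        session_id=rec.session_id,
        day_index=rec.day_index,
        sample_rate=rec.sample_rate,
        load=tendon_load(m_pf, geom, body_weight),
    )
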