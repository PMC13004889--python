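"""Signal quality control: baseline-drift correction and recording screening.

Field insole recordings suffer two artifact families: slow/stepwise baseline
drift (the sensor reads a nonzero force while unloaded, e.g. after an insole
shift inside the shoe) and outright initialization failures (the user zeroed
the sensor while standing on it, so the signal never returns to a quiet
baseline). Drift is corrected by anchoring on *unloaded epochs* — windows in
which the total force barely changes — and subtracting the per-channel median
level held piecewise-constant between anchors. Recordings that cannot be
salvaged are excluded by rule-based screening.

The epoch length, quiet threshold and screening cutoffs below are this
package's documented defaults; they are exposed via :class:`QCRules`.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError
from .io import InsoleRecording, ParticipantProfile

CHANNELS = ("f_heel", "f_mid", "f_fore")

#: Screening exclusion categories.
REASON_NEVER_UNLOADED = "never-unloaded"
REASON_IMPLAUSIBLE_MAGNITUDE = "implausible-magnitude"
REASON_NEGATIVE_DOMINANCE = "negative-dominance"


@dataclass(frozen=True)
class QCRules:
    """Tunable QC parameters (all in SI units).

    epoch_s
        Length of the non-overlapping epochs used to find unloaded periods.
    quiet_threshold_n
        An epoch is unloaded iff the within-epoch range of total force is
        below this value; a range-based criterion is insensitive to constant
        offsets, which is exactly what makes drifted baselines detectable.
    min_unloaded_fraction, min_duration_s
        Rule (a): a long recording that essentially never goes quiet is the
        signature of an initialization failure.
    max_bw_multiple
        Rule (b): no 1-s mean of total plantar force should exceed this
        multiple of body weight.
    noise_floor_n, max_negative_fraction
        Rule (c): more than this fraction of samples below ``-noise_floor_n``
        (before clipping) indicates a corrupt zero level.
    """

    epoch_s: float = 10.0
    quiet_threshold_n: float = 20.0
    min_unloaded_fraction: float = 0.02
    min_duration_s: float = 1800.0
    max_bw_multiple: float = 10.0
    noise_floor_n: float = 5.0
    max_negative_fraction: float = 0.01


DEFAULT_RULES = QCRules()

STATUS_PASS = "pass"
STATUS_CORRECTED = "corrected"
STATUS_EXCLUDED = "excluded"


@dataclass(frozen=True)
class QCReport:
    """Outcome of drift correction and/or screening for one session."""

    session_id: str
    status: str
    exclusion_reason: str = ""
    fraction_unloaded: float = float("nan")
    #: per-channel list of (epoch_start_s, offset_n) anchors actually used
    drift_offsets: dict = field(default_factory=dict)
    #: fraction of channel-samples below -noise_floor before clipping
    negative_fraction: float = 0.0
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if (self.status == STATUS_EXCLUDED) != bool(self.exclusion_reason):
            raise DomainError(
                "status 'excluded' requires a nonempty exclusion_reason and vice versa"
            )

    def to_dict(self) -> dict:
        return {
            "session_id": self.session_id,
            "status": self.status,
            "exclusion_reason": self.exclusion_reason,
            "fraction_unloaded": self.fraction_unloaded,
            "drift_offsets": {
                ch: [[float(a), float(b)] for a, b in anchors]
                for ch, anchors in self.drift_offsets.items()
            },
            "negative_fraction": self.negative_fraction,
            "warnings": list(self.warnings),
        }


def epoch_edges(n_samples: int, sample_rate: float, epoch_s: float) -> np.ndarray:
    """Start indices of non-overlapping epochs, plus the final ``n_samples``.

    A trailing partial epoch shorter than ``epoch_s`` is merged into the
    previous epoch so no epoch is shorter than a full window (except when the
    whole recording is shorter than one epoch, which becomes a single epoch).
    """
    if epoch_s <= 0:
        raise DomainError(f"epoch_s must be > 0, got {epoch_s}")
    spe = max(int(round(epoch_s * sample_rate)), 1)
    if n_samples < spe:
        warnings.warn(
            "recording shorter than one QC epoch; treating it as a single epoch",
            stacklevel=2,
        )
        return np.array([0, n_samples])
    starts = np.arange(0, n_samples, spe)
    if n_samples - starts[-1] < spe and len(starts) > 1:
        starts = starts[:-1]
    return np.append(starts, n_samples)


def detect_unloaded_epochs(
    rec: InsoleRecording,
    epoch_s: float = DEFAULT_RULES.epoch_s,
    quiet_threshold_n: float = DEFAULT_RULES.quiet_threshold_n,
) -> np.ndarray:
    """Boolean mask over epochs: True where the insole appears unloaded.

    An epoch is unloaded iff the within-epoch *range* (max - min) of the
    total force is below ``quiet_threshold_n``; a constant 800 N offset is
    therefore still "unloaded" while any gait-like oscillation is not.
    """
    if quiet_threshold_n < 0:
        raise DomainError(f"quiet_threshold_n must be >= 0, got {quiet_threshold_n}")
    total = rec.total_force
    edges = epoch_edges(rec.n_samples, rec.sample_rate, epoch_s)
    mask = np.empty(len(edges) - 1, dtype=bool)
    for i, (a, b) in enumerate(zip(edges[:-1], edges[1:])):
        seg = total[a:b]
        mask[i] = (seg.max() - seg.min()) < quiet_threshold_n if len(seg) else True
    return mask


def _unloaded_fraction(edges: np.ndarray, mask: np.ndarray, n: int) -> float:
    if n == 0:
        return float("nan")
    lengths = np.diff(edges)
    return float(lengths[mask].sum() / n)


def correct_baseline_drift(
    rec: InsoleRecording,
    mask: np.ndarray | None = None,
    rules: QCRules = DEFAULT_RULES,
) -> tuple[InsoleRecording, QCReport]:
    """Subtract piecewise-constant per-channel baseline offsets.

    For every unloaded epoch the per-channel median level is taken as an
    offset anchor; the offset signal holds each anchor's value until the next
    anchor (first anchor back-filled to the session start). Corrected forces
    are clipped at 0 N from below, encoding the non-negativity of contact
    force. The operation is idempotent to within clipping round-off.
    """
    edges = epoch_edges(rec.n_samples, rec.sample_rate, rules.epoch_s)
    if mask is None:
        mask = detect_unloaded_epochs(rec, rules.epoch_s, rules.quiet_threshold_n)
    mask = np.asarray(mask, dtype=bool)
    if len(mask) != len(edges) - 1:
        raise DomainError("epoch mask does not match the recording's epoch grid")
    frac = _unloaded_fraction(edges, mask, rec.n_samples)

    if not mask.any():
        report = QCReport(
            session_id=rec.session_id,
            status=STATUS_PASS,
            fraction_unloaded=frac,
            warnings=("no unloaded epoch found; drift correction skipped",),
        )
        return rec, report

    anchor_idx = np.flatnonzero(mask)
    anchor_starts = edges[anchor_idx]
    anchor_t = anchor_starts / rec.sample_rate
    sample_idx = np.arange(rec.n_samples)
    # most recent anchor at or before each sample; earlier samples use anchor 0
    which = np.clip(np.searchsorted(anchor_starts, sample_idx, side="right") - 1, 0, None)

    corrected: dict[str, np.ndarray] = {}
    offsets_rep: dict[str, list[tuple[float, float]]] = {}
    neg_count = 0
    changed = False
    for ch in CHANNELS:
        f = getattr(rec, ch)
        anchors = np.array(
            [np.median(f[edges[i] : edges[i + 1]]) for i in anchor_idx]
        )
        offset_signal = anchors[which]
        shifted = f - offset_signal
        neg_count += int(np.count_nonzero(shifted < -rules.noise_floor_n))
        corrected[ch] = np.maximum(shifted, 0.0)
        offsets_rep[ch] = list(zip(anchor_t, anchors))
        if np.max(np.abs(anchors)) > 1e-9:
            changed = True

    out = rec.replace(**corrected)
    report = QCReport(
        session_id=rec.session_id,
        status=STATUS_CORRECTED if changed else STATUS_PASS,
        fraction_unloaded=frac,
        drift_offsets=offsets_rep,
        negative_fraction=neg_count / max(3 * rec.n_samples, 1),
    )
    return out, report


def screen_recording(
    rec: InsoleRecording,
    profile: ParticipantProfile,
    rules: QCRules = DEFAULT_RULES,
    drift_report: QCReport | None = None,
) -> QCReport:
    """Apply the exclusion rules to a drift-corrected recording.

    Rules (first match wins):
      (a) never-unloaded: the recording is long yet almost never quiet;
      (b) implausible magnitude: some 1-s mean of total force exceeds
          ``max_bw_multiple`` body weights;
      (c) negative dominance: too many pre-clipping samples were strongly
          negative (taken from ``drift_report`` when provided).
    """
    mask = detect_unloaded_epochs(rec, rules.epoch_s, rules.quiet_threshold_n)
    edges = epoch_edges(rec.n_samples, rec.sample_rate, rules.epoch_s)
    frac = _unloaded_fraction(edges, mask, rec.n_samples)
    neg_frac = drift_report.negative_fraction if drift_report is not None else 0.0
    prior_status = drift_report.status if drift_report is not None else STATUS_PASS

    reason = ""
    if frac < rules.min_unloaded_fraction and rec.duration_s > rules.min_duration_s:
        reason = REASON_NEVER_UNLOADED
    if not reason:
        total = rec.total_force
        w = max(int(round(rec.sample_rate)), 1)
        if rec.n_samples >= w:
            cs = np.concatenate(([0.0], np.cumsum(total)))
            sec_means = (cs[w:] - cs[:-w]) / w
        else:
            sec_means = np.array([total.mean()]) if rec.n_samples else np.array([])
        if sec_means.size and sec_means.max() > rules.max_bw_multiple * profile.body_weight:
            reason = REASON_IMPLAUSIBLE_MAGNITUDE
    if not reason and neg_frac > rules.max_negative_fraction:
        reason = REASON_NEGATIVE_DOMINANCE

    status = STATUS_EXCLUDED if reason else prior_status
    return QCReport(
        session_id=rec.session_id,
        status=status,
        exclusion_reason=reason,
        fraction_unloaded=frac,
        drift_offsets=dict(drift_report.drift_offsets) if drift_report else {},
        negative_fraction=neg_frac,
        warnings=tuple(drift_report.warnings) if drift_report else (),
    )
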