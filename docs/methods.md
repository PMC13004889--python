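# Methods

## Tendon-load model

The insole measures three plantar contact forces (heel, midfoot, forefoot
pads) at a nominal 20 Hz. Each force is assumed perpendicular to the sole
and applied at a fixed per-pad center of pressure, so the net ankle
plantarflexion moment is

    M_PF = F_heel·r_heel + F_mid·r_mid + F_fore·r_fore,

with moment arms signed anterior-positive about the ankle joint axis. The
Achilles tendon is treated as the sole transmitter of the plantarflexion
moment, giving a proxy tendon force `F_AT = M_PF / r_AT` with a standardized
tendon moment arm `r_AT = 0.05 m`. Negative (dorsiflexion) moments are
clamped to zero tendon load — a tendon cannot transmit compression — and the
result is normalized by body weight (`BW = mass × 9.80665 m/s²`), unit ×BW.

Default pad arms are `r_heel = −0.02 m`, `r_mid = 0.05 m`, `r_fore =
0.12 m` (the heel pad may sit posterior to the ankle axis, hence the
negative sign, which the model permits). These are this package's own
calibration, chosen so that synthesized walking reproduces the ≈3×BW
tendon-load peaks typical of gait; size-specific presets (`S`/`M`/`L`)
scale the arms with foot length and real deployments should measure them
per insole size.

## Quality control

Two artifact families dominate field recordings: baseline drift (the
sensor reads a nonzero force while unloaded) and initialization failures
(the sensor was zeroed while loaded, so the signal never returns to a
quiet baseline).

*Unloaded-epoch detection.* The recording is split into non-overlapping
10 s epochs; an epoch is unloaded iff the within-epoch **range** of total
force is below 20 N. A range criterion is deliberately insensitive to
constant offsets — a drifted-but-resting sensor still registers as
unloaded, which is exactly what makes the drift observable.

*Drift correction.* Within every unloaded epoch the per-channel median is
an offset anchor; the offset signal holds each anchor piecewise-constant
until the next anchor (first anchor back-filled). Piecewise-constant
interpolation was chosen over linear because anchors can be sparse and a
held level never extrapolates a trend into loaded periods; the cost is
that a step drift starting mid-bout is only corrected from the next quiet
epoch onward. Corrected forces are clipped at 0 N (contact forces are
non-negative). The correction is idempotent.

*Screening.* A recording is excluded when (a) it is longer than 30 min yet
less than 2% of it is unloaded (initialization-failure signature), (b) any
1-s mean of total force exceeds 10×BW, or (c) more than 1% of pre-clipping
samples fall below −5 N. The epoch length, quiet threshold and screening
cutoffs are this package's documented defaults (exposed via `QCRules`),
not values inherited from any particular deployment; published pipelines
describe this screening only qualitatively, so the numeric rules here are
deliberately conservative and config-exposed.

## Cumulative load metrics

Thresholds: 0.3×BW (load of a seated heel raise, the lowest-loading tendon
exercise — the boundary of "loading at all", which also defines the total
loading time used for wear-time normalization) and 3.0×BW (≈ peak tendon
load of walking — loading beyond it comes predominantly from dynamic
exercise). Time-above uses a samplewise indicator (`load ≥ thr`) with no
sub-sample interpolation; the impulse is the trapezoidal integral at the
native rate of the **full** load magnitude over supra-threshold samples
(area down to zero, not the excess above the line — the reading consistent
with per-hour normalized overall loads landing near the mean walking-level
load). Threshold crossings are resolved at sample resolution, so each
crossing contributes at most one sample period of error; at 20 Hz and
realistic bout counts this stays well below 1% of any accumulated
quantity. Sessions are concatenated without bridging gaps: unrecorded time
contributes nothing. Both normalized loads divide by the *overall* loading
time; when that time is zero the normalized values are reported as NaN and
flagged, never as 0 or infinity.

## Day-subsampling reliability

For each participant with ≥ 6 recorded days, the biomarkers are
re-estimated from all C(6, k) combinations of the first six recorded days,
k = 1…6 (k = 5 is leave-one-day-out, k = 1 is single days; intermediate k
use the full enumeration, which is cheap at ≤ 20 subsets). The reference
is the participant's full set of recorded days. Agreement is summarized
per (metric, k) by MAPE (absolute percent errors pooled over participants
and subsets; participants with a zero reference are dropped with a
warning), the Pearson correlation of per-participant subset means against
the reference, and the intraclass correlation across day-aligned subsets.
The ICC form is fixed to ICC(2,1) — two-way random effects, absolute
agreement, single measures (computed via pingouin) — because the question
"does one day's estimate agree with another's" is an absolute-agreement,
single-rater question. These are descriptive statistics; no inferential
testing is attached to the curves.

## Associations

Pearson correlations (two-sided p from the t transform with n−2 df) between
the two normalized loads and 13 participant measures: 7 dynamometer
capacity measures (peak moment isometric/30°s⁻¹/150°s⁻¹ in %H×W, peak
power and work per contraction at both speeds, normalized by body height ×
weight), 3 motion-capture measures (heel-raise and countermovement-jump
height in %BH, incline heel-raise repetitions), and 3 survey measures
(age, VISA-A, PAS). Strength classes use closed lower bounds: strong
|r| ≥ 0.6, moderate 0.4 ≤ |r| < 0.6, weak |r| < 0.4. Significance at
α = 0.05 is ancillary and deliberately uncorrected for multiplicity; rows
with < 3 complete pairs or zero variance are flagged, not dropped.

## Synthetic cohorts

The generator favors analytic tractability over biomechanical detail:
every activity is a periodic train of raised-cosine load pulses (stance
phases), so time-above and supra-threshold impulse have closed forms per
pulse and per-participant ground truth is exact for the continuous
waveform. Archetypes: light ambulation (peak 0.6×BW), walking (3.0×BW,
stance 0.65 s within a 1.09 s stride), running (4.2×BW), heel-raise sets
(4.5×BW) and jumps (5.5×BW); exercise peaks follow the convention that
high-level loading comes from dynamic exercise. Per-bout peaks carry a 7%
coefficient of variation — real gait does not reproduce one exact peak,
and a degenerate all-pulses-at-threshold waveform would make
supra-threshold quantities ill-conditioned. Pulse periods are
incommensurate with the 20 Hz grid so sampling phases self-average.

Each participant records 6–14 days with 1–3 sessions/day of 1–1.5 h — a
deliberately compact emulation of wear time that keeps cohort-scale tests
fast while producing per-day loading times and normalized loads
(norm_overall ≈ 1.0–1.4 ×BW, norm_high ≈ 0–0.4 ×BW) in realistic ranges.
A latent per-participant activity level drives exercise frequency and
hence the spread of high-level load across the cohort.

Load waveforms are inverted into pad forces through the same moment-arm
model the estimator uses, with pad weights progressing linearly from a
heel-dominant to a forefoot-dominant mix across each loaded segment and
the total force chosen so the inversion is exact; estimation therefore
recovers the input trace to floating-point precision, and any end-to-end
error comes from sampling, integration, and artifacts. Injected artifacts:
Gaussian sensor noise (σ = 0.5 N, clipped at 0), constant single-channel
initialization offsets (5–40 N), stepwise drifts (10–60 N at a random
onset), and whole-session initialization failures (a random-walk baseline
that never goes quiet; screening rule (a) must exclude these, and their
content is excluded from the ground truth as unusable by construction).

Outcome measures are drawn as `y = mean + sd·(ρ·z + √(1−ρ²)·ε)` where `z`
is the standardized ground-truth normalized high-level load — a direct
Gaussian mixing construction whose target Pearson correlation ρ is exact
in expectation and exactly affine at ρ = ±1. Values are clipped to
physical bounds and integer scales (PAS, repetition counts) are rounded,
which attenuates realized correlations by a few percent. Marginal means
and spreads mirror a typical tendinopathy cohort (e.g. age 47 ± 12, VISA-A
54 ± 26, PAS 3.8 ± 1.6).

What passing the recovery tests does **not** show: the generator contains
no double support, no load sharing between feet, no slow postural loads,
no non-stationary drift shapes, and less between-participant heterogeneity
in the overall load than real cohorts (one visible consequence: 1-day ICCs
of the overall load are near zero on synthetic cohorts because
between-participant variance is small, whereas field data shows moderate
1-day ICCs). Recovery within tolerance demonstrates the pipeline's
internal consistency, not validity of the load model against in-vivo
measurements.

## Numerical choices and degenerate inputs

- Gravitational constant 9.80665 m/s²; SI units (N, s, m) on disk, hours
  and ×BW·h in summaries.
- CSV serialization uses `%.17g` and round-trip float parsing, so
  write→read is bit-exact.
- Day boundaries follow the local calendar date of the session start; a
  session spanning midnight stays with its start date.
- A trailing partial QC epoch is merged into the previous epoch;
  recordings shorter than one epoch become a single epoch with a warning.
- Empty traces yield zero time/impulse; zero loading time flags normalized
  values as undefined (NaN) with a warning.
- Equal-threshold ties: the samplewise indicator uses `≥`, and the
  strength classifier assigns boundary values to the higher class.
- All analysis stages are deterministic; randomness exists only in the
  generator, which fans a single seed into per-participant substreams so
  cohorts are extensible without perturbing existing participants.

## Scale of the shipped experiments

The end-to-end recovery checks run on 20 participants × 10 days and the
reliability-shape check on 12 participants × 6 days with the session
durations above — cohort sizes chosen so the full suite completes in a few
minutes on a laptop while still exercising every code path at realistic
sampling rates. The acceptance script uses the default 15-participant,
6–14-day conditions.
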