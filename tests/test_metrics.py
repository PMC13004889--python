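import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tendonload as tl

FS = 20.0


def trace(load, session_id="S1", day=1, pid="P01"):
    return tl.TendonLoadTrace(
        participant_id=pid, session_id=session_id, day_index=day,
        sample_rate=FS, load=np.asarray(load, float),
    )


def step_trace(rng, n=2000):
    """Random non-negative piecewise-constant load trace."""
    n_steps = rng.integers(5, 30)
    edges = np.sort(rng.choice(np.arange(1, n), n_steps, replace=False))
    levels = rng.uniform(0, 6, n_steps + 1)
    load = np.empty(n)
    prev = 0
    for e, lv in zip(np.append(edges, n), levels):
        load[prev:e] = lv
        prev = e
    return load


def impulse_oracle(load, fs, thr, m=16):
    """Midpoint Riemann refinement of the linear interpolant (independent
    of the trapezoid route; exact for piecewise-linear signals)."""
    masked = np.where(load >= thr, load, 0.0)
    u = (np.arange(m) + 0.5) / m
    vals = masked[:-1, None] * (1 - u) + masked[1:, None] * u
    return float(vals.sum()) / (m * fs) / 3600.0


def time_oracle(load, fs, thr):
    count = sum(1 for v in load if v >= thr)
    return count / fs / 3600.0


class TestTimeAbove:
    def test_constant_above(self):
        t = trace(np.full(int(7200 * FS), 1.0))
        assert tl.time_above(t, 0.3) == pytest.approx(2.0)

    def test_constant_below(self):
        t = trace(np.full(int(600 * FS), 0.2))
        assert tl.time_above(t, 0.3) == 0.0

    def test_square_wave_duty_cycle(self):
        # 50% duty 0<->1 xBW over 1 h
        cycle = np.concatenate([np.ones(10), np.zeros(10)])
        t = trace(np.tile(cycle, 3600))
        assert tl.time_above(t, 0.3) == pytest.approx(0.5, abs=1 / FS / 3600)

    def test_empty(self):
        assert tl.time_above(trace([]), 0.3) == 0.0


class TestImpulseAbove:
    def test_constant(self):
        t = trace(np.full(int(7200 * FS) + 1, 1.0))
        assert tl.impulse_above(t, 0.3) == pytest.approx(2.0, rel=1e-9)

    def test_constant_high(self):
        t = trace(np.full(int(1800 * FS) + 1, 4.0))
        assert tl.impulse_above(t, 3.0) == pytest.approx(2.0, rel=1e-9)

    def test_piecewise(self):
        # 0.5 h at 4 xBW then 1.5 h at 0.5 xBW
        load = np.concatenate([np.full(int(1800 * FS), 4.0), np.full(int(5400 * FS), 0.5)])
        t = trace(load)
        assert tl.impulse_above(t, 0.3) == pytest.approx(2.75, rel=1e-3)
        assert tl.impulse_above(t, 3.0) == pytest.approx(2.0, rel=1e-3)

    def test_matches_rectangle_sum_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            load = step_trace(rng)
            thr = rng.uniform(0, 5)
            t = trace(load)
            assert tl.impulse_above(t, thr) == pytest.approx(
                impulse_oracle(load, FS, thr), rel=1e-9, abs=1e-15
            )
            assert tl.time_above(t, thr) == pytest.approx(
                time_oracle(load, FS, thr), rel=1e-12, abs=1e-15
            )


@given(st.integers(0, 2**32 - 1))
@settings(deadline=None, max_examples=25, derandomize=True)
def test_monotone_in_threshold(seed):
    rng = np.random.default_rng(seed)
    load = step_trace(rng, n=500)
    t = trace(load)
    thrs = np.sort(rng.uniform(0, 6, 4))
    times = [tl.time_above(t, x) for x in thrs]
    imps = [tl.impulse_above(t, x) for x in thrs]
    assert all(a >= b - 1e-12 for a, b in zip(times, times[1:]))
    assert all(a >= b - 1e-12 for a, b in zip(imps, imps[1:]))


class TestSummarize:
    def test_single_day_constant(self):
        t = trace(np.full(int(7200 * FS), 1.0))
        s = tl.summarize([t])
        assert s.loading_time_h == pytest.approx(2.0)
        assert s.norm_overall_bw == pytest.approx(1.0, rel=1e-4)
        assert s.norm_high_bw == 0.0

    def test_mixed_levels(self):
        load = np.concatenate([np.full(int(1800 * FS), 4.0), np.full(int(5400 * FS), 0.5)])
        s = tl.summarize([trace(load)])
        assert s.high_time_h == pytest.approx(0.5, rel=1e-3)
        assert s.norm_overall_bw == pytest.approx(1.375, rel=1e-3)
        assert s.norm_high_bw == pytest.approx(1.0, rel=1e-3)

    def test_additive_over_disjoint_day_sets(self):
        rng = np.random.default_rng(11)
        traces = [trace(step_trace(rng), session_id=f"s{d}", day=d) for d in range(1, 5)]
        sa = tl.summarize(traces, days={1, 2})
        sb = tl.summarize(traces, days={3, 4})
        sall = tl.summarize(traces)
        assert sall.loading_time_h == pytest.approx(sa.loading_time_h + sb.loading_time_h, rel=1e-12)
        assert sall.high_time_h == pytest.approx(sa.high_time_h + sb.high_time_h, rel=1e-12, abs=1e-15)
        assert sall.overall_impulse_bwh == pytest.approx(
            sa.overall_impulse_bwh + sb.overall_impulse_bwh, rel=1e-12)
        assert sall.high_impulse_bwh == pytest.approx(
            sa.high_impulse_bwh + sb.high_impulse_bwh, rel=1e-12, abs=1e-15)

    def test_norm_overall_within_load_range(self):
        """The per-hour overall load is a time-average of supra-threshold load."""
        rng = np.random.default_rng(13)
        for _ in range(10):
            load = np.concatenate([np.zeros(10), step_trace(rng, n=800), np.zeros(10)])
            s = tl.summarize([trace(load)])
            if not s.norms_defined:
                continue
            supra = load[load >= 0.3]
            assert s.norm_overall_bw >= max(0.3, supra.min()) - 1e-9
            assert s.norm_overall_bw <= load.max() + 1e-9

    def test_zero_loading_time_flagged(self):
        with pytest.warns(UserWarning, match="undefined"):
            s = tl.summarize([trace(np.zeros(100))])
        assert not s.norms_defined
        assert np.isnan(s.norm_overall_bw) and np.isnan(s.norm_high_bw)

    def test_summary_invariants_enforced(self):
        with pytest.raises(tl.IntegrityError):
            tl.CumulativeLoadSummary(
                participant_id="P", days_included=(1,), loading_time_h=1.0,
                high_time_h=2.0, overall_impulse_bwh=1.0, high_impulse_bwh=0.5,
                norm_overall_bw=1.0, norm_high_bw=0.5,
            )
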