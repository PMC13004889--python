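import itertools

import numpy as np
import pytest

import tendonload as tl
from tendonload.metrics import DayLoad


def icc21_oracle(m):
    """ICC(2,1) from first-principles two-way ANOVA mean squares."""
    m = np.asarray(m, float)
    n, k = m.shape
    grand = m.mean()
    rm, cm = m.mean(axis=1), m.mean(axis=0)
    msr = k * ((rm - grand) ** 2).sum() / (n - 1)
    msc = n * ((cm - grand) ** 2).sum() / (k - 1)
    mse = ((m - rm[:, None] - cm[None, :] + grand) ** 2).sum() / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestEnumerateSubsets:
    @pytest.mark.parametrize("k, expected", [(6, 1), (5, 6), (3, 20), (1, 6)])
    def test_counts(self, k, expected):
        design = tl.enumerate_subsets(list(range(1, 9)), k)
        assert len(design.subsets) == expected
        assert all(len(s) == k for s in design.subsets)

    def test_k5_is_leave_one_out(self):
        design = tl.enumerate_subsets([1, 2, 3, 4, 5, 6], 5)
        omitted = [set(range(1, 7)) - set(s) for s in design.subsets]
        assert sorted(next(iter(o)) for o in omitted) == [1, 2, 3, 4, 5, 6]

    def test_k1_is_single_days(self):
        design = tl.enumerate_subsets([2, 3, 5, 6, 7, 9, 11], 1)
        assert design.subsets == ((2,), (3,), (5,), (6,), (7,), (9,))

    def test_too_few_days_rejected(self):
        with pytest.raises(tl.DomainError, match="at least 6"):
            tl.enumerate_subsets([1, 2, 3], 2)


class TestMape:
    def test_identical_is_zero(self):
        assert tl.mape({"a": [1.0, 1.0]}, {"a": 1.0}) == 0.0

    def test_ten_percent(self):
        assert tl.mape({"a": [1.1]}, {"a": 1.0}) == pytest.approx(10.0)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(3)
        est = {f"p{i}": rng.uniform(0.5, 2.0, 7) for i in range(6)}
        ref = {f"p{i}": rng.uniform(0.5, 2.0) for i in range(6)}
        acc = [abs(e - ref[p]) / ref[p] * 100 for p, arr in est.items() for e in arr]
        oracle = sum(acc) / len(acc)
        assert tl.mape(est, ref) == pytest.approx(oracle, abs=1e-12)

    def test_zero_reference_dropped(self):
        with pytest.warns(UserWarning, match="zero reference"):
            out = tl.mape({"a": [1.0], "b": [2.0]}, {"a": 0.0, "b": 1.0})
        assert out == pytest.approx(100.0)


class TestPearson:
    def test_perfect_positive(self):
        x = np.arange(5.0)
        r, p = tl.pearson(x, 2 * x + 1)
        assert r == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = np.arange(5.0)
        r, _ = tl.pearson(x, -x)
        assert r == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 9.0])
        y = np.array([2.0, 1.0, 5.0, 3.0, 8.0])
        r, p = tl.pearson(x, y)
        xm, ym = x - x.mean(), y - y.mean()
        r_oracle = (xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum())
        assert r == pytest.approx(r_oracle, abs=1e-12)
        t = r_oracle * np.sqrt(3 / (1 - r_oracle**2))
        import scipy.stats as ss
        assert p == pytest.approx(2 * ss.t.sf(abs(t), 3), abs=1e-12)

    def test_zero_variance_flagged(self):
        with pytest.warns(UserWarning, match="variance"):
            r, p = tl.pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(r)


class TestICC:
    def test_identical_columns_is_one(self):
        col = np.array([1.0, 5.0, 9.0, 2.0])
        m = np.column_stack([col, col, col])
        assert tl.icc(m) == pytest.approx(1.0)

    def test_matches_anova_oracle_3x3(self):
        m = np.array([[9, 2, 5], [6, 1, 3], [8, 4, 6]], dtype=float)
        assert tl.icc(m) == pytest.approx(icc21_oracle(m), abs=1e-9)

    def test_matches_anova_oracle_random(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            m = rng.normal(5, 2, (5, 4))
            assert tl.icc(m) == pytest.approx(icc21_oracle(m), abs=1e-9)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(123)
        m = rng.standard_normal((500, 4))
        assert abs(tl.icc(m)) < 0.15

    def test_missing_cells_complete_case(self):
        m = np.array([[1.0, 2.0], [np.nan, 3.0], [2.0, 4.0], [5.0, 1.0]])
        with pytest.warns(UserWarning, match="missing"):
            val = tl.icc(m)
        assert val == pytest.approx(icc21_oracle(m[[0, 2, 3]]), abs=1e-9)


def random_day_loads(rng, n_days, base=1.0, high=0.1, noise=0.02):
    out = {}
    for d in range(1, n_days + 1):
        time = rng.uniform(0.8, 1.2)
        out[d] = DayLoad(
            loading_time_h=time,
            high_time_h=0.05 * time,
            overall_impulse_bwh=time * base * (1 + rng.normal(0, noise)),
            high_impulse_bwh=time * high * (1 + rng.normal(0, noise)),
        )
    return out


class TestReliabilityAnalysis:
    def test_subset_mean_of_additive_quantity(self):
        """Mean over all k-subsets of loading time equals k/6 of the 6-day sum."""
        rng = np.random.default_rng(2)
        loads = random_day_loads(rng, 6)
        days = sorted(loads)
        total = sum(loads[d].loading_time_h for d in days)
        for k in range(1, 7):
            design = tl.enumerate_subsets(days, k)
            means = [sum(loads[d].loading_time_h for d in s) for s in design.subsets]
            assert np.mean(means) == pytest.approx(k / 6 * total, rel=1e-12)

    def test_stationary_cohort_curve(self):
        """Statistically identical days: MAPE small and non-increasing in k."""
        rng = np.random.default_rng(6)
        cohort = {f"p{i}": random_day_loads(rng, 8, base=rng.uniform(0.8, 1.6))
                  for i in range(10)}
        report = tl.reliability_analysis(cohort)
        for metric in ("overall", "high"):
            curve = report.query("metric == @metric").sort_values("k")
            mape = curve["mape_mean_pct"].to_numpy()
            assert (np.diff(mape) <= 1e-9).all()
            assert mape[-1] < 3.0

    def test_exactly_six_days_k6_zero_error(self):
        rng = np.random.default_rng(9)
        cohort = {f"p{i}": random_day_loads(rng, 6) for i in range(4)}
        report = tl.reliability_analysis(cohort)
        k6 = report.query("k == 6")
        assert (k6["mape_mean_pct"].abs() < 1e-9).all()

    def test_short_participants_excluded_with_warning(self):
        rng = np.random.default_rng(10)
        cohort = {f"p{i}": random_day_loads(rng, 7) for i in range(3)}
        cohort["short"] = random_day_loads(rng, 4)
        with pytest.warns(UserWarning, match="short"):
            report = tl.reliability_analysis(cohort)
        assert (report["n_participants"] == 3).all()
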