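"""Statistical battery vs independent oracles (enumeration, scipy, statsmodels)."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from lvecho.phantom import simulate_physio_log
from lvecho.stats import (
    PhysioLog,
    bin_indicators,
    mcnemar,
    paired_t,
    physio_effect,
    significance_band,
    wilcoxon_signed_rank,
)


def wilcoxon_enumeration_oracle(diffs):
    """Two-sided exact signed-rank p by brute force over all sign patterns."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [
        np.dot(signs, ranks)
        for signs in itertools.product((0, 1), repeat=len(ranks))
    ]
    ws = np.asarray(ws)
    p_le = np.mean(ws <= w_obs + 1e-9)
    p_ge = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2 * min(p_le, p_ge))


class TestWilcoxon:
    def test_all_ties_give_p_one(self):
        res = wilcoxon_signed_rank([(1, 1), (2, 2)])
        assert res.p_value == 1.0 and res.n_effective == 0

    def test_textbook_case(self):
        # differences 1..5, all positive: W+ = 15, two-sided p = 2/32
        res = wilcoxon_signed_rank([(d, 0) for d in (1, 2, 3, 4, 5)])
        assert res.statistic == 15.0
        assert res.p_value == pytest.approx(0.0625)

    @pytest.mark.parametrize("n", range(2, 11))
    def test_exact_matches_enumeration_oracle(self, n):
        rng = np.random.default_rng(n)
        for _ in range(20):
            a = rng.integers(0, 3, n)
            b = rng.integers(0, 3, n)
            if np.all(a == b):
                continue
            res = wilcoxon_signed_rank(list(zip(a, b)))
            assert res.p_value == pytest.approx(
                wilcoxon_enumeration_oracle(a.astype(float) - b), abs=1e-12
            )

    def test_exact_at_twelve_pairs(self):
        rng = np.random.default_rng(12)
        a = rng.integers(0, 3, 14)
        b = rng.integers(0, 3, 14)
        a[:2] = b[:2]  # force some ties → n_effective ≤ 12
        res = wilcoxon_signed_rank(list(zip(a, b)))
        if res.n_effective <= 12:
            assert res.p_value == pytest.approx(
                wilcoxon_enumeration_oracle(a.astype(float) - b), abs=1e-12
            )

    def test_approximation_matches_scipy(self):
        rng = np.random.default_rng(5)
        a = rng.integers(0, 3, 100)
        b = rng.integers(0, 3, 100)
        res = wilcoxon_signed_rank(list(zip(a, b)))
        d = a.astype(float) - b
        ref = sps.wilcoxon(d[d != 0], correction=True, mode="approx")
        assert res.p_value == pytest.approx(float(ref.pvalue), rel=1e-9)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 2), st.integers(0, 2)), min_size=1, max_size=30))
    def test_symmetry_under_pair_swap(self, pairs):
        p1 = wilcoxon_signed_rank(pairs).p_value
        p2 = wilcoxon_signed_rank([(b, a) for a, b in pairs]).p_value
        assert p1 == pytest.approx(p2)
        assert 0.0 <= p1 <= 1.0


class TestMcNemar:
    def test_no_discordant_pairs(self):
        res = mcnemar([(1, 1), (0, 0)])
        assert res.p_value == 1.0

    def test_balanced_discordance_approx(self):
        pairs = [(1, 0)] * 14 + [(0, 1)] * 14
        res = mcnemar(pairs, exact_threshold=0)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_chi_square_closed_form(self):
        pairs = [(1, 0)] * 5 + [(0, 1)] * 1
        res = mcnemar(pairs, exact_threshold=0)
        assert res.statistic == pytest.approx((5 - 1) ** 2 / 6)

    def test_exact_binomial_enumeration(self):
        pairs = [(1, 0)] * 5 + [(0, 1)] * 1
        res = mcnemar(pairs)
        oracle = 2 * sum(math.comb(6, k) for k in (0, 1)) / 2**6
        assert res.p_value == pytest.approx(oracle)  # 0.21875

    def test_matches_statsmodels(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        rng = np.random.default_rng(0)
        x = rng.integers(0, 2, 40)
        y = rng.integers(0, 2, 40)
        res = mcnemar(list(zip(x, y)))
        table = pd.crosstab(pd.Series(x), pd.Series(y)).reindex(
            index=[0, 1], columns=[0, 1], fill_value=0
        )
        ref = sm_mcnemar(table.to_numpy(), exact=True)
        assert res.p_value == pytest.approx(float(ref.pvalue))

    def test_exact_and_chi2_agree_for_small_p(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.random(200) < 0.75
            y = rng.random(200) < 0.45
            b = int((x & ~y).sum())
            c = int((~x & y).sum())
            p_exact = min(1.0, 2 * sps.binom.cdf(min(b, c), b + c, 0.5))
            p_chi2 = float(sps.chi2.sf((b - c) ** 2 / (b + c), 1))
            if p_exact < 0.05:
                assert abs(p_exact - p_chi2) < 0.01

    def test_bin_indicators(self):
        assert bin_indicators(["a", "b", "a"], "a") == [1, 0, 1]


class TestPairedT:
    def test_symmetric_differences_give_p_one(self):
        res = paired_t([-2, -1, 0, 1, 2])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_closed_form_case(self):
        res = paired_t([1, 2, 3, 4])
        assert res.statistic == pytest.approx(2.5 / (1.29099 / 2), rel=1e-4)
        assert res.p_value == pytest.approx(0.0305, abs=2e-4)
        ref = sps.ttest_rel([1, 2, 3, 4], [0, 0, 0, 0])
        assert res.p_value == pytest.approx(float(ref.pvalue))
        lo, hi = res.ci_low, res.ci_high
        assert lo < 2.5 < hi

    def test_zero_variance_degenerate(self):
        res = paired_t([3.0, 3.0, 3.0])
        assert res.p_value == 0.0 and res.ci_low == res.ci_high == 3.0
        assert "zero variance" in res.method_note


class TestPhysioEffect:
    def make_log(self, series):
        rows = [
            {"animal": 1, "t_min": t, "sao2": 98.0, "hr": v, "map": 80.0}
            for t, v in enumerate(series)
        ]
        return PhysioLog(pd.DataFrame(rows), injections=[("x", 5)])

    def test_flat_series_zero_effect(self):
        eff = physio_effect(self.make_log([90.0] * 12), "x")
        assert (eff["rel_diff_pct"] == 0).all()

    def test_step_change_arithmetic(self):
        # HR 100 before, 96 after the injection at minute 5 → −4%
        eff = physio_effect(self.make_log([100.0] * 6 + [96.0] * 6), "x")
        hr = eff[eff["variable"] == "hr"]["rel_diff_pct"].iloc[0]
        assert hr == pytest.approx(-4.0)

    def test_insufficient_window_rejected(self):
        with pytest.raises(ValueError, match="insufficient"):
            physio_effect(self.make_log([100.0] * 7), "x")

    def test_windows_exclude_injection_minute(self):
        # spike exactly at the injection minute must not affect the estimate
        series = [100.0] * 5 + [500.0] + [100.0] * 6
        eff = physio_effect(self.make_log(series), "x")
        assert (eff["rel_diff_pct"] == 0).all()


def test_significance_bands():
    assert significance_band(0.2) == "NS"
    assert significance_band(0.01) == "P<0.05"
    assert significance_band(0.0001) == "P<0.001"
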