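import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dermometry.stats import (
    comparison_plan,
    mann_whitney_u,
    null_rejection_rate,
    run_comparison_plan,
    summarize,
    summarize_groups,
    t_test,
)


def mw_enumeration_oracle(a, b):
    """Exact two-sided Mann-Whitney p by brute force over all labelings."""
    a, b = list(a), list(b)
    pooled = a + b
    n1 = len(a)

    def u_of(sample, rest):
        return sum(
            (x > y) + 0.5 * (x == y) for x in sample for y in rest
        )

    u_obs = u_of(a, b)
    n12 = n1 * len(b)
    us = [
        u_of(combo, [pooled[i] for i in range(len(pooled)) if i not in idx])
        for idx in map(set, itertools.combinations(range(len(pooled)), n1))
        for combo in [[pooled[i] for i in idx]]
    ]
    n = len(us)
    p_le = sum(u <= u_obs for u in us) / n
    p_ge = sum(u >= u_obs for u in us) / n
    return u_obs, min(1.0, 2.0 * min(p_le, p_ge))


class TestSummarize:
    def test_constant_sample(self):
        s = summarize([2, 2, 2, 2])
        assert (s.n, s.mean, s.sem) == (4, 2.0, 0.0)

    def test_hand_computed_sem(self):
        s = summarize([1, 2, 3, 4, 5])
        assert s.mean == 3.0
        assert s.sem == pytest.approx(math.sqrt(2.5 / 5))  # sd(n-1)/sqrt(n)

    def test_translation_equivariance(self):
        a = summarize([1.0, 4.0, 2.5, 3.0])
        b = summarize([1.0 + 7, 4.0 + 7, 2.5 + 7, 3.0 + 7])
        assert b.mean == pytest.approx(a.mean + 7)
        assert b.sem == pytest.approx(a.sem)

    def test_single_value_fails(self):
        with pytest.raises(ValueError):
            summarize([1.0])


class TestMannWhitney:
    def test_fully_separated_samples(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)  # 2 extreme / 20 labelings
        assert res.method_note == "exact"

    def test_identical_samples_give_central_u(self):
        a = [1.0, 2.0, 3.0, 4.0]
        res = mann_whitney_u(a, a)
        assert res.statistic == pytest.approx(len(a) ** 2 / 2)

    def test_exact_p_matches_enumeration(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            a = rng.normal(0, 1, 6)
            b = rng.normal(0.5, 1, 6)
            res = mann_whitney_u(a, b, mode="exact")
            _, p_oracle = mw_enumeration_oracle(a, b)
            assert res.p_value == pytest.approx(p_oracle, abs=1e-12)

    def test_u_plus_u_prime_is_n1n2(self):
        rng = np.random.default_rng(4)
        for n1, n2 in [(3, 5), (6, 6), (10, 4)]:
            a, b = rng.normal(size=n1), rng.normal(size=n2)
            ua = mann_whitney_u(a, b).statistic
            ub = mann_whitney_u(b, a).statistic
            assert ua + ub == pytest.approx(n1 * n2)

    def test_label_swap_preserves_p(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=7), rng.normal(1, 1, size=5)
        assert mann_whitney_u(a, b).p_value == pytest.approx(
            mann_whitney_u(b, a).p_value
        )

    def test_exact_and_approx_agree_at_n8(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            a, b = rng.normal(size=8), rng.normal(size=8)
            pe = mann_whitney_u(a, b, mode="exact").p_value
            pa = mann_whitney_u(a, b, mode="approx").p_value
            # the continuity-corrected normal approximation sits within
            # about one point-probability (~0.012 at n1=n2=8) of exact
            assert abs(pe - pa) < 0.012

    @given(
        shift=st.floats(-2, 2),
        scale=st.floats(0.1, 10),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_monotone_transform_invariance(self, shift, scale):
        """Any strictly increasing map of both samples preserves U and p."""
        rng = np.random.default_rng(7)
        a, b = rng.normal(size=6), rng.normal(0.8, 1, size=6)
        base = mann_whitney_u(a, b)
        f = lambda x: np.exp(scale * x) + shift  # strictly increasing
        res = mann_whitney_u(f(a), f(b))
        assert res.statistic == base.statistic
        assert res.p_value == pytest.approx(base.p_value)

    def test_ties_fall_back_to_approximation(self):
        res = mann_whitney_u([1, 2, 2, 3], [2, 3, 3, 4], mode="auto")
        assert res.method_note == "normal_approx"

    def test_empty_sample_fails(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestTTest:
    def test_identical_samples_give_t0_p1(self):
        a = [1.0, 2.0, 3.0]
        res = t_test(a, a)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_closed_form_pooled_variance(self):
        res = t_test([1, 2, 3], [2, 3, 4], variant="student")
        # pooled sd = 1, t = (2-3)/sqrt(1*(1/3+1/3)) = -sqrt(3/2)
        assert res.statistic == pytest.approx(-math.sqrt(1.5))
        assert res.method_note == "student"

    def test_scale_invariance(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(size=10), rng.normal(1, 1, size=10)
        assert t_test(3 * a, 3 * b).statistic == pytest.approx(
            t_test(a, b).statistic
        )

    def test_degenerate_zero_variance(self):
        same = t_test([2, 2, 2], [2, 2, 2])
        assert same.p_value == 1.0 and not same.significant
        diff = t_test([2, 2, 2], [3, 3, 3])
        assert diff.p_value == 0.0 and diff.method_note == "degenerate"


def _make_table(rng, variables=("linearity_index", "d_band_length"), n=6, mu=None):
    rows = []
    for var in variables:
        for cond in ("CT", "HA"):
            for tp in (24, 48):
                for layer in ("papillary", "reticular"):
                    shift = (mu or {}).get((var, cond, tp, layer), 0.0)
                    for v in rng.normal(shift, 1, n):
                        rows.append(
                            {
                                "variable": var,
                                "value": v,
                                "units": "x",
                                "condition": cond,
                                "timepoint": tp,
                                "layer": layer,
                                "replicate": 1,
                            }
                        )
    return pd.DataFrame(rows)


class TestComparisonPlan:
    def test_plan_cardinality_is_fixed(self):
        # 4 treatment + 4 time + 4 layer contrasts per variable
        assert len(comparison_plan()) == 12

    def test_full_table_emits_all_comparisons(self):
        table = _make_table(np.random.default_rng(0))
        results = run_comparison_plan(table)
        assert len(results) == 2 * 12
        tests = {r.variable: r.test for r in results}
        assert tests["d_band_length"] == "t_test"
        assert tests["linearity_index"] == "mann_whitney"

    def test_missing_group_skipped(self, caplog):
        table = _make_table(np.random.default_rng(0), variables=("fibril_size",))
        table = table[
            ~(
                (table.condition == "HA")
                & (table.timepoint == 48)
                & (table.layer == "reticular")
            )
        ]
        results = run_comparison_plan(table)
        # HA-48h-reticular participates in 1 treatment + 1 time + 1 layer contrast
        assert len(results) == 12 - 3

    def test_group_summaries_match_direct_computation(self):
        table = _make_table(np.random.default_rng(1), variables=("fibril_size",))
        summaries = summarize_groups(table)
        assert len(summaries) == 8
        row = summaries.iloc[0]
        sub = table[
            (table.condition == row.condition)
            & (table.timepoint == row.timepoint)
            & (table.layer == row.layer)
        ]["value"]
        assert row["mean"] == pytest.approx(sub.mean())
        assert row["sem"] == pytest.approx(sub.sem())

    def test_null_rejection_rate_near_alpha(self):
        rate = null_rejection_rate(40, n_per_group=20, test="mann_whitney", seed=0)
        assert 0.02 <= rate <= 0.08
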