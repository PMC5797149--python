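"""Statistical battery: routing, post-hoc machinery, oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as ss

from telecg.stats import (
    describe,
    kruskal_dunn,
    normality_check,
    one_way_anova_snk,
    route_and_compare,
    sidak_adjust,
    two_way_anova_sidak,
)


class TestNormality:
    def test_gaussian_sample_passes(self):
        x = np.random.default_rng(0).normal(0, 1, 200)
        ok, w = normality_check(x)
        assert ok and w > 0.98

    def test_exponential_sample_fails_with_high_probability(self):
        rng = np.random.default_rng(1)
        fails = sum(not normality_check(rng.exponential(1, 50))[0]
                    for _ in range(50))
        assert fails >= 45

    def test_constant_or_tiny_sample_forces_nonparametric(self):
        assert normality_check([5.0, 5.0, 5.0]) == (False, pytest.approx(np.nan, nan_ok=True))
        assert not normality_check([1.0, 2.0])[0]

    def test_routing_switches_branch(self):
        rng = np.random.default_rng(2)
        gauss = {g: rng.normal(0, 1, 20) for g in "abc"}
        skew = {g: rng.exponential(1, 50) for g in "abc"}
        assert "ANOVA" in route_and_compare(gauss).test
        assert "Kruskal" in route_and_compare(skew).test


class TestSNK:
    def test_identical_groups_f_zero_no_significance(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = one_way_anova_snk({"a": x, "b": x.copy(), "c": x.copy()})
        assert res.statistic == pytest.approx(0.0)
        assert not any(c.significant for c in res.pairwise)

    def test_two_groups_equal_pooled_t_test(self):
        """q = sqrt(2)|t| identity makes SNK with 2 groups the t-test."""
        rng = np.random.default_rng(3)
        for _ in range(10):
            a, b = rng.normal(0, 1, 6), rng.normal(0.8, 1, 7)
            res = one_way_anova_snk({"a": a, "b": b})
            _, p = ss.ttest_ind(a, b)
            assert res.pairwise[0].p_adjusted == pytest.approx(p, abs=1e-10)
            assert res.pairwise[0].statistic == pytest.approx(
                np.sqrt(2) * abs(ss.ttest_ind(a, b)[0]), rel=1e-9)

    def test_single_shifted_group_drives_its_three_pairs(self):
        """4 groups, one clearly shifted: its pairs dominate the calls."""
        rng = np.random.default_rng(4)
        hits = {pair: 0 for pair in itertools.combinations("abcd", 2)}
        n_rep = 100
        for _ in range(n_rep):
            samples = {g: rng.normal(0, 1, 6) for g in "abc"}
            samples["d"] = rng.normal(4, 1, 6)  # large programmed effect
            res = one_way_anova_snk(samples)
            for c in res.pairwise:
                if c.significant:
                    hits[c.pair] += 1
        for pair in hits:
            if "d" in pair:
                assert hits[pair] >= 0.95 * n_rep
            else:
                assert hits[pair] <= 0.10 * n_rep

    def test_blocking_rule_reports_nonsignificant_inner_pairs(self):
        # all groups near-identical: the widest span blocks the inner pairs
        rng = np.random.default_rng(5)
        samples = {g: rng.normal(0, 1, 6) for g in "abcd"}
        res = one_way_anova_snk(samples)
        blocked = [c for c in res.pairwise if c.note]
        assert blocked and all(not c.significant for c in blocked)

    def test_zero_variance_with_unequal_means(self):
        res = one_way_anova_snk({"a": np.ones(4), "b": np.full(4, 2.0)})
        assert res.pairwise[0].significant
        assert res.pairwise[0].p_adjusted == 0.0

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(6)
        data = {g: rng.normal(0, 1, 6) for g in "abc"}
        res1 = one_way_anova_snk(data)
        res2 = one_way_anova_snk({"z" + g: v for g, v in data.items()})
        p1 = sorted(c.p_adjusted for c in res1.pairwise)
        p2 = sorted(c.p_adjusted for c in res2.pairwise)
        assert p1 == pytest.approx(p2)


class TestTwoWay:
    @staticmethod
    def _frame(rng, effects=None, n=6):
        effects = effects or {}
        rows = []
        for g in "ABC":
            for f in ("day", "night"):
                mu = effects.get((g, f), 0.0)
                for v in rng.normal(mu, 1, n):
                    rows.append({"group": g, "factor": f, "value": v})
        return pd.DataFrame(rows)

    def test_matches_statsmodels_on_balanced_layout(self):
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        rng = np.random.default_rng(7)
        df = self._frame(rng, {("A", "night"): 1.0, ("C", "day"): 0.5})
        res = two_way_anova_sidak(df)
        tab = anova_lm(smf.ols("value ~ C(group)*C(factor)", df).fit(), typ=2)
        assert res.extra["F_a"] == pytest.approx(tab.loc["C(group)", "F"])
        assert res.extra["F_b"] == pytest.approx(tab.loc["C(factor)", "F"])
        assert res.extra["F_interaction"] == pytest.approx(
            tab.loc["C(group):C(factor)", "F"])

    def test_missing_cell_rejected(self):
        rng = np.random.default_rng(8)
        df = self._frame(rng)
        df = df[~((df.group == "B") & (df.factor == "night"))]
        with pytest.raises(ValueError, match="missing cell"):
            two_way_anova_sidak(df)

    def test_sidak_identity_for_single_comparison(self):
        assert sidak_adjust(0.04, 1) == pytest.approx(0.04)
        assert sidak_adjust(0.04, 3) == pytest.approx(1 - 0.96**3)

    def test_programmed_daynight_difference_detected_within_strains(self):
        rng = np.random.default_rng(9)
        effects = {(g, "night"): 3.0 for g in "ABC"}
        detected = 0
        for _ in range(20):
            res = two_way_anova_sidak(self._frame(rng, effects))
            detected += all(c.significant for c in res.pairwise)
        assert detected >= 18


class TestKruskalDunn:
    def test_identical_groups_h_zero(self):
        x = np.array([1.0, 2.0, 3.0])
        res = kruskal_dunn({"a": x, "b": x.copy()})
        assert res.statistic == pytest.approx(0.0, abs=1e-12) or res.p_value > 0.9

    def test_all_tied_h_zero(self):
        res = kruskal_dunn({"a": np.ones(4), "b": np.ones(4)})
        assert res.statistic == 0.0

    def test_h_matches_rank_formula_bruteforce_small_instances(self):
        """H from first principles on every instance with total n <= 10."""
        rng = np.random.default_rng(10)
        for sizes in [(3, 3), (2, 4), (3, 3, 3), (2, 3, 4), (2, 2, 3, 3)]:
            vals = [rng.normal(0, 1, n) for n in sizes]
            res = kruskal_dunn({f"g{i}": v for i, v in enumerate(vals)})
            pooled = np.concatenate(vals)
            ranks = ss.rankdata(pooled)
            N = len(pooled)
            idx = np.cumsum([0] + list(sizes))
            h = 12.0 / (N * (N + 1)) * sum(
                sizes[i] * (ranks[idx[i]:idx[i + 1]].mean() - (N + 1) / 2) ** 2
                for i in range(len(sizes)))
            # no ties here, so no correction term
            assert res.statistic == pytest.approx(h, rel=1e-9)

    def test_monotone_shift_orders_mean_ranks(self):
        rng = np.random.default_rng(11)
        res = kruskal_dunn({
            "lo": rng.normal(0, 1, 8), "mid": rng.normal(2, 1, 8),
            "hi": rng.normal(4, 1, 8)})
        mr = res.extra["mean_ranks"]
        assert mr["lo"] < mr["mid"] < mr["hi"]

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(12)
        data = {g: rng.exponential(1, 7) + i for i, g in enumerate("abc")}
        r1 = kruskal_dunn(data)
        r2 = kruskal_dunn({g: np.log(v) for g, v in data.items()})
        assert r1.statistic == pytest.approx(r2.statistic)
        for c1, c2 in zip(r1.pairwise, r2.pairwise):
            assert c1.p_adjusted == pytest.approx(c2.p_adjusted)


class TestDescribe:
    def test_mean_and_sem_example(self):
        d = describe([1.0, 2.0, 3.0])
        assert d.mean == 2.0
        assert d.sem == pytest.approx(0.5773502691896258)

    def test_symmetric_sample_mean_equals_median(self):
        d = describe([1, 2, 3, 4, 5])
        assert d.mean == d.median

    def test_percentiles_match_numpy_sorting_definition(self):
        rng = np.random.default_rng(13)
        x = rng.normal(0, 1, 400)
        d = describe(x)
        assert d.p5 == pytest.approx(np.percentile(x, 5))
        assert d.p95 == pytest.approx(np.percentile(x, 95))
        assert d.p5 <= d.q1 <= d.median <= d.q3 <= d.p95
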