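"""Group statistics: ANOVA (raw and from summaries), Levene routing,
LSD pairwise tests, Kruskal-Wallis (raw and from mean ranks), OLS."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from dcekinetics import (GroupSummary, anova_from_summary, anova_oneway,
                         compare_groups, kruskal_wallis, kw_from_mean_ranks,
                         levene_homogeneity, linfit, lsd_pairwise)


def groups_with_summary(means, sds, n, seed=0):
    """Raw groups whose sample mean/SD match the given summaries exactly."""
    rng = np.random.default_rng(seed)
    out = []
    for m, s in zip(means, sds):
        z = rng.normal(size=n)
        z = (z - z.mean()) / z.std(ddof=1)
        out.append(m + s * z)
    return out


def random_groups(rng, k=3, balanced=False):
    sizes = [int(rng.integers(3, 9)) for _ in range(k)]
    if balanced:
        sizes = [sizes[0]] * k
    return [rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), n)
            for n in sizes]


class TestAnova:
    def test_identical_groups_give_f_zero(self):
        g = [1.0, 2.0, 3.0]
        res = anova_oneway([g, g, g])
        assert res.f == 0.0 and res.p == 1.0
        assert res.df_between == 2 and res.df_within == 6

    def test_two_groups_f_is_t_squared(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 8), rng.normal(1, 1, 6)
        res = anova_oneway([a, b])
        t, p = sps.ttest_ind(a, b)
        assert res.f == pytest.approx(t ** 2, rel=1e-12)
        assert res.p == pytest.approx(p, rel=1e-12)

    def test_zero_within_variance_flags_infinite_f(self):
        res = anova_oneway([[1.0, 1.0], [2.0, 2.0]])
        assert res.infinite_f and math.isinf(res.f) and res.p == 0.0

    def test_summary_equals_raw_on_constructed_groups(self):
        means = [137.000, 129.750, 129.750]
        sds = [41.012, 27.765, 27.765]
        raw = anova_oneway(groups_with_summary(means, sds, 4))
        summ = anova_from_summary(GroupSummary(tuple(means), tuple(sds),
                                               (4, 4, 4)))
        assert summ.f == pytest.approx(raw.f, abs=1e-10)
        assert summ.p == pytest.approx(raw.p, abs=1e-10)

    @given(st.integers(0, 2 ** 31), st.booleans())
    def test_summary_raw_equivalence_property(self, seed, balanced):
        rng = np.random.default_rng(seed)
        gs = random_groups(rng, balanced=balanced)
        raw = anova_oneway(gs)
        summ = anova_from_summary(GroupSummary(
            tuple(g.mean() for g in gs),
            tuple(g.std(ddof=1) for g in gs),
            tuple(g.size for g in gs)))
        assert summ.f == pytest.approx(raw.f, abs=1e-10 * max(1, raw.f))

    def test_equal_means_any_sds_give_f_zero(self):
        res = anova_from_summary(GroupSummary((5.0, 5.0, 5.0),
                                              (1.0, 2.0, 3.0), (4, 4, 4)))
        assert res.f == 0.0


class TestLevene:
    def test_identical_groups_do_not_reject(self):
        g = [1.0, 2.0, 3.0, 4.0]
        stat, p = levene_homogeneity([g, g, g])
        assert stat == 0.0 and p == 1.0

    def test_tenfold_spread_is_detected(self):
        rng = np.random.default_rng(17)
        gs = [rng.normal(0, 1, 20), rng.normal(0, 1, 20),
              rng.normal(0, 10, 20)]
        _, p = levene_homogeneity(gs)
        assert p < 0.05

    def test_type_i_error_calibrated(self):
        rng = np.random.default_rng(170)
        rejections = sum(
            levene_homogeneity([rng.normal(0, 1, 20) for _ in range(3)])[1]
            < 0.05
            for _ in range(1000))
        assert 0.03 <= rejections / 1000 <= 0.07


class TestLSD:
    def test_identical_pair_p_one(self):
        g = [1.0, 2.0, 3.0]
        pw = lsd_pairwise([g, g])
        assert pw[(0, 1)] == pytest.approx(1.0)

    def test_two_group_case_is_pooled_t_test(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(0, 1, 7), rng.normal(0.8, 1, 7)
        pw = lsd_pairwise([a, b])
        _, p = sps.ttest_ind(a, b)
        assert pw[(0, 1)] == pytest.approx(p, rel=1e-12)

    def test_reference_early_enhancement_significance_pattern(self):
        # groups rebuilt from published mean/SD summaries (n=4): the low
        # dose differs from both higher doses at alpha=0.05
        gs = groups_with_summary([1.197, 1.399, 1.557],
                                 [0.091, 0.048, 0.112], 4)
        pw = lsd_pairwise(gs, labels=["0.2", "0.3", "0.5"])
        assert pw[("0.2", "0.3")] < 0.05
        assert pw[("0.2", "0.5")] < 0.05
        assert pw[("0.3", "0.5")] < 0.05

    @given(st.integers(0, 2 ** 31),
           st.floats(min_value=-50, max_value=50),
           st.floats(min_value=0.1, max_value=20))
    def test_affine_invariance(self, seed, shift, scale):
        rng = np.random.default_rng(seed)
        gs = random_groups(rng)
        base = lsd_pairwise(gs)
        moved = lsd_pairwise([scale * g + shift for g in gs])
        for pair in base:
            assert moved[pair] == pytest.approx(base[pair], rel=1e-9)


class TestKruskalWallis:
    def test_all_tied_gives_h_zero(self):
        g = [5.0, 5.0, 5.0]
        res = kruskal_wallis([g, g, g])
        assert res.h == 0.0 and res.p == 1.0

    def test_published_mean_ranks_reproduce_h(self):
        res = kw_from_mean_ranks([8.250, 5.750, 5.500], [4, 4, 4])
        assert res.h == pytest.approx(1.423, abs=5e-4)
        assert res.df == 2

    def test_rank_sum_conservation_enforced(self):
        with pytest.raises(ValueError, match="conservation"):
            kw_from_mean_ranks([8.0, 6.0, 6.0], [4, 4, 4])

    def test_constructed_ranks_brute_force(self):
        # arrange 12 distinct values so the group mean ranks are
        # 8.25 / 5.75 / 5.5, then H must match the raw statistic
        # rank sets summing to 33, 23, 22 (means 8.25, 5.75, 5.5)
        gs = [[2, 8, 11, 12], [3, 5, 6, 9], [1, 4, 7, 10]]
        raw = kruskal_wallis(gs)
        summ = kw_from_mean_ranks([8.25, 5.75, 5.5], [4, 4, 4])
        assert raw.h == pytest.approx(summ.h, abs=1e-12)

    @given(st.integers(0, 2 ** 31))
    def test_mean_rank_identity_without_ties(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.permutation(rng.uniform(0, 100, 15))  # distinct
        gs = [vals[:4], vals[4:9], vals[9:]]
        raw = kruskal_wallis(gs)
        ranks = sps.rankdata(np.concatenate(gs))
        mean_ranks = [ranks[:4].mean(), ranks[4:9].mean(), ranks[9:].mean()]
        summ = kw_from_mean_ranks(mean_ranks, [4, 5, 6])
        assert raw.h == pytest.approx(summ.h, abs=1e-12)

    def test_two_group_identity_with_raw_statistic(self):
        rng = np.random.default_rng(23)
        vals = rng.permutation(rng.uniform(0, 10, 14))
        gs = [vals[:7], vals[7:]]
        ranks = sps.rankdata(np.concatenate(gs))
        summ = kw_from_mean_ranks([ranks[:7].mean(), ranks[7:].mean()],
                                  [7, 7])
        assert kruskal_wallis(gs).h == pytest.approx(summ.h, abs=1e-12)


class TestLinfit:
    def test_perfect_line(self):
        x = np.arange(10.0)
        slope, intercept, r, p = linfit(x, 3.0 * x - 2.0)
        assert slope == pytest.approx(3.0) and intercept == pytest.approx(-2)
        assert r == pytest.approx(1.0) and p < 1e-10

    def test_constant_y_flagged(self):
        slope, intercept, r, p = linfit(np.arange(5.0), np.full(5, 7.0))
        assert slope == 0.0 and math.isnan(r)

    def test_zero_x_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            linfit(np.full(5, 1.0), np.arange(5.0))

    def test_generative_recovery_within_3_se(self):
        rng = np.random.default_rng(31)
        x = np.arange(20.0)
        y = -150.0 * x + 16000.0 + rng.normal(0, 50, 20)
        slope, _, _, _ = linfit(x, y)
        res = sps.linregress(x, y)
        assert abs(slope - (-150.0)) < 3 * res.stderr


class TestCompareGroups:
    def _table(self, rng, shift=(0.0, 0.0, 0.0), n=7):
        rows = []
        for dose, d in zip((0.2, 0.3, 0.5), shift):
            for _ in range(n):
                rows.append({"dose": dose, "a": rng.normal(d, 1),
                             "b": rng.normal(0, 1)})
        return pd.DataFrame(rows)

    def test_dose_effect_flagged_only_where_present(self):
        rng = np.random.default_rng(2)
        table = self._table(rng, shift=(0.0, 2.0, 4.0))
        report = compare_groups(table)
        assert report["a"].significant
        assert not report["b"].significant
        assert report["a"].pairwise_flags()[(0.2, 0.5)]

    def test_routing_recorded_with_homogeneity_p(self):
        rng = np.random.default_rng(3)
        report = compare_groups(self._table(rng))
        for row in report:
            assert row.route in ("anova", "kruskal-wallis")
            assert (row.route == "kruskal-wallis") == (row.homogeneity_p < 0.05)
            if row.route == "anova":
                assert row.pairwise is not None and len(row.pairwise) == 3
            else:
                assert row.mean_ranks is not None

    def test_two_identical_groups_give_p_one(self):
        table = pd.DataFrame({"dose": [0.2] * 3 + [0.3] * 3,
                              "a": [1.0, 2.0, 3.0] * 2})
        report = compare_groups(table)
        assert report["a"].p == pytest.approx(1.0)
        assert not report["a"].significant

    def test_single_group_rejected(self):
        table = pd.DataFrame({"dose": [0.2] * 5, "a": np.arange(5.0)})
        with pytest.raises(ValueError, match="2 groups"):
            compare_groups(table)

    def test_report_roundtrips_to_dict_and_frame(self):
        rng = np.random.default_rng(8)
        report = compare_groups(self._table(rng))
        d = report.to_dict()
        assert {r["parameter"] for r in d["parameters"]} == {"a", "b"}
        frame = report.to_frame()
        assert list(frame["parameter"]) == ["a", "b"]
        assert "0.2" in d["groups"]
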