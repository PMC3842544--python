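"""Variance confinement, moderated paired t, FDR adjustment and calls."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy import stats as sps

from cpgdrift.dm import (
    adjust_pvalues,
    call_directions,
    estimate_moderation,
    overlap_comparisons,
    paired_moderated_t,
    pair_differences,
    variance_filter,
)
from cpgdrift.types import ModerationParams, PairedDesign, SiteStat
from tests.conftest import make_beta

DESIGN_AB = PairedDesign(
    "A", "B", (("D1", "A_D1", "B_D1"), ("D2", "A_D2", "B_D2"), ("D3", "A_D3", "B_D3"))
)


def beta_from_diffs(diffs: np.ndarray) -> "BetaMatrix":
    """Matrix whose condition-A columns are 0.4 and B columns 0.4 + diff."""
    diffs = np.atleast_2d(diffs)
    a = np.full_like(diffs, 0.4)
    return make_beta(np.hstack([a, a + diffs]), [f"cg{i}" for i in range(len(diffs))],
                     ["A", "B"], ["D1", "D2", "D3"])


class TestVarianceFilter:
    def test_keep_all_is_identity(self, paired_beta):
        out = variance_filter(paired_beta, 1.0)
        assert out.site_ids == paired_beta.site_ids

    def test_top_variance_sites_retained_in_order(self):
        # per-site across-sample variances 0.00, 0.01, 0.02, 0.03 (brute-force ranked)
        rng = np.random.default_rng(0)
        vals = np.empty((4, 6))
        for i, target in enumerate([0.0, 0.01, 0.02, 0.03]):
            x = rng.uniform(0.3, 0.7, 6)
            x = (x - x.mean()) / x.std(ddof=1) * math.sqrt(target) + 0.5 if target else np.full(6, 0.5)
            vals[i] = x
        m = make_beta(vals, ["s0", "s1", "s2", "s3"], ["A", "B"], ["D1", "D2", "D3"])
        out = variance_filter(m, 0.5)
        assert out.site_ids == ["s2", "s3"]  # original order preserved

    @pytest.mark.parametrize("bad", [0.0, -0.2, 1.5])
    def test_bad_fraction_rejected(self, paired_beta, bad):
        with pytest.raises(ValueError):
            variance_filter(paired_beta, bad)


class TestPairedModeratedT:
    def test_worked_fixture_matches_closed_form(self):
        m = beta_from_diffs(np.array([[0.10, 0.12, 0.08]]))
        (s,) = paired_moderated_t(m, DESIGN_AB, ModerationParams(0.0, 1.0))
        assert s.delta == pytest.approx(0.10, abs=1e-12)
        assert s.df == 2
        assert s.t_mod == pytest.approx(0.10 / (0.02 / math.sqrt(3)), rel=1e-9)  # 8.660254
        assert s.p == pytest.approx(2 * sps.t.sf(8.660254037844387, 2), rel=1e-6)

    def test_prior_df_zero_equals_classical_t(self):
        rng = np.random.default_rng(17)
        diffs = rng.normal(0.02, 0.05, size=(30, 3))
        m = beta_from_diffs(np.clip(diffs, -0.3, 0.3))
        stats_list = paired_moderated_t(m, DESIGN_AB, ModerationParams(0.0, 1.0))
        d = pair_differences(m, DESIGN_AB)
        t_ref, p_ref = sps.ttest_rel(d + 0.4, np.full_like(d, 0.4), axis=1)
        for s, t_exp, p_exp in zip(stats_list, t_ref, p_ref):
            assert s.t_mod == pytest.approx(t_exp, rel=1e-10)
            assert s.p == pytest.approx(p_exp, rel=1e-10)

    def test_all_zero_differences_give_t0_p1(self):
        m = beta_from_diffs(np.zeros((1, 3)))
        (s,) = paired_moderated_t(m, DESIGN_AB, ModerationParams(3.0, 1e-4))
        assert s.t_mod == 0.0 and s.p == 1.0
        (s0,) = paired_moderated_t(m, DESIGN_AB, ModerationParams(0.0, 1.0))
        assert s0.t_mod == 0.0 and s0.p == 1.0

    def test_infinite_prior_df_limit(self):
        m = beta_from_diffs(np.array([[0.10, 0.12, 0.08], [0.0, 0.05, -0.02]]))
        s0sq = 0.003
        stats_inf = paired_moderated_t(m, DESIGN_AB, ModerationParams(math.inf, s0sq))
        d = pair_differences(m, DESIGN_AB)
        for s, row in zip(stats_inf, d):
            assert s.t_mod == pytest.approx(row.mean() / math.sqrt(s0sq / 3), rel=1e-9)

    def test_missing_pair_dropped_pairwise(self):
        vals = np.array([[0.4, np.nan, 0.4, 0.5, 0.55, 0.6]])
        m = make_beta(vals, ["cg0"], ["A", "B"], ["D1", "D2", "D3"])
        (s,) = paired_moderated_t(m, DESIGN_AB, ModerationParams(0.0, 1.0))
        # donor D2 has a missing A value: only pairs D1, D3 remain
        diffs = np.array([0.5 - 0.4, 0.6 - 0.4])
        assert s.df == 1
        assert s.delta == pytest.approx(diffs.mean())

    def test_site_with_single_pair_dropped_entirely(self):
        vals = np.array([[0.4, np.nan, np.nan, 0.5, 0.55, 0.6], [0.4] * 6])
        m = make_beta(vals, ["cg0", "cg1"], ["A", "B"], ["D1", "D2", "D3"])
        stats_list = paired_moderated_t(m, DESIGN_AB, ModerationParams(0.0, 1.0))
        assert [s.cpg_id for s in stats_list] == ["cg1"]

    def test_all_sites_dropped_is_error(self):
        vals = np.array([[np.nan, np.nan, 0.4, 0.5, 0.55, 0.6]])
        m = make_beta(vals, ["cg0"], ["A", "B"], ["D1", "D2", "D3"])
        with pytest.raises(ValueError, match="all sites"):
            paired_moderated_t(m, DESIGN_AB, ModerationParams(0.0, 1.0))


class TestModerationEstimate:
    def test_recovers_hyperparameters_from_scaled_f_variances(self):
        # s2 ~ s0^2 * (chi2_d0/d0)^-1 * chi2_df/df  (marginal scaled F)
        rng = np.random.default_rng(7)
        d0, s0sq, df = 6.0, 0.02, 3.0
        n = 20_000
        true_var = s0sq * d0 / rng.chisquare(d0, n)
        s2 = true_var * rng.chisquare(df, n) / df
        params = estimate_moderation(s2, np.full(n, df))
        assert params.prior_df == pytest.approx(d0, rel=0.15)
        assert params.prior_var == pytest.approx(s0sq, rel=0.05)

    def test_homoscedastic_data_gives_infinite_prior(self):
        rng = np.random.default_rng(8)
        # variances concordant beyond sampling noise -> full shrinkage
        s2 = np.full(500, 0.01) * (1 + rng.normal(0, 1e-4, 500))
        params = estimate_moderation(s2, np.full(500, 2.0))
        assert math.isinf(params.prior_df)


class TestAdjustPvalues:
    def test_single_p_identity(self):
        np.testing.assert_allclose(adjust_pvalues([0.04]), [0.04])

    def test_step_up_hand_computed(self):
        # BH: p_(i) * m / i, cummin from the largest rank
        np.testing.assert_allclose(adjust_pvalues([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_never_decreases_and_order_invariant(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(1e-6, 1, 200)
        adj = adjust_pvalues(p)
        assert np.all(adj >= p) and np.all(adj <= 1)
        perm = rng.permutation(200)
        np.testing.assert_allclose(adjust_pvalues(p[perm]), adj[perm])

    @pytest.mark.parametrize("bad", [[0.0], [1.2], [-0.1], [float("nan")]])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            adjust_pvalues(bad)


class TestCallDirections:
    def mk(self, cpg, delta, p):
        return SiteStat(cpg, delta, 0.01, 2.0, 1.0, p)

    def test_definitions(self):
        stats_list = [self.mk("a", 0.2, 1e-4), self.mk("b", -0.2, 1e-4), self.mk("c", 0.2, 0.9)]
        out, n_hyper, n_hypo = call_directions(stats_list, alpha=0.05)
        assert [s.direction for s in out] == ["hyper", "hypo", "ns"]
        assert (n_hyper, n_hypo) == (1, 1)
        assert all(s.adj_p >= s.p for s in out)

    def test_counts_conserved(self):
        rng = np.random.default_rng(9)
        stats_list = [self.mk(f"cg{i}", rng.normal(), rng.uniform(1e-8, 1)) for i in range(50)]
        out, n_hyper, n_hypo = call_directions(stats_list)
        n_ns = sum(1 for s in out if s.direction == "ns")
        assert n_hyper + n_hypo + n_ns == 50

    @pytest.mark.parametrize("bad", [0.0, 1.0, -1.0])
    def test_bad_alpha_rejected(self, bad):
        with pytest.raises(ValueError):
            call_directions([self.mk("a", 0.1, 0.01)], alpha=bad)


class TestOverlaps:
    def test_two_sets(self):
        venn = overlap_comparisons({"X": {"a", "b"}, "Y": {"b", "c"}})
        assert venn[frozenset({"X", "Y"})] == 1
        assert venn[frozenset({"X"})] == 1
        assert venn[frozenset({"Y"})] == 1

    def test_three_identical_sets(self):
        s = set("abcde")
        venn = overlap_comparisons({"X": s, "Y": set(s), "Z": set(s)})
        assert venn == {frozenset({"X", "Y", "Z"}): 5}

    def test_random_sets_match_bruteforce(self):
        rng = np.random.default_rng(4)
        universe = [f"cg{i}" for i in range(300)]
        sets = {n: set(rng.choice(universe, 100, replace=False)) for n in "XYZ"}
        venn = overlap_comparisons(sets)
        assert sum(venn.values()) == len(sets["X"] | sets["Y"] | sets["Z"])
        # brute-force every region of the 3-set Venn diagram
        for key, count in venn.items():
            inside = set.intersection(*(sets[n] for n in key))
            outside = set.union(*(sets[n] for n in set("XYZ") - key), set())
            assert count == len(inside - outside)

    def test_single_set_rejected(self):
        with pytest.raises(ValueError):
            overlap_comparisons({"X": {"a"}})
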