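"""CGI relation, gene-region assignment and enrichment statistics."""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
import pytest

from cpgdrift.context import (
    assign_cgi_relation,
    assign_gene_region,
    category_enrichment_profile,
    fisher_enrichment_2x2,
    gene_set_enrichment,
    hypergeometric_enrichment,
    merge_intervals,
)
from cpgdrift.types import CpGRecord, GeneModel, GenomicInterval, SiteStat

CGIS = [GenomicInterval("chr1", 10_000, 11_000, "cgi1"), GenomicInterval("chr1", 20_000, 20_500)]


def hypergeom_tail_exact(N: int, K: int, n: int, k: int) -> float:
    """Enumeration oracle: P(X >= k) for X ~ Hypergeom(N, K, n)."""
    num = sum(comb(K, j) * comb(N - K, n - j) for j in range(k, min(n, K) + 1))
    return float(Fraction(num, comb(N, n)))


class TestCgiRelation:
    @pytest.mark.parametrize(
        "pos,expected",
        [
            (10_500, "Island"),   # inside
            (10_999, "Island"),   # last island base (half-open end)
            (11_000, "Shore"),    # first base outside
            (9_999, "Shore"),     # 1 bp left of the start
            (11_000 + 1_499, "Shore"),   # 1,500 bp from the edge: 2 kb shore
            (11_000 + 1_999, "Shore"),
            (11_000 + 2_999, "Shelf"),   # 3,000 bp out
            (10_000 - 10_000, "OpenSea"),  # 10 kb out
        ],
    )
    def test_distance_rule(self, pos, expected):
        assert assign_cgi_relation(pos, "chr1", CGIS) == expected

    def test_matches_bruteforce_nearest_edge_scan(self):
        rng = np.random.default_rng(12)
        cgis = [GenomicInterval("chr1", int(s), int(s) + int(w)) for s, w in
                zip(sorted(rng.integers(0, 100_000, 8) * 10), rng.integers(200, 2_000, 8))]
        for pos in rng.integers(0, 1_100_000, 300):
            pos = int(pos)
            got = assign_cgi_relation(pos, "chr1", cgis)
            # brute force: scan every base of every island for the closest
            best = min(
                min(abs(pos - b) for b in range(iv.start, iv.end)) for iv in merge_intervals(cgis)
            )
            expected = ("Island" if best == 0 else "Shore" if best <= 2_000
                        else "Shelf" if best <= 4_000 else "OpenSea")
            assert got == expected, (pos, best)

    def test_invariant_under_order_and_adjacent_merge(self):
        shuffled = [CGIS[1], CGIS[0]]
        split = [GenomicInterval("chr1", 10_000, 10_400), GenomicInterval("chr1", 10_400, 11_000),
                 CGIS[1]]
        for pos in (10_500, 11_500, 13_500, 50_000):
            ref = assign_cgi_relation(pos, "chr1", CGIS)
            assert assign_cgi_relation(pos, "chr1", shuffled) == ref
            assert assign_cgi_relation(pos, "chr1", split) == ref

    def test_classes_partition_every_position(self):
        rng = np.random.default_rng(13)
        for pos in rng.integers(0, 60_000, 200):
            rel = assign_cgi_relation(int(pos), "chr1", CGIS)
            assert rel in {"Island", "Shore", "Shelf", "OpenSea"}


class TestGeneRegion:
    PLUS = GeneModel("G1", "chr1", "+", 5_000, (5_000, 9_000), (5_000, 5_150), (5_150, 5_450),
                     (8_700, 9_000))
    MINUS = GeneModel("G2", "chr1", "-", 8_999, (5_000, 9_000), (8_850, 9_000), (8_550, 8_850),
                      (5_000, 5_300))

    @pytest.mark.parametrize(
        "pos,expected",
        [
            (4_900, {"TSS200"}),    # 100 bp upstream of a + TSS
            (4_000, {"TSS1500"}),   # 1,000 bp upstream
            (3_400, {"Intergenic"}),  # beyond the 1,500 bp band
            (5_100, {"UTR5"}),
            (5_300, {"Exon1"}),
            (7_000, {"Body"}),
            (8_800, {"UTR3"}),
            (20_000, {"Intergenic"}),
        ],
    )
    def test_plus_strand(self, pos, expected):
        assert assign_gene_region(pos, "chr1", [self.PLUS]) == expected

    @pytest.mark.parametrize(
        "pos,expected",
        [
            (9_099, {"TSS200"}),   # 100 bp upstream on the - strand is to the right
            (9_999, {"TSS1500"}),
            (8_900, {"UTR5"}),
            (8_600, {"Exon1"}),
            (5_100, {"UTR3"}),
            (7_000, {"Body"}),
        ],
    )
    def test_minus_strand(self, pos, expected):
        assert assign_gene_region(pos, "chr1", [self.MINUS]) == expected

    def test_multi_gene_accumulates_labels(self):
        labels = assign_gene_region(7_000, "chr1", [self.PLUS, self.MINUS])
        assert labels == {"Body"}
        labels = assign_gene_region(5_100, "chr1", [self.PLUS, self.MINUS])
        assert labels == {"UTR5", "UTR3"}


class TestHypergeometric:
    def test_worked_example_5_over_210(self):
        bg = {f"x{i}" for i in range(10)}
        cat = set(list(bg)[:5])
        sel = set(list(cat)[:4])
        rec = hypergeometric_enrichment(sel, cat, bg)
        assert rec.p == pytest.approx(5 / 210, abs=1e-12)
        assert (rec.k, rec.n, rec.K, rec.N) == (4, 4, 5, 10)

    def test_fold_one_when_proportions_match(self):
        bg = {f"x{i}" for i in range(20)}
        cat = {f"x{i}" for i in range(10)}           # K/N = 1/2
        sel = {"x0", "x1", "x10", "x11"}             # k/n = 1/2
        rec = hypergeometric_enrichment(sel, cat, bg)
        assert rec.fold == pytest.approx(1.0)

    def test_category_is_everything(self):
        bg = {f"x{i}" for i in range(8)}
        rec = hypergeometric_enrichment({"x0", "x1"}, set(bg), bg)
        assert rec.p == 1.0 and rec.fold == pytest.approx(1.0)

    def test_selection_outside_background_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_enrichment({"y"}, {"x0"}, {"x0", "x1"})


class TestGeneSetEnrichment:
    def test_worked_table_matches_enumeration(self):
        # 2x2 [[4,1],[6,9]]: enumeration oracle gives 49/323
        universe = {f"g{i}" for i in range(20)}
        in_set = {f"g{i}" for i in range(10)}
        selected = {"g0", "g1", "g2", "g3", "g15"}  # 4 in-set, 1 out
        (rec,) = gene_set_enrichment(selected, {"S": in_set}, universe)
        assert (rec.k, rec.n, rec.K, rec.N) == (4, 5, 10, 20)
        assert rec.p == pytest.approx(hypergeom_tail_exact(20, 10, 5, 4), abs=1e-12)
        assert rec.p == pytest.approx(49 / 323, abs=1e-12)

    def test_selected_equals_universe(self):
        universe = {f"g{i}" for i in range(12)}
        recs = gene_set_enrichment(set(universe), {"S": {"g0", "g1"}}, universe)
        assert recs[0].p == 1.0

    def test_disjoint_set_p1(self):
        universe = {f"g{i}" for i in range(12)}
        (rec,) = gene_set_enrichment({"g0"}, {"S": {"g5", "g6"}}, universe)
        assert rec.k == 0 and rec.p == 1.0

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            gene_set_enrichment({"g0"}, {"S": {"g0"}}, set())


class TestCategoryProfile:
    def _stats(self, manifest, hyper_ids):
        return [
            SiteStat(r.cpg_id, 0.2 if r.cpg_id in hyper_ids else 0.0, 0.01, 2.0, 1.0,
                     1e-6 if r.cpg_id in hyper_ids else 0.9,
                     adj_p=1e-5 if r.cpg_id in hyper_ids else 0.95,
                     direction="hyper" if r.cpg_id in hyper_ids else "ns")
            for r in manifest
        ]

    def test_planted_categories_have_smallest_pvalues(self, small_genome):
        manifest = small_genome.manifest
        targets = [r.cpg_id for r in manifest
                   if "TSS1500" in r.region_labels or r.cgi_relation == "Shore"]
        hyper = set(targets[: len(targets) // 3])
        records = category_enrichment_profile(self._stats(manifest, hyper), manifest)
        hyper_recs = sorted((r for r in records if r.category.startswith("hyper:")),
                            key=lambda r: r.p)
        top2 = {r.category for r in hyper_recs[:2]}
        assert top2 == {"hyper:TSS1500", "hyper:Shore"}

    def test_empty_selection_gives_k0_p1(self, small_genome):
        records = category_enrichment_profile(
            self._stats(small_genome.manifest, set()), small_genome.manifest
        )
        hypo = [r for r in records if r.category.startswith("hypo:")]
        assert all(r.k == 0 and r.p == 1.0 for r in hypo)

    def test_hypo_folds_near_one_on_hyper_only_data(self, small_genome):
        manifest = small_genome.manifest
        hyper = {manifest[3].cpg_id}
        records = category_enrichment_profile(self._stats(manifest, hyper), manifest)
        assert all(r.k == 0 for r in records if r.category.startswith("hypo:"))


class TestFisherHypergeomAgreement:
    def test_matched_margins_agree(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            N = int(rng.integers(4, 40))
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            k = int(rng.integers(max(0, n + K - N), min(n, K) + 1))
            table = np.array([[k, n - k], [K - k, N - K - n + k]])
            fisher = fisher_enrichment_2x2(table)
            assert fisher.p == pytest.approx(hypergeom_tail_exact(N, K, n, k), abs=1e-10)
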