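"""The synthetic-data generator: determinism, construction invariants and
statistical moments of the planted structure."""

from __future__ import annotations

import numpy as np
import pytest

from cpgdrift import io as cio
from cpgdrift.context import merge_intervals
from cpgdrift.dm import pair_differences
from cpgdrift.simulate import (
    REGION_MIXTURE,
    SimConfig,
    simulate_beta,
    simulate_expression,
    simulate_manifest,
    simulate_sequences_and_peaks,
    write_simulation,
)
from cpgdrift.types import PairedDesign


class TestManifestGeneration:
    def test_deterministic_under_seed(self, tmp_path):
        paths_a = write_simulation(SimConfig(n_cpg=1_000, seed=7), tmp_path / "a")
        paths_b = write_simulation(SimConfig(n_cpg=1_000, seed=7), tmp_path / "b")
        for key in paths_a:
            assert paths_a[key].read_bytes() == paths_b[key].read_bytes(), key

    def test_all_classes_represented(self, small_genome):
        assert {r.cgi_relation for r in small_genome.manifest} == {
            "Island", "Shore", "Shelf", "OpenSea"
        }
        labels = {lab for r in small_genome.manifest for lab in r.region_labels}
        assert labels == set(REGION_MIXTURE)

    def test_shore_sites_within_2kb_of_an_island(self, small_genome):
        cgis = merge_intervals(small_genome.cgi_intervals)
        for r in small_genome.manifest:
            if r.cgi_relation != "Shore":
                continue
            dists = [
                0 if iv.start <= r.pos < iv.end
                else iv.start - r.pos if r.pos < iv.start
                else r.pos - iv.end + 1
                for iv in cgis if iv.chrom == r.chrom
            ]
            assert 0 < min(dists) <= 2_000, r.cpg_id

    def test_every_probe_position_is_cg(self, small_genome):
        for r in small_genome.manifest:
            seq = small_genome.sequences[r.chrom]
            assert seq[r.pos : r.pos + 2] == "CG", r.cpg_id

    def test_label_counts_match_mixture_within_3sd(self):
        cfg = SimConfig(n_cpg=8_000, seed=23)
        genome = simulate_manifest(cfg)
        counts = {lab: 0 for lab in REGION_MIXTURE}
        for r in genome.manifest:
            for lab in r.region_labels:
                counts[lab] += 1
        for lab, p in REGION_MIXTURE.items():
            expected = cfg.n_cpg * p
            sd = np.sqrt(cfg.n_cpg * p * (1 - p))
            assert abs(counts[lab] - expected) <= 3 * sd + 4, lab  # +4: anchor probes

    def test_roundtrips_through_readers(self, small_genome, tmp_path):
        cio.write_manifest(small_genome.manifest, tmp_path / "m.tsv")
        assert cio.read_manifest(tmp_path / "m.tsv") == small_genome.manifest
        cio.write_bed(small_genome.cgi_intervals, tmp_path / "c.bed")
        assert cio.read_bed(tmp_path / "c.bed") == sorted(
            small_genome.cgi_intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)
        )

    def test_too_small_array_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_cpg=50)


class TestBetaGeneration:
    def test_values_in_unit_interval_and_paired_structure(self, small_study):
        config, genome, beta, truth = small_study
        arr = beta.values.to_numpy()
        assert np.nanmin(arr) >= 0 and np.nanmax(arr) <= 1
        assert len(beta.sample_ids) == len(config.conditions) * config.n_donors
        assert truth.planted_union <= {r.cpg_id for r in genome.manifest}

    def test_planted_sites_only_in_effect_categories(self, small_study):
        config, genome, _, truth = small_study
        by_id = {r.cpg_id: r for r in genome.manifest}
        for cid in truth.planted_union:
            r = by_id[cid]
            assert (r.region_labels & config.effect_categories) or (
                r.cgi_relation in config.effect_categories
            )

    def test_noiseless_limit_recovers_delta_exactly(self):
        cfg = SimConfig(n_cpg=500, seed=3, noise_sd=1e-9, donor_sd=0.0, effect_fraction=0.2)
        genome = simulate_manifest(cfg)
        beta, truth = simulate_beta(cfg, genome)
        design = PairedDesign.from_samples(beta.samples, "CD34pos_d0", "CD34pos_woMSC")
        diffs = pair_differences(beta, design).mean(axis=1)
        ids = np.array(beta.site_ids)
        planted = np.isin(ids, list(truth.planted_union))
        target = np.array([truth.true_delta[c] for c in ids[planted]])
        np.testing.assert_allclose(diffs[planted], target, atol=1e-6)
        np.testing.assert_allclose(diffs[~planted], 0.0, atol=1e-6)

    def test_mean_planted_delta_within_3se(self):
        cfg = SimConfig(n_cpg=10_000, seed=5)
        genome = simulate_manifest(cfg)
        beta, truth = simulate_beta(cfg, genome)
        design = PairedDesign.from_samples(beta.samples, "CD34pos_d0", "CD34pos_woMSC")
        diffs = pair_differences(beta, design)
        planted = np.isin(np.array(beta.site_ids), list(truth.planted_union))
        per_site = diffs[planted].mean(axis=1)
        target = np.mean([truth.true_delta[c] for c in np.array(beta.site_ids)[planted]])
        se = per_site.std(ddof=1) / np.sqrt(per_site.size)
        assert abs(per_site.mean() - target) <= 3 * se
        assert target == pytest.approx(cfg.effect_delta, abs=0.01)

    def test_null_config_plants_zero_deltas(self):
        cfg = SimConfig(n_cpg=500, seed=9, effect_delta=0.0)
        genome = simulate_manifest(cfg)
        _, truth = simulate_beta(cfg, genome)
        assert all(d == 0.0 for d in truth.true_delta.values())

    def test_requesting_too_many_effect_sites_is_error(self):
        cfg = SimConfig(n_cpg=500, seed=1, n_effect_sites=10_000)
        genome = simulate_manifest(cfg)
        with pytest.raises(ValueError, match="effect sites"):
            simulate_beta(cfg, genome)

    def test_bad_noise_sd_rejected(self):
        with pytest.raises(ValueError, match="noise_sd"):
            SimConfig(n_cpg=500, noise_sd=0.0)


class TestSequencesAndPeaks:
    def test_extreme_plant_rates(self, small_genome):
        cfg = SimConfig(n_cpg=1_000, seed=11, motif_plant_rate_fg=1.0, motif_plant_rate_bg=0.0,
                        peak_plant_rate_fg=1.0, peak_plant_rate_bg=0.0)
        beta, truth = simulate_beta(cfg, small_genome)
        windows, peaks = simulate_sequences_and_peaks(cfg, small_genome, truth)
        planted = truth.planted_union
        assert truth.motif_fg == {c for c in planted if c in windows}
        assert not truth.motif_bg
        for cid in truth.motif_fg:
            assert cfg.motif_consensus in windows[cid]
        assert truth.peak_sites == {c for c in planted if c in windows}

    def test_plant_count_within_3sd_of_binomial(self, small_genome):
        cfg = SimConfig(n_cpg=1_000, seed=19, effect_fraction=1.0, motif_plant_rate_fg=0.3)
        beta, truth = simulate_beta(cfg, small_genome)
        windows, _ = simulate_sequences_and_peaks(cfg, small_genome, truth)
        n_fg = len([c for c in truth.planted_union if c in windows])
        sd = np.sqrt(n_fg * 0.3 * 0.7)
        assert abs(len(truth.motif_fg) - 0.3 * n_fg) <= 3 * sd

    def test_peaks_validate_and_sort_via_reader(self, small_genome, tmp_path):
        cfg = SimConfig(n_cpg=1_000, seed=11)
        beta, truth = simulate_beta(cfg, small_genome)
        _, peaks = simulate_sequences_and_peaks(cfg, small_genome, truth)
        cio.write_bed(peaks, tmp_path / "p.bed")
        assert cio.read_bed(tmp_path / "p.bed") == peaks

    def test_oversize_consensus_rejected(self, small_genome):
        cfg = SimConfig(n_cpg=1_000, seed=11, motif_consensus="A" * 200)
        beta, truth = simulate_beta(cfg, small_genome)
        with pytest.raises(ValueError, match="consensus"):
            simulate_sequences_and_peaks(cfg, small_genome, truth)


class TestExpression:
    def _study(self, coupling, seed=31):
        cfg = SimConfig(n_cpg=2_000, seed=seed,
                        effect_categories=frozenset({"TSS200", "Exon1"}),
                        effect_fraction=0.5, expression_coupling=coupling)
        genome = simulate_manifest(cfg)
        beta, truth = simulate_beta(cfg, genome)
        expr = simulate_expression(cfg, genome, truth)
        return cfg, genome, truth, expr

    def test_coupled_genes_shifted_by_coupling_times_delta(self):
        cfg, genome, truth, expr = self._study(coupling=-4.0)
        assert truth.coupled_genes
        design = PairedDesign.from_samples(expr.samples, "CD34pos_d0", "CD34pos_woMSC")
        a = expr.values[[p[1] for p in design.pairs]].to_numpy()
        b = expr.values[[p[2] for p in design.pairs]].to_numpy()
        diffs = (b - a).mean(axis=1)
        coupled = np.isin(np.array(expr.gene_ids), list(truth.coupled_genes))
        se = diffs[coupled].std(ddof=1) / np.sqrt(coupled.sum())
        assert abs(diffs[coupled].mean() - (-4.0 * cfg.effect_delta)) <= 3 * se + 0.02
        se_null = diffs[~coupled].std(ddof=1) / np.sqrt((~coupled).sum())
        assert abs(diffs[~coupled].mean()) <= 3 * se_null

    def test_zero_coupling_no_shift(self):
        _, _, truth, expr = self._study(coupling=0.0)
        design = PairedDesign.from_samples(expr.samples, "CD34pos_d0", "CD34pos_woMSC")
        a = expr.values[[p[1] for p in design.pairs]].to_numpy()
        b = expr.values[[p[2] for p in design.pairs]].to_numpy()
        diffs = (b - a).mean(axis=1)
        coupled = np.isin(np.array(expr.gene_ids), list(truth.coupled_genes))
        se = diffs[coupled].std(ddof=1) / np.sqrt(max(coupled.sum(), 1))
        assert abs(diffs[coupled].mean()) <= 3 * se

    def test_deterministic_under_seed(self):
        _, _, _, e1 = self._study(coupling=-4.0, seed=5)
        _, _, _, e2 = self._study(coupling=-4.0, seed=5)
        assert e1.values.equals(e2.values)
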