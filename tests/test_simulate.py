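"""Synthetic-data generator: determinism, truth conservation, signal structure."""
import numpy as np
import pytest
from scipy.stats import binom

from pirnadev import cage
from pirnadev.simulate import (ConfigurationError, SimulationConfig, StageProfile,
                               generate_reference, plant_target_sites,
                               random_gene_tpm, simulate_ctss_sample,
                               simulate_small_rna_sample)
from conftest import adult_brain_profile


class TestReference:
    def test_cluster_count_and_intergenic_fraction(self, tiny_reference, tiny_config):
        clusters = tiny_reference.clusters
        assert len(clusters) == tiny_config.n_clusters
        realized = sum(c.klass == "intergenic" for c in clusters) / len(clusters)
        assert abs(realized - tiny_config.intergenic_fraction) <= 1 / len(clusters)

    def test_emulates_study_cluster_annotation_size(self):
        config = SimulationConfig(genome_length=3_000_000, n_chromosomes=4,
                                  n_clusters=214, cluster_length_range=(800, 1200),
                                  rng_seed=3)
        ref = generate_reference(config)
        assert len(ref.clusters) == 214

    def test_zero_clusters_valid_empty_annotation(self):
        ref = generate_reference(SimulationConfig(genome_length=20_000,
                                                  n_clusters=0, rng_seed=5))
        assert ref.clusters == [] and len(ref.genome) == 2

    def test_clusters_nonoverlapping_within_genome(self, tiny_reference):
        by_chrom = {}
        for c in tiny_reference.clusters:
            by_chrom.setdefault(c.chrom, []).append(c)
        for chrom, cs in by_chrom.items():
            cs.sort(key=lambda c: c.start)
            assert cs[0].start >= 0
            assert cs[-1].end <= len(tiny_reference.genome[chrom])
            for a, b in zip(cs, cs[1:]):
                assert a.end <= b.start

    def test_determinism_byte_identical(self, tiny_config):
        a = generate_reference(tiny_config)
        b = generate_reference(tiny_config)
        assert a.genome == b.genome
        assert a.clusters == b.clusters
        assert a.genes == b.genes
        assert a.repeats == b.repeats
        assert a.ncrnas == b.ncrnas

    def test_clusters_that_do_not_fit_rejected(self):
        config = SimulationConfig(genome_length=10_000, n_chromosomes=1,
                                  n_clusters=20, cluster_length_range=(900, 1000),
                                  rng_seed=1)
        with pytest.raises(ConfigurationError):
            generate_reference(config)

    def test_repeats_carry_consensus_lengths(self, tiny_reference):
        assert all(r.consensus_length > 0 for r in tiny_reference.repeats)


class TestSmallRnaSample:
    def test_truth_conservation(self, tiny_reference):
        profile = StageProfile("s", 2000, 0.3, 0.6, [(26, 1.0)], "poolX")
        records, truth = simulate_small_rna_sample(tiny_reference, profile, 3)
        assert len(records) == len(truth.alignments) == 2000
        assert len({t.read_id for t in truth.alignments}) == 2000

    def test_u1_degenerate_all_cluster_inserts_start_with_t(self, tiny_reference):
        profile = StageProfile("s", 500, 1.0, 1.0, [(26, 1.0)], "poolX")
        records, truth = simulate_small_rna_sample(tiny_reference, profile, 4)
        for (rid, seq, _), t in zip(records, truth.alignments):
            assert t.origin != "background"
            assert seq[4] == "T"  # first insert base, after the 4-base barcode

    def test_length_point_mass(self, tiny_reference):
        profile = StageProfile("s", 300, 0.5, 0.5, [(25, 1.0)], "poolX")
        # modal length 25 draws 25 or 26; force the degenerate case via 35 cap
        profile35 = StageProfile("s", 300, 0.5, 0.5, [(35, 1.0)], "poolX")
        _, truth = simulate_small_rna_sample(tiny_reference, profile35, 4)
        assert all(t.end - t.start == 35 for t in truth.alignments)

    def test_cluster_fraction_within_exact_binomial_interval(self, study_reference):
        profile = adult_brain_profile(50_000)
        _, truth = simulate_small_rna_sample(study_reference, profile, 9)
        k = sum(t.origin != "background" for t in truth.alignments)
        lo = binom.ppf(0.005, 50_000, 0.07)
        hi = binom.ppf(0.995, 50_000, 0.07)
        assert lo <= k <= hi

    def test_background_reads_avoid_clusters(self, tiny_reference):
        profile = StageProfile("s", 500, 0.0, 0.25, [(26, 1.0)], "poolX")
        _, truth = simulate_small_rna_sample(tiny_reference, profile, 6)
        for t in truth.alignments:
            assert t.origin == "background"
            for c in tiny_reference.clusters:
                if c.chrom == t.chrom:
                    assert t.end <= c.start or t.start >= c.end

    def test_cluster_reads_without_clusters_rejected(self):
        ref = generate_reference(SimulationConfig(genome_length=20_000,
                                                  n_clusters=0, rng_seed=5))
        profile = StageProfile("s", 10, 0.5, 0.5, [(26, 1.0)], "p")
        with pytest.raises(ConfigurationError):
            simulate_small_rna_sample(ref, profile, 1)

    def test_determinism(self, tiny_reference):
        profile = StageProfile("s", 400, 0.4, 0.7, [(26, 1.0)], "poolX")
        a = simulate_small_rna_sample(tiny_reference, profile, 12)
        b = simulate_small_rna_sample(tiny_reference, profile, 12)
        assert a[0] == b[0]
        assert a[1].alignments == b[1].alignments


class TestSharedPools:
    def _cluster_unique_seqs(self, reference, truth, records):
        seqs = set()
        by_id = {t.read_id: t for t in truth.alignments}
        for rid, seq, _ in records:
            t = by_id[rid]
            if t.origin != "background":
                seqs.add(seq[4: 4 + (t.end - t.start)])
        return seqs

    def test_shared_pool_high_sharing_disjoint_low(self, study_reference):
        mixture = [(26, 1.0)]
        a = StageProfile("a", 20_000, 0.5, 0.8, mixture, "shared")
        b = StageProfile("b", 20_000, 0.5, 0.8, mixture, "shared")
        c = StageProfile("c", 20_000, 0.5, 0.8, mixture, "other")
        ra = simulate_small_rna_sample(study_reference, a, 21)
        rb = simulate_small_rna_sample(study_reference, b, 22)
        rc = simulate_small_rna_sample(study_reference, c, 23)
        sa = self._cluster_unique_seqs(study_reference, ra[1], ra[0])
        sb = self._cluster_unique_seqs(study_reference, rb[1], rb[0])
        sc = self._cluster_unique_seqs(study_reference, rc[1], rc[0])
        assert len(sa & sb) / len(sa) >= 0.8
        assert len(sa & sc) / len(sa) <= 0.05


class TestCtssSimulation:
    def test_silent_gene_promoter_empty(self, tiny_reference):
        tpm = {g.gene_id: 0.0 for g in tiny_reference.genes}
        tpm[tiny_reference.genes[0].gene_id] = 50.0
        table = simulate_ctss_sample(tiny_reference, tpm, seed=2, total_tags=20_000)
        active = tiny_reference.genes[0]
        for g in tiny_reference.genes[1:]:
            if g.chrom != active.chrom:
                sub = table[table["chrom"] == g.chrom]
                for tss in g.tss_positions:
                    lo, hi = tss - 1000, tss + 1000
                    assert not ((sub["position"] >= lo) & (sub["position"] <= hi)).any()

    def test_reverse_cumulative_exponent_recovered(self, tiny_reference):
        tpm = random_gene_tpm(tiny_reference, seed=4)
        table = simulate_ctss_sample(tiny_reference, tpm, alpha=1.25,
                                     total_tags=50_000, seed=5)
        fit = cage.fit_power_law(table["count"].to_numpy(), fit_range=(1, 1000))
        assert abs(fit.alpha - 1.25) <= 0.15

    def test_determinism(self, tiny_reference):
        tpm = random_gene_tpm(tiny_reference, seed=4)
        a = simulate_ctss_sample(tiny_reference, tpm, seed=6, total_tags=10_000)
        b = simulate_ctss_sample(tiny_reference, tpm, seed=6, total_tags=10_000)
        assert a.equals(b)


class TestPlantedTargets:
    def test_planted_sites_recovered_with_full_sensitivity(self, tiny_reference):
        from pirnadev.targets import signature_scan
        guides, senses, sites = plant_target_sites(tiny_reference, n_sites=4, seed=8)
        found = signature_scan(guides, senses, tiny_reference.genome)
        for site in sites:
            assert any(
                f.chrom == site["chrom"] and f.start == site["start"]
                and f.guide_id == site["guide_id"] for f in found
            )

    def test_planted_sites_lie_within_gene_intervals(self, tiny_reference):
        _, _, sites = plant_target_sites(tiny_reference, n_sites=4, seed=8)
        genes = {g.gene_id: g for g in tiny_reference.genes}
        for site in sites:
            g = genes[site["gene_id"]]
            assert g.start <= site["start"] and site["end"] <= g.end
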