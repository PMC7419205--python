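"""The genome-evolution simulator: structure, truth tables, divergence laws."""

import math

import numpy as np
import pytest

from paleodup import kaks, simcore
from paleodup.errors import ConfigurationError, DataError
from paleodup.model import check_ranks

from conftest import truth_pairs


class TestAncestralGenome:
    def test_paper_scale_ancestor_shape(self):
        # ten chromosomes, 4216 genes: the reconstructed ancestral karyotype
        cfg = simcore.SimulationConfig(seed=1, n_chromosomes=10, n_genes=4216,
                                       codon_length=10)
        g = simcore.simulate_ancestral_genome(cfg)
        assert len(g.chromosomes) == 10
        assert g.n_genes == 4216
        check_ranks(g.gene_models())

    def test_minimal_genome(self):
        cfg = simcore.SimulationConfig(seed=1, n_chromosomes=1, n_genes=1, codon_length=5)
        g = simcore.simulate_ancestral_genome(cfg)
        models = g.gene_models()
        assert len(models) == 1 and models[0].rank == 0
        gid = models[0].gene_id
        assert g.truth[gid].ancestral_id == gid

    def test_seed_contract(self):
        mk = lambda s: simcore.simulate_ancestral_genome(
            simcore.SimulationConfig(seed=s, n_chromosomes=2, n_genes=20, codon_length=20)
        )
        g1, g1b, g2 = mk(1), mk(1), mk(2)
        assert g1.cds == g1b.cds
        assert g1.cds != g2.cds
        assert g1.n_genes == g2.n_genes

    def test_no_internal_stops(self):
        cfg = simcore.SimulationConfig(seed=3, n_chromosomes=1, n_genes=30, codon_length=50)
        g = simcore.simulate_ancestral_genome(cfg)
        _, stops = kaks._genetic_code()
        for cds in g.cds.values():
            assert not set(kaks.encode_codons(cds)) & stops

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            simcore.SimulationConfig(seed=1, n_genes=0)
        with pytest.raises(ConfigurationError):
            simcore.SimulationConfig(seed=1, loss_prob=1.0)
        with pytest.raises(ConfigurationError):
            simcore.SimulationConfig(seed=1, wgd_times=(77.8, 112.1))  # not decreasing
        with pytest.raises(ConfigurationError):
            simcore.SimulationConfig(seed=1, subst_rate_r=0.0)


class TestWgd:
    def _small(self, n=100, seed=2):
        return simcore.simulate_ancestral_genome(
            simcore.SimulationConfig(seed=seed, n_chromosomes=2, n_genes=n, codon_length=5)
        )

    def test_no_loss_doubles_genes_and_truth_pairs(self):
        g = self._small(100)
        simcore.apply_wgd(g, 50.0, 0.0, np.random.default_rng(0))
        assert g.n_genes == 200
        assert len(truth_pairs(g)) == 100
        check_ranks(g.gene_models())

    def test_retention_within_binomial_bounds(self):
        g = self._small(1000)
        simcore.apply_wgd(g, 50.0, 0.2, np.random.default_rng(1))
        retained = g.n_genes - 1000
        sigma = math.sqrt(1000 * 0.8 * 0.2)
        assert abs(retained - 800) <= 3 * sigma

    def test_two_wgds_give_four_copies(self):
        g = self._small(50)
        rng = np.random.default_rng(2)
        simcore.apply_wgd(g, 100.0, 0.0, rng)
        simcore.apply_wgd(g, 50.0, 0.0, rng)
        by_locus = {}
        for genes in g.chromosomes.values():
            for gid in genes:
                by_locus.setdefault(g.truth[gid].ancestral_id, []).append(gid)
        assert all(len(v) == 4 for v in by_locus.values())

    def test_loss_prob_one_rejected(self):
        with pytest.raises(ConfigurationError):
            simcore.apply_wgd(self._small(10), 50.0, 1.0, np.random.default_rng(0))


class TestSequenceEvolution:
    def test_zero_age_event_leaves_pairs_identical(self):
        g = simcore.simulate_ancestral_genome(
            simcore.SimulationConfig(seed=4, n_chromosomes=1, n_genes=20, codon_length=30)
        )
        simcore.apply_wgd(g, 0.0, 0.0, np.random.default_rng(0))
        cfg = simcore.SimulationConfig(seed=4, n_chromosomes=1, n_genes=20, codon_length=30)
        simcore.evolve_pair_sequences(g, cfg)
        for a, b in truth_pairs(g):
            assert g.cds[a] == g.cds[b]

    def test_mean_pairwise_ks_matches_2rT(self, one_wgd_genome):
        # r=4.21e-9, T=77.8 Ma, ks_sd=0: mean measured Ks ~ 0.655
        _, genome = one_wgd_genome
        vals = np.array([
            kaks.ng86_from_indices(
                kaks.encode_codons(genome.cds[a]), kaks.encode_codons(genome.cds[b])
            ).ks
            for a, b in truth_pairs(genome)
        ])
        assert len(vals) >= 300
        assert abs(vals.mean() - 0.655) < 0.01

    def test_ks_law_with_dispersion(self):
        # CLT: over >=500 pairs, mean Ks within 3 SE of 2rT; sd ~ ks_sd
        cfg = simcore.SimulationConfig(
            seed=9, n_chromosomes=2, n_genes=500, wgd_times=(35.6,),
            loss_prob=0.0, ks_sd=0.12, subst_rate_r=4.21e-9, codon_length=300,
        )
        g = simcore.simulate_lineage(cfg)
        vals = np.array([
            kaks.ng86_from_indices(
                kaks.encode_codons(g.cds[a]), kaks.encode_codons(g.cds[b])
            ).ks
            for a, b in truth_pairs(g)
        ])
        target = 2 * 4.21e-9 * 35.6e6  # ~0.3
        assert abs(vals.mean() - target) < 3 * vals.std() / np.sqrt(len(vals))
        assert 0.8 * 0.12 < vals.std() < 1.6 * 0.12

    def test_saturating_event_age_refused(self):
        cfg = simcore.SimulationConfig(seed=1, n_chromosomes=1, n_genes=4,
                                       wgd_times=(400.0,), codon_length=10)
        with pytest.raises(ConfigurationError, match="exceeds 2.5"):
            simcore.simulate_lineage(cfg)

    def test_lineage_determinism(self):
        cfg = simcore.SimulationConfig(seed=6, n_chromosomes=2, n_genes=40,
                                       wgd_times=(30.0,), loss_prob=0.1, codon_length=50)
        g1 = simcore.simulate_lineage(cfg)
        g2 = simcore.simulate_lineage(cfg)
        assert g1.cds == g2.cds
        assert g1.chromosomes == g2.chromosomes


class TestExpectedPairwiseKs:
    def test_inverse_roundtrip(self):
        for target in (0.05, 0.3, 0.655, 0.944, 2.0):
            s = simcore._ks_to_path_time(target)
            assert simcore.expected_pairwise_ks(s) == pytest.approx(target, abs=1e-3)

    def test_zero_time_zero_ks(self):
        assert simcore.expected_pairwise_ks(0.0) == pytest.approx(0.0, abs=1e-9)


class TestLtrCohort:
    def test_mean_k_matches_2rT(self):
        # mode chosen so 2rT = 0.03
        r = 1.51e-9
        mode = 0.03 / (2 * r) / 1e6
        coh = simcore.simulate_ltr_cohort(500, (mode, 0.0), r=r, ltr_length=1000, seed=3)
        lam = np.array([
            np.mean([x != y for x, y in zip(s5, s3)]) for _, s5, s3, _ in coh.pairs
        ])
        K = -0.75 * np.log1p(-4 * lam / 3)
        assert abs(K.mean() - 0.03) < 3 * K.std() / np.sqrt(len(K))

    def test_empty_cohort(self):
        assert simcore.simulate_ltr_cohort(0, (10.0, 1.0), seed=1).pairs == []

    def test_zero_rate_identical_copies(self):
        coh = simcore.simulate_ltr_cohort(5, (10.0, 1.0), r=0.0, ltr_length=300, seed=2)
        for _, s5, s3, _ in coh.pairs:
            assert s5 == s3

    def test_equal_copy_lengths(self):
        coh = simcore.simulate_ltr_cohort(10, (9.9, 2.0), ltr_length=400, seed=7)
        for _, s5, s3, _ in coh.pairs:
            assert len(s5) == len(s3) == 400

    def test_short_ltr_rejected(self):
        with pytest.raises(ConfigurationError):
            simcore.simulate_ltr_cohort(5, (10.0, 1.0), ltr_length=100, seed=1)


class TestReads:
    def test_coverage_arithmetic(self):
        g = simcore.random_genome(100_000, seed=1)
        reads = simcore.simulate_reads(g, 30, 150, seed=2)
        assert len(reads) == 20_000
        total = sum(len(s) for _, s in reads)
        assert abs(total - 30 * 100_000) <= 150

    def test_zero_coverage_rejected(self):
        with pytest.raises(ConfigurationError):
            simcore.simulate_reads(simcore.random_genome(1000, seed=1), 0, 100, seed=2)

    def test_read_longer_than_genome_rejected(self):
        with pytest.raises(DataError):
            simcore.simulate_reads(simcore.random_genome(500, seed=1), 10, 600, seed=2)

    def test_seed_contract(self):
        g = simcore.random_genome(10_000, seed=3)
        assert simcore.simulate_reads(g, 5, 100, seed=9) == simcore.simulate_reads(
            g, 5, 100, seed=9
        )


class TestRearrangementsAndTandem:
    def test_fission_fusion_preserve_gene_content(self):
        cfg = simcore.SimulationConfig(seed=8, n_chromosomes=3, n_genes=60, codon_length=5)
        g = simcore.simulate_ancestral_genome(cfg)
        before = sorted(gid for genes in g.chromosomes.values() for gid in genes)
        simcore.apply_rearrangements(g, 6, np.random.default_rng(1))
        after = sorted(gid for genes in g.chromosomes.values() for gid in genes)
        assert before == after
        check_ranks(g.gene_models())

    def test_tandem_copies_are_adjacent(self):
        cfg = simcore.SimulationConfig(seed=8, n_chromosomes=1, n_genes=50, codon_length=5)
        g = simcore.simulate_ancestral_genome(cfg)
        simcore.apply_tandem_duplications(g, 0.3, 10.0, np.random.default_rng(2))
        genes = g.chromosomes["chr01"]
        for i, gid in enumerate(genes):
            rec = g.truth[gid]
            if rec.event == "tandem":
                assert genes[i - 1] == rec.parent_id
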