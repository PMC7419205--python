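import numpy as np
import pytest

from paleodup import simcore
from paleodup.model import GeneModel


@pytest.fixture(scope="session")
def one_wgd_genome():
    """A small lineage with one 77.8 Ma WGD, no loss, evolved sequences."""
    cfg = simcore.SimulationConfig(
        seed=5, n_chromosomes=2, n_genes=300, wgd_times=(77.8,),
        loss_prob=0.0, ks_sd=0.0, codon_length=300,
    )
    return cfg, simcore.simulate_lineage(cfg)


@pytest.fixture(scope="session")
def sister_lineages():
    """Ancestor, an unchanged sister A, and a two-WGD sister B (20% loss)."""
    cfg = simcore.SimulationConfig(seed=11, n_chromosomes=5, n_genes=1000)
    anc = simcore.simulate_ancestral_genome(cfg)
    a = simcore.copy_lineage(anc, "A")
    b = simcore.copy_lineage(anc, "B")
    rng = np.random.default_rng(101)
    simcore.apply_wgd(b, 112.1, 0.2, rng)
    simcore.apply_wgd(b, 77.8, 0.2, rng)
    return anc, a, b


def truth_pairs(genome):
    """All extant gene pairs sharing an ancestral locus."""
    by_locus = {}
    for chrom_genes in genome.chromosomes.values():
        for g in chrom_genes:
            by_locus.setdefault(genome.truth[g].ancestral_id, []).append(g)
    pairs = []
    for genes in by_locus.values():
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                pairs.append((genes[i], genes[j]))
    return pairs


def make_genes(spec):
    """Compact gene builder: spec = {chrom: [gene ids in rank order]}."""
    genes = []
    for chrom, ids in spec.items():
        for rank, gid in enumerate(ids):
            start = rank * 1000
            genes.append(GeneModel(gid, chrom, rank, start, start + 500))
    return genes
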