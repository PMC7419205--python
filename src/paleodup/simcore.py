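"""Synthetic genome-evolution generator.

Everything downstream (synteny, Ka/Ks, peak fitting, dating, the k-mer
survey) can be exercised on data from this module, whose generative model
is the inverse of the dating formulas used for inference:

* paralog pairs created by a whole-genome duplication (WGD) of age ``T``
  accumulate a synonymous divergence whose NG86-measured Ks is centred on
  ``2 r T`` with dispersion ``ks_sd``;
* the two LTR copies of a retroelement inserted ``T`` years ago diverge
  under Jukes–Cantor so that their expected genetic distance is ``2 r T``;
* reads are error-free and uniform, so the k-mer spectrum has a single
  coverage peak at approximately ``coverage * (L - k + 1) / L``.

Sequence divergence is simulated along the duplication tree of each
ancestral locus: every branch receives a target divergence drawn from
``Normal(r * dt, ks_sd / sqrt(2))`` (truncated at 0) and synonymous
substitutions are placed one at a time until the NG86 distance from the
branch start reaches the target. Sister pairs therefore measure
``Normal(2 r T, ks_sd)`` on average, and because Jukes–Cantor distances are
additive in expectation, pairs split at an older event are unbiased too.
Nonsynonymous positions are never touched (Ka ~ 0), so Ks measurement is
not confounded by selection modelling.

All randomness flows from the seed in :class:`SimulationConfig`; identical
config and seed give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from . import kaks
from .errors import ConfigurationError, DataError
from .model import GeneModel

#: synonymous substitution rate used for LTR dating in the source analysis
LTR_RATE = 1.51e-9
#: intergenic spacing used when laying out simulated gene coordinates (bp)
_SPACER = 1000


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated lineage.

    Parameters
    ----------
    seed : RNG seed; the only source of randomness.
    n_chromosomes, n_genes : ancestral genome shape.
    wgd_times : WGD ages in Ma, strictly decreasing toward the present.
    subst_rate_r : synonymous substitutions / site / year.
    ks_sd : dispersion of pairwise Ks around 2rT per duplication event.
    loss_prob : probability that a newly created WGD duplicate is lost.
    n_rearrangements : number of chromosome fission/fusion operations.
    tandem_prob : per-gene probability of a tandem copy.
    codon_length : codons per simulated gene.
    """

    seed: int
    n_chromosomes: int = 5
    n_genes: int = 1000
    wgd_times: tuple[float, ...] = ()
    subst_rate_r: float = 4.21e-9
    ks_sd: float = 0.12
    loss_prob: float = 0.2
    n_rearrangements: int = 0
    tandem_prob: float = 0.0
    tandem_age_ma: float = 10.0
    codon_length: int = 300

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1 or self.n_genes < 1:
            raise ConfigurationError("n_chromosomes and n_genes must be positive")
        if self.n_genes < self.n_chromosomes:
            raise ConfigurationError("need at least one gene per chromosome")
        if not 0.0 <= self.loss_prob < 1.0:
            raise ConfigurationError("loss_prob must be in [0, 1)")
        if self.subst_rate_r <= 0:
            raise ConfigurationError("subst_rate_r must be positive")
        if any(t <= 0 for t in self.wgd_times):
            raise ConfigurationError("WGD ages must be positive")
        if list(self.wgd_times) != sorted(self.wgd_times, reverse=True) or len(
            set(self.wgd_times)
        ) != len(self.wgd_times):
            raise ConfigurationError("wgd_times must be strictly decreasing toward the present")
        if self.codon_length < 1:
            raise ConfigurationError("codon_length must be positive")


@dataclass
class TruthRecord:
    """Provenance of one extant gene."""

    ancestral_id: str
    event: str  # "none" | "wgd<k>" | "tandem"
    parent_id: str | None = None
    event_age_ma: float | None = None


@dataclass
class SimulatedGenome:
    """Gene order, CDS and full provenance of one simulated lineage."""

    chromosomes: dict[str, list[str]]  # chromosome -> ordered gene ids
    cds: dict[str, str]
    truth: dict[str, TruthRecord]
    codon_length: int
    events: list[tuple[str, float]] = field(default_factory=list)  # (label, age Ma)
    _id_counter: int = 0

    @property
    def n_genes(self) -> int:
        return sum(len(g) for g in self.chromosomes.values())

    def gene_models(self) -> list[GeneModel]:
        glen = 3 * self.codon_length
        out = []
        for chrom, gene_ids in self.chromosomes.items():
            for rank, gid in enumerate(gene_ids):
                start = rank * (glen + _SPACER)
                out.append(GeneModel(gid, chrom, rank, start, start + glen))
        return out

    def new_gene_id(self) -> str:
        self._id_counter += 1
        return f"g{self._id_counter:06d}"


def _random_cds_indices(rng: np.random.Generator, n_codons: int) -> np.ndarray:
    """Uniform sense codons (no stops) as codon indices."""
    _, stops = kaks._genetic_code()
    sense = np.array([i for i in range(64) if i not in stops], dtype=np.int64)
    return sense[rng.integers(0, len(sense), size=n_codons)]


def _indices_to_cds(idx: np.ndarray) -> str:
    return "".join(kaks.index_codon(int(i)) for i in idx)


def simulate_ancestral_genome(config: SimulationConfig) -> SimulatedGenome:
    """Ancestral genome: genes distributed round-robin across chromosomes.

    Every gene receives a random CDS of ``codon_length`` sense codons and
    maps to itself in the truth table.
    """
    rng = np.random.default_rng(config.seed)
    chrom_names = [f"chr{i + 1:02d}" for i in range(config.n_chromosomes)]
    chromosomes: dict[str, list[str]] = {c: [] for c in chrom_names}
    genome = SimulatedGenome(chromosomes, {}, {}, config.codon_length)
    for i in range(config.n_genes):
        gid = genome.new_gene_id()
        chromosomes[chrom_names[i % config.n_chromosomes]].append(gid)
        genome.cds[gid] = _indices_to_cds(_random_cds_indices(rng, config.codon_length))
        genome.truth[gid] = TruthRecord(ancestral_id=gid, event="none")
    return genome


def apply_wgd(
    genome: SimulatedGenome,
    event_age: float,
    loss_prob: float,
    rng: np.random.Generator,
) -> SimulatedGenome:
    """Duplicate every chromosome, then lose each new gene independently.

    The surviving duplicates carry a truth record naming the event and their
    parent gene; expected retained duplicates = n_genes * (1 - loss_prob).
    """
    if loss_prob >= 1.0 or loss_prob < 0.0:
        raise ConfigurationError("loss_prob must be in [0, 1)")
    if genome.n_genes == 0:
        raise DataError("cannot duplicate an empty genome")
    event_label = f"wgd{sum(1 for e, _ in genome.events if e.startswith('wgd')) + 1}"
    genome.events.append((event_label, event_age))
    new_chroms: dict[str, list[str]] = {}
    for chrom, gene_ids in list(genome.chromosomes.items()):
        dup_name = f"{chrom}.{event_label}"
        dup_genes = []
        for gid in gene_ids:
            if rng.random() < loss_prob:
                continue
            new_id = genome.new_gene_id()
            genome.cds[new_id] = genome.cds[gid]
            genome.truth[new_id] = TruthRecord(
                ancestral_id=genome.truth[gid].ancestral_id,
                event=event_label,
                parent_id=gid,
                event_age_ma=event_age,
            )
            dup_genes.append(new_id)
        if dup_genes:
            new_chroms[dup_name] = dup_genes
    genome.chromosomes.update(new_chroms)
    return genome


def apply_tandem_duplications(
    genome: SimulatedGenome,
    tandem_prob: float,
    age_ma: float,
    rng: np.random.Generator,
) -> SimulatedGenome:
    """Insert a rank-adjacent copy of each gene with probability tandem_prob."""
    if not 0.0 <= tandem_prob < 1.0:
        raise ConfigurationError("tandem_prob must be in [0, 1)")
    for chrom, gene_ids in genome.chromosomes.items():
        out = []
        for gid in gene_ids:
            out.append(gid)
            if rng.random() < tandem_prob:
                new_id = genome.new_gene_id()
                genome.cds[new_id] = genome.cds[gid]
                genome.truth[new_id] = TruthRecord(
                    ancestral_id=genome.truth[gid].ancestral_id,
                    event="tandem",
                    parent_id=gid,
                    event_age_ma=age_ma,
                )
                out.append(new_id)
        genome.chromosomes[chrom] = out
    return genome


def apply_rearrangements(
    genome: SimulatedGenome, n_rearrangements: int, rng: np.random.Generator
) -> SimulatedGenome:
    """Random chromosome fissions (split at a uniform rank) and fusions."""
    counter = 0
    for _ in range(n_rearrangements):
        names = [c for c in genome.chromosomes]
        splittable = [c for c in names if len(genome.chromosomes[c]) >= 2]
        do_fission = (rng.random() < 0.5 and splittable) or len(names) < 2
        counter += 1
        if do_fission:
            if not splittable:
                continue
            chrom = splittable[int(rng.integers(0, len(splittable)))]
            genes = genome.chromosomes.pop(chrom)
            cut = int(rng.integers(1, len(genes)))
            genome.chromosomes[f"{chrom}.f{counter}a"] = genes[:cut]
            genome.chromosomes[f"{chrom}.f{counter}b"] = genes[cut:]
        else:
            i, j = rng.choice(len(names), size=2, replace=False)
            a, b = names[int(i)], names[int(j)]
            merged = genome.chromosomes.pop(a) + genome.chromosomes.pop(b)
            genome.chromosomes[f"fus{counter}"] = merged
    return genome


def copy_lineage(genome: SimulatedGenome, label: str) -> SimulatedGenome:
    """Deep-copy a genome into an independent lineage with relabelled genes.

    Gene and chromosome ids get a lineage prefix (truth ancestral ids are
    preserved) so two sister lineages can be compared without id clashes.
    """
    chroms = {
        f"{label}_{c}": [f"{label}_{g}" for g in genes]
        for c, genes in genome.chromosomes.items()
    }
    cds = {f"{label}_{g}": s for g, s in genome.cds.items()}
    truth = {
        f"{label}_{g}": TruthRecord(
            ancestral_id=t.ancestral_id,
            event=t.event,
            parent_id=None if t.parent_id is None else f"{label}_{t.parent_id}",
            event_age_ma=t.event_age_ma,
        )
        for g, t in genome.truth.items()
    }
    return SimulatedGenome(
        chroms, cds, truth, genome.codon_length, list(genome.events), genome._id_counter
    )


# ---------------------------------------------------------------------------
# sequence evolution
#
# Synonymous divergence is simulated as a continuous-time Markov chain on
# codons whose only moves are single-nucleotide synonymous changes, each at
# unit rate. The rate matrix is symmetric, so the uniform distribution over
# sense codons (the ancestral codon distribution) is stationary and the
# chain is reversible: the expected NG86-measured Ks between two sequences
# separated by total path time s is a closed-form monotone function g(s)
# (computed by eigendecomposition below). Inverting g turns any desired
# pairwise Ks into a branch duration, which makes *every* pair of extant
# copies — sisters and cross-event pairs alike — unbiased at its target,
# something no per-branch distance targeting can achieve because the
# JC-corrected NG86 metric is not additive along branches.


@lru_cache(maxsize=1)
def _syn_ctmc() -> tuple[np.ndarray, np.ndarray, float, np.ndarray]:
    """Eigensystem of the synonymous-change CTMC and NG86 coupling terms.

    Returns (eigenvalues w, coefficients c, E[S] per codon, eigenvectors V)
    such that the expected pathway-averaged synonymous difference count per
    codon column between two ends of a path of duration s is
    ``E_Sd(s) = sum_k c_k exp(w_k s)``.
    """
    nbrs = kaks.synonymous_neighbors()
    _, stops = kaks._genetic_code()
    sense = sorted(set(range(64)) - stops)
    n = len(sense)
    pos = {c: i for i, c in enumerate(sense)}
    Q = np.zeros((n, n))
    for c in sense:
        for nb in nbrs[c]:
            Q[pos[c], pos[nb]] += 1.0
        Q[pos[c], pos[c]] = -len(nbrs[c])
    w, V = np.linalg.eigh(Q)
    sd_table, _ = kaks.difference_tables()
    M = sd_table[np.ix_(sense, sense)]
    # E_Sd(s) = (1/n) tr(P(s) M) = sum_k exp(w_k s) (v_k^T M v_k) / n
    c = np.einsum("ik,ij,jk->k", V, M, V) / n
    s_mean = float(kaks.synonymous_site_table()[sense].mean())
    return w, c, s_mean, V


def expected_pairwise_ks(path_time: float) -> float:
    """Expected NG86 Ks between two sequences separated by ``path_time``."""
    w, c, s_mean, _ = _syn_ctmc()
    e_sd = float(c @ np.exp(w * path_time))
    ps = e_sd / s_mean
    if ps >= 0.75:
        return math.inf
    return kaks.jukes_cantor(ps)


@lru_cache(maxsize=1)
def _ks_to_time_interpolator():
    """Monotone inverse of :func:`expected_pairwise_ks` on a dense grid."""
    times = np.concatenate([[0.0], np.geomspace(1e-4, 20.0, 4000)])
    ks = np.array([expected_pairwise_ks(t) for t in times])
    valid = np.isfinite(ks)
    times, ks = times[valid], ks[valid]
    keep = np.concatenate([[True], np.diff(ks) > 0])
    return ks[keep], times[keep]


def _ks_to_path_time(target_ks: float) -> float:
    ks, times = _ks_to_time_interpolator()
    if target_ks <= 0:
        return 0.0
    if target_ks > ks[-1]:
        raise ConfigurationError(
            f"target Ks {target_ks:.3f} exceeds the saturation limit "
            f"{ks[-1]:.3f} of the synonymous substitution process"
        )
    return float(np.interp(target_ks, ks, times))


def _ctmc_branch(seq: np.ndarray, duration: float, rng: np.random.Generator) -> np.ndarray:
    """Evolve each codon column independently for ``duration`` time units."""
    if duration <= 0:
        return seq.copy()
    nbrs = kaks.synonymous_neighbors()
    out = seq.copy()
    for col in range(out.size):
        t = 0.0
        cur = int(out[col])
        deg = len(nbrs[cur])
        while deg:
            t += rng.exponential(1.0 / deg)
            if t >= duration:
                break
            cur = nbrs[cur][int(rng.integers(0, deg))]
            deg = len(nbrs[cur])
        out[col] = cur
    return out


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal(mean, sd) truncated at zero (rejection sampling)."""
    if sd == 0:
        return max(0.0, mean)
    for _ in range(10000):
        x = rng.normal(mean, sd)
        if x >= 0:
            return x
    raise ConfigurationError("truncated-normal sampling failed: mean too negative")


def evolve_pair_sequences(genome: SimulatedGenome, config: SimulationConfig) -> dict[str, str]:
    """Evolve extant CDS along each locus's duplication tree.

    Each branch carries a half-pairwise Ks budget: the deterministic part is
    ``r * dt`` for a branch spanning ``dt`` years, plus Normal(0,
    ks_sd/sqrt(2)) noise (cumulative budgets never decrease). Budgets are
    converted to CTMC durations through the inverse of
    :func:`expected_pairwise_ks`, so a pair of copies split ``T`` Ma ago
    measures Ks with mean 2rT and dispersion ~ ``ks_sd``. Returns the
    updated gene_id -> CDS mapping (also stored on the genome).
    """
    r = config.subst_rate_r
    for _, age in genome.events:
        if 2.0 * r * age * 1e6 > 2.5:
            raise ConfigurationError(
                f"expected pairwise Ks 2rT = {2 * r * age * 1e6:.2f} exceeds 2.5 "
                "(saturated; outside the usable fit window)"
            )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EC5]))
    # per-branch K-space jitter of sqrt(2)*ks_sd gives sister pairs sd ~ ks_sd
    jitter_sd = config.ks_sd * math.sqrt(2.0)

    children: dict[str, list[tuple[str, float]]] = {}
    for gid, rec in genome.truth.items():
        if rec.parent_id is not None:
            children.setdefault(rec.parent_id, []).append((gid, rec.event_age_ma or 0.0))
    for kids in children.values():
        kids.sort(key=lambda ka: -ka[1])  # oldest split first

    out: dict[str, str] = {}

    def _grow(seq: np.ndarray, age_hi: float, age_lo: float) -> np.ndarray:
        """Branch from a node at age_hi down to age_lo (ultrametric durations).

        A node at event age T sits at time-depth such that every pair split
        there has total path time ginv(2rT); hence this branch's duration is
        (ginv(K_hi_eff) - ginv(K_lo)) / 2 with a K-space jitter on the top.
        """
        if age_hi <= age_lo:
            return seq.copy()
        k_hi = 2.0 * r * age_hi * 1e6
        k_lo = 2.0 * r * age_lo * 1e6
        if jitter_sd > 0:
            k_hi = max(k_lo, k_hi + rng.normal(0.0, jitter_sd))
        duration = (_ks_to_path_time(k_hi) - _ks_to_path_time(k_lo)) / 2.0
        return _ctmc_branch(seq, duration, rng)

    def evolve(seq: np.ndarray, gid: str, age_from: float) -> None:
        cur, t = seq, age_from
        for child_id, age in children.get(gid, ()):
            cur = _grow(cur, t, age)
            t = age
            evolve(cur, child_id, age)
        cur = _grow(cur, t, 0.0)
        out[gid] = _indices_to_cds(cur)

    founders = [gid for gid, rec in genome.truth.items() if rec.parent_id is None]
    for gid in sorted(founders):
        if gid not in genome.cds:
            continue
        seq = kaks.encode_codons(genome.cds[gid])
        kids = children.get(gid)
        if not kids:
            out[gid] = genome.cds[gid]
            continue
        # shared history before the locus's first split does not affect any pair
        evolve(seq, gid, kids[0][1])

    extant = {g for genes in genome.chromosomes.values() for g in genes}
    genome.cds = {g: out.get(g, genome.cds[g]) for g in genome.cds if g in extant or g in out}
    # keep non-extant intermediate parents out of the returned FASTA
    return {g: genome.cds[g] for g in sorted(extant & set(genome.cds))}


def simulate_lineage(config: SimulationConfig) -> SimulatedGenome:
    """Full scenario: ancestor -> WGDs -> rearrangements -> tandems -> sequences."""
    genome = simulate_ancestral_genome(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xA11]))
    for age in config.wgd_times:
        apply_wgd(genome, age, config.loss_prob, rng)
    if config.tandem_prob > 0:
        apply_tandem_duplications(genome, config.tandem_prob, config.tandem_age_ma, rng)
    if config.n_rearrangements > 0:
        apply_rearrangements(genome, config.n_rearrangements, rng)
    if genome.events or config.tandem_prob > 0:
        evolve_pair_sequences(genome, config)
    return genome


# ---------------------------------------------------------------------------
# homology hits (BLAST-tabular stand-in for simulated data)


def homology_hits(genome_a: SimulatedGenome, genome_b: SimulatedGenome | None = None):
    """BLAST-outfmt6-like hits between genes sharing an ancestral locus.

    For simulated lineages homology is known from the truth table, so hits
    are emitted directly instead of running an aligner. Returns a pandas
    DataFrame with the standard 12 columns.
    """
    import pandas as pd

    self_cmp = genome_b is None or genome_b is genome_a
    by_locus_a: dict[str, list[str]] = {}
    for chrom_genes in genome_a.chromosomes.values():
        for g in chrom_genes:
            by_locus_a.setdefault(genome_a.truth[g].ancestral_id, []).append(g)
    rows = []
    length = 3 * genome_a.codon_length
    if self_cmp:
        for locus, genes in by_locus_a.items():
            for i in range(len(genes)):
                for j in range(i + 1, len(genes)):
                    rows.append((genes[i], genes[j]))
    else:
        by_locus_b: dict[str, list[str]] = {}
        for chrom_genes in genome_b.chromosomes.values():
            for g in chrom_genes:
                by_locus_b.setdefault(genome_b.truth[g].ancestral_id, []).append(g)
        for locus, genes_a in by_locus_a.items():
            for ga in genes_a:
                for gb in by_locus_b.get(locus, ()):
                    rows.append((ga, gb))
    return pd.DataFrame(
        {
            "qseqid": [a for a, _ in rows],
            "sseqid": [b for _, b in rows],
            "pident": 95.0,
            "length": length,
            "mismatch": 0,
            "gapopen": 0,
            "qstart": 1,
            "qend": length,
            "sstart": 1,
            "send": length,
            "evalue": 1e-100,
            "bitscore": 500.0,
        }
    )


# ---------------------------------------------------------------------------
# LTR cohort


@dataclass
class LTRCohort:
    """Simulated LTR retroelements: (id, 5' LTR, 3' LTR, true age in Ma)."""

    pairs: list[tuple[str, str, str, float]]


def simulate_ltr_cohort(
    n: int,
    age_distribution: tuple[float, float],
    r: float = LTR_RATE,
    ltr_length: int = 1000,
    seed: int = 0,
) -> LTRCohort:
    """Simulate ``n`` LTR pairs with insertion ages ~ truncated Normal.

    Both copies of each element evolve independently from one ancestral LTR
    under Jukes–Cantor, so the expected pairwise distance is ``2 r T``.
    """
    if n < 0:
        raise ConfigurationError("n must be non-negative")
    if n and ltr_length < 200:
        raise ConfigurationError("ltr_length must be >= 200 bp")
    if r < 0:
        raise ConfigurationError("rate must be non-negative")
    mode, sd = age_distribution
    rng = np.random.default_rng(seed)
    pairs = []
    bases = np.frombuffer(b"ACGT", dtype="S1").astype("U1")
    for i in range(n):
        age = _truncated_normal(rng, mode, sd)
        d = r * age * 1e6  # per-branch JC distance
        p_expected = 0.75 * (1.0 - math.exp(-8.0 * d / 3.0))
        if p_expected >= 0.75 - 1e-12:
            raise ConfigurationError("expected LTR divergence saturates Jukes–Cantor")
        ancestor = rng.integers(0, 4, size=ltr_length)
        copies = []
        for _ in range(2):
            p = 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))
            mask = rng.random(ltr_length) < p
            shift = rng.integers(1, 4, size=ltr_length)
            seq = np.where(mask, (ancestor + shift) % 4, ancestor)
            copies.append("".join(bases[seq]))
        pairs.append((f"ltr{i + 1:05d}", copies[0], copies[1], age))
    return LTRCohort(pairs)


# ---------------------------------------------------------------------------
# reads


def random_genome(length: int, seed: int = 0, n_chromosomes: int = 1) -> dict[str, str]:
    """Random uniform-composition genome sequence(s) for the read simulator."""
    if length < n_chromosomes:
        raise ConfigurationError("genome length must be >= number of chromosomes")
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype="S1").astype("U1")
    sizes = [length // n_chromosomes] * n_chromosomes
    sizes[-1] += length - sum(sizes)
    return {
        f"seq{i + 1}": "".join(bases[rng.integers(0, 4, size=sz)])
        for i, sz in enumerate(sizes)
    }


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def simulate_reads(
    genome: dict[str, str],
    coverage: float,
    read_length: int,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Error-free reads uniformly sampled from both strands.

    Total bases ~ coverage x genome length (to within one read). Returns
    (read_id, sequence) tuples; use :func:`paleodup.io.write_fastq` to
    serialise with uniform top-quality scores.
    """
    if coverage <= 0:
        raise ConfigurationError("coverage must be positive")
    total = sum(len(s) for s in genome.values())
    if read_length > max((len(s) for s in genome.values()), default=0):
        raise DataError("read_length exceeds the longest sequence")
    rng = np.random.default_rng(seed)
    n_reads = int(round(coverage * total / read_length))
    names = [c for c in genome if len(genome[c]) >= read_length]
    weights = np.array([len(genome[c]) - read_length + 1 for c in names], dtype=float)
    weights /= weights.sum()
    chrom_pick = rng.choice(len(names), size=n_reads, p=weights)
    reads = []
    for i in range(n_reads):
        chrom = names[int(chrom_pick[i])]
        seq = genome[chrom]
        pos = int(rng.integers(0, len(seq) - read_length + 1))
        frag = seq[pos : pos + read_length]
        if rng.random() < 0.5:
            frag = frag.translate(_COMPLEMENT)[::-1]
        reads.append((f"read{i + 1:07d}", frag))
    return reads
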