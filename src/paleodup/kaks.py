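"""Pairwise codon alignment and NG86 Ka/Ks estimation.

The estimator is the Nei–Gojobori (1986) counting method: synonymous and
nonsynonymous *sites* are counted per codon as the fraction of the three
possible changes at each position that preserve the amino acid (averaged
over the two codons of a pair), *differences* are counted by averaging over
all minimal substitution pathways between the two codons of a column
(pathways passing through a stop codon are excluded), and the resulting
proportions ps = Sd/S and pn = Nd/N are corrected for multiple hits with
the Jukes–Cantor formula d = -(3/4) ln(1 - 4p/3).

Codon alignment is performed at the protein level (global alignment,
BLOSUM62, affine gaps) and back-translated, so gaps always occupy whole
codons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import standard_dna_table

from .errors import DataError
from .model import SyntenicBlock

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: default Ks window used downstream: drops allelic near-zero pairs (< 0.01)
#: and saturated pairs (> 2.5)
KS_WINDOW = (0.01, 2.5)


def codon_index(codon: str) -> int:
    """Encode an ACGT codon as an integer 0..63 (-1 if ambiguous)."""
    try:
        return (
            16 * _BASE_INDEX[codon[0]]
            + 4 * _BASE_INDEX[codon[1]]
            + _BASE_INDEX[codon[2]]
        )
    except KeyError:
        return -1


def index_codon(idx: int) -> str:
    return BASES[idx >> 4] + BASES[(idx >> 2) & 3] + BASES[idx & 3]


@lru_cache(maxsize=1)
def _genetic_code() -> tuple[list[str], set[int]]:
    """Amino acid per codon index ('*' for stops) and the set of stop indices."""
    aa = []
    stops = set()
    for idx in range(64):
        codon = index_codon(idx)
        if codon in standard_dna_table.stop_codons:
            aa.append("*")
            stops.add(idx)
        else:
            aa.append(standard_dna_table.forward_table[codon])
    return aa, stops


@lru_cache(maxsize=1)
def synonymous_site_table() -> np.ndarray:
    """S(codon): synonymous site count per codon (NaN for stop codons).

    For each of the 3 positions, the fraction of the 3 single-nucleotide
    changes that are synonymous; changes creating a stop codon count as
    nonsynonymous.
    """
    aa, stops = _genetic_code()
    table = np.full(64, np.nan)
    for idx in range(64):
        if idx in stops:
            continue
        s = 0.0
        for pos in range(3):
            shift = (2 - pos) * 2
            for alt in range(4):
                if alt == (idx >> shift) & 3:
                    continue
                alt_idx = (idx & ~(3 << shift)) | (alt << shift)
                if alt_idx not in stops and aa[alt_idx] == aa[idx]:
                    s += 1.0 / 3.0
        table[idx] = s
    return table


def _pathway_counts(c1: int, c2: int) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) difference counts."""
    aa, stops = _genetic_code()
    diff_pos = [p for p in range(3) if ((c1 >> ((2 - p) * 2)) & 3) != ((c2 >> ((2 - p) * 2)) & 3)]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order: tuple[int, ...]) -> tuple[float, float] | None:
        cur, sd, nd = c1, 0.0, 0.0
        for p in order:
            shift = (2 - p) * 2
            nxt = (cur & ~(3 << shift)) | (c2 & (3 << shift))
            if nxt in stops and nxt != c2:
                return None  # pathway through a stop codon: excluded
            if aa[cur] == aa[nxt] and cur not in stops and nxt not in stops:
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        return sd, nd

    results = [r for r in (walk(o) for o in permutations(diff_pos)) if r is not None]
    if not results:
        # all minimal pathways blocked by stops: fall back to averaging over
        # every pathway, counting steps into/out of a stop as nonsynonymous
        results = []
        for order in permutations(diff_pos):
            cur, sd, nd = c1, 0.0, 0.0
            for p in order:
                shift = (2 - p) * 2
                nxt = (cur & ~(3 << shift)) | (c2 & (3 << shift))
                if cur not in stops and nxt not in stops and aa[cur] == aa[nxt]:
                    sd += 1.0
                else:
                    nd += 1.0
                cur = nxt
            results.append((sd, nd))
    sd = sum(r[0] for r in results) / len(results)
    nd = sum(r[1] for r in results) / len(results)
    return sd, nd


@lru_cache(maxsize=1)
def difference_tables() -> tuple[np.ndarray, np.ndarray]:
    """64x64 pathway-averaged synonymous / nonsynonymous difference counts."""
    _, stops = _genetic_code()
    sd = np.zeros((64, 64))
    nd = np.zeros((64, 64))
    for c1 in range(64):
        for c2 in range(64):
            if c1 in stops or c2 in stops:
                sd[c1, c2] = np.nan
                nd[c1, c2] = np.nan
                continue
            sd[c1, c2], nd[c1, c2] = _pathway_counts(c1, c2)
    return sd, nd


@lru_cache(maxsize=1)
def synonymous_neighbors() -> dict[int, list[int]]:
    """Codon index -> list of single-nucleotide synonymous neighbour codons."""
    aa, stops = _genetic_code()
    out: dict[int, list[int]] = {}
    for idx in range(64):
        if idx in stops:
            continue
        nbrs = []
        for pos in range(3):
            shift = (2 - pos) * 2
            for alt in range(4):
                if alt == (idx >> shift) & 3:
                    continue
                alt_idx = (idx & ~(3 << shift)) | (alt << shift)
                if alt_idx not in stops and aa[alt_idx] == aa[idx]:
                    nbrs.append(alt_idx)
        out[idx] = nbrs
    return out


def jukes_cantor(p: float) -> float:
    """JC69 multiple-hit correction d = -(3/4) ln(1 - 4p/3); inf at p >= 3/4."""
    if p >= 0.75:
        return math.inf
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass
class CodonAlignment:
    """A pairwise codon-aware alignment (gaps in whole-codon units)."""

    aligned_a: str
    aligned_b: str
    n_codons_compared: int

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise DataError("aligned sequences differ in length")
        if len(self.aligned_a) % 3:
            raise DataError("alignment length not divisible by 3")


@dataclass
class KsEstimate:
    """NG86 site/difference counts and JC-corrected rates for one pair."""

    S: float
    N: float
    Sd: float
    Nd: float
    ps: float
    pn: float
    ks: float | None
    ka: float | None
    saturated: bool
    n_codons_compared: int


def _translate(cds: str, name: str) -> str:
    if len(cds) % 3:
        raise DataError(f"sequence {name}: length {len(cds)} not divisible by 3")
    aa_map, stops = _genetic_code()
    prot = []
    for i in range(0, len(cds), 3):
        idx = codon_index(cds[i : i + 3].upper())
        if idx < 0:
            prot.append("X")
        elif idx in stops:
            if i + 3 == len(cds):
                break  # trailing stop codon is tolerated and dropped
            raise DataError(f"sequence {name}: internal stop codon at position {i}")
        else:
            prot.append(aa_map[idx])
    return "".join(prot)


def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aligner.mode = "global"
    return aligner


def align_codons(cds_a: str, cds_b: str, name_a: str = "a", name_b: str = "b") -> CodonAlignment:
    """Codon-aware global alignment via protein alignment + back-translation."""
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    prot_a = _translate(cds_a, name_a)
    prot_b = _translate(cds_b, name_b)
    if not prot_a or not prot_b:
        raise DataError("empty protein after translation")
    aln = _protein_aligner().align(prot_a, prot_b)[0]
    pa, pb = str(aln[0]), str(aln[1])
    out_a, out_b = [], []
    i = j = 0
    for ca, cb in zip(pa, pb):
        out_a.append(cds_a[3 * i : 3 * i + 3] if ca != "-" else "---")
        out_b.append(cds_b[3 * j : 3 * j + 3] if cb != "-" else "---")
        i += ca != "-"
        j += cb != "-"
    aligned_a, aligned_b = "".join(out_a), "".join(out_b)
    n = sum(
        1
        for k in range(0, len(aligned_a), 3)
        if "-" not in aligned_a[k : k + 3] + aligned_b[k : k + 3]
    )
    return CodonAlignment(aligned_a, aligned_b, n)


def encode_codons(seq: str) -> np.ndarray:
    """Encode a gapless CDS into an int array of codon indices."""
    return np.array([codon_index(seq[i : i + 3]) for i in range(0, len(seq), 3)], dtype=np.int64)


def ng86_from_indices(a: np.ndarray, b: np.ndarray) -> KsEstimate:
    """NG86 Ka/Ks from two equal-length arrays of codon indices.

    Columns containing ambiguous codons (index -1) are skipped.
    """
    if a.shape != b.shape:
        raise DataError("codon index arrays differ in length")
    mask = (a >= 0) & (b >= 0)
    a, b = a[mask], b[mask]
    n = int(a.size)
    if n == 0:
        raise DataError("no gap-free, unambiguous codon columns to compare")
    s_table = synonymous_site_table()
    sd_table, nd_table = difference_tables()
    S = float((s_table[a].sum() + s_table[b].sum()) / 2.0)
    N = 3.0 * n - S
    Sd = float(sd_table[a, b].sum())
    Nd = float(nd_table[a, b].sum())
    if np.isnan(S) or np.isnan(Sd):
        raise DataError("stop codon encountered in an aligned column")
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    saturated = ps >= 0.75 or pn >= 0.75
    ks = None if ps >= 0.75 else jukes_cantor(ps)
    ka = None if pn >= 0.75 else jukes_cantor(pn)
    return KsEstimate(S, N, Sd, Nd, ps, pn, ks, ka, saturated, n)


def ng86_kaks(alignment: CodonAlignment) -> KsEstimate:
    """NG86 Ka/Ks with Jukes–Cantor correction over gap-free codon columns."""
    if alignment.n_codons_compared < 1:
        raise DataError("alignment has no gap-free codon columns")
    a_cod, b_cod = [], []
    for k in range(0, len(alignment.aligned_a), 3):
        ca = alignment.aligned_a[k : k + 3]
        cb = alignment.aligned_b[k : k + 3]
        if "-" in ca or "-" in cb:
            continue
        a_cod.append(codon_index(ca.upper()))
        b_cod.append(codon_index(cb.upper()))
    return ng86_from_indices(np.array(a_cod, dtype=np.int64), np.array(b_cod, dtype=np.int64))


def kaks_table(blocks: list[SyntenicBlock], cds: dict[str, str]) -> pd.DataFrame:
    """Ka/Ks for every anchor pair of every block.

    Returns a DataFrame with columns gene_a, gene_b, block_id, ka, ks,
    saturated, ordered by (block_id, anchor rank within block).
    """
    rows = []
    for block in blocks:
        for pair in block.anchors:
            for g in (pair.gene_a, pair.gene_b):
                if g not in cds:
                    raise DataError(f"no CDS found for gene {g}")
            aln = align_codons(cds[pair.gene_a], cds[pair.gene_b], pair.gene_a, pair.gene_b)
            est = ng86_kaks(aln)
            rows.append(
                {
                    "gene_a": pair.gene_a,
                    "gene_b": pair.gene_b,
                    "block_id": block.block_id,
                    "ka": np.nan if est.ka is None else est.ka,
                    "ks": np.nan if est.ks is None else est.ks,
                    "saturated": est.saturated,
                }
            )
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "block_id", "ka", "ks", "saturated"])
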