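"""Collinear (syntenic) block detection, duplicate classification and depth.

Blocks are chained MCScanX-style by dynamic programming over anchor gene
ranks: within each chromosome pair, the highest-scoring strictly collinear
chain (both orientations searched, inter-anchor rank gaps bounded by
``max_gap``) is extracted, its anchors removed, and the search repeated
until no chain of at least ``min_anchors`` anchors remains. The chain score
is the number of anchors minus 0.5 per gapped junction, a scoring simple
enough for an exhaustive oracle to verify.

Syntenic depth counts, for every gene of one genome, the number of distinct
blocks whose rank span on that genome covers the gene; the modal depths of
the two genomes give the classical depth ratio (1:4 for an unduplicated
outgroup against a doubly duplicated genome, and so on).
"""

from __future__ import annotations

from collections.abc import Iterable

import numpy as np
import pandas as pd

from .errors import DataError
from .model import AnchorPair, DepthProfile, GeneModel, SyntenicBlock, modal_depth

DEFAULT_MIN_ANCHORS = 5
DEFAULT_MAX_GAP = 25
DEFAULT_TOP_K = 5
GAP_PENALTY = 0.5


def _gene_index(genes: Iterable[GeneModel]) -> dict[str, GeneModel]:
    return {g.gene_id: g for g in genes}


def find_anchors(
    genes_a: list[GeneModel],
    genes_b: list[GeneModel],
    homology_hits: pd.DataFrame,
    top_k: int = DEFAULT_TOP_K,
    min_score: float = 0.0,
) -> list[AnchorPair]:
    """Filter homology hits into anchor pairs.

    Per query gene the ``top_k`` best-scoring partners with score >=
    ``min_score`` are kept; self-hits are removed and the symmetric closure
    is applied (a pair kept from either direction is kept). Hits must use
    the BLAST outfmt-6 column names ``qseqid``, ``sseqid``, ``bitscore``.
    """
    idx_a = _gene_index(genes_a)
    idx_b = _gene_index(genes_b)
    known = set(idx_a) | set(idx_b)
    for col in ("qseqid", "sseqid", "bitscore"):
        if col not in homology_hits.columns:
            raise DataError(f"homology table lacks required column {col!r}")
    best: dict[str, list[tuple[float, str]]] = {}
    for q, s, score in zip(
        homology_hits["qseqid"], homology_hits["sseqid"], homology_hits["bitscore"]
    ):
        if q not in known:
            raise DataError(f"unknown gene id in homology hits: {q!r}")
        if s not in known:
            raise DataError(f"unknown gene id in homology hits: {s!r}")
        if q == s or score < min_score:
            continue
        best.setdefault(q, []).append((float(score), s))
    kept: dict[tuple[str, str], float] = {}
    for q, partners in best.items():
        partners.sort(key=lambda t: (-t[0], t[1]))
        seen = set()
        for score, s in partners:
            if s in seen:
                continue
            seen.add(s)
            if len(seen) > top_k:
                break
            key = (q, s) if q <= s else (s, q)
            kept[key] = max(score, kept.get(key, -np.inf))
    anchors = []
    for (x, y), score in sorted(kept.items()):
        # orient pairs genome-a first where the genomes differ
        if x in idx_a and y in idx_b:
            a, b = x, y
        elif y in idx_a and x in idx_b:
            a, b = y, x
        else:  # both on the same side (self-comparison)
            a, b = x, y
        anchors.append(AnchorPair(a, b, score))
    return anchors


def _chain_dp(
    coords: list[tuple[int, int, int]],
    orientation: int,
    max_gap: int,
) -> tuple[float, list[int]]:
    """Best collinear chain among (rank_a, rank_b, anchor_index) triples.

    ``orientation`` is +1 (rank_b increasing) or -1 (decreasing). Returns
    (score, anchor indices in chain order). Score = chain length minus
    GAP_PENALTY per junction whose rank step exceeds 1 on either genome.
    """
    pts = sorted(coords, key=lambda t: (t[0], orientation * t[1]))
    n = len(pts)
    dp = [1.0] * n
    back = [-1] * n
    for j in range(n):
        ra_j, rb_j, _ = pts[j]
        for i in range(j):
            ra_i, rb_i, _ = pts[i]
            da = ra_j - ra_i
            db = orientation * (rb_j - rb_i)
            if da < 1 or db < 1 or da > max_gap or db > max_gap:
                continue
            step = 1.0 - (GAP_PENALTY if (da > 1 or db > 1) else 0.0)
            if dp[i] + step > dp[j] + 1e-12:
                dp[j] = dp[i] + step
                back[j] = i
    if n == 0:
        return 0.0, []
    end = int(np.argmax(dp))
    chain = []
    k = end
    while k != -1:
        chain.append(pts[k][2])
        k = back[k]
    chain.reverse()
    return dp[end], chain


def chain_blocks(
    anchors: list[AnchorPair],
    genes_a: list[GeneModel],
    genes_b: list[GeneModel],
    min_anchors: int = DEFAULT_MIN_ANCHORS,
    max_gap: int = DEFAULT_MAX_GAP,
) -> list[SyntenicBlock]:
    """Extract maximal-score collinear chains as syntenic blocks.

    Chains are extracted greedily per chromosome pair (best chain first,
    anchors then removed), both orientations searched; chains with fewer
    than ``min_anchors`` anchors are discarded. Each anchor belongs to at
    most one block.
    """
    idx_a = _gene_index(genes_a)
    idx_b = _gene_index(genes_b)
    self_cmp = set(idx_a) == set(idx_b)

    groups: dict[tuple[str, str], list[tuple[int, int, AnchorPair]]] = {}
    for pair in anchors:
        ga = idx_a.get(pair.gene_a)
        gb = idx_b.get(pair.gene_b)
        if ga is None or gb is None:
            # try the flipped orientation before giving up
            ga, gb = idx_a.get(pair.gene_b), idx_b.get(pair.gene_a)
            if ga is None or gb is None:
                raise DataError(f"anchor genes not found: {pair.gene_a}, {pair.gene_b}")
        if self_cmp and (gb.chromosome, gb.rank) < (ga.chromosome, ga.rank):
            ga, gb = gb, ga  # canonical side order within one genome
        groups.setdefault((ga.chromosome, gb.chromosome), []).append((ga.rank, gb.rank, pair))

    blocks: list[SyntenicBlock] = []
    block_id = 0
    for (chrom_a, chrom_b), items in sorted(groups.items()):
        remaining = list(items)
        while True:
            coords = [(ra, rb, i) for i, (ra, rb, _) in enumerate(remaining)]
            best = None
            for orientation in (1, -1):
                score, chain = _chain_dp(coords, orientation, max_gap)
                if chain and (best is None or score > best[0] + 1e-12):
                    best = (score, chain, orientation)
            if best is None or len(best[1]) < min_anchors:
                break
            score, chain, orientation = best
            chain_pairs = [remaining[i][2] for i in chain]
            ranks_a = [remaining[i][0] for i in chain]
            ranks_b = [remaining[i][1] for i in chain]
            block_id += 1
            blocks.append(
                SyntenicBlock(
                    block_id=block_id,
                    anchors=chain_pairs,
                    chrom_a=chrom_a,
                    chrom_b=chrom_b,
                    orientation="same" if orientation == 1 else "inverted",
                    score=score,
                    span_a=(min(ranks_a), max(ranks_a)),
                    span_b=(min(ranks_b), max(ranks_b)),
                )
            )
            used = set(chain)
            remaining = [it for i, it in enumerate(remaining) if i not in used]
    return blocks


def classify_duplications(
    genes: list[GeneModel],
    anchors: list[AnchorPair],
    blocks: list[SyntenicBlock],
    proximal_max: int = 10,
) -> dict[tuple[str, str], str]:
    """Assign each paralog pair one duplication class.

    Precedence: pair inside a block -> ``wgd_segmental``; same chromosome
    and rank-adjacent -> ``tandem``; within ``proximal_max`` ranks ->
    ``proximal``; otherwise ``dispersed``.
    """
    idx = _gene_index(genes)
    in_block = set()
    for block in blocks:
        for pair in block.anchors:
            key = tuple(sorted((pair.gene_a, pair.gene_b)))
            in_block.add(key)
    out: dict[tuple[str, str], str] = {}
    for pair in anchors:
        key = tuple(sorted((pair.gene_a, pair.gene_b)))
        ga, gb = idx.get(pair.gene_a), idx.get(pair.gene_b)
        if ga is None or gb is None:
            raise DataError(f"anchor genes not found: {pair.gene_a}, {pair.gene_b}")
        if key in in_block:
            out[key] = "wgd_segmental"
        elif ga.chromosome == gb.chromosome and abs(ga.rank - gb.rank) == 1:
            out[key] = "tandem"
        elif ga.chromosome == gb.chromosome and abs(ga.rank - gb.rank) <= proximal_max:
            out[key] = "proximal"
        else:
            out[key] = "dispersed"
    return out


def syntenic_depth(
    blocks: list[SyntenicBlock],
    genes_a: list[GeneModel],
    genes_b: list[GeneModel],
    min_cov_anchors: int = DEFAULT_MIN_ANCHORS,
) -> DepthProfile:
    """Per-gene block-coverage depth in both genomes and the modal ratio.

    A gene's depth is the number of distinct blocks (with at least
    ``min_cov_anchors`` anchors) whose rank span on its genome covers its
    rank. ``ratio_label`` is ``"modal_b:modal_a"``: with genome *a* as the
    outgroup this is the conventional outgroup:target ratio. Self-
    comparisons format the two modal depths smallest-first.
    """
    usable = [b for b in blocks if b.n_anchors >= min_cov_anchors]
    depth_a = {g.gene_id: 0 for g in genes_a}
    depth_b = {g.gene_id: 0 for g in genes_b}
    spans_a: dict[str, list[tuple[int, int]]] = {}
    spans_b: dict[str, list[tuple[int, int]]] = {}
    for blk in usable:
        spans_a.setdefault(blk.chrom_a, []).append(blk.span_a)
        spans_b.setdefault(blk.chrom_b, []).append(blk.span_b)
    for g in genes_a:
        depth_a[g.gene_id] = sum(
            lo <= g.rank <= hi for lo, hi in spans_a.get(g.chromosome, ())
        )
    for g in genes_b:
        depth_b[g.gene_id] = sum(
            lo <= g.rank <= hi for lo, hi in spans_b.get(g.chromosome, ())
        )
    self_cmp = {g.gene_id for g in genes_a} == {g.gene_id for g in genes_b}
    if self_cmp:
        # each gene may appear on either side of a block; merge the counts
        merged = {
            gid: depth_a.get(gid, 0) + depth_b.get(gid, 0) for gid in depth_a
        }
        depth_a = depth_b = merged
    modal_a = modal_depth(depth_a)
    modal_b = modal_depth(depth_b)
    if self_cmp:
        lo, hi = sorted((modal_a, modal_b))
        label = f"{lo}:{hi}"
    else:
        label = f"{modal_b}:{modal_a}"
    return DepthProfile(depth_a, depth_b, modal_a, modal_b, label)
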