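"""Anchor filtering, collinear chaining, duplicate classes, syntenic depth."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from paleodup import simcore, synteny
from paleodup.errors import DataError
from paleodup.synteny import GAP_PENALTY

from conftest import make_genes


def hits_frame(rows):
    """rows: (qseqid, sseqid, bitscore) triples -> minimal outfmt-6 frame."""
    return pd.DataFrame(
        [
            dict(qseqid=q, sseqid=s, pident=90.0, length=100, mismatch=0, gapopen=0,
                 qstart=1, qend=100, sstart=1, send=100, evalue=1e-50, bitscore=b)
            for q, s, b in rows
        ]
    )


def brute_force_best_chain(coords, max_gap):
    """Exhaustive chaining oracle: best score over every subset of anchors.

    A subset is a valid chain if, sorted by rank_a, ranks are strictly
    increasing on a, strictly monotone on b, and consecutive steps are
    within max_gap on both genomes. Score = size - GAP_PENALTY per gapped
    junction. Feasible up to ~15 anchors.
    """
    n = len(coords)
    best = 0.0
    for size in range(1, n + 1):
        for subset in combinations(range(n), size):
            pts = sorted((coords[i] for i in subset), key=lambda t: t[0])
            for orient in (1, -1):
                ok = True
                score = float(len(pts))
                for (a1, b1), (a2, b2) in zip(pts, pts[1:]):
                    da, db = a2 - a1, orient * (b2 - b1)
                    if da < 1 or db < 1 or da > max_gap or db > max_gap:
                        ok = False
                        break
                    if da > 1 or db > 1:
                        score -= GAP_PENALTY
                if ok:
                    best = max(best, score)
    return best


class TestFindAnchors:
    def setup_method(self):
        self.genes_a = make_genes({"a1": ["x1", "x2", "x3"]})
        self.genes_b = make_genes({"b1": ["y1", "y2", "y3"]})

    def test_reciprocal_hit_gives_one_anchor(self):
        anchors = synteny.find_anchors(
            self.genes_a, self.genes_b, hits_frame([("x1", "y1", 200.0)])
        )
        assert len(anchors) == 1
        assert (anchors[0].gene_a, anchors[0].gene_b) == ("x1", "y1")

    def test_self_hit_removed(self):
        anchors = synteny.find_anchors(
            self.genes_a, self.genes_a, hits_frame([("x1", "x1", 500.0)])
        )
        assert anchors == []

    def test_top_k_keeps_best_scores(self):
        rows = [("x1", f"y{j}", 100.0 + j) for j in range(1, 4)]
        genes_b = make_genes({"b1": [f"y{j}" for j in range(1, 4)]})
        anchors = synteny.find_anchors(self.genes_a, genes_b, hits_frame(rows), top_k=2)
        partners = {a.gene_b for a in anchors}
        assert partners == {"y2", "y3"}  # the two best-scoring

    def test_min_score_filter(self):
        anchors = synteny.find_anchors(
            self.genes_a, self.genes_b,
            hits_frame([("x1", "y1", 10.0), ("x2", "y2", 90.0)]),
            min_score=50.0,
        )
        assert [(a.gene_a, a.gene_b) for a in anchors] == [("x2", "y2")]

    def test_unknown_gene_id_named_in_error(self):
        with pytest.raises(DataError, match="zz9"):
            synteny.find_anchors(self.genes_a, self.genes_b,
                                 hits_frame([("x1", "zz9", 100.0)]))


class TestChainBlocks:
    def _diagonal(self, n, chrom_a="a1", chrom_b="b1"):
        genes_a = make_genes({chrom_a: [f"p{i}" for i in range(n)]})
        genes_b = make_genes({chrom_b: [f"q{i}" for i in range(n)]})
        anchors = [synteny.AnchorPair(f"p{i}", f"q{i}", 100.0) for i in range(n)]
        return genes_a, genes_b, anchors

    def test_perfect_diagonal_single_block(self):
        genes_a, genes_b, anchors = self._diagonal(6)
        blocks = synteny.chain_blocks(anchors, genes_a, genes_b)
        assert len(blocks) == 1
        assert blocks[0].n_anchors == 6
        assert blocks[0].orientation == "same"
        assert blocks[0].score == pytest.approx(6.0)

    def test_min_anchor_filter(self):
        genes_a, genes_b, anchors = self._diagonal(4)
        assert synteny.chain_blocks(anchors, genes_a, genes_b, min_anchors=5) == []

    def test_inverted_diagonal_detected(self):
        genes_a = make_genes({"a1": [f"p{i}" for i in range(6)]})
        genes_b = make_genes({"b1": [f"q{i}" for i in range(6)]})
        anchors = [synteny.AnchorPair(f"p{i}", f"q{5 - i}", 100.0) for i in range(6)]
        blocks = synteny.chain_blocks(anchors, genes_a, genes_b)
        assert len(blocks) == 1
        assert blocks[0].orientation == "inverted"

    def test_matches_exhaustive_oracle_on_random_instances(self):
        rng = np.random.default_rng(0)
        for trial in range(8):
            n_a, n_b = 18, 18
            genes_a = make_genes({"a1": [f"p{i}" for i in range(n_a)]})
            genes_b = make_genes({"b1": [f"q{i}" for i in range(n_b)]})
            m = 12
            coords = set()
            while len(coords) < m:
                coords.add((int(rng.integers(0, n_a)), int(rng.integers(0, n_b))))
            coords = sorted(coords)
            anchors = [synteny.AnchorPair(f"p{ra}", f"q{rb}", 50.0) for ra, rb in coords]
            blocks = synteny.chain_blocks(anchors, genes_a, genes_b,
                                          min_anchors=1, max_gap=25)
            best_block = max(b.score for b in blocks)
            oracle = brute_force_best_chain(coords, max_gap=25)
            assert best_block == pytest.approx(oracle)

    def test_symmetry_under_genome_swap(self):
        _, a, b = None, *self._sister_pair()
        ga, gb = a.gene_models(), b.gene_models()
        hits = simcore.homology_hits(a, b)
        anchors_ab = synteny.find_anchors(ga, gb, hits)
        blocks_ab = synteny.chain_blocks(anchors_ab, ga, gb)
        hits_rev = hits.rename(columns={"qseqid": "sseqid", "sseqid": "qseqid"})
        anchors_ba = synteny.find_anchors(gb, ga, hits_rev)
        blocks_ba = synteny.chain_blocks(anchors_ba, gb, ga)
        sig_ab = sorted(
            (b_.chrom_a, b_.chrom_b, b_.span_a, b_.span_b, b_.n_anchors) for b_ in blocks_ab
        )
        sig_ba = sorted(
            (b_.chrom_b, b_.chrom_a, b_.span_b, b_.span_a, b_.n_anchors) for b_ in blocks_ba
        )
        assert sig_ab == sig_ba

    @staticmethod
    def _sister_pair():
        cfg = simcore.SimulationConfig(seed=21, n_chromosomes=2, n_genes=120,
                                       codon_length=5)
        anc = simcore.simulate_ancestral_genome(cfg)
        a = simcore.copy_lineage(anc, "A")
        b = simcore.copy_lineage(anc, "B")
        simcore.apply_wgd(b, 60.0, 0.1, np.random.default_rng(5))
        return a, b


class TestClassifyDuplications:
    def test_classes_and_precedence(self):
        genes = make_genes({"c1": [f"g{i}" for i in range(15)], "c2": ["h0", "h1"]})
        anchors = [
            synteny.AnchorPair("g7", "g8", 10.0),    # rank-adjacent: tandem
            synteny.AnchorPair("g0", "g9", 10.0),    # within 10 ranks: proximal
            synteny.AnchorPair("g0", "h0", 10.0),    # different chromosome: dispersed
            synteny.AnchorPair("g1", "g2", 10.0),    # adjacent but inside a block
        ]
        from paleodup.model import SyntenicBlock

        block = SyntenicBlock(1, [anchors[3]], "c1", "c1", "same", 1.0)
        classes = synteny.classify_duplications(genes, anchors, [block])
        assert classes[("g7", "g8")] == "tandem"
        assert classes[("g0", "g9")] == "proximal"
        assert classes[("g0", "h0")] == "dispersed"
        assert classes[("g1", "g2")] == "wgd_segmental"

    def test_every_pair_gets_exactly_one_class(self):
        rng = np.random.default_rng(1)
        genes = make_genes({c: [f"{c}g{i}" for i in range(30)] for c in ("c1", "c2")})
        ids = [g.gene_id for g in genes]
        anchors = []
        seen = set()
        while len(anchors) < 40:
            x, y = rng.choice(len(ids), size=2, replace=False)
            key = tuple(sorted((ids[x], ids[y])))
            if key not in seen:
                seen.add(key)
                anchors.append(synteny.AnchorPair(key[0], key[1], 1.0))
        classes = synteny.classify_duplications(genes, anchors, [])
        assert len(classes) == 40
        assert set(classes.values()) <= {"wgd_segmental", "tandem", "proximal", "dispersed"}


class TestSyntenicDepth:
    def test_identical_genomes_one_to_one(self):
        cfg = simcore.SimulationConfig(seed=13, n_chromosomes=2, n_genes=60, codon_length=5)
        anc = simcore.simulate_ancestral_genome(cfg)
        a = simcore.copy_lineage(anc, "A")
        b = simcore.copy_lineage(anc, "B")
        ga, gb = a.gene_models(), b.gene_models()
        anchors = synteny.find_anchors(ga, gb, simcore.homology_hits(a, b))
        blocks = synteny.chain_blocks(anchors, ga, gb)
        profile = synteny.syntenic_depth(blocks, ga, gb)
        assert profile.ratio_label == "1:1"

    def test_single_wgd_gives_one_to_two(self):
        cfg = simcore.SimulationConfig(seed=17, n_chromosomes=3, n_genes=300, codon_length=5)
        anc = simcore.simulate_ancestral_genome(cfg)
        a = simcore.copy_lineage(anc, "A")
        b = simcore.copy_lineage(anc, "B")
        simcore.apply_wgd(b, 60.0, 0.0, np.random.default_rng(3))
        ga, gb = a.gene_models(), b.gene_models()
        anchors = synteny.find_anchors(ga, gb, simcore.homology_hits(a, b))
        blocks = synteny.chain_blocks(anchors, ga, gb)
        profile = synteny.syntenic_depth(blocks, ga, gb)
        assert profile.ratio_label == "1:2"

    def test_no_blocks_zero_profile(self):
        genes = make_genes({"a1": ["x1", "x2"]})
        genes_b = make_genes({"b1": ["y1", "y2"]})
        profile = synteny.syntenic_depth([], genes, genes_b)
        assert profile.ratio_label == "0:0"

    def test_depth_never_decreases_with_added_wgd(self, sister_lineages):
        anc, a, b2 = sister_lineages
        b1 = simcore.copy_lineage(anc, "B")
        simcore.apply_wgd(b1, 112.1, 0.2, np.random.default_rng(101))

        def modal(a_g, b_g):
            ga, gb = a_g.gene_models(), b_g.gene_models()
            anchors = synteny.find_anchors(ga, gb, simcore.homology_hits(a_g, b_g))
            blocks = synteny.chain_blocks(anchors, ga, gb)
            return synteny.syntenic_depth(blocks, ga, gb).modal_depth_a

        assert modal(a, b2) >= modal(a, b1)
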