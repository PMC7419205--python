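"""Syntenic depth ratio between a two-WGD lineage and its unduplicated sister.

Two lineages descend from one simulated ancestor; lineage B undergoes two
WGDs with 20% duplicate loss. Collinear blocks are chained from homology
anchors and the per-gene block-coverage depth is computed in both
directions. A 1:4 modal ratio is the classical structural signature of two
rounds of genome doubling absent from the sister.
"""

import numpy as np

from paleodup import simcore, synteny

config = simcore.SimulationConfig(seed=11, n_chromosomes=5, n_genes=1000)
ancestor = simcore.simulate_ancestral_genome(config)
sister = simcore.copy_lineage(ancestor, "A")
doubled = simcore.copy_lineage(ancestor, "B")
rng = np.random.default_rng(101)
simcore.apply_wgd(doubled, 112.1, 0.2, rng)
simcore.apply_wgd(doubled, 77.8, 0.2, rng)

genes_a, genes_b = sister.gene_models(), doubled.gene_models()
hits = simcore.homology_hits(sister, doubled)
anchors = synteny.find_anchors(genes_a, genes_b, hits)
blocks = synteny.chain_blocks(anchors, genes_a, genes_b, min_anchors=5, max_gap=25)
profile = synteny.syntenic_depth(blocks, genes_a, genes_b)

print(f"anchors:           {len(anchors)}")
print(f"syntenic blocks:   {len(blocks)}")
print(f"depth ratio (A:B): {profile.ratio_label}")
# "1:4" = each sister-genome region is covered by 4 syntenic regions of the
# doubled genome, while each doubled-genome region maps to 1 sister region.
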