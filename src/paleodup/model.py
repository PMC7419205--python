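"""Core genomic data model shared across modules.

Coordinates are stored 0-based half-open throughout the package; GFF3
input/output converts at the boundary. Synteny works on gene *ranks*
(ordinal position along a chromosome), which must be consecutive integers
starting at 0 on every chromosome.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .errors import DataError


@dataclass(frozen=True)
class GeneModel:
    """One gene: the atom of synteny.

    Parameters
    ----------
    gene_id : unique identifier.
    chromosome : chromosome / scaffold name.
    rank : 0-based ordinal position along the chromosome.
    start, end : 0-based half-open bp coordinates, ``start < end``.
    strand : ``"+"`` or ``"-"``.
    """

    gene_id: str
    chromosome: str
    rank: int
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise DataError(
                f"gene {self.gene_id}: start ({self.start}) must be < end ({self.end})"
            )
        if self.strand not in ("+", "-"):
            raise DataError(f"gene {self.gene_id}: strand must be '+' or '-'")


def check_ranks(genes: list[GeneModel]) -> None:
    """Validate that ranks are consecutive 0..n-1 per chromosome."""
    by_chrom: dict[str, list[int]] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g.rank)
    for chrom, ranks in by_chrom.items():
        if sorted(ranks) != list(range(len(ranks))):
            raise DataError(f"chromosome {chrom}: gene ranks are not consecutive from 0")


@dataclass(frozen=True)
class AnchorPair:
    """A homologous gene pair usable as a collinearity anchor."""

    gene_a: str
    gene_b: str
    score: float

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise DataError(f"anchor pair cannot be a self-hit: {self.gene_a}")


@dataclass
class SyntenicBlock:
    """An ordered chain of anchor pairs collinear on two chromosomes.

    ``anchors`` are ordered by increasing rank on chromosome *a*; ranks on
    chromosome *b* increase for ``orientation == "same"`` and decrease for
    ``"inverted"``. ``median_ks`` is filled by the peaks module.
    """

    block_id: int
    anchors: list[AnchorPair]
    chrom_a: str
    chrom_b: str
    orientation: str  # "same" | "inverted"
    score: float
    span_a: tuple[int, int] = (0, 0)  # inclusive rank span on chromosome a
    span_b: tuple[int, int] = (0, 0)
    median_ks: float | None = None

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)


@dataclass
class DepthProfile:
    """Syntenic depth of each genome relative to the other.

    ``depth_a[gene_id]`` counts the distinct blocks whose rank span on
    genome *a* covers that gene; likewise ``depth_b``. Modal depths are
    taken over genes with depth >= 1. ``ratio_label`` is formatted
    ``"modal_b:modal_a"`` — with genome *a* as the outgroup/reference this
    reproduces the conventional outgroup:target ratio (e.g. ``"1:4"``).
    """

    depth_a: dict[str, int]
    depth_b: dict[str, int]
    modal_depth_a: int
    modal_depth_b: int
    ratio_label: str


def modal_depth(depths: dict[str, int]) -> int:
    """Most common depth among genes covered at least once (0 if none)."""
    covered = [d for d in depths.values() if d >= 1]
    if not covered:
        return 0
    counts = Counter(covered)
    top = max(counts.values())
    # deterministic tie-break: smallest depth among the most common
    return min(d for d, c in counts.items() if c == top)
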