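"""K-mer based genome-size estimation (genome survey).

Canonical k-mers (the lexicographic minimum of a k-mer and its reverse
complement) are counted over the reads; the multiplicity histogram shows an
error region at low depth and a coverage peak at roughly
``coverage * (L - k + 1) / L``. Genome size is estimated as the number of
k-mer occurrences above the error cutoff divided by the peak depth.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, DataError

_BASE_CODE = np.full(256, -1, dtype=np.int8)
for i, b in enumerate("ACGT"):
    _BASE_CODE[ord(b)] = i
    _BASE_CODE[ord(b.lower())] = i


@dataclass
class KmerHistogram:
    """Histogram of k-mer multiplicities: depth -> number of distinct k-mers."""

    k: int
    counts: dict[int, int]

    @property
    def total_kmers(self) -> int:
        """Total counted k-mer occurrences (sum of depth x count)."""
        return sum(d * c for d, c in self.counts.items())


@dataclass
class KmerSurveyResult:
    """Genome-size estimate from a k-mer histogram.

    ``peak_depth`` is the integer count mode above the error cutoff;
    ``refined_peak_depth`` interpolates a parabola through the mode and its
    neighbours to remove the integer quantisation of the coverage peak and
    is what the size estimate divides by.
    """

    peak_depth: int
    refined_peak_depth: float
    genome_size_bp: float
    error_cutoff: int
    used_kmer_occurrences: int


def _kmer_codes(seq: str, k: int) -> np.ndarray:
    """Canonical k-mer codes of one read (k-mers with non-ACGT skipped)."""
    codes = _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    window = np.lib.stride_tricks.sliding_window_view(codes, k).astype(np.int64)
    valid = (window >= 0).all(axis=1)
    window = window[valid]
    if window.size == 0:
        return np.empty(0, dtype=np.int64)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    fwd = window @ powers
    rev = (3 - window[:, ::-1]) @ powers
    return np.minimum(fwd, rev)


def _iter_reads(source) -> "list[str]":
    """Sequences from a FASTA/FASTQ path, a dict, or an iterable of strings."""
    if isinstance(source, dict):
        return list(source.values())
    if isinstance(source, (str, Path)):
        from Bio import SeqIO

        path = Path(source)
        with open(path) as handle:
            first = handle.read(1)
        fmt = "fastq" if first == "@" else "fasta"
        return [str(rec.seq) for rec in SeqIO.parse(str(path), fmt)]
    out = []
    for item in source:
        out.append(item[1] if isinstance(item, tuple) else str(item))
    return out


def count_kmers(reads, k: int = 17) -> KmerHistogram:
    """Count canonical k-mers over reads and histogram their multiplicities.

    ``reads`` may be a FASTA/FASTQ path, a dict of sequences, or an
    iterable of sequences / (id, sequence) tuples. k must be odd (so no
    k-mer equals its own reverse complement) and between 11 and 31.
    """
    if k % 2 == 0 or not 11 <= k <= 31:
        raise ConfigurationError("k must be odd and between 11 and 31")
    seqs = _iter_reads(reads)
    if not seqs:
        raise DataError("no reads provided")
    chunks = [_kmer_codes(s, k) for s in seqs]
    codes = np.concatenate([c for c in chunks if c.size] or [np.empty(0, dtype=np.int64)])
    if codes.size == 0:
        raise DataError("no valid k-mers in the input reads")
    _, multiplicities = np.unique(codes, return_counts=True)
    depths, n_kmers = np.unique(multiplicities, return_counts=True)
    return KmerHistogram(k, {int(d): int(c) for d, c in zip(depths, n_kmers)})


def estimate_genome_size(hist: KmerHistogram) -> KmerSurveyResult:
    """Genome size = k-mer occurrences above the error cutoff / peak depth.

    The error cutoff is the first local minimum of the count-vs-depth curve
    (the trough between the low-depth error spike and the coverage peak);
    the peak depth is the count argmax above the cutoff. A histogram that
    only decreases has no coverage peak and raises a DataError.
    """
    if not hist.counts:
        raise DataError("empty k-mer histogram")
    max_depth = max(hist.counts)
    dense = np.zeros(max_depth + 2, dtype=np.int64)
    for d, c in hist.counts.items():
        if d < 1:
            raise DataError("k-mer depths must be >= 1")
        dense[d] = c
    # first strict rise marks the end of the error region
    cutoff = 0
    for d in range(1, max_depth):
        if dense[d + 1] > dense[d]:
            cutoff = d
            break
    else:
        raise DataError("no peak: k-mer histogram is monotone decreasing")
    region = dense[cutoff + 1 : max_depth + 1]
    peak_depth = cutoff + 1 + int(np.argmax(region))
    if peak_depth <= cutoff or dense[peak_depth] == 0:
        raise DataError("no peak above the error cutoff")
    # refine the peak by a least-squares parabola over a window around the
    # mode: single-bin counts are noisy, the underlying coverage curve is not
    refined = float(peak_depth)
    w = max(2, peak_depth // 6)
    lo_d = max(cutoff + 1, peak_depth - w)
    hi_d = min(max_depth, peak_depth + w)
    if hi_d - lo_d >= 2:
        ds = np.arange(lo_d, hi_d + 1, dtype=float)
        ys = dense[lo_d : hi_d + 1].astype(float)
        a, b, _ = np.polyfit(ds, ys, 2)
        if a < 0:
            vertex = -b / (2 * a)
            if lo_d <= vertex <= hi_d:
                refined = float(vertex)
    used = int(sum(d * c for d, c in hist.counts.items() if d > cutoff))
    return KmerSurveyResult(peak_depth, refined, used / refined, cutoff, used)
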