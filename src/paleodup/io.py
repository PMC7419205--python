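"""Standard-format readers and writers.

Internal coordinates are 0-based half-open everywhere. GFF3 is read and
written 1-based inclusive (conversion at the boundary); BED is taken as
0-based half-open verbatim. Gene ranks are assigned by start position per
chromosome when loading positions from either format.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import DataError
from .model import GeneModel

BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


# --- FASTA / FASTQ ---------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA -> ordered dict of id -> sequence."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise DataError(f"{path}: duplicate sequence id {rec.id!r}")
        out[rec.id] = str(rec.seq)
    if not out:
        raise DataError(f"{path}: no FASTA records")
    return out


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def write_fastq(reads: list[tuple[str, str]], path: str | Path) -> None:
    """Write (id, sequence) reads with uniform top quality."""
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


# --- gene positions --------------------------------------------------------


def _assign_ranks(raw: list[tuple[str, str, int, int, str]]) -> list[GeneModel]:
    """(id, chrom, start0, end0, strand) -> GeneModel list with per-chromosome ranks."""
    by_chrom: dict[str, list[tuple[int, int, str, str]]] = {}
    for gid, chrom, start, end, strand in raw:
        by_chrom.setdefault(chrom, []).append((start, end, gid, strand))
    genes = []
    for chrom in by_chrom:
        for rank, (start, end, gid, strand) in enumerate(sorted(by_chrom[chrom])):
            genes.append(GeneModel(gid, chrom, rank, start, end, strand))
    return genes


def read_gff3(path: str | Path, feature_type: str = "gene") -> list[GeneModel]:
    """Gene features from GFF3 (1-based inclusive -> 0-based half-open)."""
    raw = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise DataError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(fields)}")
            chrom, _, ftype, start, end, _, strand, _, attrs = fields
            if ftype != feature_type:
                continue
            gid = None
            for item in attrs.split(";"):
                if item.startswith("ID="):
                    gid = item[3:].strip()
            if gid is None:
                raise DataError(f"{path}:{lineno}: {feature_type} feature without ID attribute")
            try:
                s, e = int(start), int(end)
            except ValueError as exc:
                raise DataError(f"{path}:{lineno}: non-integer coordinates") from exc
            raw.append((gid, chrom, s - 1, e, strand if strand in "+-" else "+"))
    if not raw:
        raise DataError(f"{path}: no {feature_type!r} features found")
    return _assign_ranks(raw)


def write_gff3(genes: list[GeneModel], path: str | Path, source: str = "paleodup") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chromosome, g.start)):
            fh.write(
                f"{g.chromosome}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


def read_bed(path: str | Path) -> list[GeneModel]:
    """4-column BED (0-based half-open) -> GeneModel list."""
    raw = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise DataError(f"{path}:{lineno}: BED needs at least 4 columns")
            chrom, start, end, name = fields[:4]
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "+"
            try:
                raw.append((name, chrom, int(start), int(end), strand))
            except ValueError as exc:
                raise DataError(f"{path}:{lineno}: non-integer coordinates") from exc
    if not raw:
        raise DataError(f"{path}: no BED records")
    return _assign_ranks(raw)


def write_bed(genes: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chromosome, g.start)):
            fh.write(f"{g.chromosome}\t{g.start}\t{g.end}\t{g.gene_id}\n")


# --- homology and reports --------------------------------------------------


def read_blast_tab(path: str | Path) -> pd.DataFrame:
    """12-column BLAST outfmt-6 TSV."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except Exception as exc:
        raise DataError(f"{path}: cannot parse BLAST tabular file: {exc}") from exc
    if df.shape[1] < 12:
        raise DataError(f"{path}: expected 12 BLAST outfmt-6 columns, got {df.shape[1]}")
    df = df.iloc[:, :12]
    df.columns = BLAST6_COLUMNS
    return df


def write_blast_tab(hits: pd.DataFrame, path: str | Path) -> None:
    hits.to_csv(path, sep="\t", header=False, index=False)


def provenance_header(seed: int | None, config_digest: str | None = None) -> str:
    from . import __version__

    parts = [f"# paleodup v{__version__}"]
    if config_digest:
        parts.append(f"config={config_digest}")
    if seed is not None:
        parts.append(f"seed={seed}")
    return " ".join(parts)


def config_digest(config: dict) -> str:
    return hashlib.sha1(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:12]


def write_tsv(df: pd.DataFrame, path: str | Path, seed: int | None = None,
              digest: str | None = None) -> None:
    """TSV with a one-line provenance header comment."""
    with open(path, "w") as fh:
        fh.write(provenance_header(seed, digest) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_json_report(obj: dict, path: str | Path, seed: int | None = None,
                      digest: str | None = None) -> None:
    from . import __version__

    payload = {"_provenance": {"tool": f"paleodup v{__version__}", "seed": seed,
                               "config": digest}}
    payload.update(obj)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_blocks_tsv(blocks, path: str | Path, seed: int | None = None,
                     digest: str | None = None) -> None:
    rows = [
        {
            "block_id": b.block_id,
            "chrom_a": b.chrom_a,
            "chrom_b": b.chrom_b,
            "orientation": b.orientation,
            "n_anchors": b.n_anchors,
            "score": b.score,
            "median_ks": "" if b.median_ks is None else b.median_ks,
            "anchors": ",".join(f"{p.gene_a}|{p.gene_b}" for p in b.anchors),
        }
        for b in blocks
    ]
    write_tsv(pd.DataFrame(rows), path, seed, digest)


def write_collinearity(blocks, path: str | Path) -> None:
    """MCScanX-like `.collinearity` text report."""
    with open(path, "w") as fh:
        fh.write("############### Paleodup collinearity ###############\n")
        for b in blocks:
            plus = "plus" if b.orientation == "same" else "minus"
            fh.write(
                f"## Alignment {b.block_id}: score={b.score:.1f} "
                f"N={b.n_anchors} {b.chrom_a}&{b.chrom_b} {plus}\n"
            )
            for i, p in enumerate(b.anchors):
                fh.write(f"{b.block_id}-{i:3d}:\t{p.gene_a}\t{p.gene_b}\n")
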