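"""File input/output: FASTA, FASTQ, taxonomy tables, TSV reports.

FASTA goes through Biopython, FASTQ through pysam's FastxFile (both
handle gzip transparently). Tabular outputs are plain TSV so they diff
and version cleanly.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator

import pysam
from Bio import SeqIO

from .errors import FormatError
from .holodb import TaxonLineage
from .reads import ReadRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "read_taxonomy",
    "write_tsv",
]


def _maybe_gzip_handle(path: str | Path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """(contig_id, sequence) pairs from a plain or gzipped FASTA."""
    with _maybe_gzip_handle(path) as fh:
        records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(fh, "fasta")]
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    return records


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    path = str(path)
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "wt") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Stream ReadRecords from a plain or gzipped FASTQ."""
    try:
        with pysam.FastxFile(str(path)) as fh:
            for entry in fh:
                if entry.quality is None:
                    raise FormatError(
                        f"{path}: record {entry.name!r} has no quality string"
                    )
                yield ReadRecord(entry.name, entry.sequence, entry.quality)
    except OSError as exc:
        raise FormatError(f"{path}: unreadable FASTQ ({exc})")


def read_taxonomy(path: str | Path) -> dict[str, TaxonLineage]:
    """TSV `genome_id<TAB>kingdom;phylum;...;species` -> lineages."""
    lineages: dict[str, TaxonLineage] = {}
    with _maybe_gzip_handle(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(
                    f"{path}: line {lineno}: expected 2 tab-separated "
                    f"columns, got {len(fields)}"
                )
            gid, lineage = fields
            lineages[gid] = TaxonLineage.from_string(lineage)
    if not lineages:
        raise FormatError(f"{path}: empty taxonomy table")
    return lineages


def write_tsv(
    path: str | Path,
    header: list[str],
    rows: Iterable[Iterable],
    comments: list[str] | None = None,
) -> None:
    with open(path, "wt") as fh:
        for comment in comments or []:
            fh.write(f"# {comment}\n")
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")
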