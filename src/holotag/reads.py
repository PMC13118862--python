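"""FASTQ read quality filtering and enzyme-tag extraction.

The filter applies three whole-read rules, in fixed order for drop
attribution: (a) any ambiguous base call (N); (b) a homopolymer run
strictly exceeding ``max_homopolymer`` bases; (c) strictly more than
``max_low_frac`` of bases below the phred threshold ``low_q``.
Reads are never trimmed -- a read either survives intact or is dropped.

Tag extraction takes, per read, the leftmost recognition match (either
strand) whose full tag window fits inside the read, and emits the
window's canonical sequence. One tag per read: the physical type IIB
insert is a single excised fragment.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

from .enzyme import EnzymeSpec, _pattern_regex
from .errors import FormatError
from .sequence import canonical, revcomp

__all__ = [
    "ReadRecord",
    "DropReport",
    "TagObservations",
    "quality_filter",
    "extract_read_tags",
]

PHRED_OFFSET = 33


class ReadRecord(NamedTuple):
    read_id: str
    sequence: str
    quality: str  # phred+33


@dataclass
class DropReport:
    """Per-rule drop counts (first matching rule attributed)."""

    n_base: int = 0
    homopolymer: int = 0
    low_quality: int = 0

    @property
    def total(self) -> int:
        return self.n_base + self.homopolymer + self.low_quality


_HOMOPOLYMER_CACHE: dict[int, re.Pattern] = {}


def _homopolymer_regex(max_run: int) -> re.Pattern:
    pat = _HOMOPOLYMER_CACHE.get(max_run)
    if pat is None:
        k = max_run + 1
        pat = re.compile("|".join(f"{b}{{{k}}}" for b in "ACGTN"))
        _HOMOPOLYMER_CACHE[max_run] = pat
    return pat


def read_passes(
    read: ReadRecord,
    low_q: int = 10,
    max_low_frac: float = 0.20,
    max_homopolymer: int = 10,
) -> str | None:
    """Return None if the read passes, else the name of the first
    failed rule ('n_base' | 'homopolymer' | 'low_quality')."""
    seq = read.sequence.upper()
    if len(seq) != len(read.quality) or not seq:
        raise FormatError(
            f"read {read.read_id!r}: sequence/quality length mismatch "
            f"({len(seq)} vs {len(read.quality)})"
        )
    if "N" in seq:
        return "n_base"
    if _homopolymer_regex(max_homopolymer).search(seq):
        return "homopolymer"
    cutoff = chr(PHRED_OFFSET + low_q)
    n_low = sum(1 for q in read.quality if q < cutoff)
    if n_low > max_low_frac * len(seq):
        return "low_quality"
    return None


def quality_filter(
    reads: Iterable[ReadRecord],
    low_q: int = 10,
    max_low_frac: float = 0.20,
    max_homopolymer: int = 10,
) -> tuple[list[ReadRecord], DropReport]:
    """Apply the three drop rules; pure per-read predicate."""
    kept: list[ReadRecord] = []
    report = DropReport()
    for read in reads:
        rule = read_passes(read, low_q, max_low_frac, max_homopolymer)
        if rule is None:
            kept.append(read)
        elif rule == "n_base":
            report.n_base += 1
        elif rule == "homopolymer":
            report.homopolymer += 1
        else:
            report.low_quality += 1
    return kept, report


@dataclass
class TagObservations:
    """Canonical-tag counts observed in one sample."""

    counts: Counter = field(default_factory=Counter)
    n_reads_with_site: int = 0
    n_reads_without_site: int = 0
    enzyme: EnzymeSpec | None = None

    @property
    def total(self) -> int:
        return self.n_reads_with_site + self.n_reads_without_site


def first_tag_in_read(seq: str, enzyme: EnzymeSpec) -> str | None:
    """Canonical tag of the leftmost full-window recognition match in
    *seq*, or None. Matches on either strand; windows containing N are
    passed over (a later clean match may still qualify)."""
    seq = seq.upper()
    fwd = _pattern_regex(enzyme.recognition)
    rc_rec = revcomp(enzyme.recognition)
    rev = _pattern_regex(rc_rec) if rc_rec != enzyme.recognition else None
    n = len(seq)
    hits = [m.start() for m in fwd.finditer(seq)]
    strands = ["+"] * len(hits)
    if rev is not None:
        for m in rev.finditer(seq):
            hits.append(m.start())
            strands.append("-")
    for pos, strand in sorted(zip(hits, strands)):
        if strand == "+":
            start = pos - enzyme.left_flank
        else:
            start = pos - enzyme.right_flank
        end = start + enzyme.tag_length
        if start < 0 or end > n:
            continue
        window = seq[start:end]
        if "N" in window:
            continue
        tag = window if strand == "+" else revcomp(window)
        return canonical(tag)
    return None


def extract_read_tags(
    reads: Iterable[ReadRecord],
    enzyme: EnzymeSpec,
    *,
    keep_ids: bool = False,
) -> TagObservations | tuple[TagObservations, list[tuple[str, str]]]:
    """One canonical tag observation per read (leftmost valid window)."""
    obs = TagObservations(enzyme=enzyme)
    pairs: list[tuple[str, str]] = []
    for read in reads:
        tag = first_tag_in_read(read.sequence, enzyme)
        if tag is None:
            obs.n_reads_without_site += 1
        else:
            obs.counts[tag] += 1
            obs.n_reads_with_site += 1
            if keep_ids:
                pairs.append((read.read_id, tag))
    if keep_ids:
        return obs, pairs
    return obs
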