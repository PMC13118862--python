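"""In silico type IIB restriction digestion.

A type IIB enzyme (BcgI being the canonical example) cuts on both sides
of its bipartite recognition site and excises a uniform-length fragment.
We model the resulting sequencing unit as a fixed-geometry *tag*:
``left_flank`` bases, the recognition site, ``right_flank`` bases.
Digestion scans both strands of a contig for the (possibly degenerate)
recognition pattern and slices the corresponding tag windows.

Tags are keyed everywhere by their *canonical* sequence -- the
lexicographic minimum of the tag and its reverse complement -- because
the sequencer observes tags in unknown orientation.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import InputError
from .sequence import IUPAC_CODES, canonical, revcomp, validate_sequence

__all__ = [
    "EnzymeSpec",
    "BCGI",
    "TagOccurrence",
    "SkipReport",
    "DigestSummary",
    "find_sites",
    "extract_tags",
    "digest_genome",
]


@dataclass(frozen=True)
class EnzymeSpec:
    """Geometry of a type IIB recognition site and its flanks.

    Parameters
    ----------
    name : str
        Enzyme name (metadata only).
    recognition : str
        IUPAC pattern of the recognition site, e.g. ``CGANNNNNNTGC``
        for BcgI.
    left_flank, right_flank : int
        Number of bases excised on each side of the recognition site,
        in the site's own orientation.
    """

    name: str
    recognition: str
    left_flank: int
    right_flank: int

    def __post_init__(self) -> None:
        rec = self.recognition.upper()
        if not rec:
            raise InputError("empty recognition pattern")
        bad = set(rec) - set(IUPAC_CODES)
        if bad:
            raise InputError(
                f"recognition pattern contains non-IUPAC codes: {sorted(bad)}"
            )
        object.__setattr__(self, "recognition", rec)
        if self.left_flank < 0 or self.right_flank < 0:
            raise InputError("flank lengths must be non-negative")
        if self.tag_length <= 0:
            raise InputError("tag length must be positive")

    @property
    def recognition_length(self) -> int:
        return len(self.recognition)

    @property
    def tag_length(self) -> int:
        return self.left_flank + len(self.recognition) + self.right_flank

    def __str__(self) -> str:  # used in DB metadata
        return (
            f"{self.name}:{self.recognition}"
            f":{self.left_flank}:{self.right_flank}"
        )


#: BcgI: CGA(N6)TGC recognition, 10-nt flanks -> 32-nt tags (the 2-nt
#: terminal overhangs of the physical fragment are not modeled).
BCGI = EnzymeSpec("BcgI", "CGANNNNNNTGC", 10, 10)


@dataclass(frozen=True)
class TagOccurrence:
    """One digested tag with plus-strand genome coordinates."""

    genome_id: str
    contig_id: str
    window_start: int  # 0-based plus-strand start of the tag window
    strand: str  # "+" or "-"
    sequence: str  # in found orientation
    canonical: str


@dataclass
class SkipReport:
    """Counts of sites whose tag window could not be extracted."""

    flank: int = 0  # window extends past the contig
    ambiguous_base: int = 0  # non-ACGT base inside the window

    @property
    def total(self) -> int:
        return self.flank + self.ambiguous_base


@dataclass
class DigestSummary:
    """Per-genome digestion result: canonical tag -> occurrence count."""

    genome_id: str
    counts: Counter = field(default_factory=Counter)
    skips: SkipReport = field(default_factory=SkipReport)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def no_site(self) -> bool:
        return self.total == 0


def _pattern_regex(pattern: str) -> re.Pattern:
    """Compile an IUPAC pattern into an overlapping-match regex.

    Fully degenerate positions (N) accept any of ACGTN; constrained
    positions accept only their concrete expansion, so a sequence N can
    never satisfy them.
    """
    parts = []
    for code in pattern:
        if code == "N":
            parts.append("[ACGTN]")
        else:
            bases = "".join(sorted(IUPAC_CODES[code]))
            parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return re.compile("(?=" + "".join(parts) + ")")


def find_sites(seq: str, enzyme: EnzymeSpec) -> list[tuple[int, str]]:
    """Locate all recognition-site matches on both strands.

    Returns ``(recognition_start, strand)`` pairs sorted by position;
    ``recognition_start`` is the 0-based plus-strand offset of the
    site's leftmost base regardless of strand. Overlapping matches are
    all reported.
    """
    seq = validate_sequence(seq)
    fwd = _pattern_regex(enzyme.recognition)
    rc_pattern = revcomp(enzyme.recognition)
    hits = [(m.start(), "+") for m in fwd.finditer(seq)]
    if rc_pattern != enzyme.recognition:
        rev = _pattern_regex(rc_pattern)
        hits.extend((m.start(), "-") for m in rev.finditer(seq))
    else:
        hits.extend((pos, "-") for pos, _ in list(hits))
    hits.sort()
    return hits


def _window_bounds(pos: int, strand: str, enzyme: EnzymeSpec) -> tuple[int, int]:
    """Plus-strand [start, end) of the tag window for a site at *pos*."""
    if strand == "+":
        start = pos - enzyme.left_flank
    else:
        # On the minus strand the left flank extends to the right in
        # plus coordinates.
        start = pos - enzyme.right_flank
    return start, start + enzyme.tag_length


def extract_tags(
    contig_id: str,
    seq: str,
    enzyme: EnzymeSpec,
    *,
    genome_id: str = "",
    skips: SkipReport | None = None,
) -> list[TagOccurrence]:
    """Excise one tag per recognition site with a fully valid window.

    Sites whose window runs off the contig or contains a non-ACGT base
    are skipped and tallied in *skips* by reason.
    """
    seq = validate_sequence(seq, context=f"contig {contig_id}")
    if skips is None:
        skips = SkipReport()
    out: list[TagOccurrence] = []
    n = len(seq)
    for pos, strand in find_sites(seq, enzyme):
        start, end = _window_bounds(pos, strand, enzyme)
        if start < 0 or end > n:
            skips.flank += 1
            continue
        window = seq[start:end]
        if "N" in window:
            skips.ambiguous_base += 1
            continue
        tag = window if strand == "+" else revcomp(window)
        out.append(
            TagOccurrence(
                genome_id=genome_id,
                contig_id=contig_id,
                window_start=start,
                strand=strand,
                sequence=tag,
                canonical=canonical(tag),
            )
        )
    return out


def digest_genome(
    records: Sequence[tuple[str, str]] | Iterable[tuple[str, str]],
    genome_id: str,
    enzyme: EnzymeSpec = BCGI,
) -> DigestSummary:
    """Digest every contig of a genome and aggregate canonical-tag counts.

    A genome yielding zero valid tags is flagged ``no_site`` for
    downstream exclusion.
    """
    records = list(records)
    if not records:
        raise InputError(f"genome {genome_id!r}: empty record list")
    summary = DigestSummary(genome_id=genome_id)
    for contig_id, seq in records:
        for occ in extract_tags(
            contig_id, seq, enzyme, genome_id=genome_id, skips=summary.skips
        ):
            summary.counts[occ.canonical] += 1
    return summary
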