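"""Nucleotide string utilities shared across the package.

All sequences are handled as uppercase ACGTN strings; coordinates are
0-based, half-open, on the plus strand.
"""

from __future__ import annotations

from .errors import InputError

# IUPAC nucleotide codes -> set of concrete bases they stand for.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")

VALID_SEQ_CHARS = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(seq: str) -> str:
    """Orientation-free key: the lexicographic minimum of seq and its
    reverse complement."""
    rc = revcomp(seq)
    return seq if seq <= rc else rc


def validate_sequence(seq: str, *, context: str = "sequence") -> str:
    """Uppercase *seq* and reject characters outside A/C/G/T/N.

    Returns the normalized sequence; raises :class:`InputError` naming
    the offending symbol and its 0-based position.
    """
    up = seq.upper()
    if not set(up) <= VALID_SEQ_CHARS:
        for i, ch in enumerate(up):
            if ch not in VALID_SEQ_CHARS:
                raise InputError(
                    f"invalid character {ch!r} at position {i} in {context}"
                )
    return up


def iupac_matches(pattern_code: str, base: str) -> bool:
    """Does a single IUPAC *pattern_code* accept *base*?

    Fully degenerate positions (code N) accept any base including N;
    every other code accepts only its concrete ACGT expansion, so an N
    in the sequence never satisfies a constrained position.
    """
    if pattern_code == "N":
        return True
    return base in IUPAC_CODES[pattern_code]
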