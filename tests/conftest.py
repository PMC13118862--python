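"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from holotag.enzyme import BCGI
from holotag.sequence import IUPAC_CODES, revcomp


@pytest.fixture
def bcgi():
    return BCGI


def random_seq(rng: np.random.Generator, length: int, alphabet="ACGT") -> str:
    return "".join(
        alphabet[i] for i in rng.integers(0, len(alphabet), size=length)
    )


def naive_find_sites(seq: str, enzyme) -> list[tuple[int, str]]:
    """Sliding-window scan of the pattern and its reverse complement;
    the independent oracle for site finding. N in the sequence matches
    only a fully degenerate (N) pattern position."""
    seq = seq.upper()

    def matches(pattern: str, start: int) -> bool:
        for p, code in enumerate(pattern):
            base = seq[start + p]
            if code == "N":
                continue
            if base not in IUPAC_CODES[code]:
                return False
        return True

    hits = []
    fwd = enzyme.recognition
    rev = revcomp(enzyme.recognition)
    for i in range(len(seq) - len(fwd) + 1):
        if matches(fwd, i):
            hits.append((i, "+"))
        if matches(rev, i):
            hits.append((i, "-"))
    return sorted(hits)


def naive_extract_windows(seq: str, enzyme) -> list[str]:
    """Oracle tag extraction: canonical windows of all valid sites."""
    from holotag.sequence import canonical

    seq = seq.upper()
    out = []
    for pos, strand in naive_find_sites(seq, enzyme):
        start = pos - (
            enzyme.left_flank if strand == "+" else enzyme.right_flank
        )
        end = start + enzyme.tag_length
        if start < 0 or end > len(seq):
            continue
        window = seq[start:end]
        if "N" in window:
            continue
        tag = window if strand == "+" else revcomp(window)
        out.append(canonical(tag))
    return out
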