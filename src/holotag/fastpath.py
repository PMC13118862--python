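"""Vectorized read processing over fixed-length read matrices.

Holobiont 2bRAD libraries are dominated by host reads (~99%), so
realistic library sizes run to tens of millions of reads. This module
implements the quality filter and leftmost-site tag extraction over an
(n_reads, read_length) uint8 ASCII base matrix, semantically identical
to the per-read string path in :mod:`holotag.reads` (equivalence is
property-tested). The per-read scans are compiled with numba when
available, with pure-numpy fallbacks; both paths are exercised by the
test suite.

Sequences must be uppercase A/C/G/T/N (the codecs enforce this).
"""

from __future__ import annotations

from collections import Counter

import numpy as np

from .enzyme import EnzymeSpec
from .errors import InputError
from .sequence import IUPAC_CODES, revcomp

__all__ = [
    "encode_reads",
    "decode_reads",
    "quality_filter_matrix",
    "find_sites_matrix",
    "extract_tags_matrix",
    "tag_counts_from_matrix",
]

_N = ord("N")

#: complement lookup over ASCII codes (ACGTN only)
_COMP_LUT = np.arange(256, dtype=np.uint8)
for _x, _y in zip(b"ACGTN", b"TGCAN"):
    _COMP_LUT[_x] = _y
    _COMP_LUT[_x + 32] = _y  # lowercase input tolerated

_UPPER_LUT = np.arange(256, dtype=np.uint8)
for _x in b"acgtn":
    _UPPER_LUT[_x] = _x - 32

try:
    import numba

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def encode_reads(seqs: list[str]) -> np.ndarray:
    """Uniform-length string list -> (n, L) uint8 ASCII matrix."""
    if not seqs:
        return np.empty((0, 0), dtype=np.uint8)
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise InputError("matrix path requires uniform read length")
    arr = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    return _UPPER_LUT[arr.reshape(len(seqs), lengths.pop())].copy()


def decode_reads(mat: np.ndarray) -> list[str]:
    return [row.tobytes().decode("ascii") for row in mat]


def _accept_table(pattern: str) -> np.ndarray:
    """(span, 256) acceptance booleans; N accepts ACGTN."""
    acc = np.zeros((len(pattern), 256), dtype=np.bool_)
    for p, code in enumerate(pattern):
        bases = "ACGTN" if code == "N" else "".join(IUPAC_CODES[code])
        for b in bases:
            acc[p, ord(b)] = True
    return acc


# ---------------------------------------------------------------------------
# Quality filter


def _scan_reads_numpy(seqs: np.ndarray, max_run: int) -> tuple[np.ndarray, np.ndarray]:
    has_n = (seqs == _N).any(axis=1)
    eq = seqs[:, 1:] == seqs[:, :-1]
    if eq.shape[1] >= max_run:
        width = eq.shape[1] - max_run + 1
        run = eq[:, :width].copy()
        for shift in range(1, max_run):
            run &= eq[:, shift : shift + width]
        has_run = run.any(axis=1)
    else:
        has_run = np.zeros(seqs.shape[0], dtype=bool)
    return has_n, has_run


if _HAVE_NUMBA:

    @numba.njit(cache=False, nogil=True)
    def _scan_reads_kernel(seqs, max_run):  # pragma: no cover
        n, length = seqs.shape
        has_n = np.zeros(n, dtype=np.bool_)
        has_run = np.zeros(n, dtype=np.bool_)
        for i in range(n):
            run = 1
            seen_n = False
            longest = 1
            prev = seqs[i, 0]
            if prev == 78:  # 'N'
                seen_n = True
            for j in range(1, length):
                b = seqs[i, j]
                if b == 78:
                    seen_n = True
                if b == prev:
                    run += 1
                    if run > longest:
                        longest = run
                else:
                    run = 1
                    prev = b
            has_n[i] = seen_n
            has_run[i] = longest > max_run
        return has_n, has_run


def quality_filter_matrix(
    seqs: np.ndarray,
    quals: np.ndarray,
    low_q: int = 10,
    max_low_frac: float = 0.20,
    max_homopolymer: int = 10,
) -> tuple[np.ndarray, dict[str, int]]:
    """Vectorized three-rule filter.

    *quals* holds raw phred scores (not ASCII); a single-row quals
    matrix is treated as a constant model shared by all reads. Returns
    a keep mask plus per-rule drop counts with the string-path
    attribution order (N, homopolymer, low quality).
    """
    n, length = seqs.shape
    if _HAVE_NUMBA and n:
        has_n, has_run = _scan_reads_kernel(
            np.ascontiguousarray(seqs), max_homopolymer
        )
    else:
        has_n, has_run = _scan_reads_numpy(seqs, max_homopolymer)
    if quals.shape[0] == 1 and n != 1:
        bad = int((quals[0] < low_q).sum()) > max_low_frac * length
        low_frac_bad = np.full(n, bad)
    else:
        low_frac_bad = (quals < low_q).sum(axis=1) > max_low_frac * length
    drop_n = has_n
    drop_run = has_run & ~drop_n
    drop_low = low_frac_bad & ~drop_n & ~has_run
    keep = ~(drop_n | has_run | low_frac_bad)
    report = {
        "n_base": int(drop_n.sum()),
        "homopolymer": int(drop_run.sum()),
        "low_quality": int(drop_low.sum()),
    }
    return keep, report


# ---------------------------------------------------------------------------
# Leftmost-site search (used by the read simulator's sanitizer)


if _HAVE_NUMBA:

    @numba.njit(cache=False, nogil=True)
    def _leftmost_kernel(seqs, acc_plus, acc_minus, span, lflank, rflank,
                         tag_len):  # pragma: no cover
        n, length = seqs.shape
        out_start = np.full(n, -1, dtype=np.int64)
        out_strand = np.ones(n, dtype=np.int8)
        width = length - span + 1
        max_start = length - tag_len
        for i in range(n):
            for o in range(width):
                if o >= lflank and o - lflank <= max_start:
                    ok = True
                    for p in range(span):
                        if not acc_plus[p, seqs[i, o + p]]:
                            ok = False
                            break
                    if ok:
                        out_start[i] = o - lflank
                        out_strand[i] = 1
                        break
                if o >= rflank and o - rflank <= max_start:
                    ok = True
                    for p in range(span):
                        if not acc_minus[p, seqs[i, o + p]]:
                            ok = False
                            break
                    if ok:
                        out_start[i] = o - rflank
                        out_strand[i] = -1
                        break
        return out_start, out_strand


def _match_offsets(seqs: np.ndarray, pattern: str) -> np.ndarray:
    """Boolean (n, L - len(pattern) + 1): pattern matches at offset."""
    n, length = seqs.shape
    span = len(pattern)
    width = length - span + 1
    if width <= 0:
        return np.zeros((n, 0), dtype=bool)
    out: np.ndarray | None = None
    for p, code in enumerate(pattern):
        if code == "N":
            continue
        bases = sorted(IUPAC_CODES[code])
        window = seqs[:, p : p + width]
        col = window == ord(bases[0])
        for b in bases[1:]:
            col |= window == ord(b)
        out = col if out is None else (out & col)
    if out is None:  # fully degenerate pattern
        out = np.ones((n, width), dtype=bool)
    return out


def _find_sites_matrix_numpy(
    seqs: np.ndarray, enzyme: EnzymeSpec
) -> tuple[np.ndarray, np.ndarray]:
    n, length = seqs.shape
    rec = enzyme.recognition
    rc_rec = revcomp(rec)
    plus = _match_offsets(seqs, rec)
    minus = _match_offsets(seqs, rc_rec) if rc_rec != rec else plus
    width = plus.shape[1]
    hi = length - enzyme.tag_length  # max window start
    valid_plus = np.zeros(width, dtype=bool)
    valid_minus = np.zeros(width, dtype=bool)
    for off in range(width):
        if enzyme.left_flank <= off and off - enzyme.left_flank <= hi:
            valid_plus[off] = True
        if enzyme.right_flank <= off and off - enzyme.right_flank <= hi:
            valid_minus[off] = True
    plus = plus & valid_plus
    minus = minus & valid_minus
    any_p = plus.any(axis=1)
    any_m = minus.any(axis=1)
    off_p = np.where(any_p, plus.argmax(axis=1), length)
    off_m = np.where(any_m, minus.argmax(axis=1), length)
    use_minus = off_m < off_p
    offset = np.minimum(off_p, off_m)
    strand = np.where(use_minus, -1, 1).astype(np.int8)
    flank = np.where(use_minus, enzyme.right_flank, enzyme.left_flank)
    start = np.where(any_p | any_m, offset - flank, -1)
    return start, strand


def find_sites_matrix(
    seqs: np.ndarray, enzyme: EnzymeSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Leftmost full-window site per read: (window_start, strand).

    window_start = -1 when a read has no valid site; strand is +1/-1.
    At equal recognition offsets the plus strand wins, matching the
    string path's (offset, strand) ordering.
    """
    if _HAVE_NUMBA and seqs.shape[0]:
        rec = enzyme.recognition
        return _leftmost_kernel(
            np.ascontiguousarray(seqs),
            _accept_table(rec),
            _accept_table(revcomp(rec)),
            enzyme.recognition_length,
            enzyme.left_flank,
            enzyme.right_flank,
            enzyme.tag_length,
        )
    return _find_sites_matrix_numpy(seqs, enzyme)


# ---------------------------------------------------------------------------
# Tag extraction


if _HAVE_NUMBA:

    @numba.njit(cache=False, nogil=True)
    def _extract_kernel(seqs, acc_plus, acc_minus, span, lflank, rflank,
                        tag_len, comp):  # pragma: no cover
        n, length = seqs.shape
        out = np.zeros((n, tag_len), dtype=np.uint8)
        found = np.zeros(n, dtype=np.bool_)
        width = length - span + 1
        max_start = length - tag_len
        window = np.empty(tag_len, dtype=np.uint8)
        for i in range(n):
            for o in range(width):
                for s in range(2):
                    if s == 0:
                        flank = lflank
                    else:
                        flank = rflank
                    if o < flank or o - flank > max_start:
                        continue
                    ok = True
                    for p in range(span):
                        b = seqs[i, o + p]
                        if s == 0:
                            if not acc_plus[p, b]:
                                ok = False
                                break
                        else:
                            if not acc_minus[p, b]:
                                ok = False
                                break
                    if not ok:
                        continue
                    w0 = o - flank
                    clean = True
                    for p in range(tag_len):
                        b = seqs[i, w0 + p]
                        if b == 78:  # N in window: try later sites
                            clean = False
                            break
                        window[p] = b
                    if not clean:
                        continue
                    if s == 1:  # minus strand: reverse complement
                        for p in range(tag_len // 2):
                            a = window[p]
                            window[p] = comp[window[tag_len - 1 - p]]
                            window[tag_len - 1 - p] = comp[a]
                        if tag_len % 2 == 1:
                            mid = tag_len // 2
                            window[mid] = comp[window[mid]]
                    # Canonical: compare with reverse complement.
                    take_rc = False
                    for p in range(tag_len):
                        a = window[p]
                        b = comp[window[tag_len - 1 - p]]
                        if a != b:
                            take_rc = b < a
                            break
                    if take_rc:
                        for p in range(tag_len):
                            out[i, p] = comp[window[tag_len - 1 - p]]
                    else:
                        for p in range(tag_len):
                            out[i, p] = window[p]
                    found[i] = True
                    break
                if found[i]:
                    break
        return out, found


def _revcomp_rows(mat: np.ndarray) -> np.ndarray:
    return _COMP_LUT[mat][:, ::-1]


def _lex_min_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise lexicographic minimum of two equal-shape byte matrices."""
    diff = a != b
    any_diff = diff.any(axis=1)
    first = diff.argmax(axis=1)
    rows = np.arange(a.shape[0])
    take_a = ~any_diff | (a[rows, first] <= b[rows, first])
    return np.where(take_a[:, None], a, b)


def _extract_tags_numpy(
    seqs: np.ndarray, enzyme: EnzymeSpec
) -> tuple[np.ndarray, np.ndarray]:
    start, strand = _find_sites_matrix_numpy(seqs, enzyme)
    found = start >= 0
    idx = np.nonzero(found)[0]
    tag_len = enzyme.tag_length
    if idx.size == 0:
        return np.empty((0, tag_len), dtype=np.uint8), found
    cols = start[idx, None] + np.arange(tag_len)[None, :]
    windows = seqs[idx[:, None], cols]
    has_n = (windows == _N).any(axis=1)
    keep = ~has_n
    salvage_rows = idx[has_n]
    windows = windows[keep]
    minus = strand[idx][keep] < 0
    oriented = np.where(minus[:, None], _revcomp_rows(windows), windows)
    canon = _lex_min_rows(oriented, _revcomp_rows(oriented))
    found_out = found.copy()
    if salvage_rows.size:
        # N inside the leftmost window: the string path falls through
        # to a later clean site; rare, so delegate per read.
        from .reads import first_tag_in_read

        salvaged = []
        for r in salvage_rows:
            tag = first_tag_in_read(
                seqs[r].tobytes().decode("ascii"), enzyme
            )
            if tag is None:
                found_out[r] = False
            else:
                salvaged.append(
                    np.frombuffer(tag.encode("ascii"), dtype=np.uint8)
                )
        if salvaged:
            canon = np.vstack([canon, np.array(salvaged)])
    return canon, found_out


def extract_tags_matrix(
    seqs: np.ndarray, enzyme: EnzymeSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Canonical tags for the leftmost valid site of each read.

    Returns ``(windows, found)``: *windows* an (m, tag_length) uint8
    matrix of canonical tags for the m reads with an extractable site
    (windows containing N are passed over in favour of later clean
    sites, as in the string path), *found* the per-read boolean mask.
    Row order of *windows* is not meaningful to callers (counts only).
    """
    if _HAVE_NUMBA and seqs.shape[0]:
        rec = enzyme.recognition
        out, found = _extract_kernel(
            np.ascontiguousarray(seqs),
            _accept_table(rec),
            _accept_table(revcomp(rec)),
            enzyme.recognition_length,
            enzyme.left_flank,
            enzyme.right_flank,
            enzyme.tag_length,
            _COMP_LUT,
        )
        return out[found], found
    return _extract_tags_numpy(seqs, enzyme)


def tag_counts_from_matrix(windows: np.ndarray) -> Counter:
    """Unique canonical tag rows with counts, as a Counter of strings."""
    if windows.shape[0] == 0:
        return Counter()
    view = np.ascontiguousarray(windows).view(
        np.dtype((np.void, windows.shape[1]))
    ).ravel()
    uniq, counts = np.unique(view, return_counts=True)
    out: Counter = Counter()
    for v, c in zip(uniq, counts):
        out[v.tobytes().decode("ascii")] = int(c)
    return out
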