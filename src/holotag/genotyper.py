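"""Host genotyping at tag loci.

Host-routed tag observations are matched to reference tag loci in tag
space (Hamming distance, both orientations). Each locus pileup is then
called codominantly: with the two most frequent alleles at counts
``n1 >= n2`` and ``M = n1 + n2``, the locus is heterozygous when the
balanced-binomial likelihood of the minor count beats the sequencing-
error binomial, ``Binom(n2; M, 0.5) > Binom(n2; M, err)``, and
homozygous otherwise; loci under ``min_depth`` total coverage stay
undetermined. Downstream: allele-sharing (IBS) distances, a
neighbor-joining tree, and PCA on 0/1/2-coded genotypes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import binom

from .errors import InputError, InternalError
from .sequence import canonical, revcomp

__all__ = [
    "LocusPileup",
    "GenotypeCall",
    "GenotypeMatrix",
    "assign_to_loci",
    "call_genotype",
    "call_sample",
    "concordance",
    "allele_sharing_distance",
    "neighbor_joining",
    "pca",
]


@dataclass
class LocusPileup:
    """Allele (canonical tag sequence) -> read count at one locus."""

    locus_id: str
    alleles: Counter = field(default_factory=Counter)

    @property
    def depth(self) -> int:
        return sum(self.alleles.values())


@dataclass(frozen=True)
class GenotypeCall:
    locus_id: str
    status: str  # "called" | "undetermined"
    alleles: tuple[str, str] | None  # lexicographically ordered
    depth: int

    @property
    def is_het(self) -> bool:
        return (
            self.status == "called"
            and self.alleles is not None
            and self.alleles[0] != self.alleles[1]
        )


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def _pigeonhole_parts(tag_len: int, n_parts: int) -> list[tuple[int, int]]:
    bounds = np.linspace(0, tag_len, n_parts + 1).astype(int)
    return [(int(bounds[i]), int(bounds[i + 1])) for i in range(n_parts)]


class LocusIndex:
    """Nearest-reference lookup in tag space.

    Splits each reference tag into ``max_mismatch + 1`` segments; any
    query within ``max_mismatch`` of a reference matches at least one
    segment exactly (pigeonhole), so candidate loci come from segment
    dictionaries instead of a full scan. Both query orientations are
    considered; distances are exact Hamming on the candidates.
    """

    def __init__(self, reference_tags: Sequence[str], max_mismatch: int = 2):
        self.refs = list(reference_tags)
        self.max_mismatch = max_mismatch
        if not self.refs:
            self.tag_len = 0
            return
        self.tag_len = len(self.refs[0])
        if any(len(t) != self.tag_len for t in self.refs):
            raise InternalError("reference tags must share one length")
        self.exact = {t: i for i, t in enumerate(self.refs)}
        self.parts = _pigeonhole_parts(self.tag_len, max_mismatch + 1)
        self.segments: list[dict[str, list[int]]] = []
        for lo, hi in self.parts:
            seg: dict[str, list[int]] = {}
            for i, t in enumerate(self.refs):
                seg.setdefault(t[lo:hi], []).append(i)
            self.segments.append(seg)

    def _candidates(self, query: str) -> set[int]:
        out: set[int] = set()
        for (lo, hi), seg in zip(self.parts, self.segments):
            out.update(seg.get(query[lo:hi], ()))
        return out

    def lookup(self, tag: str) -> tuple[int | None, bool]:
        """(locus index or None, ambiguous?) for a canonical query."""
        if len(tag) != self.tag_len:
            raise InternalError(
                f"observed tag length {len(tag)} != reference "
                f"{self.tag_len}"
            )
        hit = self.exact.get(tag)
        if hit is not None:
            return hit, False
        rc = revcomp(tag)
        cands = self._candidates(tag) | self._candidates(rc)
        best = self.max_mismatch + 1
        winners: list[int] = []
        for i in cands:
            ref = self.refs[i]
            d = min(_hamming(tag, ref), _hamming(rc, ref))
            if d < best:
                best, winners = d, [i]
            elif d == best:
                winners.append(i)
        if best > self.max_mismatch or not winners:
            return None, False
        if len(winners) > 1:
            return None, True
        return winners[0], False


def assign_to_loci(
    observations: Mapping[str, int],
    reference_tags: Sequence[str],
    max_mismatch: int = 2,
) -> tuple[dict[str, LocusPileup], int]:
    """Build per-locus pileups from host tag observations.

    An observed canonical tag joins the locus whose reference canonical
    tag is nearest in Hamming distance (both orientations considered,
    exact matches trivially nearest); ties between equally distant loci
    discard the observation as ambiguous. Returns the pileups plus the
    count of discarded ambiguous observations.
    """
    index = LocusIndex(reference_tags, max_mismatch)
    if not index.refs:
        return {}, 0
    pileups: dict[str, LocusPileup] = {}
    ambiguous = 0
    for tag, count in observations.items():
        hit, is_ambiguous = index.lookup(tag)
        if hit is None:
            if is_ambiguous:
                ambiguous += count
            continue
        locus = index.refs[hit]
        pileups.setdefault(locus, LocusPileup(locus_id=locus)).alleles[
            tag
        ] += count
    return pileups, ambiguous


def call_genotype(
    pileup: LocusPileup, min_depth: int = 4, err: float = 0.01
) -> GenotypeCall:
    """Codominant call for one locus (see module docstring).

    Alleles beyond the top two contribute to the depth gate but not to
    the hom/het contest; likelihood ties break toward homozygote.
    """
    if not pileup.alleles:
        raise InputError(f"empty pileup for locus {pileup.locus_id}")
    depth = pileup.depth
    if depth < min_depth:
        return GenotypeCall(pileup.locus_id, "undetermined", None, depth)
    # Deterministic top-two: by count desc, then allele string.
    ranked = sorted(pileup.alleles.items(), key=lambda kv: (-kv[1], kv[0]))
    a1, n1 = ranked[0]
    if len(ranked) == 1:
        return GenotypeCall(pileup.locus_id, "called", (a1, a1), depth)
    a2, n2 = ranked[1]
    m = n1 + n2
    if binom.pmf(n2, m, 0.5) > binom.pmf(n2, m, err):
        pair = tuple(sorted((a1, a2)))
        return GenotypeCall(pileup.locus_id, "called", pair, depth)
    return GenotypeCall(pileup.locus_id, "called", (a1, a1), depth)


def call_sample(
    pileups: Mapping[str, LocusPileup],
    loci: Sequence[str],
    min_depth: int = 4,
    err: float = 0.01,
) -> dict[str, GenotypeCall]:
    """Genotype every locus in *loci*; loci without any pileup are
    undetermined at depth 0."""
    calls: dict[str, GenotypeCall] = {}
    for locus in loci:
        pile = pileups.get(locus)
        if pile is None or pile.depth == 0:
            calls[locus] = GenotypeCall(locus, "undetermined", None, 0)
        else:
            calls[locus] = call_genotype(pile, min_depth, err)
    return calls


def _stratum_table() -> dict:
    return {"genotyped": 0, "same": 0, "different": 0, "agreement": None}


def concordance(
    calls1: Mapping[str, GenotypeCall],
    calls2: Mapping[str, GenotypeCall],
) -> dict:
    """Agreement over loci called in both samples, overall and
    stratified by the genotype class (hom/het) of *calls1*."""
    if set(calls1) != set(calls2):
        raise InputError("concordance requires the same locus universe")
    out = {
        "overall": _stratum_table(),
        "homozygote": _stratum_table(),
        "heterozygote": _stratum_table(),
    }
    for locus, c1 in calls1.items():
        c2 = calls2[locus]
        if c1.status != "called" or c2.status != "called":
            continue
        stratum = "heterozygote" if c1.is_het else "homozygote"
        same = c1.alleles == c2.alleles
        for key in ("overall", stratum):
            out[key]["genotyped"] += 1
            out[key]["same" if same else "different"] += 1
    for table in out.values():
        if table["genotyped"]:
            table["agreement"] = table["same"] / table["genotyped"]
    return out


@dataclass
class GenotypeMatrix:
    """Genotype calls for samples x loci over one locus universe."""

    samples: list[str]
    loci: list[str]
    calls: dict[str, dict[str, GenotypeCall]]

    def __post_init__(self) -> None:
        for s in self.samples:
            if set(self.calls[s]) != set(self.loci):
                raise InputError(
                    f"sample {s!r} does not cover the locus universe"
                )

    def major_allele(self, locus: str) -> str | None:
        copies: Counter = Counter()
        for s in self.samples:
            call = self.calls[s][locus]
            if call.status == "called" and call.alleles:
                copies[call.alleles[0]] += 1
                copies[call.alleles[1]] += 1
        if not copies:
            return None
        return sorted(copies.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]

    def numeric_coding(self) -> tuple[np.ndarray, list[str]]:
        """(n_samples, n_loci) copies of the non-major allele; NaN for
        undetermined calls. Loci with no called genotype are dropped."""
        cols: list[np.ndarray] = []
        kept: list[str] = []
        for locus in self.loci:
            major = self.major_allele(locus)
            if major is None:
                continue
            col = np.full(len(self.samples), np.nan)
            for i, s in enumerate(self.samples):
                call = self.calls[s][locus]
                if call.status == "called" and call.alleles:
                    col[i] = sum(1 for a in call.alleles if a != major)
            cols.append(col)
            kept.append(locus)
        if not cols:
            return np.empty((len(self.samples), 0)), []
        return np.column_stack(cols), kept


def _shared_copies(a: tuple[str, str], b: tuple[str, str]) -> int:
    ca, cb = Counter(a), Counter(b)
    return sum((ca & cb).values())


def allele_sharing_distance(matrix: GenotypeMatrix) -> np.ndarray:
    """1 - mean IBS/2 over loci called in both samples."""
    n = len(matrix.samples)
    if n < 2:
        raise InputError("allele-sharing distance needs >= 2 samples")
    d = np.zeros((n, n))
    for i in range(n):
        ci = matrix.calls[matrix.samples[i]]
        for j in range(i + 1, n):
            cj = matrix.calls[matrix.samples[j]]
            sims = []
            for locus in matrix.loci:
                a, b = ci[locus], cj[locus]
                if a.status == "called" and b.status == "called":
                    sims.append(_shared_copies(a.alleles, b.alleles) / 2)
            if not sims:
                raise InputError(
                    f"samples {matrix.samples[i]!r} and "
                    f"{matrix.samples[j]!r} share no called loci"
                )
            d[i, j] = d[j, i] = 1.0 - float(np.mean(sims))
    return d


def _fmt_branch(x: float) -> str:
    return f"{max(x, 0.0):.10g}"


def neighbor_joining(dist: np.ndarray, labels: Sequence[str]) -> str:
    """Saitou-Nei neighbor joining; unrooted Newick output.

    Deterministic: the minimal Q entry with the smallest (i, j) index
    pair is joined first; negative branch lengths are clamped to 0.
    """
    d = np.asarray(dist, dtype=float).copy()
    n = d.shape[0]
    if d.shape != (n, n) or n != len(labels):
        raise InputError("distance matrix / label size mismatch")
    if n < 3:
        raise InputError("neighbor joining needs >= 3 taxa")
    if not np.allclose(d, d.T, atol=1e-12):
        raise InputError("distance matrix must be symmetric")
    if (d < 0).any():
        raise InputError("distance matrix must be non-negative")
    if not np.allclose(np.diag(d), 0.0):
        raise InputError("distance matrix must have a zero diagonal")

    nodes = [str(lbl) for lbl in labels]
    while len(nodes) > 3:
        m = d.shape[0]
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        iu = np.triu_indices(m, k=1)
        flat = q[iu]
        best = int(np.argmin(flat))  # first min in row-major order:
        i, j = int(iu[0][best]), int(iu[1][best])  # smallest index pair
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        merged = (
            f"({nodes[i]}:{_fmt_branch(li)},{nodes[j]}:{_fmt_branch(lj)})"
        )
        new_row = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d2 = np.empty((m - 1, m - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = new_row[keep]
        d2[:-1, -1] = new_row[keep]
        d2[-1, -1] = 0.0
        d = d2
        nodes = [nodes[k] for k in keep] + [merged]
    # Final unrooted trifurcation from the three-point closed form.
    a, b, c = 0, 1, 2
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    return (
        f"({nodes[a]}:{_fmt_branch(la)},{nodes[b]}:{_fmt_branch(lb)},"
        f"{nodes[c]}:{_fmt_branch(lc)});"
    )


def pca(
    matrix: GenotypeMatrix, impute: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """PCA of mean-centered 0/1/2 genotype codings.

    Undetermined calls are imputed to the locus mean (or, with
    ``impute=False``, loci with any undetermined call are dropped);
    monomorphic loci are dropped. Sign convention: each component's
    largest-magnitude loading is positive. Returns sample coordinates
    and explained-variance fractions.
    """
    if len(matrix.samples) < 2:
        raise InputError("PCA needs >= 2 samples")
    coded, _ = matrix.numeric_coding()
    if coded.shape[1] == 0:
        raise InputError("no informative loci for PCA")
    if impute:
        means = np.nanmean(coded, axis=0)
        idx = np.where(np.isnan(coded))
        coded[idx] = means[idx[1]]
    else:
        coded = coded[:, ~np.isnan(coded).any(axis=0)]
    # Drop monomorphic columns.
    coded = coded[:, coded.std(axis=0) > 0]
    if coded.shape[1] < 2:
        raise InputError("fewer than 2 informative loci for PCA")
    centered = coded - coded.mean(axis=0)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    # Fix signs from loadings.
    for k in range(len(s)):
        lead = np.argmax(np.abs(vt[k]))
        if vt[k, lead] < 0:
            vt[k] *= -1
            u[:, k] *= -1
    coords = u * s
    var = s**2
    explained = var / var.sum() if var.sum() > 0 else var
    return coords, explained
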