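"""Community diversity statistics.

Alpha diversity: Shannon-Wiener H = -sum p_i ln p_i (natural log by
default), Simpson D = 1 - sum p_i^2, and the bias-corrected Chao1
richness estimator S_obs + F1(F1-1) / (2(F2+1)) (defined even without
doubletons). Beta diversity: Bray-Curtis dissimilarity and a
permutation PERMANOVA with the (1 + exceedances) / (1 + N) p-value
estimator, so p is never exactly zero.
"""

from __future__ import annotations

import math
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

from .errors import InputError

__all__ = [
    "shannon",
    "simpson",
    "chao1",
    "bray_curtis",
    "bray_curtis_matrix",
    "permanova",
]


def _as_probs(p: Sequence[float]) -> np.ndarray:
    arr = np.asarray(p, dtype=float)
    if (arr < 0).any():
        raise InputError("abundances must be non-negative")
    total = arr.sum()
    if total <= 0:
        raise InputError("all-zero abundance vector")
    return arr / total


def shannon(p: Sequence[float], base: float | None = None) -> float:
    """Shannon-Wiener index; natural log unless *base* is given.
    Zero-abundance terms contribute 0."""
    probs = _as_probs(p)
    nz = probs[probs > 0]
    h = float(-(nz * np.log(nz)).sum())
    if base is not None:
        h /= math.log(base)
    return h


def simpson(p: Sequence[float]) -> float:
    """Gini-Simpson index 1 - sum p_i^2."""
    probs = _as_probs(p)
    return float(1.0 - (probs**2).sum())


def chao1(counts: Sequence[int]) -> float:
    """Bias-corrected Chao1 richness from integer species counts."""
    arr = np.asarray(counts)
    if not np.issubdtype(arr.dtype, np.integer):
        as_float = np.asarray(counts, dtype=float)
        if not np.allclose(as_float, np.round(as_float)):
            raise InputError("Chao1 requires integer counts")
        arr = np.round(as_float).astype(int)
    if (arr < 0).any():
        raise InputError("counts must be non-negative")
    s_obs = int((arr > 0).sum())
    f1 = int((arr == 1).sum())
    f2 = int((arr == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2 * (f2 + 1))


def bray_curtis(x: Sequence[float], y: Sequence[float]) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y)."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise InputError("vectors must share the species universe")
    if (xa < 0).any() or (ya < 0).any():
        raise InputError("abundances must be non-negative")
    denom = (xa + ya).sum()
    if denom == 0:
        raise InputError("Bray-Curtis undefined for two all-zero vectors")
    return float(np.abs(xa - ya).sum() / denom)


def bray_curtis_matrix(
    table: Mapping[str, Mapping[str, float]]
) -> tuple[np.ndarray, list[str]]:
    """Pairwise Bray-Curtis over samples of an abundance table
    (sample -> species -> abundance)."""
    samples = sorted(table)
    species = sorted({sp for v in table.values() for sp in v})
    mat = np.array(
        [[table[s].get(sp, 0.0) for sp in species] for s in samples]
    )
    n = len(samples)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = bray_curtis(mat[i], mat[j])
    return d, samples


def _permanova_f(
    d2: np.ndarray, groups: np.ndarray, uniq: np.ndarray
) -> tuple[float, float]:
    """(pseudo-F, R^2) from squared distances and group labels."""
    n = d2.shape[0]
    a = len(uniq)
    ss_t = d2[np.triu_indices(n, k=1)].sum() / n
    ss_w = 0.0
    for g in uniq:
        idx = np.nonzero(groups == g)[0]
        ng = len(idx)
        sub = d2[np.ix_(idx, idx)]
        ss_w += sub[np.triu_indices(ng, k=1)].sum() / ng
    ss_b = ss_t - ss_w
    f = (ss_b / (a - 1)) / (ss_w / (n - a))
    return f, ss_b / ss_t


def permanova(
    dist: np.ndarray,
    groups: Sequence[str],
    n_permutations: int = 999,
    seed: int | None = None,
) -> dict:
    """One-way PERMANOVA on a distance matrix.

    Returns ``{"F": pseudo-F, "R2": SS_between/SS_total, "p": permutation
    p-value}``. The permutation null shuffles group labels with the
    given seed; p = (1 + #{F_perm >= F_obs}) / (1 + n_permutations).
    """
    d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or not np.allclose(d, d.T, atol=1e-12):
        raise InputError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(d), 0.0):
        raise InputError("distance matrix must have a zero diagonal")
    groups = np.asarray(list(groups))
    if len(groups) != n:
        raise InputError("one group label per sample required")
    uniq, counts = np.unique(groups, return_counts=True)
    if len(uniq) < 2:
        raise InputError("PERMANOVA needs >= 2 groups")
    if (counts < 2).any():
        small = uniq[counts < 2]
        raise InputError(f"groups with < 2 members: {list(small)}")
    d2 = d**2
    f_obs, r2 = _permanova_f(d2, groups, uniq)
    rng = np.random.default_rng(seed)
    exceed = 0
    perm = groups.copy()
    for _ in range(n_permutations):
        rng.shuffle(perm)
        f_perm, _ = _permanova_f(d2, perm, uniq)
        if f_perm >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return {"F": float(f_obs), "R2": float(r2), "p": float(p)}


def permanova_exhaustive(dist: np.ndarray, groups: Sequence[str]) -> dict:
    """Exact enumeration analogue of :func:`permanova` over all distinct
    label assignments (feasible for small n; used as an oracle)."""
    d = np.asarray(dist, dtype=float) ** 2
    groups = np.asarray(list(groups))
    uniq = np.unique(groups)
    if len(uniq) != 2:
        raise InputError("exhaustive mode supports exactly 2 groups")
    n = len(groups)
    k = int((groups == uniq[0]).sum())
    f_obs, r2 = _permanova_f(d, groups, uniq)
    exceed = 0
    total = 0
    for pick in combinations(range(n), k):
        perm = np.full(n, uniq[1], dtype=groups.dtype)
        perm[list(pick)] = uniq[0]
        f_perm, _ = _permanova_f(d, perm, uniq)
        total += 1
        if f_perm >= f_obs - 1e-12:
            exceed += 1
    return {"F": float(f_obs), "R2": float(r2), "p": exceed / total}
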