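"""Compiled inner loops for combination scoring, ranking and sampling.

The swarm evaluates tens of thousands of SNP combinations per run; these
numba kernels compute the per-combination contingency counts and the three
truncated objectives (plus the untruncated K2) in a single pass, rank the
population, and draw weighted SNP samples.  They must agree with the
plain-numpy implementations in :mod:`epissa.objectives`, which remain the
reference path (and are what the module-level scoring functions use); the
test suite cross-checks the two.

Factorial and plain logarithms come from tables precomputed per dataset
(indices never exceed the sample count), so scoring a cell is a handful of
loads.  Truncation selects the ``ml - 1`` cells with the smallest
contributions under the total order (contribution, cell index) — exactly the
cells a stable ascending sort would keep first — via a bounded max-heap.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "cell_counts",
    "objective_bundle",
    "score_combination",
    "rank_and_order",
    "weighted_sample_noreplace",
]


@njit(cache=True)
def cell_counts(geno_t: np.ndarray, phen: np.ndarray, snps: np.ndarray) -> np.ndarray:
    """(3^k, 2) control/case counts of the joint genotypes of ``snps``.

    ``geno_t`` is SNP-major (n_snps, n_samples) so each selected SNP's
    genotypes stream through contiguously.
    """
    m = geno_t.shape[1]
    k = snps.size
    size = 1
    for _ in range(k):
        size *= 3
    enc = np.zeros(m, np.int64)
    for j in range(k):
        col = geno_t[snps[j]]
        for i in range(m):
            enc[i] = enc[i] * 3 + col[i]
    out = np.zeros((size, 2), np.int64)
    for i in range(m):
        out[enc[i], phen[i]] += 1
    return out


@njit(cache=True)
def _sift_down(hv: np.ndarray, hi: np.ndarray, start: int, size: int) -> None:
    # max-heap under the lexicographic order (value, index)
    root = start
    while True:
        child = 2 * root + 1
        if child >= size:
            break
        if child + 1 < size:
            if (hv[child + 1] > hv[child]) or (
                hv[child + 1] == hv[child] and hi[child + 1] > hi[child]
            ):
                child += 1
        if (hv[child] > hv[root]) or (hv[child] == hv[root] and hi[child] > hi[root]):
            hv[root], hv[child] = hv[child], hv[root]
            hi[root], hi[child] = hi[child], hi[root]
            root = child
        else:
            break


@njit(cache=True)
def _smallest_cells(
    contrib: np.ndarray, n0: np.ndarray, n1: np.ndarray, keep: int
):
    """Sum of the ``keep`` smallest contributions (ties to lower index) and
    the pooled class counts of everything else."""
    r = contrib.size
    hv = contrib[:keep].copy()
    hi = np.arange(keep)
    for s in range(keep // 2 - 1, -1, -1):
        _sift_down(hv, hi, s, keep)
    for i in range(keep, r):
        v = contrib[i]
        if (v < hv[0]) or (v == hv[0] and i < hi[0]):
            hv[0] = v
            hi[0] = i
            _sift_down(hv, hi, 0, keep)
    total = 0.0
    k0 = 0
    k1 = 0
    for j in range(keep):
        total += hv[j]
        k0 += n0[hi[j]]
        k1 += n1[hi[j]]
    p0 = int(n0.sum()) - k0
    p1 = int(n1.sum()) - k1
    return total, p0, p1


@njit(cache=True)
def objective_bundle(
    full_counts: np.ndarray, ml: int, m: int, logfact: np.ndarray, logn: np.ndarray
) -> np.ndarray:
    """(k2_truncated, ce_truncated, gini_truncated, k2_raw) in one pass.

    ``full_counts`` is the dense (3^k, 2) table; rows observed in no sample
    are dropped, the per-cell contributions of the three objectives are
    computed, and each objective is truncated independently: the ml - 1 cells
    with its smallest contributions are kept, the rest pooled into one cell.
    ``ml <= 0`` means no truncation.  ``logfact[n] = ln(n!)``; ``logn[n] = ln n``.
    """
    size = full_counts.shape[0]
    r = 0
    for x in range(size):
        if full_counts[x, 0] > 0 or full_counts[x, 1] > 0:
            r += 1
    n0 = np.empty(r, np.int64)
    n1 = np.empty(r, np.int64)
    j = 0
    for x in range(size):
        c0 = full_counts[x, 0]
        c1 = full_counts[x, 1]
        if c0 > 0 or c1 > 0:
            n0[j] = c0
            n1[j] = c1
            j += 1

    k2c = np.empty(r, np.float64)
    cec = np.empty(r, np.float64)
    gic = np.empty(r, np.float64)
    k2_raw = 0.0
    for x in range(r):
        a = n0[x]
        b = n1[x]
        t = a + b
        v = logfact[t + 1] - logfact[a] - logfact[b]
        k2c[x] = v
        k2_raw += v
        h = 0.0
        if a > 0:
            h += a * (logn[t] - logn[a])
        if b > 0:
            h += b * (logn[t] - logn[b])
        cec[x] = h / m
        gic[x] = 2.0 * a * b / (t * m)

    out = np.empty(4, np.float64)
    out[3] = k2_raw
    if ml <= 0 or r <= ml:
        out[0] = k2c.sum()
        out[1] = cec.sum()
        out[2] = gic.sum()
        return out

    for obj in range(3):
        contrib = k2c if obj == 0 else (cec if obj == 1 else gic)
        total, p0, p1 = _smallest_cells(contrib, n0, n1, ml - 1)
        t = p0 + p1
        if t > 0:
            if obj == 0:
                total += logfact[t + 1] - logfact[p0] - logfact[p1]
            elif obj == 1:
                h = 0.0
                if p0 > 0:
                    h += p0 * (logn[t] - logn[p0])
                if p1 > 0:
                    h += p1 * (logn[t] - logn[p1])
                total += h / m
            else:
                total += 2.0 * p0 * p1 / (t * m)
        out[obj] = total
    return out


@njit(cache=True)
def score_combination(
    geno: np.ndarray,
    phen: np.ndarray,
    snps: np.ndarray,
    ml: int,
    m: int,
    logfact: np.ndarray,
    logn: np.ndarray,
) -> np.ndarray:
    """Counts + objectives in one call; see :func:`objective_bundle`."""
    return objective_bundle(cell_counts(geno, phen, snps), ml, m, logfact, logn)


@njit(cache=True)
def rank_and_order(scores: np.ndarray, counters: np.ndarray):
    """Competition ranks, rank sums, and the population order.

    ``scores`` is (n, 3); rank per objective is 1 + number of strictly
    smaller values.  The returned ``order`` sorts ascending by
    (rank_sum, k2 score, insertion counter) — a stable total order.
    """
    n = scores.shape[0]
    ranks = np.empty((n, 3), np.int64)
    for j in range(3):
        srt = np.sort(scores[:, j].copy())
        for i in range(n):
            ranks[i, j] = np.searchsorted(srt, scores[i, j]) + 1
    rank_sum = ranks[:, 0] + ranks[:, 1] + ranks[:, 2]
    order = np.argsort(counters, kind="mergesort")
    order = order[np.argsort(scores[order, 0], kind="mergesort")]
    order = order[np.argsort(rank_sum[order], kind="mergesort")]
    return ranks, rank_sum, order


@njit(cache=True)
def weighted_sample_noreplace(
    weights: np.ndarray, k: int, uniforms: np.ndarray
) -> np.ndarray:
    """Sequential weighted draws without replacement.

    Each draw picks index i with probability weights[i] / sum(remaining);
    the drawn weight is then removed.  ``uniforms`` supplies k U(0,1)
    variates, so the caller controls the randomness.
    """
    w = weights.copy()
    total = w.sum()
    out = np.empty(k, np.int64)
    for d in range(k):
        r = uniforms[d] * total
        acc = 0.0
        pick = w.size - 1
        for i in range(w.size):
            acc += w[i]
            if r < acc:
                pick = i
                break
        # guard against picking an exhausted index through rounding
        while w[pick] == 0.0:
            pick = (pick + 1) % w.size
        out[d] = pick
        total -= w[pick]
        w[pick] = 0.0
    return out
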