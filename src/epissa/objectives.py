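"""Association objectives for SNP combinations against a binary phenotype.

Three objective functions score a combination X of SNPs against case-control
status Y, all computed from the genotype-combination contingency table and all
oriented so that *lower is stronger*:

* ``k2`` — the negative natural log of the Cooper-Herskovits K2 (Bayesian
  Dirichlet) marginal likelihood of Y given the partition induced by X;
* ``ce`` — the conditional entropy H(Y | X) in nats;
* ``gini`` — the expected Gini impurity of Y within genotype cells.

Because all three sum over observed genotype cells, their values drift with the
number of occupied cells.  To compare combinations of different effective
length fairly, each objective is computed on a *truncated* table: the cells
with the ``ml - 1`` smallest per-cell contributions (for that objective) are
kept as-is and all remaining cells are pooled into a single merged cell, so at
most ``ml`` rows contribute.

The auto-parameter rules tie the search order and the table cap to the sample
counts: ``mo = floor(ln(min(m0, m1)) - 0.5)`` keeps the expected samples per
genotype cell near e, and ``ml = floor(min(m0, m1) / 10)`` caps the table.

The G-test of independence (used for significance gating, never truncated)
is the standard likelihood-ratio statistic 2·Σ O ln(O/E) on observed cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, xlogy
from scipy.stats import chi2

from .io import Dataset

__all__ = [
    "auto_mo",
    "auto_ml",
    "contingency",
    "truncate",
    "k2_score",
    "ce_score",
    "gini_score",
    "g_test",
    "g_test_counts",
    "Scorer",
    "TruncatedContingencyTable",
    "ObjectiveScores",
    "SampleTooSmallError",
    "DegenerateTableError",
]

OBJECTIVES = ("k2", "ce", "gini")


class SampleTooSmallError(ValueError):
    pass


class DegenerateTableError(ValueError):
    pass


def auto_mo(m0: int, m1: int) -> int:
    """Maximum epistasis order derived from the smaller class count."""
    if min(m0, m1) < 2:
        raise SampleTooSmallError("need at least 2 samples in each class")
    mo = math.floor(math.log(min(m0, m1)) - 0.5)
    if mo < 1:
        raise SampleTooSmallError(
            f"sample counts ({m0}, {m1}) give maximum order {mo} < 1"
        )
    return mo


def auto_ml(m0: int, m1: int) -> int:
    """Contingency-table length cap derived from the smaller class count."""
    ml = min(m0, m1) // 10
    if ml < 2:
        raise SampleTooSmallError(f"sample counts ({m0}, {m1}) give table cap {ml} < 2")
    return ml


@dataclass
class TruncatedContingencyTable:
    """Per-genotype-combination class counts, optionally with a pooled cell.

    ``keys`` are mixed-radix (base-3) encodings of the genotype combination;
    ``counts`` has one row per retained cell with columns (controls, cases).
    When pooling occurred, ``pooled`` holds the merged (controls, cases) counts
    of all non-retained cells and at most ``ml`` rows contribute in total.
    """

    keys: np.ndarray
    counts: np.ndarray
    class_totals: tuple[int, int]
    ml: float = math.inf
    pooled: tuple[int, int] | None = None

    @property
    def n_cells(self) -> int:
        return int(self.counts.shape[0]) + (1 if self.pooled is not None else 0)

    def total(self) -> int:
        t = int(self.counts.sum())
        if self.pooled is not None:
            t += self.pooled[0] + self.pooled[1]
        return t


@dataclass(frozen=True)
class ObjectiveScores:
    k2: float
    ce: float
    gini: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.k2, self.ce, self.gini)


def _observed_counts(dataset: Dataset, snps) -> np.ndarray:
    """(r, 2) control/case counts for every genotype combination observed."""
    snps = list(snps)
    if not snps:
        raise ValueError("empty SNP set")
    sub = dataset.genotypes[:, snps].astype(np.int64)
    powers = 3 ** np.arange(len(snps), dtype=np.int64)
    key = sub @ powers
    joint = key * 2 + dataset.phenotype
    c = np.bincount(joint, minlength=2 * 3 ** len(snps)).reshape(-1, 2)
    mask = c.any(axis=1)
    return c[mask]


def contingency(dataset: Dataset, snps) -> TruncatedContingencyTable:
    """Untruncated contingency table over the combinations observed in >= 1 sample."""
    snps = list(snps)
    if not snps:
        raise ValueError("empty SNP set")
    sub = dataset.genotypes[:, snps].astype(np.int64)
    powers = 3 ** np.arange(len(snps), dtype=np.int64)
    key = sub @ powers
    joint = key * 2 + dataset.phenotype
    c = np.bincount(joint, minlength=2 * 3 ** len(snps)).reshape(-1, 2)
    mask = c.any(axis=1)
    return TruncatedContingencyTable(
        keys=np.flatnonzero(mask),
        counts=c[mask],
        class_totals=(dataset.m0, dataset.m1),
    )


# ---------------------------------------------------------------------------
# per-cell contributions


def _k2_cells(counts: np.ndarray, logfact: np.ndarray) -> np.ndarray:
    # binary phenotype: ln((m_x + 1)!) - ln(m_x0!) - ln(m_x1!)
    mx0 = counts[:, 0]
    mx1 = counts[:, 1]
    return logfact[mx0 + mx1 + 1] - logfact[mx0] - logfact[mx1]


def _ce_cells(counts: np.ndarray, m: int) -> np.ndarray:
    # p(x) * H(Y | X = x), in nats; 0 ln 0 := 0
    mx0 = counts[:, 0]
    mx1 = counts[:, 1]
    mx = mx0 + mx1
    return (xlogy(mx0, mx) - xlogy(mx0, mx0) + xlogy(mx1, mx) - xlogy(mx1, mx1)) / m


def _gini_cells(counts: np.ndarray, m: int) -> np.ndarray:
    # p(x) * sum_y p(y|x)(1 - p(y|x)) = 2 m_x0 m_x1 / (m m_x)
    mx0 = counts[:, 0].astype(np.float64)
    mx1 = counts[:, 1].astype(np.float64)
    return 2.0 * mx0 * mx1 / ((mx0 + mx1) * m)


def _cells(objective: str, counts: np.ndarray, m: int, logfact: np.ndarray) -> np.ndarray:
    if objective == "k2":
        return _k2_cells(counts, logfact)
    if objective == "ce":
        return _ce_cells(counts, m)
    if objective == "gini":
        return _gini_cells(counts, m)
    raise ValueError(f"unknown objective {objective!r}")


def _logfact_table(m: int) -> np.ndarray:
    return gammaln(np.arange(m + 3, dtype=np.float64) + 1.0)


def truncate(
    table: TruncatedContingencyTable, ml: int, objective: str
) -> TruncatedContingencyTable:
    """Pool the weakest cells so at most ``ml`` rows contribute to ``objective``.

    The ``ml - 1`` cells with the smallest per-cell contribution are retained;
    every other cell's counts are merged into one pooled cell.  Tables with at
    most ``ml`` rows are returned unchanged.
    """
    if ml < 2:
        raise ValueError("ml must be >= 2")
    if table.pooled is not None:
        raise ValueError("table is already truncated")
    r = table.counts.shape[0]
    if r <= ml:
        return table
    m = table.class_totals[0] + table.class_totals[1]
    contrib = _cells(objective, table.counts, m, _logfact_table(m))
    order = np.argsort(contrib, kind="stable")
    keep = np.sort(order[: ml - 1])
    drop = np.sort(order[ml - 1 :])
    pooled = (int(table.counts[drop, 0].sum()), int(table.counts[drop, 1].sum()))
    return TruncatedContingencyTable(
        keys=table.keys[keep],
        counts=table.counts[keep],
        class_totals=table.class_totals,
        ml=ml,
        pooled=pooled,
    )


def _truncated_sum(
    counts: np.ndarray, ml: float, objective: str, m: int, logfact: np.ndarray
) -> float:
    contrib = _cells(objective, counts, m, logfact)
    if counts.shape[0] <= ml:
        return float(contrib.sum())
    ml = int(ml)
    order = np.argsort(contrib, kind="stable")
    keep = order[: ml - 1]
    drop = order[ml - 1 :]
    pooled = counts[drop].sum(axis=0)[None, :]
    return float(contrib[keep].sum() + _cells(objective, pooled, m, logfact)[0])


# ---------------------------------------------------------------------------
# public scoring API


def k2_score(dataset: Dataset, snps, ml: float = math.inf) -> float:
    """Negative-log K2 of the combination, after k2-specific truncation."""
    counts = _observed_counts(dataset, snps)
    m = dataset.n_samples
    return _truncated_sum(counts, ml, "k2", m, _logfact_table(m))


def ce_score(dataset: Dataset, snps, ml: float = math.inf) -> float:
    """Conditional entropy H(Y|X) in nats, after ce-specific truncation."""
    counts = _observed_counts(dataset, snps)
    return _truncated_sum(counts, ml, "ce", dataset.n_samples, _logfact_table(0))


def gini_score(dataset: Dataset, snps, ml: float = math.inf) -> float:
    """Expected Gini impurity of Y within genotype cells, after truncation."""
    counts = _observed_counts(dataset, snps)
    return _truncated_sum(counts, ml, "gini", dataset.n_samples, _logfact_table(0))


def g_test_counts(counts: np.ndarray) -> tuple[float, int, float]:
    """G-test of independence on an (r, 2) table of observed class counts."""
    counts = np.asarray(counts, dtype=np.float64)
    counts = counts[counts.sum(axis=1) > 0]
    r = counts.shape[0]
    col = counts.sum(axis=0)
    if r < 2 or (col > 0).sum() < 2:
        raise DegenerateTableError("need >= 2 observed combos and both classes")
    m = counts.sum()
    row = counts.sum(axis=1)
    expected = np.outer(row, col) / m
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = 2.0 * float(xlogy(counts, counts / expected).sum())
    stat = max(stat, 0.0)
    df = (r - 1) * (counts.shape[1] - 1)
    return stat, df, float(chi2.sf(stat, df))


def g_test(dataset: Dataset, snps) -> tuple[float, int, float]:
    """G-test of independence between the combination's genotypes and the class.

    The statistic is 2 SUM O ln(O/E) over observed cells; the degrees of
    freedom use the full genotype space of the combination,
    ``df = (3^k - 1) x (|YG| - 1)``, not just the observed combinations.
    For sparse tables (high-order combinations on modest samples) this is
    deliberately conservative: a combination only reaches a small p-value by
    genuine association, not by fragmenting the sample into many tiny pure
    cells.  No truncation is applied.
    """
    snps = list(set(snps))
    stat, _, _ = g_test_counts(_observed_counts(dataset, snps))
    df = 3 ** len(snps) - 1
    return stat, df, float(chi2.sf(stat, df))


class Scorer:
    """Memoizing scorer binding a dataset and a table cap ``ml``.

    The swarm re-evaluates SNP combinations heavily; scores and G-tests are
    cached per deduplicated SNP-index set.  Caching never changes a value.
    """

    def __init__(self, dataset: Dataset, ml: float = math.inf):
        from ._kernels import cell_counts, score_combination

        self.dataset = dataset
        self.ml = ml
        self._ml_int = 0 if math.isinf(ml) else int(ml)
        # SNP-major layout: selected columns stream contiguously in the kernel
        self._geno = np.ascontiguousarray(dataset.genotypes.T, dtype=np.int8)
        self._phen = np.ascontiguousarray(dataset.phenotype, dtype=np.int8)
        self._m = dataset.n_samples
        self._cell_counts = cell_counts
        self._score_combination = score_combination
        # logfact[n] = ln(n!), logn[n] = ln n, for n up to the sample count
        self._logfact = _logfact_table(self._m)
        self._logn = np.log(np.maximum(np.arange(self._m + 3, dtype=np.float64), 1.0))
        self._scores: dict[tuple[int, ...], ObjectiveScores] = {}
        self._k2raw: dict[tuple[int, ...], float] = {}
        self._gtests: dict[tuple[int, ...], tuple[float, int, float]] = {}

    def _counts(self, key: tuple[int, ...]) -> np.ndarray:
        c = self._cell_counts(self._geno, self._phen, np.asarray(key, dtype=np.int64))
        return c[c.any(axis=1)]

    def _compute(self, key: tuple[int, ...]) -> ObjectiveScores:
        out = self._score_combination(
            self._geno,
            self._phen,
            np.asarray(key, dtype=np.int64),
            self._ml_int,
            self._m,
            self._logfact,
            self._logn,
        )
        s = ObjectiveScores(out[0], out[1], out[2])
        self._scores[key] = s
        self._k2raw[key] = out[3]
        return s

    def scores(self, snps) -> ObjectiveScores:
        key = tuple(sorted(set(snps)))
        hit = self._scores.get(key)
        if hit is not None:
            return hit
        return self._compute(key)

    def k2(self, snps) -> float:
        """The (truncated) K2 population objective."""
        return self.scores(snps).k2

    def k2_raw(self, snps) -> float:
        """Untruncated K2 — used by backward noise elimination.

        Truncation makes combinations of *different* sizes incomparable (a
        longer combination gets to keep only its purest cells), so the
        elimination step, which compares a set against its subsets, scores
        with the full table: the per-cell prior penalty then favours the
        smallest set that explains the phenotype.
        """
        key = tuple(sorted(set(snps)))
        hit = self._k2raw.get(key)
        if hit is not None:
            return hit
        self._compute(key)
        return self._k2raw[key]

    def g_test(self, snps) -> tuple[float, int, float]:
        key = tuple(sorted(set(snps)))
        hit = self._gtests.get(key)
        if hit is not None:
            return hit
        stat, _, _ = g_test_counts(self._counts(key))
        df = 3 ** len(key) - 1
        res = (stat, df, float(chi2.sf(stat, df)))
        self._gtests[key] = res
        return res
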