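import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2, power_divergence

from epissa.objectives import (
    DegenerateTableError,
    SampleTooSmallError,
    Scorer,
    auto_ml,
    auto_mo,
    ce_score,
    contingency,
    g_test,
    g_test_counts,
    gini_score,
    k2_score,
    truncate,
)
from conftest import make_dataset


# ---------------------------------------------------------------------------
# auto parameters


@pytest.mark.parametrize(
    "m0, m1, expected", [(800, 800, 6), (1868, 2938, 7), (20, 20, 2)]
)
def test_auto_mo(m0, m1, expected):
    assert auto_mo(m0, m1) == expected


@pytest.mark.parametrize(
    "m0, m1, expected", [(800, 800, 80), (1868, 2938, 186), (25, 99, 2)]
)
def test_auto_ml(m0, m1, expected):
    assert auto_ml(m0, m1) == expected


def test_auto_parameters_reject_tiny_samples():
    with pytest.raises(SampleTooSmallError):
        auto_mo(3, 3)
    with pytest.raises(SampleTooSmallError):
        auto_ml(15, 400)


# ---------------------------------------------------------------------------
# contingency tables


def test_contingency_constant_snp():
    ds = make_dataset([[0], [0], [0]], [0, 0, 1])
    t = contingency(ds, [0])
    assert t.n_cells == 1
    assert t.counts.tolist() == [[2, 1]]


def test_contingency_distinct_combos():
    ds = make_dataset([[0, 0], [0, 1], [1, 0], [2, 2]], [0, 0, 1, 1])
    t = contingency(ds, [0, 1])
    assert t.n_cells == 4
    assert (t.counts.sum(axis=1) == 1).all()


def test_contingency_conserves_class_totals(dnme_dataset):
    ds, _ = dnme_dataset
    t = contingency(ds, [0, 1, 2])
    assert t.counts[:, 0].sum() == ds.m0
    assert t.counts[:, 1].sum() == ds.m1


def test_contingency_rejects_empty():
    ds = make_dataset([[0]], [0])
    with pytest.raises(ValueError):
        contingency(ds, [])


def test_truncate_noop_below_cap():
    ds = make_dataset([[0, 0], [0, 1], [1, 0]], [0, 0, 1])
    t = contingency(ds, [0, 1])
    assert truncate(t, 5, "k2") is t


@pytest.mark.parametrize("objective", ["k2", "ce", "gini"])
def test_truncate_pools_weakest_and_conserves(objective, dnme_dataset):
    ds, _ = dnme_dataset
    t = contingency(ds, [0, 1, 2, 3])  # up to 81 combos
    ml = 5
    assert t.n_cells > ml
    tt = truncate(t, ml, objective)
    assert tt.n_cells <= ml
    assert tt.counts.shape[0] == ml - 1
    assert tt.total() == t.total()
    # per-class conservation through pooling
    assert tt.counts[:, 0].sum() + tt.pooled[0] == ds.m0
    assert tt.counts[:, 1].sum() + tt.pooled[1] == ds.m1


def test_truncate_retains_smallest_contributions():
    # 4 cells with hand-computable K2 contributions; cap at 3 keeps the 2 smallest
    geno = np.repeat([0, 1, 2], [8, 30, 30]).reshape(-1, 1)
    phen = np.array([0] * 8 + [0] * 15 + [1] * 15 + [0] * 15 + [1] * 15)
    # cell contributions: ln(9!/8!) tiny for the pure cell, large for split cells
    ds = make_dataset(geno, phen)
    t = contingency(ds, [0])
    tt = truncate(t, 2, "k2")
    # smallest-contribution cell is the pure (8, 0) one
    assert tt.counts.tolist() == [[8, 0]]
    assert tt.pooled == (30, 30)


# ---------------------------------------------------------------------------
# K2 / CE / Gini worked values


def test_k2_single_cell_split():
    ds = make_dataset([[0], [0]], [0, 1])
    assert k2_score(ds, [0]) == pytest.approx(math.log(6), abs=1e-12)


def test_k2_single_cell_pure():
    ds = make_dataset([[0], [0]], [0, 0])
    assert k2_score(ds, [0]) == pytest.approx(math.log(3), abs=1e-12)


def test_k2_prefers_separating_snp_over_permutation():
    rng = np.random.default_rng(5)
    geno = np.array([[0], [0], [0], [1], [1], [1], [2], [2], [0], [1]])
    phen = (geno[:, 0] > 0).astype(int)  # perfectly determined by the SNP
    ds = make_dataset(geno, phen)
    base = k2_score(ds, [0])
    for _ in range(20):
        perm = make_dataset(geno, rng.permutation(phen))
        assert base <= k2_score(perm, [0])


def test_ce_perfect_association_is_zero():
    ds = make_dataset([[0], [0], [1], [1]], [0, 0, 1, 1])
    assert ce_score(ds, [0]) == pytest.approx(0.0, abs=1e-12)


def test_ce_independent_balanced_is_ln2():
    ds = make_dataset([[0], [0], [1], [1]], [0, 1, 0, 1])
    assert ce_score(ds, [0]) == pytest.approx(math.log(2), abs=1e-12)


def test_gini_perfect_and_independent():
    perfect = make_dataset([[0], [0], [1], [1]], [0, 0, 1, 1])
    indep = make_dataset([[0], [0], [1], [1]], [0, 1, 0, 1])
    assert gini_score(perfect, [0]) == pytest.approx(0.0, abs=1e-12)
    assert gini_score(indep, [0]) == pytest.approx(0.5, abs=1e-12)


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=25, deadline=None)
def test_ce_gini_bounds_random_balanced(seed):
    rng = np.random.default_rng(seed)
    n = 12
    geno = rng.integers(0, 3, size=(n, 2))
    phen = np.repeat([0, 1], n // 2)
    ds = make_dataset(geno, phen)
    ce = ce_score(ds, [0, 1])
    gi = gini_score(ds, [0, 1])
    assert -1e-12 <= ce <= math.log(2) + 1e-12
    assert -1e-12 <= gi <= 0.5 + 1e-12


def test_all_objectives_minimal_on_perfect_separator():
    """On <= 12 samples, a separating combination beats every phenotype permutation."""
    from itertools import permutations

    geno = np.array([[0, 0], [0, 1], [1, 0], [1, 1], [2, 0], [2, 1]])
    phen = np.array([0, 0, 0, 1, 1, 1])
    ds = make_dataset(geno, phen)
    base = (ce_score(ds, [0, 1]), gini_score(ds, [0, 1]), k2_score(ds, [0, 1]))
    assert base[0] == pytest.approx(0.0, abs=1e-12)
    assert base[1] == pytest.approx(0.0, abs=1e-12)
    seen = set()
    for p in permutations(phen.tolist()):
        if p in seen:
            continue
        seen.add(p)
        alt = make_dataset(geno, np.array(p))
        assert ce_score(alt, [0, 1]) >= base[0] - 1e-12
        assert gini_score(alt, [0, 1]) >= base[1] - 1e-12
        assert k2_score(alt, [0, 1]) >= base[2] - 1e-12


def test_truncated_equals_untruncated_when_table_fits(dnme_dataset):
    ds, _ = dnme_dataset
    for snps in [[0], [1, 2], [3, 4]]:
        r = contingency(ds, snps).counts.shape[0]
        assert r <= 80
        assert k2_score(ds, snps, 80) == pytest.approx(k2_score(ds, snps), abs=1e-9)
        assert ce_score(ds, snps, 80) == pytest.approx(ce_score(ds, snps), abs=1e-9)
        assert gini_score(ds, snps, 80) == pytest.approx(gini_score(ds, snps), abs=1e-9)


def test_scores_finite_at_large_m():
    rng = np.random.default_rng(0)
    n = 100_000
    geno = rng.integers(0, 3, size=(n, 1), dtype=np.int8)
    phen = rng.integers(0, 2, size=n, dtype=np.int8)
    ds = make_dataset(geno, phen)
    assert np.isfinite(k2_score(ds, [0]))
    assert np.isfinite(ce_score(ds, [0]))
    assert np.isfinite(gini_score(ds, [0]))


# ---------------------------------------------------------------------------
# G-test


def test_g_test_independence_exact():
    stat, df, p = g_test_counts(np.array([[30, 30], [30, 30]]))
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_g_test_worked_example():
    stat, df, p = g_test_counts(np.array([[50, 10], [10, 50]]))
    assert stat == pytest.approx(58.2206332, abs=1e-6)
    assert df == 1
    assert p == pytest.approx(chi2.sf(stat, 1), rel=1e-12)


def test_g_test_monotone_in_statistic():
    stats = []
    for d in [0, 5, 10, 20]:
        s, df, p = g_test_counts(np.array([[30 + d, 30 - d], [30 - d, 30 + d]]))
        stats.append((s, p))
    for (s1, p1), (s2, p2) in zip(stats, stats[1:]):
        assert s2 > s1
        assert p2 < p1


def test_g_test_degenerate_tables():
    with pytest.raises(DegenerateTableError):
        g_test_counts(np.array([[10, 20]]))
    with pytest.raises(DegenerateTableError):
        g_test_counts(np.array([[10, 0], [20, 0]]))


@given(
    st.integers(2, 9),
    st.integers(0, 2**31 - 1),
)
@settings(max_examples=60, deadline=None)
def test_g_test_matches_scipy_oracle(rows, seed):
    """Randomized r x 2 integer tables agree with scipy's log-likelihood G-test."""
    rng = np.random.default_rng(seed)
    counts = rng.integers(0, 31, size=(rows, 2))
    counts = counts[counts.sum(axis=1) > 0]
    if counts.shape[0] < 2 or (counts.sum(axis=0) > 0).sum() < 2:
        return
    stat, df, p = g_test_counts(counts)
    col = counts.sum(axis=0)
    row = counts.sum(axis=1)
    expected = np.outer(row, col) / counts.sum()
    keep = expected > 0
    ref, _ = power_divergence(
        counts[keep], expected[keep], ddof=counts.size - 1 - df, lambda_="log-likelihood"
    )
    assert stat == pytest.approx(float(ref), rel=1e-10, abs=1e-10)
    assert p == pytest.approx(float(chi2.sf(ref, df)), rel=1e-9, abs=1e-12)


def test_g_test_on_dataset_statistic_matches_counts(dnme_dataset):
    """Same statistic as the generic table test; df spans the full 3^k space."""
    ds, _ = dnme_dataset
    stat, df, p = g_test(ds, [0, 1])
    t = contingency(ds, [0, 1])
    stat_c, df_c, _ = g_test_counts(t.counts)
    assert stat == pytest.approx(stat_c)
    assert df == 8  # (3^2 - 1) x (2 - 1), regardless of observed combos
    assert p == pytest.approx(chi2.sf(stat, 8))


def test_g_test_df_conservative_for_sparse_high_order(dnme_dataset):
    """A 6-SNP noise combination must not look significant just because its
    table fragments the sample into many small pure cells."""
    ds, truth = dnme_dataset
    functional = next(iter(truth.functional_sets))
    noise = [i for i, n in enumerate(ds.snp_names) if n not in functional][:6]
    stat, df, p = g_test(ds, noise)
    assert df == 3**6 - 1
    t = contingency(ds, noise)
    assert t.counts.shape[0] < df + 1  # genuinely sparse: many empty combos
    _, _, p_observed_df = g_test_counts(t.counts)
    assert p > p_observed_df
    assert p > 0.05


# ---------------------------------------------------------------------------
# memoization


def test_scorer_memoization_matches_direct(dnme_dataset):
    ds, _ = dnme_dataset
    sc = Scorer(ds, ml=80)
    for snps in [(3, 1), (1, 3), (5, 9, 2)]:
        s = sc.scores(snps)
        assert s.k2 == pytest.approx(k2_score(ds, set(snps), 80), abs=1e-9)
        assert s.ce == pytest.approx(ce_score(ds, set(snps), 80), abs=1e-9)
        assert s.gini == pytest.approx(gini_score(ds, set(snps), 80), abs=1e-9)
        assert sc.scores(snps) is s  # cached, order-insensitive
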