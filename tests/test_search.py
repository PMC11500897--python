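import numpy as np
import pytest

from epissa import SearchParams
from epissa.search import EpiSSA, spas_chaos, trim_population
from conftest import make_dataset


def small_engine(dnme_dataset, **kw):
    ds, _ = dnme_dataset
    defaults = dict(n=10, max_generations=3, seed=7)
    defaults.update(kw)
    e = EpiSSA(ds, SearchParams(**defaults))
    e.init_population()
    return e


def test_params_validation():
    with pytest.raises(ValueError):
        SearchParams(pd=0.0)
    with pytest.raises(ValueError):
        SearchParams(st=0.3)
    with pytest.raises(ValueError):
        SearchParams(n=2, sd=0.2)


def test_resolved_autofills(dnme_dataset):
    ds, _ = dnme_dataset
    p = SearchParams().resolved(ds)
    assert p.mo == 6
    assert p.ml == 80


def test_init_population_structure(dnme_dataset):
    e = small_engine(dnme_dataset)
    assert len(e.pop) == 10
    for s in e.pop:
        assert len(s.position) == 6
        assert len(set(s.position)) == 6
        assert all(0 <= i < 100 for i in s.position)


def test_init_population_deterministic(dnme_dataset):
    a = small_engine(dnme_dataset)
    b = small_engine(dnme_dataset)
    assert [s.position for s in a.pop] == [s.position for s in b.pop]


def test_init_population_forced_full_set():
    rng = np.random.default_rng(0)
    geno = rng.integers(0, 3, size=(40, 3), dtype=np.int8)
    phen = np.repeat([0, 1], 20)
    ds = make_dataset(geno, phen)
    e = EpiSSA(ds, SearchParams(n=10, max_generations=1, mo=3, ml=4, seed=0))
    e.init_population()
    for s in e.pop:
        assert sorted(s.position) == [0, 1, 2]


def test_infeasible_when_fewer_snps_than_order():
    rng = np.random.default_rng(0)
    ds = make_dataset(rng.integers(0, 3, size=(40, 2)), np.repeat([0, 1], 20))
    with pytest.raises(ValueError):
        EpiSSA(ds, SearchParams(n=10, mo=3, ml=4))


@pytest.mark.parametrize("op", ["update_producers", "update_scroungers"])
def test_updates_conserve_population_size(dnme_dataset, op):
    e = small_engine(dnme_dataset)
    getattr(e, op)()
    assert len(e.pop) == 10
    for s in e.pop:
        assert len(set(s.position)) == 6


def test_update_deterministic_under_seed(dnme_dataset):
    a = small_engine(dnme_dataset)
    b = small_engine(dnme_dataset)
    for e in (a, b):
        e.update_producers()
        e.update_scroungers()
    assert [s.position for s in a.pop] == [s.position for s in b.pop]


def test_best_ranksum_never_worsens_through_keep_better(dnme_dataset):
    e = small_engine(dnme_dataset)
    best_scores = e.pop.best.scores.as_tuple()
    for _ in range(5):
        e.update_producers()
        e.update_scroungers()
        new_best = e.pop.best.scores.as_tuple()
        # incumbent best can only be replaced by something at least as good in rank
        assert e.pop.best.rank_sum <= max(m.rank_sum for m in e.pop)
        best_scores = new_best


def test_spawn_scouts_grows_population(dnme_dataset):
    e = small_engine(dnme_dataset)
    e.spawn_scouts()
    assert len(e.pop) == 12  # n + floor(n * sd)


def test_scout_count_at_paper_settings(dnme_dataset):
    e = small_engine(dnme_dataset, n=20)
    e.spawn_scouts()
    assert len(e.pop) == 24


def test_pss_branch_forced_sampling(dnme_dataset):
    e = small_engine(dnme_dataset)
    e.pss[:] = 1e-12
    target = [3, 17, 42, 58, 76, 99]
    e.pss[target] = 1.0
    assert sorted(e._pss_position()) == target


def test_spas_chaos_values(dnme_dataset):
    e = small_engine(dnme_dataset, n=20)
    # all sparrows identical -> mo/(n*mo) = 1/n
    pos = e.pop.best.position
    for s in e.pop:
        s.position = pos
    assert spas_chaos(e.pop, 6) == pytest.approx(6 / 120)  # 0.05
    # pairwise disjoint positions -> 1.0
    for i, s in enumerate(e.pop.members[:16]):
        s.position = tuple(range(i * 6, i * 6 + 6))
    assert spas_chaos(RangeOnly(e.pop.members[:16]), 6) == pytest.approx(1.0)


class RangeOnly:
    """Minimal population view for spas_chaos."""

    def __init__(self, members):
        self.members = members

    def __len__(self):
        return len(self.members)

    def distinct_snps(self):
        out = set()
        for m in self.members:
            out.update(m.position)
        return out


def test_spas_chaos_bounds(dnme_dataset):
    e = small_engine(dnme_dataset)
    v = e.spas_chaos()
    assert 0 < v <= 1


def test_trim_restores_size_and_direction(dnme_dataset):
    e = small_engine(dnme_dataset)
    e.spawn_scouts()
    best = e.pop.best
    trim_population(e.pop, local_optimum=False, count=2)
    assert len(e.pop) == 10
    assert best in e.pop.members  # non-local-optimum trim keeps the best

    e.spawn_scouts()
    best = e.pop.best
    trim_population(e.pop, local_optimum=True, count=2)
    assert len(e.pop) == 10
    assert best not in e.pop.members  # local-optimum trim removes the best


def test_population_size_invariant_across_iterations(dnme_dataset):
    ds, _ = dnme_dataset
    e = EpiSSA(ds, SearchParams(n=10, max_generations=4, seed=1))
    e.init_population()
    for g in range(4):
        e.step(g)
        assert len(e.pop) == 10
        for s in e.pop:
            assert len(set(s.position)) == 6


def test_pss_monotone_decay_and_positive(dnme_dataset):
    ds, _ = dnme_dataset
    e = EpiSSA(ds, SearchParams(n=10, max_generations=6, seed=1))
    e.init_population()
    prev = e.pss.copy()
    for g in range(6):
        e.step(g)
        assert (e.pss <= prev + 1e-15).all()
        assert (e.pss > 0).all()
        prev = e.pss.copy()


def test_zero_generations_yields_no_findings(dnme_dataset):
    ds, _ = dnme_dataset
    from epissa.search import run

    assert run(ds, SearchParams(n=10, max_generations=0, seed=0)) == []


def test_full_run_deterministic(dnme_dataset):
    ds, _ = dnme_dataset
    from epissa.search import run

    p = SearchParams(n=10, max_generations=10, seed=5)
    a = run(ds, p)
    b = run(ds, p)
    assert [(f.snp_indices, f.p_value) for f in a] == [
        (f.snp_indices, f.p_value) for f in b
    ]


def test_run_finds_planted_pair(dnme_dataset):
    ds, truth = dnme_dataset
    from epissa.search import run

    findings = run(ds, SearchParams(n=20, max_generations=160, seed=0))
    names = {frozenset(f.snp_names) for f in findings}
    assert frozenset({"M0P0", "M0P1"}) in names
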