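"""The sparrow-search engine for epistatic-interaction detection.

The population holds ``n`` candidate SNP combinations ("sparrows"), each a
vector of ``mo`` distinct SNP indices, ordered by the rankSum aggregation of
the K2 / CE / Gini objectives.  Every generation:

1. *Producers* (the best ``floor(pd*n)`` members) each propose a mutant —
   one random position replaced in the safe regime (a single uniform draw
   ``r < st`` per pass), ``floor(mo/2)`` positions otherwise — and the worse
   of original/proposal is discarded.
2. *Scroungers* (the rest) either cross over with a randomly chosen good
   producer (first half of the population) or are redrawn from the pss
   weight vector (second half), again keep-the-better.
3. *Scouts*: ``floor(n*sd)`` randomly selected members each spawn one new
   sparrow (pss draw for the incumbent best, crossover with a strictly
   better producer otherwise); all are added, growing the population.
4. The best ``floor(n*sd)`` combinations are purified and tested for
   significance (see :mod:`epissa.detection`); the pss weights of every
   examined vector's SNPs decay by 0.9, pushing later sampling toward
   unexplored SNPs.
5. If the proportion of distinct SNPs in the population (spasChaos) falls
   below a threshold the search is deemed stuck in a local optimum and the
   *best* ``floor(n*sd)`` members are removed, otherwise the worst, restoring
   size ``n``.

After the final generation the accumulated findings pass the iBiggest
false-positive filter and are returned sorted by p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .detection import EpistasisFinding, detect_in_population, filter_findings
from .io import Dataset
from .objectives import Scorer, auto_ml, auto_mo
from .ranking import RankedPopulation

__all__ = [
    "SearchParams",
    "Sparrow",
    "init_population",
    "update_producers",
    "update_scroungers",
    "spawn_scouts",
    "spas_chaos",
    "trim_population",
    "run",
    "EpiSSA",
]


@dataclass(frozen=True)
class SearchParams:
    """Tunable parameters of the search.

    ``mo = 0`` and ``ml = 0`` mean "derive from the sample counts" via the
    auto-parameter rules; all other defaults follow the method's standard
    settings.
    """

    n: int = 20
    max_generations: int = 160
    pd: float = 0.4
    sd: float = 0.2
    st: float = 0.8
    mo: int = 0
    ml: int = 0
    cg: float = 0.05
    threshold_spas_chaos: float = 0.6
    seed: int = 0
    bonferroni: bool = False  # divide cG by C(N, |R|) per purified set size

    def __post_init__(self):
        if not (0.0 < self.pd < 1.0):
            raise ValueError("pd must be in (0, 1)")
        if not (0.0 < self.sd < 1.0):
            raise ValueError("sd must be in (0, 1)")
        if not (0.5 <= self.st <= 1.0):
            raise ValueError("st must be in [0.5, 1]")
        if int(self.n * self.pd) < 1 or int(self.n * self.sd) < 1:
            raise ValueError("n*pd and n*sd must be >= 1")

    def resolved(self, dataset: Dataset) -> "SearchParams":
        """Fill mo/ml from the dataset when left at 0."""
        mo = self.mo or auto_mo(dataset.m0, dataset.m1)
        ml = self.ml or auto_ml(dataset.m0, dataset.m1)
        if mo < 1:
            raise ValueError("mo must be >= 1")
        if int(self.n * self.pd) < 2:
            raise ValueError("need at least 2 producers (n*pd >= 2)")
        return replace(self, mo=mo, ml=ml)


@dataclass(eq=False)  # identity semantics: equal-looking sparrows are distinct birds
class Sparrow:
    """A candidate SNP combination: ``mo`` distinct indices plus cached scores."""

    position: tuple[int, ...]
    scores: object
    counter: int
    rank_sum: int = 0
    ranks: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self):
        if len(set(self.position)) != len(self.position):
            raise ValueError("position indices must be distinct")


class EpiSSA:
    """One search run bound to a dataset; drives all randomness from one RNG."""

    def __init__(self, dataset: Dataset, params: SearchParams):
        self.dataset = dataset
        self.params = params.resolved(dataset)
        if dataset.n_snps < self.params.mo:
            raise ValueError(
                f"dataset has {dataset.n_snps} SNPs < order {self.params.mo}"
            )
        self.rng = np.random.default_rng(self.params.seed)
        self.scorer = Scorer(dataset, ml=self.params.ml)
        self.pss = np.ones(dataset.n_snps, dtype=np.float64)
        self.store: dict[frozenset[int], EpistasisFinding] = {}
        self._counter = 0
        self.pop = RankedPopulation()

    # -- construction helpers ------------------------------------------------

    def _new_sparrow(self, position) -> Sparrow:
        pos = tuple(int(i) for i in position)
        s = Sparrow(position=pos, scores=self.scorer.scores(pos), counter=self._counter)
        self._counter += 1
        return s

    def _random_position(self) -> tuple[int, ...]:
        return tuple(
            self.rng.choice(self.dataset.n_snps, size=self.params.mo, replace=False)
        )

    def _pss_position(self) -> tuple[int, ...]:
        from ._kernels import weighted_sample_noreplace

        mo = self.params.mo
        draw = weighted_sample_noreplace(self.pss, mo, self.rng.random(mo))
        return tuple(int(i) for i in draw)

    def _mutate(self, position: tuple[int, ...], n_positions: int) -> tuple[int, ...]:
        """Replace ``n_positions`` random slots with fresh SNPs, keeping all distinct."""
        pos = list(position)
        slots = self.rng.choice(len(pos), size=n_positions, replace=False)
        for j in slots:
            while True:
                s = int(self.rng.integers(self.dataset.n_snps))
                if s not in pos:
                    pos[j] = s
                    break

        return tuple(pos)

    def _crossover(self, a: tuple[int, ...], b: tuple[int, ...]) -> tuple[int, ...]:
        """floor(mo/2) SNPs from ``a`` plus the rest from ``b``, all distinct."""
        mo = self.params.mo
        half = mo // 2
        take_a = self.rng.choice(len(a), size=half, replace=False)
        new = [a[i] for i in take_a]
        chosen = set(new)
        for i in self.rng.permutation(len(b)):
            if len(new) == mo:
                break
            s = b[i]
            if s not in chosen:
                new.append(s)
                chosen.add(s)
        if len(new) < mo:  # heavy overlap: fill from the union of both parents
            union = [s for s in set(a) | set(b) if s not in chosen]
            for i in self.rng.permutation(len(union)):
                if len(new) == mo:
                    break
                new.append(union[i])
        return tuple(new)

    def _keep_better(self, incumbent: Sparrow, proposal: tuple[int, ...]) -> None:
        """Insert the proposal, re-rank, and discard the worse of the pair.

        Ties (equal rankSum) keep the incumbent.
        """
        snap = self.pop.snapshot()
        new = self._new_sparrow(proposal)
        self.pop.add(new)
        if new.rank_sum < incumbent.rank_sum:
            self.pop.remove(incumbent)
        else:
            self.pop.reject_last(new, snap)

    # -- one generation ------------------------------------------------------

    def init_population(self) -> None:
        sparrows = [self._new_sparrow(self._random_position()) for _ in range(self.params.n)]
        self.pop = RankedPopulation(sparrows)

    def update_producers(self) -> None:
        p = self.params
        producers = list(self.pop.members[: int(p.pd * p.n)])
        safe = self.rng.random() < p.st
        n_repl = 1 if safe else max(1, p.mo // 2)
        for sparrow in producers:
            self._keep_better(sparrow, self._mutate(sparrow.position, n_repl))

    def update_scroungers(self) -> None:
        p = self.params
        n_prod = int(p.pd * p.n)
        snapshot = list(self.pop.members)
        producers = snapshot[:n_prod]
        for i in range(n_prod, p.n):
            sparrow = snapshot[i]
            if i < p.n // 2:
                pick = self.rng.choice(n_prod, size=2, replace=False)
                pa, pb = producers[pick[0]], producers[pick[1]]
                best_prod = pa if pa.rank_sum <= pb.rank_sum else pb
                proposal = self._crossover(sparrow.position, best_prod.position)
            else:
                proposal = self._pss_position()
            self._keep_better(sparrow, proposal)

    def spawn_scouts(self) -> None:
        p = self.params
        k = int(p.n * p.sd)
        snapshot = list(self.pop.members)
        producers = snapshot[: int(p.pd * p.n)]
        chosen = self.rng.choice(len(snapshot), size=k, replace=False)
        new_positions = []
        for idx in chosen:
            a = snapshot[idx]
            if idx == 0:
                new_positions.append(self._pss_position())
            else:
                better = [b for b in producers if b.rank_sum < a.rank_sum]
                if better:
                    b = better[int(self.rng.integers(len(better)))]
                    new_positions.append(self._crossover(a.position, b.position))
                else:
                    new_positions.append(self._pss_position())
        for pos in new_positions:
            self.pop.add(self._new_sparrow(pos), refresh=False)
        self.pop.refresh()

    def spas_chaos(self) -> float:
        return spas_chaos(self.pop, self.params.mo)

    def trim(self) -> None:
        k = len(self.pop) - self.params.n
        local_optimum = self.spas_chaos() < self.params.threshold_spas_chaos
        trim_population(self.pop, local_optimum, k)

    def step(self, iteration: int = 0) -> None:
        self.update_producers()
        self.update_scroungers()
        self.spawn_scouts()
        detect_in_population(
            self.pop, self.params, self.pss, self.store, self.scorer, iteration
        )
        self.trim()

    def run(self) -> list[EpistasisFinding]:
        self.init_population()
        for g in range(self.params.max_generations):
            self.step(g)
        names = self.dataset.snp_names
        findings = [f.named(names) for f in self.store.values()]
        return filter_findings(findings)


# ---------------------------------------------------------------------------
# functional API


def init_population(params: SearchParams, dataset: Dataset, rng=None) -> RankedPopulation:
    engine = EpiSSA(dataset, params)
    if rng is not None:
        engine.rng = rng
    engine.init_population()
    return engine.pop


def update_producers(engine: EpiSSA) -> None:
    engine.update_producers()


def update_scroungers(engine: EpiSSA) -> None:
    engine.update_scroungers()


def spawn_scouts(engine: EpiSSA) -> None:
    engine.spawn_scouts()


def spas_chaos(pop, mo: int) -> float:
    """Proportion of distinct SNPs in the population: |distinct| / (n * mo)."""
    if len(pop) == 0:
        raise ValueError("empty population")
    return len(pop.distinct_snps()) / (len(pop) * mo)


def trim_population(pop, local_optimum: bool, count: int) -> None:
    """Remove ``count`` members: the best-ranked on a local optimum, else the worst."""
    if count <= 0:
        return
    doomed = pop.members[:count] if local_optimum else pop.members[-count:]
    for m in list(doomed):
        pop.remove(m, refresh=False)
    pop.refresh()


def run(dataset: Dataset, params: SearchParams) -> list[EpistasisFinding]:
    """Run the full search on ``dataset``; deterministic given ``params.seed``."""
    return EpiSSA(dataset, params).run()
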