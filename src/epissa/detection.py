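"""Extraction of disease-associated SNP sets from good candidate combinations.

A candidate position vector of length ``mo`` usually mixes a true interacting
set with noise SNPs.  ``eliminate_noise`` strips the noise by greedy backward
K2 descent: a SNP is removable when deleting it does not increase the K2
objective.  Surviving sets of size >= 2 are gated by the G-test at the
significance threshold ``cG`` and recorded (deduplicated on the SNP set).
After the search, ``filter_findings`` cuts the p-sorted result list at the
largest jump in consecutive p-value ratios (the iBiggest rule), discarding the
weak tail as likely false positives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .objectives import DegenerateTableError, Scorer

__all__ = [
    "EpistasisFinding",
    "eliminate_noise",
    "detect_in_population",
    "filter_findings",
]


@dataclass(frozen=True)
class EpistasisFinding:
    """A deduplicated SNP set with its G-test p-value."""

    snp_indices: frozenset[int]
    p_value: float
    statistic: float = math.nan
    df: int = 0
    first_iteration: int = 0
    snp_names: tuple[str, ...] = field(default_factory=tuple)

    def named(self, snp_names: list[str]) -> "EpistasisFinding":
        names = tuple(sorted(snp_names[i] for i in self.snp_indices))
        return EpistasisFinding(
            self.snp_indices, self.p_value, self.statistic, self.df,
            self.first_iteration, names,
        )


def eliminate_noise(snps, scorer: Scorer) -> frozenset[int]:
    """Greedy backward K2 noise elimination.

    Repeatedly removes the single SNP whose deletion yields the lowest K2 of
    the remainder, as long as that K2 does not exceed the current set's K2
    (noise SNPs leave K2 unchanged or lower when dropped).  Ties break toward
    the lowest SNP index.  Stops at a local minimum or at size 1.

    The *untruncated* K2 is used: sets of different sizes are compared here,
    and the table-cap truncation (built to compare equal-length position
    vectors fairly) would let larger sets keep only their purest cells,
    masking weak interactions.
    """
    current = set(snps)
    if not current:
        raise ValueError("empty SNP set")
    while len(current) > 1:
        base = scorer.k2_raw(current)
        best_k2 = math.inf
        best_snp = None
        for x in sorted(current):
            rest = current - {x}
            k2r = scorer.k2_raw(rest)
            if k2r < best_k2:
                best_k2 = k2r
                best_snp = x
        if best_k2 <= base:
            current.discard(best_snp)
        else:
            break
    return frozenset(current)


def detect_in_population(
    pop,
    params,
    pss: np.ndarray,
    store: dict[frozenset[int], EpistasisFinding],
    scorer: Scorer,
    iteration: int = 0,
) -> None:
    """Run noise elimination + G-test gating on the top ``floor(n*sd)`` members.

    Significant purified sets (size >= 2, p <= cG) are added to ``store``
    (first-seen record kept); with ``params.bonferroni`` the threshold for a
    purified set R is cG / C(N, |R|), correcting for the number of candidate
    sets of that size.  The pss weight of every SNP in each *examined*
    position vector decays by the factor 0.9 — every iteration, recorded or
    not — steering later pss-guided sampling away from regions the search has
    already focused on.  This continuous decay is what keeps the search
    covering new SNPs on large panels.
    """
    k = int(params.n * params.sd)
    n_snps = scorer.dataset.n_snps
    for sparrow in pop.members[:k]:
        purified = eliminate_noise(sparrow.position, scorer)
        if len(purified) >= 2:
            try:
                stat, df, p = scorer.g_test(purified)
            except DegenerateTableError:
                stat = df = None
                p = 1.0
            threshold = params.cg
            if getattr(params, "bonferroni", False):
                threshold = params.cg / math.comb(n_snps, len(purified))
            if p <= threshold and purified not in store:
                store[purified] = EpistasisFinding(
                    snp_indices=purified,
                    p_value=p,
                    statistic=stat,
                    df=df,
                    first_iteration=iteration,
                )
        idx = list(sparrow.position)
        # floor keeps weights strictly positive through very long runs
        pss[idx] = np.maximum(pss[idx] * 0.9, 1e-300)


def filter_findings(findings) -> list[EpistasisFinding]:
    """Cut the p-sorted finding list at the largest consecutive p-value ratio.

    With findings sorted ascending by p (1-based positions), the ratio
    ``p_i / p_{i-1}`` is computed for i in [2, ne] (conventions 0/0 := 1 and
    x/0 := inf) and the list is cut just before the *largest* position
    attaining the maximum ratio; everything from that position on is dropped
    as noise.  Lists of at most two findings are returned whole.
    """
    findings = sorted(
        findings,
        key=lambda f: (f.p_value, len(f.snp_indices), f.snp_names, sorted(f.snp_indices)),
    )
    ne = len(findings)
    if ne <= 2:
        return findings
    ratios = []
    for i in range(1, ne):
        prev, cur = findings[i - 1].p_value, findings[i].p_value
        if prev == 0.0:
            ratios.append(1.0 if cur == 0.0 else math.inf)
        else:
            ratios.append(cur / prev)
    biggest = max(ratios)
    # largest 1-based position i attaining the max ratio; retain more on ties
    i_biggest = max(i + 2 for i, r in enumerate(ratios) if r == biggest)
    return findings[: i_biggest - 1]
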