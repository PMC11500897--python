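"""Rank aggregation of the three objectives into the rankSum ordering.

Each member of the population is ranked independently under K2, CE and Gini
(competition ranking: equal scores share a rank, rank = 1 + number of strictly
better members) and the three ranks are summed into ``rankSum``.  All selection
decisions in the search are driven by rankSum; ties are broken by the raw K2
score and then by insertion order, which makes runs reproducible.
"""

from __future__ import annotations

import numpy as np

__all__ = ["assign_ranks", "sort_population", "RankedPopulation"]


def sort_population(pop: "RankedPopulation") -> "RankedPopulation":
    """Re-rank and re-sort in place; idempotent on an already-sorted population."""
    pop.refresh()
    return pop


def assign_ranks(scores) -> tuple[np.ndarray, np.ndarray]:
    """Competition ranks per objective and their sum.

    Parameters
    ----------
    scores
        Sequence of (k2, ce, gini) triples or objects with ``as_tuple()``.

    Returns
    -------
    ranks : (n, 3) int array, rank 1 = lowest (strongest) score
    rank_sum : (n,) int array
    """
    rows = [s.as_tuple() if hasattr(s, "as_tuple") else tuple(s) for s in scores]
    if not rows:
        raise ValueError("empty score list")
    arr = np.asarray(rows, dtype=np.float64)
    if not np.isfinite(arr).all():
        raise ValueError("scores must be finite")
    ranks = np.empty(arr.shape, dtype=np.int64)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        ranks[:, j] = np.searchsorted(np.sort(col), col, side="left") + 1
    return ranks, ranks.sum(axis=1)


class RankedPopulation:
    """An ordered population of candidates ranked by rankSum.

    Members are any objects exposing ``scores`` (with ``as_tuple()``) and a
    ``counter`` attribute (insertion order).  After every structural change,
    :meth:`refresh` recomputes all ranks over the full population and sorts
    ascending by ``(rankSum, k2, counter)``; each member's current ``rank_sum``
    is stored on the member itself.
    """

    def __init__(self, members=()):
        self.members: list = []
        self._buf = np.empty((64, 4), dtype=np.float64)  # k2, ce, gini, counter
        self._rowmem: list = [None] * 64
        self._size = 0
        for m in members:
            self._add_row(m)
        if self.members:
            self.refresh()

    def _add_row(self, member) -> None:
        if self._size == self._buf.shape[0]:
            self._buf = np.vstack([self._buf, np.empty_like(self._buf)])
            self._rowmem.extend([None] * (len(self._rowmem)))
        r = self._size
        s = member.scores
        self._buf[r, 0] = s.k2
        self._buf[r, 1] = s.ce
        self._buf[r, 2] = s.gini
        self._buf[r, 3] = member.counter
        self._rowmem[r] = member
        member._row = r
        self._size += 1
        self.members.append(member)

    def _drop_row(self, member) -> None:
        r = member._row
        last = self._size - 1
        if r != last:
            self._buf[r] = self._buf[last]
            moved = self._rowmem[last]
            self._rowmem[r] = moved
            moved._row = r
        self._rowmem[last] = None
        self._size -= 1
        self.members.remove(member)

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def __getitem__(self, i):
        return self.members[i]

    @property
    def best(self):
        return self.members[0]

    def refresh(self) -> None:
        if not self._size:
            raise ValueError("empty population")
        from ._kernels import rank_and_order

        n = self._size
        view = self._buf[:n]
        ranks, rank_sum, order = rank_and_order(view[:, :3], view[:, 3])
        rk = ranks.tolist()
        rs = rank_sum.tolist()
        rowmem = self._rowmem
        for i in range(n):
            m = rowmem[i]
            m.ranks = tuple(rk[i])
            m.rank_sum = rs[i]
        self.members = [rowmem[i] for i in order]

    def add(self, member, refresh: bool = True) -> None:
        self._add_row(member)
        if refresh:
            self.refresh()

    def remove(self, member, refresh: bool = True) -> None:
        self._drop_row(member)
        if refresh:
            self.refresh()

    def snapshot(self):
        """Capture (order, rank attrs) so a rejected insertion can be undone."""
        order = self.members[:]
        return order, [(m.rank_sum, m.ranks) for m in order]

    def reject_last(self, member, snapshot) -> None:
        """Drop ``member`` (the most recent insertion) and restore the exact
        pre-insertion rank state without recomputing — removing the inserted
        row provably returns the population to the snapshotted state."""
        self._drop_row(member)
        order, attrs = snapshot
        self.members = order[:]
        for m, (rs, rk) in zip(order, attrs):
            m.rank_sum = rs
            m.ranks = rk

    def distinct_snps(self) -> set[int]:
        out: set[int] = set()
        for m in self.members:
            out.update(m.position)
        return out
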