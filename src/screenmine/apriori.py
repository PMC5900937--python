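"""Frequent-itemset mining with a minimum-support threshold.

Apriori proceeds level-wise: frequent singletons first, then candidate
k-itemsets joined from frequent (k-1)-itemsets, pruning any candidate with
an infrequent subset (downward closure). Support is the proportion of
transactions containing every member item, and the threshold comparison is
inclusive (support == min_support is kept). With only a handful of items per
transaction matrix, supports are counted by intersecting boolean indicator
columns; no transaction-list compression is attempted.

``brute_force_itemsets`` enumerates every nonempty subset directly and is
the independent oracle the test suite checks ``apriori`` against.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .transactions import TransactionMatrix

__all__ = ["FrequentItemSetTable", "apriori", "brute_force_itemsets"]


@dataclass(frozen=True)
class FrequentItemSetTable:
    """Frequent itemsets with supports, in canonical (size, lexicographic) order."""

    entries: tuple[tuple[frozenset[str], float], ...]
    min_support: float

    def support(self, items: frozenset[str] | set[str] | tuple[str, ...]) -> float:
        key = frozenset(items)
        for itemset, s in self.entries:
            if itemset == key:
                return s
        raise KeyError(f"itemset {sorted(key)} not frequent at σ={self.min_support}")

    def itemsets(self) -> list[frozenset[str]]:
        return [s for s, _ in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "itemset": [";".join(sorted(s)) for s, _ in self.entries],
                "support": [sup for _, sup in self.entries],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _canonical(entries: dict[frozenset[str], float], min_support: float) -> FrequentItemSetTable:
    ordered = sorted(entries.items(), key=lambda e: (len(e[0]), tuple(sorted(e[0]))))
    return FrequentItemSetTable(tuple(ordered), min_support)


def _support_column(T: TransactionMatrix, items: tuple[str, ...]) -> float:
    mask = np.ones(T.n, dtype=bool)
    for item in items:
        mask &= T.column(item).astype(bool)
    return mask.sum() / T.n


def apriori(T: TransactionMatrix, min_support: float) -> FrequentItemSetTable:
    """Level-wise frequent-itemset mining at inclusive threshold ``min_support``."""
    if not 0 < min_support <= 1:
        raise ValueError("min_support must lie in (0, 1]")
    if T.n == 0:
        raise ValueError("empty transaction matrix")

    cols = {item: T.column(item).astype(bool) for item in T.items}
    n = T.n
    frequent: dict[frozenset[str], float] = {}

    # Level 1: frequent singletons, in lexicographic item order.
    level: dict[tuple[str, ...], np.ndarray] = {}
    for item in sorted(T.items):
        s = cols[item].sum() / n
        if s >= min_support:
            frequent[frozenset((item,))] = s
            level[(item,)] = cols[item]

    k = 1
    while level:
        keys = sorted(level)
        next_level: dict[tuple[str, ...], np.ndarray] = {}
        for a, b in itertools.combinations(keys, 2):
            if a[:-1] != b[:-1]:  # join step: share the first k-1 items
                continue
            candidate = a + (b[-1],)
            # Prune: every (k)-subset must itself be frequent.
            if any(
                frozenset(candidate[:i] + candidate[i + 1:]) not in frequent
                for i in range(len(candidate))
            ):
                continue
            mask = level[a] & cols[b[-1]]
            s = mask.sum() / n
            if s >= min_support:
                frequent[frozenset(candidate)] = s
                next_level[candidate] = mask
        level = next_level
        k += 1

    return _canonical(frequent, min_support)


def brute_force_itemsets(T: TransactionMatrix, min_support: float) -> FrequentItemSetTable:
    """Exhaustive enumeration oracle; refuses matrices with more than 16 items."""
    if T.m > 16:
        raise ValueError("brute-force enumeration limited to 16 items")
    if not 0 < min_support <= 1:
        raise ValueError("min_support must lie in (0, 1]")
    if T.n == 0:
        raise ValueError("empty transaction matrix")
    frequent: dict[frozenset[str], float] = {}
    for size in range(1, T.m + 1):
        for combo in itertools.combinations(sorted(T.items), size):
            s = _support_column(T, combo)
            if s >= min_support:
                frequent[frozenset(combo)] = s
    return _canonical(frequent, min_support)
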