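"""Frequent-itemset mining on a software-emulated systolic prefix tree.

Transactions are inserted (WRITE mode) into a tree of processing-element
nodes linked leftmost-child / right-sibling, with items placed in a
canonical frequency order so shared prefixes collapse into shared paths.
Candidate supports are read back by tree traversal (SCAN/COUNT modes), and
`mine_frequent` drives a level-wise candidate generation over those counts.
`apriori_oracle` recomputes the same answer by direct subset testing over
the raw transactions and exists purely as an independent check.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Iterator, Sequence


class PEMode(Enum):
    WRITE = "WRITE"
    SCAN = "SCAN"
    COUNT = "COUNT"


class TransactionDB:
    """An ordered collection of duplicate-free itemsets."""

    def __init__(self, transactions: Iterable[Iterable[str]]):
        self.transactions: list[frozenset[str]] = [frozenset(t) for t in transactions]

    def __eq__(self, other: object) -> bool:
        return (isinstance(other, TransactionDB)
                and self.transactions == other.transactions)

    def __repr__(self) -> str:
        return f"TransactionDB({self.transactions!r})"

    def __len__(self) -> int:
        return len(self.transactions)

    def __iter__(self) -> Iterator[frozenset[str]]:
        return iter(self.transactions)

    @property
    def items(self) -> set[str]:
        out: set[str] = set()
        for t in self.transactions:
            out |= t
        return out


@dataclass
class PENode:
    """One processing element: an item slot, a support count, tree links."""

    item: str | None = None  # None marks the control (root) node
    count: int = 0
    level: int = 0
    leftmost_child: "PENode | None" = None
    right_sibling: "PENode | None" = None
    mode: PEMode = PEMode.WRITE

    def children(self) -> Iterator["PENode"]:
        child = self.leftmost_child
        while child is not None:
            yield child
            child = child.right_sibling

    def find_child(self, item: str) -> "PENode | None":
        for child in self.children():
            if child.item == item:
                return child
        return None

    def n_nodes(self) -> int:
        return 1 + sum(c.n_nodes() for c in self.children())


@dataclass(frozen=True)
class ItemsetResult:
    itemset: frozenset[str]
    support: int


def order_items(db: TransactionDB) -> list[str]:
    """Canonical item order: descending support, ties lexicographic."""
    if len(db) == 0:
        raise ValueError("transaction database is empty")
    counts: dict[str, int] = {}
    for t in db:
        for item in t:
            counts[item] = counts.get(item, 0) + 1
    return sorted(counts, key=lambda it: (-counts[it], it))


def build_tree(db: TransactionDB) -> PENode:
    """WRITE mode: insert each transaction as a root path in canonical order.

    Node counts equal the number of transactions whose ordered form passes
    through the node, i.e. shares the root-to-node prefix.
    """
    order = order_items(db)
    rank = {item: k for k, item in enumerate(order)}
    root = PENode(item=None, level=0)
    for t in db:
        root.count += 1  # control node tracks total transactions seen
        node = root
        for item in sorted(t, key=rank.__getitem__):
            child = node.find_child(item)
            if child is None:
                child = PENode(item=item, level=node.level + 1)
                # append as rightmost sibling to keep insertion order stable
                if node.leftmost_child is None:
                    node.leftmost_child = child
                else:
                    last = node.leftmost_child
                    while last.right_sibling is not None:
                        last = last.right_sibling
                    last.right_sibling = child
            child.count += 1
            node = child
    return root


def count_support(root: PENode, candidate: Iterable[str],
                  _rank: dict[str, int] | None = None) -> int:
    """SCAN/COUNT modes: transactions containing ``candidate`` as a subset.

    Because both tree paths and candidates use the same canonical order,
    subset containment becomes subsequence matching along root paths. The
    count of a node covers every transaction routed through it, and for a
    fixed transaction the deepest matched candidate item is unique, so
    summing over full matches never double-counts.
    """
    cand = set(candidate)
    if not cand:
        return root.count  # every transaction contains the empty set
    total = 0
    stack: list[tuple[PENode, int]] = [(root, 0)]
    # order candidate items by tree level via first occurrence search; the
    # canonical rank is implied by the tree, so we just match set membership
    # and require all items found on the path.
    remaining0 = len(cand)
    while stack:
        node, matched = stack.pop()
        if node.item is not None and node.item in cand:
            matched += 1
            if matched == remaining0:
                total += node.count
                continue
        for child in node.children():
            stack.append((child, matched))
    return total


def mine_frequent(db: TransactionDB, min_support: int) -> list[ItemsetResult]:
    """All itemsets with support >= ``min_support``, with exact supports.

    Level-wise candidate generation; every candidate's support is obtained
    from the systolic tree (``count_support``), not from the raw
    transactions. Output sorted by (size, lexicographic items).
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    if len(db) == 0 or not db.items:
        return []
    root = build_tree(db)
    items = sorted(db.items)
    results: list[ItemsetResult] = []
    current: list[frozenset[str]] = []
    for it in items:
        s = count_support(root, [it])
        if s >= min_support:
            fs = frozenset([it])
            current.append(fs)
            results.append(ItemsetResult(fs, s))
    k = 1
    while current:
        candidates = _candidate_gen(current, k)
        nxt: list[frozenset[str]] = []
        for cand in candidates:
            s = count_support(root, cand)
            if s >= min_support:
                nxt.append(cand)
                results.append(ItemsetResult(cand, s))
        current = nxt
        k += 1
    results.sort(key=lambda r: (len(r.itemset), tuple(sorted(r.itemset))))
    return results


def _candidate_gen(frequent_k: list[frozenset[str]], k: int) -> list[frozenset[str]]:
    """Join step with the standard prune: all k-subsets must be frequent."""
    freq = set(frequent_k)
    seen: set[frozenset[str]] = set()
    out: list[frozenset[str]] = []
    for a, b in itertools.combinations(frequent_k, 2):
        union = a | b
        if len(union) != k + 1 or union in seen:
            continue
        seen.add(union)
        if all(union - {x} in freq for x in union):
            out.append(union)
    return out


def apriori_oracle(db: TransactionDB, min_support: int) -> list[ItemsetResult]:
    """Independent oracle: enumerate every non-empty subset of the universe
    and count containment directly over the transactions. Exponential in the
    number of distinct items; intended for small test databases only.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    universe = sorted(db.items)
    results: list[ItemsetResult] = []
    for r in range(1, len(universe) + 1):
        for combo in itertools.combinations(universe, r):
            cand = frozenset(combo)
            s = sum(1 for t in db if cand <= t)
            if s >= min_support:
                results.append(ItemsetResult(cand, s))
    results.sort(key=lambda r_: (len(r_.itemset), tuple(sorted(r_.itemset))))
    return results


def support_map(results: Sequence[ItemsetResult]) -> dict[frozenset[str], int]:
    return {r.itemset: r.support for r in results}


def patterns_as_item_features(results: Sequence[ItemsetResult],
                              item_ids: Sequence[str]) -> "tuple":
    """Binary item x pattern membership matrix from mined itemsets.

    Each mined pattern becomes one binary feature; an item gets 1 when it
    participates in the pattern. Returns (matrix, pattern list).
    """
    import numpy as np

    patterns = [r.itemset for r in results]
    mat = np.zeros((len(item_ids), len(patterns)), dtype=float)
    index = {it: i for i, it in enumerate(item_ids)}
    for j, pat in enumerate(patterns):
        for it in pat:
            if it in index:
                mat[index[it], j] = 1.0
    return mat, patterns
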