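"""Level-wise Apriori frequent-itemset mining and association-rule generation.

Transactions are the cleaned cases flattened into itemsets of herbs and/or
symptoms. Rules are reported with the three standard metrics

    support(L -> R)    = P(L ∪ R)          (proportion of transactions)
    confidence(L -> R) = P(L ∪ R) / P(L)
    lift(L -> R)       = confidence / P(R) (1 = independence)

and a rule is accepted when support >= 10%, confidence >= 50% and
lift >= 1.2 (the default thresholds; all cuts inclusive). "Second-order"
rules are 1 -> 1, "third-order" rules 2 -> 1, drawn from frequent itemsets
only. ``brute_force_rules`` re-derives the same output by exhaustive
enumeration with no pruning and serves as the correctness oracle in tests.

Support counting is vectorised over a boolean transaction x item matrix, so
mining stays fast at tens of thousands of transactions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Literal, Sequence

import numpy as np

from .records import CleanCase

Item = tuple[str, str]  # (name, class) with class in {"herb", "symptom"}


class MiningError(ValueError):
    pass


@dataclass(frozen=True)
class Transaction:
    case_id: str
    items: frozenset[Item]

    def __post_init__(self) -> None:
        if not self.items:
            raise MiningError(f"empty transaction for case {self.case_id!r}")


@dataclass(frozen=True)
class ItemsetSupport:
    itemset: tuple[str, ...]  # sorted item names
    count: int
    support: float


@dataclass(frozen=True)
class AssociationRule:
    lhs: tuple[str, ...]  # sorted names ("preceding")
    rhs: tuple[str, ...]  # sorted names ("following")
    support: float
    confidence: float
    lift: float
    co_count: int


@dataclass(frozen=True)
class MiningThresholds:
    """Acceptance cuts for emitted rules; defaults are the 10% / 50% / 1.2
    support / confidence / lift thresholds, plus a minimum absolute
    co-occurrence count."""

    min_support: float = 0.10
    min_confidence: float = 0.50
    min_lift: float = 1.2
    min_count: int = 1

    def __post_init__(self) -> None:
        if min(self.min_support, self.min_confidence, self.min_lift) < 0:
            raise MiningError("thresholds must be nonnegative")
        if self.min_count < 0:
            raise MiningError("min_count must be nonnegative")


def build_transactions(
    cases: Sequence[CleanCase],
    include: Literal["herbs", "symptoms", "both"] = "both",
) -> list[Transaction]:
    """One transaction per case, restricted to herbs, symptoms or both.

    Herb-only transactions drive the pairwise herb-compatibility analysis;
    mixed transactions drive the herb-symptom analysis. Cases empty under the
    restriction are dropped.
    """
    if include not in ("herbs", "symptoms", "both"):
        raise MiningError(f"include must be herbs|symptoms|both, got {include!r}")
    out: list[Transaction] = []
    for case in cases:
        items: set[Item] = set()
        if include in ("herbs", "both"):
            items.update((h, "herb") for h in case.herbs)
        if include in ("symptoms", "both"):
            items.update((s, "symptom") for s in case.symptoms)
        if items:
            out.append(Transaction(case.case_id, frozenset(items)))
    return out


# ---------------------------------------------------------------------------
# Internal dense representation
# ---------------------------------------------------------------------------

class _Matrix:
    """Boolean transactions x items matrix with itemset-support counting."""

    def __init__(self, transactions: Sequence[Transaction]):
        if not transactions:
            raise MiningError("no transactions to mine")
        self.n = len(transactions)
        self.items: list[Item] = sorted({i for t in transactions for i in t.items})
        index = {item: j for j, item in enumerate(self.items)}
        self.data = np.zeros((self.n, len(self.items)), dtype=bool)
        for row, t in enumerate(transactions):
            for item in t.items:
                self.data[row, index[item]] = True
        self._index = index

    def count(self, itemset: Iterable[Item]) -> int:
        cols = [self._index[i] for i in itemset]
        if not cols:
            return self.n
        mask = self.data[:, cols[0]].copy()
        for c in cols[1:]:
            mask &= self.data[:, c]
        return int(mask.sum())


def frequent_itemsets(
    transactions: Sequence[Transaction],
    min_support: float,
    max_size: int = 3,
) -> list[ItemsetSupport]:
    """All itemsets of size 1..max_size with support >= min_support.

    Classic level-wise search: size-k candidates are produced by joining
    frequent (k-1)-itemsets sharing a (k-2)-prefix and pruned when any (k-1)-
    subset is infrequent — valid because support is anti-monotone over the
    subset lattice. Output sorted by (size, support desc, lexicographic).
    """
    if not 0 < min_support <= 1:
        raise MiningError("min_support must be in (0, 1]")
    m = _Matrix(transactions)
    results: list[tuple[tuple[Item, ...], int]] = []

    current: list[tuple[Item, ...]] = []
    for item in m.items:
        c = m.count((item,))
        if c / m.n >= min_support:
            current.append((item,))
            results.append(((item,), c))

    size = 1
    while current and size < max_size:
        frequent_prev = set(current)
        candidates: list[tuple[Item, ...]] = []
        for a, b in combinations(current, 2):
            if a[:-1] == b[:-1]:  # join on shared prefix (lists are sorted)
                cand = a + (b[-1],) if a[-1] < b[-1] else b + (a[-1],)
                if all(
                    tuple(s) in frequent_prev
                    for s in combinations(cand, len(cand) - 1)
                ):
                    candidates.append(cand)
        current = []
        for cand in sorted(set(candidates)):
            c = m.count(cand)
            if c / m.n >= min_support:
                current.append(cand)
                results.append((cand, c))
        size += 1

    supports = [
        ItemsetSupport(tuple(name for name, _ in iset), c, c / m.n)
        for iset, c in results
    ]
    supports.sort(key=lambda s: (len(s.itemset), -s.support, s.itemset))
    return supports


def rule_metrics(
    transactions: Sequence[Transaction],
    lhs: Iterable[Item],
    rhs: Iterable[Item],
) -> tuple[float, float, float, int]:
    """(support, confidence, lift, co_count) of lhs -> rhs by direct counting."""
    lhs, rhs = frozenset(lhs), frozenset(rhs)
    if not lhs or not rhs or lhs & rhs:
        raise MiningError("lhs and rhs must be nonempty and disjoint")
    m = _Matrix(transactions)
    try:
        co = m.count(lhs | rhs)
        n_lhs = m.count(lhs)
        n_rhs = m.count(rhs)
    except KeyError as exc:
        raise MiningError(f"unknown item {exc.args[0]!r}") from exc
    if n_lhs == 0:
        raise MiningError("support(lhs) = 0: confidence undefined")
    support = co / m.n
    confidence = co / n_lhs
    lift = confidence / (n_rhs / m.n) if n_rhs else float("nan")
    return support, confidence, lift, co


def _emit_rules(
    m: _Matrix,
    splits: Iterable[tuple[tuple[Item, ...], tuple[Item, ...]]],
    thresholds: MiningThresholds,
    rhs_class: str,
) -> list[AssociationRule]:
    rules = []
    for lhs, rhs in splits:
        if rhs_class != "any" and any(cls != rhs_class for _, cls in rhs):
            continue
        co = m.count(lhs + rhs)
        if co == 0:
            continue
        n_lhs = m.count(lhs)
        n_rhs = m.count(rhs)
        support = co / m.n
        confidence = co / n_lhs
        lift = confidence / (n_rhs / m.n)
        if (support >= thresholds.min_support
                and confidence >= thresholds.min_confidence
                and lift >= thresholds.min_lift
                and co >= thresholds.min_count):
            rules.append(AssociationRule(
                tuple(sorted(name for name, _ in lhs)),
                tuple(sorted(name for name, _ in rhs)),
                support, confidence, lift, co))
    rules.sort(key=lambda r: (-r.lift, -r.support, r.lhs, r.rhs))
    return rules


def mine_rules(
    transactions: Sequence[Transaction],
    order: Literal[2, 3],
    thresholds: MiningThresholds = MiningThresholds(),
    rhs_class: Literal["herb", "symptom", "any"] = "any",
) -> list[AssociationRule]:
    """All qualifying rules of the given order, from frequent itemsets.

    Order 2 emits 1 -> 1 rules, order 3 emits 2 -> 1 rules. Every (lhs, rhs)
    split of every frequent itemset of that size is scored, so no rule whose
    support clears ``min_support`` can be missed (rule support equals the
    itemset's support). Sorted by lift desc, support desc, then names.
    """
    if order not in (2, 3):
        raise MiningError(f"order must be 2 or 3, got {order}")
    m = _Matrix(transactions)
    # min_support = 0 is allowed for exploratory runs: fall back to the
    # smallest representable support so the level-wise search still applies.
    floor = max(thresholds.min_support, 1.0 / (2 * m.n))
    itemsets = frequent_itemsets(transactions, floor, max_size=order)
    by_names = {s.itemset: s for s in itemsets if len(s.itemset) == order}
    name_to_item = {item[0]: item for item in m.items}
    splits = []
    for names in by_names:
        iset = tuple(name_to_item[n] for n in names)
        for rhs in combinations(iset, 1):
            lhs = tuple(i for i in iset if i != rhs[0])
            splits.append((lhs, rhs))
    return _emit_rules(m, splits, thresholds, rhs_class)


def brute_force_rules(
    transactions: Sequence[Transaction],
    order: Literal[2, 3],
    thresholds: MiningThresholds = MiningThresholds(),
    rhs_class: Literal["herb", "symptom", "any"] = "any",
    max_items: int = 15,
) -> list[AssociationRule]:
    """Oracle: enumerate every (lhs, rhs) split directly, no pruning.

    Guarded to small vocabularies — enumeration is exponential and exists
    for equivalence testing, not production mining.
    """
    if order not in (2, 3):
        raise MiningError(f"order must be 2 or 3, got {order}")
    m = _Matrix(transactions)
    if len(m.items) > max_items:
        raise MiningError(f"brute force limited to {max_items} distinct items")
    splits = []
    for iset in combinations(m.items, order):
        for rhs in combinations(iset, 1):
            lhs = tuple(i for i in iset if i != rhs[0])
            splits.append((lhs, rhs))
    return _emit_rules(m, splits, thresholds, rhs_class)
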