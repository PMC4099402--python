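"""Association rule mining over prescription transactions (Apriori).

A transaction is the deduplicated set of CHM identifiers issued at one
qualifying visit. Support of an itemset is the fraction of transactions
containing it; confidence of the directed rule A -> B is
support(A ∪ B) / support(A), the empirical conditional probability of the
consequent given the antecedent. A rule is significant when both support and
confidence meet their thresholds (defaults 1% and 30%, the conventional
cut-offs in CHM prescription-pattern studies). Threshold comparison is
inclusive (>=): the literature's phrasing is "higher than", but a strict
float inequality makes the boundary case untestable, so the boundary is
admitted and documented here.

Frequent itemsets are found level-wise with candidate generation by prefix
join and pruning by downward closure. Counting uses a vertical layout: each
item maps to a bitmask of the transactions containing it, so the support of
any candidate is the popcount of an AND over item masks — linear scans over
the transaction list happen once, not per candidate.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

from .cohort import Cohort

__all__ = [
    "Transaction",
    "ItemsetSupport",
    "AssociationRule",
    "MiningConfig",
    "transactions_from_cohort",
    "frequent_itemsets",
    "association_rules",
    "undirected_pairs",
]


@dataclass(frozen=True)
class Transaction:
    """One prescription as an item set (set semantics, nonempty)."""

    visit_id: str
    items: frozenset[str]

    def __post_init__(self) -> None:
        if not self.items:
            raise ValueError(f"transaction {self.visit_id}: empty item set")


@dataclass(frozen=True)
class ItemsetSupport:
    """A frequent itemset with its transaction count and support fraction."""

    items: frozenset[str]
    count: int
    support: float

    def canonical(self) -> tuple[str, ...]:
        return tuple(sorted(self.items))


@dataclass(frozen=True)
class AssociationRule:
    """Directed rule antecedent -> consequent with support and confidence."""

    antecedent: frozenset[str]
    consequent: frozenset[str]
    count: int
    support: float
    confidence: float

    def __post_init__(self) -> None:
        if not self.antecedent or not self.consequent:
            raise ValueError("antecedent and consequent must be nonempty")
        if self.antecedent & self.consequent:
            raise ValueError("antecedent and consequent must be disjoint")


@dataclass(frozen=True)
class MiningConfig:
    """Thresholds and the itemset-size cap for the mining run."""

    min_support: float = 0.01
    min_confidence: float = 0.30
    max_itemset_size: int = 3

    def __post_init__(self) -> None:
        if not 0.0 < self.min_support <= 1.0:
            raise ValueError(
                f"min_support must be in (0, 1], got {self.min_support}; "
                "a positive floor is required (0 would enumerate every itemset)"
            )
        if not 0.0 <= self.min_confidence <= 1.0:
            raise ValueError(f"min_confidence must be in [0, 1], got {self.min_confidence}")
        if self.max_itemset_size < 1:
            raise ValueError("max_itemset_size must be >= 1")


def transactions_from_cohort(cohort: Cohort) -> list[Transaction]:
    """One transaction per retained prescription, in cohort order."""
    if not cohort.visits:
        raise ValueError("cohort has no retained prescriptions")
    return [Transaction(v.visit_id, v.item_set) for v in cohort.visits]


def _item_bitmasks(transactions: Sequence[Transaction]) -> dict[str, int]:
    masks: dict[str, int] = {}
    for i, t in enumerate(transactions):
        bit = 1 << i
        for item in t.items:
            masks[item] = masks.get(item, 0) | bit
    return masks


def frequent_itemsets(
    transactions: Sequence[Transaction], config: MiningConfig | None = None
) -> list[ItemsetSupport]:
    """All itemsets of size 1..max_itemset_size with support >= min_support.

    Level-wise Apriori: level k candidates are joins of level k-1 itemsets
    sharing a (k-2)-prefix, pruned unless every (k-1)-subset is frequent
    (downward closure). Output is sorted by size, then support descending,
    then canonical item order, so runs are reproducible.
    """
    config = config or MiningConfig()
    if not transactions:
        raise ValueError("no transactions to mine")
    n = len(transactions)
    masks = _item_bitmasks(transactions)
    min_count = config.min_support * n

    results: list[ItemsetSupport] = []
    # level 1
    level: dict[tuple[str, ...], int] = {}
    for item in sorted(masks):
        c = masks[item].bit_count()
        if c >= min_count:
            level[(item,)] = c
    k = 1
    while level and k <= config.max_itemset_size:
        for key, c in level.items():
            results.append(ItemsetSupport(frozenset(key), c, c / n))
        if k == config.max_itemset_size:
            break
        frequent_keys = set(level)
        ordered = sorted(frequent_keys)
        nxt: dict[tuple[str, ...], int] = {}
        for a, b in combinations(ordered, 2):
            if a[:-1] != b[:-1]:
                continue  # prefix join: only siblings sharing the first k-1 items
            cand = a + (b[-1],)
            if any(
                tuple(cand[:i] + cand[i + 1 :]) not in frequent_keys
                for i in range(len(cand))
            ):
                continue  # downward-closure pruning
            m = masks[cand[0]]
            for item in cand[1:]:
                m &= masks[item]
            c = m.bit_count()
            if c >= min_count:
                nxt[cand] = c
        level = nxt
        k += 1

    results.sort(key=lambda s: (len(s.items), -s.support, s.canonical()))
    return results


def association_rules(
    itemsets: Iterable[ItemsetSupport],
    n_transactions: int,
    config: MiningConfig | None = None,
) -> list[AssociationRule]:
    """Single-consequent rules from frequent itemsets, filtered by thresholds.

    Every frequent itemset of size >= 2 yields one directed rule per member
    chosen as the consequent; rules with support >= min_support and
    confidence >= min_confidence are retained, sorted by support then
    confidence descending (canonical itemset string as final tie-break).
    """
    config = config or MiningConfig()
    table = {s.items: s for s in itemsets}
    rules: list[AssociationRule] = []
    for s in table.values():
        if len(s.items) < 2 or s.support < config.min_support:
            continue
        for consequent_item in sorted(s.items):
            antecedent = s.items - {consequent_item}
            ante = table.get(antecedent)
            if ante is None or ante.count == 0:
                # cannot happen for itemsets from frequent_itemsets (closure)
                raise ValueError(f"antecedent {sorted(antecedent)} missing from itemset table")
            confidence = s.count / ante.count
            if confidence >= config.min_confidence:
                rules.append(
                    AssociationRule(
                        antecedent=antecedent,
                        consequent=frozenset({consequent_item}),
                        count=s.count,
                        support=s.support,
                        confidence=confidence,
                    )
                )
    rules.sort(
        key=lambda r: (
            -r.support,
            -r.confidence,
            tuple(sorted(r.antecedent)),
            tuple(sorted(r.consequent)),
        )
    )
    return rules


def undirected_pairs(
    rules: Iterable[AssociationRule],
    itemsets: Iterable[ItemsetSupport] | None = None,
) -> list[dict]:
    """Collapse directed pair rules onto unordered significant pairs.

    A pair is significant if either direction passed the thresholds; the
    record carries both directions' confidences. The direction that failed is
    reconstructed from ``itemsets`` when given (confidence(A->B) =
    support(pair)/support(A)), else left as None. Larger antecedents are
    ignored: this view reports two-CHM combinations only.
    """
    table = {s.items: s for s in itemsets} if itemsets is not None else {}
    pairs: dict[frozenset[str], dict] = {}
    for r in rules:
        if len(r.antecedent) != 1 or len(r.consequent) != 1:
            continue
        key = r.antecedent | r.consequent
        a, b = sorted(key)
        rec = pairs.setdefault(
            key,
            {
                "chm_a": a,
                "chm_b": b,
                "count": r.count,
                "support": r.support,
                "confidence_a_to_b": None,
                "confidence_b_to_a": None,
            },
        )
        direction = "a_to_b" if r.antecedent == frozenset({a}) else "b_to_a"
        rec[f"confidence_{direction}"] = r.confidence
    for key, rec in pairs.items():
        pair_set = table.get(key)
        if pair_set is None:
            continue
        for direction, member in (("a_to_b", rec["chm_a"]), ("b_to_a", rec["chm_b"])):
            if rec[f"confidence_{direction}"] is None:
                ante = table.get(frozenset({member}))
                if ante is not None and ante.count:
                    rec[f"confidence_{direction}"] = pair_set.count / ante.count
    out = sorted(pairs.values(), key=lambda r: (-r["support"], r["chm_a"], r["chm_b"]))
    return out
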