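"""Apriori itemset mining and rule generation vs. the brute-force oracle."""

from __future__ import annotations

import math
import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from herbnet.mining import (
    AssociationRule,
    ItemsetSupport,
    MiningConfig,
    Transaction,
    association_rules,
    frequent_itemsets,
    transactions_from_cohort,
    undirected_pairs,
)
from herbnet.stats import prescription_size_stats

from .conftest import brute_force_itemsets, cohort_of


def tx(*item_sets: set[str]) -> list[Transaction]:
    return [Transaction(f"V{i}", frozenset(s)) for i, s in enumerate(item_sets)]


transactions_strategy = st.lists(
    st.sets(st.sampled_from([f"C{i}" for i in range(10)]), min_size=1, max_size=6),
    min_size=1, max_size=80,
)


class TestTransactions:
    def test_visit_items_become_a_set(self):
        cohort = cohort_of([["J", "C"]])
        t = transactions_from_cohort(cohort)
        assert len(t) == 1 and t[0].items == {"J", "C"}

    def test_bijection_with_prescriptions(self, small_synthetic):
        _, _, cohort = small_synthetic
        t = transactions_from_cohort(cohort)
        assert len(t) == cohort.n_chm_prescriptions

    def test_size_multiset_matches_size_histogram(self, small_synthetic):
        _, _, cohort = small_synthetic
        from collections import Counter

        sizes = Counter(len(t.items) for t in transactions_from_cohort(cohort))
        assert dict(sizes) == prescription_size_stats(cohort)["histogram"]

    def test_empty_transaction_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            Transaction("V1", frozenset())


class TestFrequentItemsets:
    def test_worked_example(self):
        # 4 baskets; at min_support 0.5 only {A}, {B}, {A,B} survive
        out = frequent_itemsets(tx({"A", "B"}, {"A", "B"}, {"A", "C"}, {"B"}),
                                MiningConfig(min_support=0.5))
        got = {s.items: s.support for s in out}
        assert got == {frozenset("A"): 0.75, frozenset("B"): 0.75,
                       frozenset("AB"): 0.5}

    def test_support_one_keeps_only_universal_itemsets(self):
        out = frequent_itemsets(tx({"A", "B"}, {"A", "B"}), MiningConfig(min_support=1.0))
        assert {s.items for s in out} == {frozenset("A"), frozenset("B"), frozenset("AB")}
        assert all(s.support == 1.0 for s in out)

    def test_zero_min_support_rejected(self):
        with pytest.raises(ValueError, match="positive floor"):
            MiningConfig(min_support=0.0)

    @given(transactions_strategy,
           st.floats(0.02, 0.6), st.integers(1, 4))
    def test_agrees_with_brute_force(self, item_sets, min_support, max_size):
        transactions = tx(*item_sets)
        out = frequent_itemsets(transactions,
                                MiningConfig(min_support, 0.3, max_size))
        expected = brute_force_itemsets([t.items for t in transactions],
                                        min_support, max_size)
        assert {s.items: s.count for s in out} == expected

    @given(transactions_strategy, st.floats(0.05, 0.5))
    def test_downward_closure(self, item_sets, min_support):
        transactions = tx(*item_sets)
        out = frequent_itemsets(transactions, MiningConfig(min_support))
        table = {s.items for s in out}
        for s in out:
            for item in s.items:
                if len(s.items) > 1:
                    assert (s.items - {item}) in table

    @given(transactions_strategy, st.floats(0.05, 0.4), st.floats(0.0, 0.5))
    def test_raising_min_support_is_monotone(self, item_sets, lo, bump):
        transactions = tx(*item_sets)
        low = {s.items for s in frequent_itemsets(transactions, MiningConfig(lo))}
        high = {s.items for s in frequent_itemsets(
            transactions, MiningConfig(min(lo + bump, 1.0)))}
        assert high <= low

    def test_deterministic_ordering(self):
        transactions = tx({"B", "A"}, {"A"}, {"B"}, {"A", "B"})
        a = frequent_itemsets(transactions, MiningConfig(0.25))
        b = frequent_itemsets(list(transactions), MiningConfig(0.25))
        assert a == b
        assert [s.canonical() for s in a if len(s.items) == 1] == [("A",), ("B",)]


def published_pair_itemsets() -> list[ItemsetSupport]:
    """Itemset supports reconstructed from the printed pair/marginal counts."""
    n = 13_820
    return [
        ItemsetSupport(frozenset({"JWXYS"}), 5_185, 5_185 / n),
        ItemsetSupport(frozenset({"Cyperus"}), 2_485, 2_485 / n),
        ItemsetSupport(frozenset({"JWXYS", "Cyperus"}), 1_059, 1_059 / n),
    ]


class TestAssociationRules:
    def test_published_counts_direction_asymmetry(self):
        """From the printed counts, Cyperus->JWXYS passes and JWXYS->Cyperus fails.

        support = 1059/13820 = 0.0766; confidence(Cyperus->JWXYS) =
        1059/2485 = 0.426 >= 0.30 but confidence(JWXYS->Cyperus) =
        1059/5185 = 0.204 < 0.30.
        """
        rules = association_rules(published_pair_itemsets(), 13_820, MiningConfig())
        assert len(rules) == 1
        (r,) = rules
        assert r.antecedent == {"Cyperus"} and r.consequent == {"JWXYS"}
        assert r.support == pytest.approx(0.0766, abs=5e-5)
        assert r.confidence == pytest.approx(0.426, abs=5e-4)

    def test_independent_items_confidence_equals_marginal_support(self):
        # A ⊥ B with support(B)=0.5 -> confidence(A->B)=0.5
        baskets = [{"A", "B"}, {"A"}, {"B"}, set("x")]
        transactions = tx(*baskets)
        out = frequent_itemsets(transactions, MiningConfig(0.25, 0.0, 2))
        rules = association_rules(out, 4, MiningConfig(0.25, 0.0, 2))
        conf = {(tuple(r.antecedent), tuple(r.consequent)): r.confidence for r in rules}
        assert conf[(("A",), ("B",))] == pytest.approx(0.5)

    @given(transactions_strategy, st.floats(0.0, 0.5), st.floats(0.0, 0.5))
    def test_raising_min_confidence_is_monotone(self, item_sets, lo, bump):
        transactions = tx(*item_sets)
        itemsets = frequent_itemsets(transactions, MiningConfig(0.05))
        def keys(conf):
            rules = association_rules(itemsets, len(transactions),
                                      MiningConfig(0.05, conf))
            return {(r.antecedent, r.consequent) for r in rules}
        assert keys(min(lo + bump, 1.0)) <= keys(lo)

    @given(transactions_strategy)
    def test_support_never_exceeds_confidence(self, item_sets):
        transactions = tx(*item_sets)
        itemsets = frequent_itemsets(transactions, MiningConfig(0.05))
        for r in association_rules(itemsets, len(transactions), MiningConfig(0.05, 0.0)):
            assert r.support <= r.confidence <= 1.0

    def test_disjointness_enforced(self):
        with pytest.raises(ValueError, match="disjoint"):
            AssociationRule(frozenset("A"), frozenset("A"), 1, 0.1, 0.5)

    def test_boundary_confidence_is_retained(self):
        # inclusive thresholds: confidence exactly 0.30 passes
        n = 100
        itemsets = [
            ItemsetSupport(frozenset("A"), 50, 0.5),
            ItemsetSupport(frozenset("B"), 20, 0.2),
            ItemsetSupport(frozenset("AB"), 15, 0.15),
        ]
        rules = association_rules(itemsets, n, MiningConfig(0.01, 0.30))
        directions = {(tuple(r.antecedent), tuple(r.consequent)) for r in rules}
        assert (("A",), ("B",)) in directions  # confidence 15/50 = 0.30 exactly


class TestUndirectedPairs:
    def test_one_passing_direction_keeps_pair_with_both_confidences(self):
        itemsets = published_pair_itemsets()
        rules = association_rules(itemsets, 13_820, MiningConfig())
        pairs = undirected_pairs(rules, itemsets)
        assert len(pairs) == 1
        p = pairs[0]
        assert {p["chm_a"], p["chm_b"]} == {"JWXYS", "Cyperus"}
        both = sorted(
            (p["confidence_a_to_b"], p["confidence_b_to_a"]))
        assert both[0] == pytest.approx(1_059 / 5_185)
        assert both[1] == pytest.approx(1_059 / 2_485)

    def test_no_rules_no_pairs(self):
        assert undirected_pairs([]) == []

    def test_planted_rule_recovered_at_published_thresholds(self):
        """A planted rule at the confidence boundary survives mining."""
        rng = random.Random(7)
        baskets = []
        for _ in range(6000):
            basket = set()
            if rng.random() < 0.4:
                basket.add("J")
                if rng.random() < 0.3:
                    basket.add("C")
            basket.add(f"F{rng.randrange(3)}")  # filler so baskets are nonempty
            baskets.append(basket)
        transactions = tx(*baskets)
        cfg = MiningConfig()  # 1% support, 30% confidence
        itemsets = frequent_itemsets(transactions, cfg)
        rules = association_rules(itemsets, len(transactions), cfg)
        pairs = undirected_pairs(rules, itemsets)
        planted = [p for p in pairs if {p["chm_a"], p["chm_b"]} == {"J", "C"}]
        # P(J∩C)=0.12 >> 1%; confidence(J->C)≈0.30: the pair must be present
        # via at least the C->J direction (confidence ≈ support(J∩C)/support(C) ≈ 1)
        assert planted
        n = len(transactions)
        support = planted[0]["support"]
        se = math.sqrt(0.12 * 0.88 / n)
        assert abs(support - 0.12) <= 3 * se
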