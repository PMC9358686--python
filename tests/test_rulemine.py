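"""Apriori mining vs brute-force oracle, hand examples, lattice invariants."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from herbmine import synthgen
from herbmine.records import CleanCase, clean_cases, default_dictionary
from herbmine.rulemine import (
    MiningError,
    MiningThresholds,
    Transaction,
    brute_force_rules,
    build_transactions,
    frequent_itemsets,
    mine_rules,
    rule_metrics,
)

from conftest import transactions

OPEN = MiningThresholds(0, 0, 0, 1)  # filter effectively disabled


def test_build_transactions_include_flag():
    case = CleanCase("c", frozenset({"Polyarthralgia"}),
                     frozenset({"Jinyinhua", "Wugong"}))
    both = build_transactions([case], "both")[0]
    assert both.items == frozenset({
        ("Polyarthralgia", "symptom"), ("Jinyinhua", "herb"), ("Wugong", "herb")})
    herbs = build_transactions([case], "herbs")[0]
    assert len(herbs.items) == 2
    # a case empty under the restriction is dropped
    sym_only = CleanCase("s", frozenset({"Fatigue"}), frozenset())
    assert build_transactions([sym_only], "herbs") == []
    assert len(build_transactions([sym_only], "symptoms")) == 1


def test_frequent_itemsets_hand_enumeration():
    trans = transactions({"A", "B"}, {"A", "B"}, {"A"}, {"B", "C"})
    result = frequent_itemsets(trans, 0.5)
    as_dict = {s.itemset: s.support for s in result}
    assert as_dict == {("A",): 0.75, ("B",): 0.75, ("A", "B"): 0.5}


def test_frequent_itemsets_min_support_one():
    trans = transactions({"A", "B"}, {"C"})
    assert frequent_itemsets(trans, 1.0) == []


def test_frequent_itemsets_matches_exhaustive_enumeration():
    trans = transactions({"A", "B", "C"}, {"A", "C"}, {"B", "D"}, {"A", "B", "D"},
                         {"C", "D"})
    mined = {s.itemset: s.count for s in frequent_itemsets(trans, 1e-9, max_size=3)}
    items = sorted({i for t in trans for i in t.items})
    expected = {}
    for size in (1, 2, 3):
        for combo in itertools.combinations(items, size):
            count = sum(set(combo) <= t.items for t in trans)
            if count:
                expected[tuple(n for n, _ in combo)] = count
    assert mined == expected


def test_frequent_itemsets_errors():
    with pytest.raises(MiningError):
        frequent_itemsets([], 0.5)
    with pytest.raises(MiningError):
        frequent_itemsets(transactions({"A"}), 0.0)


def test_rule_metrics_hand_examples():
    trans = transactions({"A", "B"}, {"A"}, {"B"}, {"A", "B"})
    support, confidence, lift, co = rule_metrics(
        trans, [("A", "herb")], [("B", "herb")])
    assert (support, confidence, co) == (0.5, 2 / 3, 2)
    assert lift == pytest.approx(8 / 9)

    # exact independence: supp(AB)=1/4 = supp(A) supp(B)
    trans = transactions({"A", "B"}, {"A", "C"}, {"B", "C"}, {"C"})
    assert rule_metrics(trans, [("A", "herb")], [("B", "herb")])[2] == \
        pytest.approx(1.0)

    # constant pair: confidence 1, lift 1
    trans = transactions({"A", "B"}, {"A", "B"})
    _, confidence, lift, _ = rule_metrics(trans, [("A", "herb")], [("B", "herb")])
    assert (confidence, lift) == (1.0, 1.0)


def test_rule_metrics_validation():
    trans = transactions({"A", "B"})
    with pytest.raises(MiningError):
        rule_metrics(trans, [], [("A", "herb")])
    with pytest.raises(MiningError):
        rule_metrics(trans, [("A", "herb")], [("A", "herb")])


def test_mine_rules_open_thresholds_all_pairs():
    trans = transactions({"A", "B"}, {"B", "C"}, {"A", "B", "C"})
    rules = mine_rules(trans, 2, OPEN)
    pairs = {(r.lhs[0], r.rhs[0]) for r in rules}
    expected = {(a, b) for a, b in itertools.permutations("ABC", 2)
                if sum({a, b} <= {n for n, _ in t.items} for t in trans) >= 1}
    assert pairs == expected


def test_mine_rules_single_transaction():
    rules = brute_force_rules(transactions({"A", "B"}), 2, OPEN)
    assert {(r.lhs, r.rhs) for r in rules} == {(("A",), ("B",)), (("B",), ("A",))}
    assert all(r.support == r.confidence == r.lift == 1.0 for r in rules)


def test_mine_rules_planted_pair_recovered():
    cases = synthgen.generate_cases(synthgen.planted_pair_config(2000, 11))
    clean, _ = clean_cases(cases, default_dictionary())
    trans = build_transactions(clean, "both")
    rules = mine_rules(trans, 2, MiningThresholds())
    planted = [r for r in rules if r.lhs == ("HerbA",) and r.rhs == ("SymptomB",)]
    assert len(planted) == 1
    assert planted[0].lift == pytest.approx(1.64, abs=0.1)
    assert planted[0].support == pytest.approx(0.41, abs=0.05)
    assert planted[0].confidence == pytest.approx(0.82, abs=0.05)


def test_mine_rules_independence_yields_nothing():
    cases = synthgen.generate_cases(synthgen.independence_config(5000, 13))
    clean, _ = clean_cases(cases, default_dictionary())
    trans = build_transactions(clean, "both")
    assert mine_rules(trans, 2, MiningThresholds()) == []


def test_rhs_class_filter():
    case = CleanCase("c", frozenset({"S1", "S2"}), frozenset({"H1"}))
    trans = build_transactions([case] * 4, "both")
    rules = mine_rules(trans, 2, OPEN, rhs_class="herb")
    assert {r.rhs[0] for r in rules} == {"H1"}


def test_third_order_rules_shape():
    trans = transactions(*[{"A", "B", "C"}] * 3, {"A", "B"}, {"C"})
    rules = mine_rules(trans, 3, OPEN)
    assert rules and all(len(r.lhs) == 2 and len(r.rhs) == 1 for r in rules)


def test_brute_force_guard():
    trans = transactions(set(str(i) for i in range(16)))
    with pytest.raises(MiningError, match="limited"):
        brute_force_rules(trans, 2, OPEN)
    with pytest.raises(MiningError):
        brute_force_rules([], 2, OPEN)


# ---------------------------------------------------------------------------
# Property-based checks
# ---------------------------------------------------------------------------

small_datasets = st.lists(
    st.sets(st.sampled_from("ABCDEFGH"), min_size=1, max_size=6),
    min_size=1, max_size=30)
threshold_values = st.tuples(
    st.sampled_from([0.0, 0.1, 0.3]), st.sampled_from([0.0, 0.5, 0.8]),
    st.sampled_from([0.0, 1.0, 1.2]))


@settings(max_examples=100, deadline=None)
@given(small_datasets, threshold_values, st.sampled_from([2, 3]))
def test_mine_equals_brute_force(itemsets, cuts, order):
    """The level-wise miner and exhaustive enumeration agree exactly."""
    trans = transactions(*itemsets)
    thresholds = MiningThresholds(*cuts, min_count=1)
    assert mine_rules(trans, order, thresholds) == \
        brute_force_rules(trans, order, thresholds)


@settings(max_examples=60, deadline=None)
@given(small_datasets)
def test_support_anti_monotone(itemsets):
    trans = transactions(*itemsets)
    supports = {s.itemset: s.support
                for s in frequent_itemsets(trans, 1e-9, max_size=3)}
    for itemset, support in supports.items():
        for sub in itertools.combinations(itemset, len(itemset) - 1):
            if sub:
                assert supports[sub] >= support


@settings(max_examples=60, deadline=None)
@given(small_datasets)
def test_pair_rule_symmetry_and_identities(itemsets):
    """lift and support are symmetric for 1 -> 1 rules; co_count and the
    confidence identity hold exactly."""
    trans = transactions(*itemsets)
    n = len(trans)
    rules = {(r.lhs, r.rhs): r for r in mine_rules(trans, 2, OPEN)}
    for (lhs, rhs), r in rules.items():
        assert r.co_count == round(r.support * n)
        mirror = rules.get((rhs, lhs))
        assert mirror is not None  # co_count >= 1 both ways
        assert mirror.lift == pytest.approx(r.lift, abs=1e-12)
        assert mirror.support == r.support
        # confidence * support(lhs) = support(lhs ∪ rhs)
        supp_lhs = sum(set(lhs) <= {n_ for n_, _ in t.items} for t in trans) / n
        assert r.confidence * supp_lhs == pytest.approx(r.support, abs=1e-12)


@settings(max_examples=40, deadline=None)
@given(small_datasets, st.sampled_from([2, 3]))
def test_raising_thresholds_never_adds_rules(itemsets, order):
    trans = transactions(*itemsets)
    base = {(r.lhs, r.rhs) for r in mine_rules(trans, order, OPEN)}
    for cuts in [(0.2, 0.0, 0.0), (0.0, 0.6, 0.0), (0.0, 0.0, 1.1)]:
        tightened = {(r.lhs, r.rhs)
                     for r in mine_rules(trans, order, MiningThresholds(*cuts, 1))}
        assert tightened <= base
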