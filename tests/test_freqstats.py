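"""Frequency tables, the 10% filter, pain shares, category shares, edges."""

import itertools

import pytest

from herbmine import freqstats
from herbmine.freqstats import (
    FreqError,
    FrequencyRecord,
    attribute_edges,
    category_shares,
    default_monographs,
    filter_high_frequency,
    frequency_table,
    pain_share,
    published_herb_counts,
    published_symptom_counts,
)
from herbmine.records import CleanCase


def make_cases(*itemsets, domain="herbs"):
    other = {"herbs": frozenset({"X"}), "symptoms": frozenset({"S"})}
    return [
        CleanCase(
            f"c{i}",
            symptoms=frozenset(items) if domain == "symptoms" else other["symptoms"],
            herbs=frozenset(items) if domain == "herbs" else other["herbs"],
        )
        for i, items in enumerate(itemsets)
    ]


def incidence_cases(counts: dict, n: int, domain="symptoms"):
    """n cases where item s appears in exactly counts[s] of them."""
    out = []
    for i in range(n):
        items = {s for s, c in counts.items() if i < c}
        out.append(CleanCase(
            f"c{i}",
            symptoms=frozenset(items) if domain == "symptoms" else frozenset({"S"}),
            herbs=frozenset(items) if domain == "herbs" else frozenset({"X"}),
        ))
    return out


def test_frequency_table_hand_count():
    cases = make_cases({"A", "B"}, {"A"}, {"B"})
    table = frequency_table(cases, "herbs")
    assert table == [FrequencyRecord("A", 2, 2 / 3), FrequencyRecord("B", 2, 2 / 3)]


def test_frequency_table_full_rate():
    table = frequency_table(make_cases({"A"}, {"A"}, {"A"}, {"A"}), "herbs")
    assert table[0] == FrequencyRecord("A", 4, 1.0)


def test_frequency_table_published_symptom_rates():
    """Counts over 311 cases reproduce the published percentages."""
    cases = incidence_cases(published_symptom_counts(), 311)
    table = frequency_table(cases, "symptoms")
    rates = {r.item: round(100 * r.rate, 2) for r in table}
    assert round(rates["Thready pulse"], 1) == 37.3
    assert rates["Joint pain of lower extremity"] == 33.12
    assert rates["Fatigue"] == 19.94
    assert rates["Dry eyes"] == 12.22


def test_frequency_table_sorted_descending_with_alpha_ties():
    cases = make_cases({"B", "C"}, {"C", "A"}, {"B"})
    items = [r.item for r in frequency_table(cases, "herbs")]
    assert items == ["B", "C", "A"]


def test_frequency_conservation():
    cases = make_cases({"A", "B"}, {"B", "C", "D"}, {"A"})
    table = frequency_table(cases, "herbs")
    assert sum(r.count for r in table) == sum(len(c.herbs) for c in cases)


def test_frequency_table_errors():
    with pytest.raises(FreqError):
        frequency_table([], "herbs")
    with pytest.raises(FreqError):
        frequency_table(make_cases({"A"}), "potions")


def test_filter_high_frequency_inclusive_boundary():
    table = [FrequencyRecord("keep", 38, 0.1222), FrequencyRecord("edge", 31, 0.10),
             FrequencyRecord("drop", 30, 0.099)]
    kept = [r.item for r in filter_high_frequency(table, 0.10)]
    assert kept == ["keep", "edge"]
    assert filter_high_frequency(table, 0.0) == table


def test_filter_monotone_in_threshold():
    table = [FrequencyRecord(f"i{k}", k, k / 20) for k in range(1, 20)]
    for r1, r2 in itertools.combinations([0.05, 0.1, 0.3, 0.7], 2):
        hi = {r.item for r in filter_high_frequency(table, max(r1, r2))}
        lo = {r.item for r in filter_high_frequency(table, min(r1, r2))}
        assert hi <= lo


def test_pain_share_hand_count(dictionary):
    cases = [
        CleanCase("a", frozenset({"Upper limb joint pain", "Poor sleep"}),
                  frozenset({"X"})),
        CleanCase("b", frozenset({"Poor sleep"}), frozenset({"X"})),
    ]
    share = pain_share(cases, dictionary)
    assert share.pain_fraction == pytest.approx(1 / 3)
    assert share.by_location == {"Upper limb joint pain": pytest.approx(1 / 3)}


def test_pain_share_extremes(dictionary):
    all_pain = [CleanCase("a", frozenset({"Polyarthralgia"}), frozenset({"X"}))]
    assert pain_share(all_pain, dictionary).pain_fraction == 1.0
    no_pain = [CleanCase("a", frozenset({"Poor sleep"}), frozenset({"X"}))]
    assert pain_share(no_pain, dictionary).pain_fraction == 0.0


def test_pain_share_by_location_sums_to_pain_fraction(dictionary):
    cases = [
        CleanCase("a", frozenset({"Upper limb joint pain", "Lumbosacral pain",
                                  "Poor sleep"}), frozenset({"X"})),
        CleanCase("b", frozenset({"Polyarthralgia", "Fatigue"}), frozenset({"X"})),
    ]
    share = pain_share(cases, dictionary)
    assert sum(share.by_location.values()) == pytest.approx(share.pain_fraction)


def test_category_shares_weightings():
    monographs = default_monographs()
    table = [FrequencyRecord("Jinyinhua", 30, 0.3),   # Heat-clearing
             FrequencyRecord("Wugong", 10, 0.1)]      # Liver and wind-soothing
    by_freq = category_shares(monographs, table, "frequency")
    assert by_freq["Heat-clearing medicinal"] == pytest.approx(75.0)
    assert by_freq["Liver and wind-soothing medicine"] == pytest.approx(25.0)
    by_count = category_shares(monographs, table, "count")
    assert by_count["Heat-clearing medicinal"] == pytest.approx(50.0)


def test_category_shares_published_table():
    """Frequency-weighted shares of the published 16-herb table land on the
    published ring-chart percentages (integer rounding)."""
    monographs = default_monographs()
    counts = published_herb_counts()
    table = [FrequencyRecord(h, c, c / 311) for h, c in counts.items()]
    shares = category_shares(monographs, table, "frequency")
    expected = {
        "Heat-clearing medicinal": 17,
        "Dampness-draining diuretic medicinal": 11,
        "Liver and wind-soothing medicine": 9,
        "Wind-dampness dispelling medicinal": 20,
        "Tonifying and replenishing medicinal": 21,
        "Interior-warming medicinal": 5,
        "Exterior-releasing medicinal": 9,
        "Blood-activating and stasis-dispelling medicinal": 8,
    }
    assert {k: round(v) for k, v in shares.items()} == expected


@pytest.mark.parametrize("weighting", ["frequency", "count"])
def test_category_shares_sum_to_100(weighting):
    monographs = default_monographs()
    table = [FrequencyRecord(h, c, c / 311)
             for h, c in published_herb_counts().items()]
    assert sum(category_shares(monographs, table, weighting).values()) == \
        pytest.approx(100.0, abs=0.5)


def test_category_shares_unknown_herb():
    with pytest.raises(FreqError, match="Mystery"):
        category_shares(default_monographs(), [FrequencyRecord("Mystery", 1, 0.1)])


def test_attribute_edges_examples():
    monographs = default_monographs()
    jyh = [e for e in attribute_edges(monographs.values()) if e[0] == "Jinyinhua"]
    assert jyh == [
        ("Jinyinhua", "Cold", "property"),
        ("Jinyinhua", "Sweet", "flavor"),
        ("Jinyinhua", "Stomach", "meridian"),
        ("Jinyinhua", "Lung", "meridian"),
    ]
    wugong = [e for e in attribute_edges(monographs.values()) if e[0] == "Wugong"]
    assert len(wugong) == 3
    assert attribute_edges([]) == []


def test_attribute_edge_count_invariant():
    monographs = default_monographs()
    edges = attribute_edges(monographs.values())
    expected = sum(1 + len(m.flavors) + len(m.meridians)
                   for m in monographs.values())
    assert len(edges) == expected
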