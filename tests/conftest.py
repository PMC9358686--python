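import pytest

from herbmine import records
from herbmine.records import RawCase
from herbmine.rulemine import Transaction


@pytest.fixture(scope="session")
def dictionary():
    return records.default_dictionary()


def eligible_case(case_id="c1", symptoms=("Fatigue",), herbs=("Jinyinhua",), **overrides):
    """A RawCase passing every screening criterion, with overridable fields."""
    fields = dict(
        age=45, duration=12, das28_before=4.0, das28_after=2.0,
        haq_before=1.2, haq_after=0.3, vas_before=6.0, vas_after=3.0,
        alt_uln_ratio=1.0, ast_uln_ratio=1.0, wbc=5.0,
        consent=True, tcm_treated=True,
    )
    fields.update(overrides)
    return RawCase(case_id, symptoms=list(symptoms), herbs=list(herbs), **fields)


def transactions(*itemsets, cls="herb"):
    """Build transactions from iterables of item names (single shared class)."""
    return [
        Transaction(f"t{i}", frozenset((name, cls) for name in items))
        for i, items in enumerate(itemsets)
    ]
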