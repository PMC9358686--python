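"""Case records: parsing, terminology standardization, eligibility screening.

One record is one patient visit with clinical scores, a raw symptom list and
a raw herb (prescription) list. Records pass through three steps before any
analysis sees them:

1. eligibility screening on the clinical scores (``screen_case``),
2. dictionary-driven canonicalization of symptom and herb terms,
3. deduplication into a :class:`CleanCase` — the "transaction" unit that the
   frequency, rule-mining and clustering stages consume.

The canonical vocabulary uses pinyin herb names and English symptom phrases so
outputs line up with the standard monograph tables.
"""

from __future__ import annotations

import csv
import io
import json
import logging
import math
from dataclasses import dataclass, field, fields
from importlib import resources
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger("herbmine")

POLYARTHRALGIA = "Polyarthralgia"

#: Eligibility bounds, exactly as the screening protocol states them.
#: Age 18-70 inclusive; disease duration >= 6 months; moderate activity before
#: treatment (3.2 < DAS28 < 5.1, strict) reaching remission after (DAS28 < 2.6);
#: disability HAQ-DI >= 1 before and < 0.5 after; VAS pain decreased; liver
#: enzymes below 2x the upper limit of normal; WBC strictly above 3.5e9/L.
SCREEN_CRITERIA = (
    "age", "duration", "das28_before", "das28_after", "haq_before",
    "haq_after", "vas", "alt", "ast", "wbc", "consent", "tcm_treated",
)

INCOMPLETE_RECORD = "incomplete_record"
DEGENERATE_CASE = "degenerate_case"


class RecordError(ValueError):
    """Raised for malformed or degenerate case records."""


@dataclass
class RawCase:
    """A single patient visit as recorded, before screening or cleaning.

    Score fields may be ``None`` when the source record is incomplete; such
    records are rejected by :func:`screen_case` with ``incomplete_record``.
    """

    case_id: str
    age: int | None = None
    duration: int | None = None          # months since diagnosis
    das28_before: float | None = None
    das28_after: float | None = None
    haq_before: float | None = None
    haq_after: float | None = None
    vas_before: float | None = None
    vas_after: float | None = None
    alt_uln_ratio: float | None = None   # ALT as multiple of upper limit of normal
    ast_uln_ratio: float | None = None
    wbc: float | None = None             # x 10^9 / L
    symptoms: list[str] = field(default_factory=list)
    herbs: list[str] = field(default_factory=list)
    consent: bool | None = None
    tcm_treated: bool | None = None


@dataclass(frozen=True)
class CleanCase:
    """Deduplicated canonical symptom and herb sets for one eligible case."""

    case_id: str
    symptoms: frozenset[str]
    herbs: frozenset[str]


@dataclass(frozen=True)
class ScreenDecision:
    eligible: bool
    failed_criteria: tuple[str, ...]

    def __post_init__(self) -> None:
        assert self.eligible == (len(self.failed_criteria) == 0)


@dataclass(frozen=True)
class TermDictionary:
    """Raw-to-canonical term maps plus the pain lexicon.

    ``pain_regions`` labels each regional pain term with its body region
    (upper_limb / lower_limb / lumbosacral); ``pain_lexicon`` is the full set
    of canonical terms counted as pain symptoms (the regional terms plus
    multi-joint pain).
    """

    symptom_map: Mapping[str, str]
    herb_map: Mapping[str, str]
    pain_regions: Mapping[str, str]
    pain_lexicon: frozenset[str]

    def __post_init__(self) -> None:
        for raw, canon in {**self.symptom_map, **self.herb_map}.items():
            target = self.symptom_map.get(canon, self.herb_map.get(canon, canon))
            if target != canon:
                raise RecordError(
                    f"dictionary not idempotent: {raw!r} -> {canon!r} -> {target!r}")
        missing = set(self.pain_regions) - set(self.pain_lexicon)
        if missing:
            raise RecordError(f"regional pain terms missing from pain lexicon: {missing}")


def standardize_symptom(term: str, dictionary: TermDictionary) -> str:
    """Map a raw symptom term to its canonical form (pass-through if unmapped)."""
    canonical = dictionary.symptom_map.get(term)
    if canonical is None:
        if term not in dictionary.pain_lexicon:
            logger.debug("unmapped symptom term passed through: %r", term)
        return term
    return canonical


def standardize_herb(name: str, dictionary: TermDictionary) -> str:
    """Map a raw herb name to its canonical (pharmacopeia) form.

    Regional name variants collapse ("Han Fangji" -> "Fangji") but herbs that
    are distinct drugs despite a shared pharmacopeia entry ("Chuanniuxi",
    "Niuxigen") and different parts of the same plant ("Jinyinhua" vs
    "Rendongteng") keep their own names — the dictionary simply has no entry
    for them, and unmapped names pass through unchanged.
    """
    return dictionary.herb_map.get(name, name)


def apply_multi_joint_rule(
    symptoms: frozenset[str] | set[str], dictionary: TermDictionary
) -> frozenset[str]:
    """Relabel pain spanning two or more body regions as multi-joint pain.

    When the canonical symptom set contains regional pain terms from >= 2
    distinct regions, those regional terms are *replaced* by the single term
    "Polyarthralgia" (regional pains and multi-joint pain are disjoint
    categories in the frequency tables, so a case carries one or the other).
    """
    regional = {s for s in symptoms if s in dictionary.pain_regions}
    regions = {dictionary.pain_regions[s] for s in regional}
    if len(regions) < 2:
        return frozenset(symptoms)
    return (frozenset(symptoms) - regional) | {POLYARTHRALGIA}


def _missing(value: object) -> bool:
    if value is None:
        return True
    return isinstance(value, float) and math.isnan(value)


def screen_case(case: RawCase) -> ScreenDecision:
    """Apply the inclusion/exclusion screen; strict bounds as stated.

    Returns the list of failed criterion ids (empty iff eligible). A record
    with any missing score field fails with the single id
    ``incomplete_record``.
    """
    score_fields = (
        "age", "duration", "das28_before", "das28_after", "haq_before",
        "haq_after", "vas_before", "vas_after", "alt_uln_ratio",
        "ast_uln_ratio", "wbc", "consent", "tcm_treated",
    )
    if any(_missing(getattr(case, f)) for f in score_fields):
        return ScreenDecision(False, (INCOMPLETE_RECORD,))

    failed = []
    if not 18 <= case.age <= 70:
        failed.append("age")
    if not case.duration >= 6:
        failed.append("duration")
    if not 3.2 < case.das28_before < 5.1:
        failed.append("das28_before")
    if not case.das28_after < 2.6:
        failed.append("das28_after")
    if not case.haq_before >= 1:
        failed.append("haq_before")
    if not case.haq_after < 0.5:
        failed.append("haq_after")
    if not case.vas_after < case.vas_before:
        failed.append("vas")
    if not case.alt_uln_ratio < 2:
        failed.append("alt")
    if not case.ast_uln_ratio < 2:
        failed.append("ast")
    if not case.wbc > 3.5:                 # "equal to or less than 3.5" excludes
        failed.append("wbc")
    if not case.consent:
        failed.append("consent")
    if not case.tcm_treated:
        failed.append("tcm_treated")
    return ScreenDecision(not failed, tuple(failed))


def build_clean_case(case: RawCase, dictionary: TermDictionary) -> CleanCase:
    """Canonicalize and deduplicate one case into its transaction.

    Output is invariant to the order and multiplicity of the raw lists.
    Raises :class:`RecordError` (``degenerate_case``) if either set is empty
    after cleaning.
    """
    symptoms = frozenset(standardize_symptom(s, dictionary) for s in case.symptoms)
    symptoms = apply_multi_joint_rule(symptoms, dictionary)
    herbs = frozenset(standardize_herb(h, dictionary) for h in case.herbs)
    if not symptoms or not herbs:
        raise RecordError(f"{DEGENERATE_CASE}: case {case.case_id!r} has an "
                          f"empty {'symptom' if not symptoms else 'herb'} set")
    return CleanCase(case.case_id, symptoms, herbs)


def clean_cases(
    cases: Iterable[RawCase], dictionary: TermDictionary
) -> tuple[list[CleanCase], dict[str, int]]:
    """Screen then clean a batch; returns eligible clean cases + failure tally."""
    out: list[CleanCase] = []
    tally: dict[str, int] = {}
    for case in cases:
        decision = screen_case(case)
        if decision.eligible:
            out.append(build_clean_case(case, dictionary))
        else:
            for crit in decision.failed_criteria:
                tally[crit] = tally.get(crit, 0) + 1
    return out, tally


# ---------------------------------------------------------------------------
# I/O — cases as CSV (lists ';'-joined) or JSON-lines, dictionary as CSV.
# ---------------------------------------------------------------------------

_NUMERIC = {
    "age": int, "duration": int, "das28_before": float, "das28_after": float,
    "haq_before": float, "haq_after": float, "vas_before": float,
    "vas_after": float, "alt_uln_ratio": float, "ast_uln_ratio": float,
    "wbc": float,
}
_BOOL = ("consent", "tcm_treated")
_CSV_FIELDS = [f.name for f in fields(RawCase)]


def _case_from_mapping(row: Mapping[str, object]) -> RawCase:
    kwargs: dict[str, object] = {"case_id": str(row["case_id"])}
    for name, cast in _NUMERIC.items():
        value = row.get(name)
        kwargs[name] = None if value in (None, "") else cast(float(value))
    for name in _BOOL:
        value = row.get(name)
        if value in (None, ""):
            kwargs[name] = None
        elif isinstance(value, str):
            kwargs[name] = value.strip().lower() in ("1", "true", "yes")
        else:
            kwargs[name] = bool(value)
    for name in ("symptoms", "herbs"):
        value = row.get(name, [])
        if isinstance(value, str):
            value = [t for t in value.split(";") if t]
        kwargs[name] = list(value)
    return RawCase(**kwargs)


def read_cases_csv(path_or_buf) -> list[RawCase]:
    if isinstance(path_or_buf, (str,)) or hasattr(path_or_buf, "__fspath__"):
        with open(path_or_buf, newline="", encoding="utf-8") as fh:
            return [_case_from_mapping(row) for row in csv.DictReader(fh)]
    return [_case_from_mapping(row) for row in csv.DictReader(path_or_buf)]


def write_cases_csv(cases: Sequence[RawCase], path_or_buf) -> None:
    def _write(fh) -> None:
        writer = csv.DictWriter(fh, fieldnames=_CSV_FIELDS)
        writer.writeheader()
        for case in cases:
            row = {f: getattr(case, f) for f in _CSV_FIELDS}
            row["symptoms"] = ";".join(case.symptoms)
            row["herbs"] = ";".join(case.herbs)
            writer.writerow(row)

    if isinstance(path_or_buf, str) or hasattr(path_or_buf, "__fspath__"):
        with open(path_or_buf, "w", newline="", encoding="utf-8") as fh:
            _write(fh)
    else:
        _write(path_or_buf)


def read_cases_jsonl(path) -> list[RawCase]:
    with open(path, encoding="utf-8") as fh:
        return [_case_from_mapping(json.loads(line)) for line in fh if line.strip()]


def write_cases_jsonl(cases: Sequence[RawCase], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for case in cases:
            row = {f: getattr(case, f) for f in _CSV_FIELDS}
            fh.write(json.dumps(row, ensure_ascii=False) + "\n")


def load_term_dictionary(path_or_buf) -> TermDictionary:
    """Load a terminology dictionary from CSV.

    Columns: ``raw, canonical, class`` (symptom|herb) and optional
    ``region`` / ``is_pain`` on canonical symptom rows.
    """
    if isinstance(path_or_buf, str) or hasattr(path_or_buf, "__fspath__"):
        with open(path_or_buf, newline="", encoding="utf-8") as fh:
            rows = list(csv.DictReader(fh))
    else:
        rows = list(csv.DictReader(path_or_buf))

    symptom_map: dict[str, str] = {}
    herb_map: dict[str, str] = {}
    pain_regions: dict[str, str] = {}
    pain_lexicon: set[str] = set()
    for row in rows:
        raw, canonical, cls = row["raw"], row["canonical"], row["class"]
        target = {"symptom": symptom_map, "herb": herb_map}[cls]
        if raw in target and target[raw] != canonical:
            raise RecordError(f"conflicting dictionary entries for {raw!r}")
        target[raw] = canonical
        if row.get("region"):
            pain_regions[canonical] = row["region"]
        if (row.get("is_pain") or "").strip() in ("1", "true", "yes"):
            pain_lexicon.add(canonical)
    # canonical terms map to themselves (idempotence closure)
    for mapping in (symptom_map, herb_map):
        for canonical in list(mapping.values()):
            mapping.setdefault(canonical, canonical)
    return TermDictionary(symptom_map, herb_map, pain_regions, frozenset(pain_lexicon))


def default_dictionary() -> TermDictionary:
    """The packaged dictionary implementing the standardization rules."""
    text = resources.files("herbmine.data").joinpath("term_dictionary.csv").read_text("utf-8")
    return load_term_dictionary(io.StringIO(text))
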