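"""Frequency and proportion analyses over cleaned cases.

Counts here are case-level incidences: an item counts once per case that
contains it, and rates divide by the number of eligible cases N. Tables are
sorted by count descending with alphabetical tie-break so output files are
stable across runs.
"""

from __future__ import annotations

import csv
import io
from collections import Counter
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd

from .records import CleanCase, TermDictionary

PROPERTIES = (
    "Cold", "Cool", "Slightly cold", "Neutral", "Mild", "Warm", "Extremely hot")
FLAVORS = ("Sour", "Sweet", "Bitter", "Pungent", "Salty", "Tasteless", "Bland")
MERIDIANS = (
    "Heart", "Liver", "Spleen", "Lung", "Kidney", "Small intestine",
    "Gallbladder", "Stomach", "Large intestine", "Bladder", "Triple energizer")
CATEGORIES = (
    "Heat-clearing medicinal",
    "Dampness-draining diuretic medicinal",
    "Liver and wind-soothing medicine",
    "Wind-dampness dispelling medicinal",
    "Tonifying and replenishing medicinal",
    "Interior-warming medicinal",
    "Exterior-releasing medicinal",
    "Blood-activating and stasis-dispelling medicinal",
)


class FreqError(ValueError):
    pass


@dataclass(frozen=True)
class FrequencyRecord:
    item: str
    count: int
    rate: float  # proportion of cases, count / N


@dataclass(frozen=True)
class HerbMonograph:
    """Pharmacopeia annotation of one herb: thermal property, flavors,
    meridian tropism and efficacy category."""

    name: str
    property: str
    flavors: tuple[str, ...]
    meridians: tuple[str, ...]
    category: str

    def __post_init__(self) -> None:
        if self.property not in PROPERTIES:
            raise FreqError(f"{self.name}: unknown property {self.property!r}")
        if not self.flavors or any(f not in FLAVORS for f in self.flavors):
            raise FreqError(f"{self.name}: invalid flavors {self.flavors}")
        if not self.meridians or any(m not in MERIDIANS for m in self.meridians):
            raise FreqError(f"{self.name}: invalid meridians {self.meridians}")
        if self.category not in CATEGORIES:
            raise FreqError(f"{self.name}: unknown category {self.category!r}")


@dataclass(frozen=True)
class PainShare:
    """Occurrence-weighted split of symptoms into pain vs other."""

    pain_fraction: float
    by_location: Mapping[str, float]  # pain term -> share of ALL occurrences


def frequency_table(
    cases: Sequence[CleanCase], domain: Literal["herbs", "symptoms"]
) -> list[FrequencyRecord]:
    """Per-item case counts and rates, sorted by count desc then name."""
    if not cases:
        raise FreqError("frequency_table requires at least one case")
    if domain not in ("herbs", "symptoms"):
        raise FreqError(f"domain must be herbs|symptoms, got {domain!r}")
    n = len(cases)
    counts: Counter[str] = Counter()
    for case in cases:
        counts.update(getattr(case, domain))
    return [
        FrequencyRecord(item, c, c / n)
        for item, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def filter_high_frequency(
    table: Sequence[FrequencyRecord], min_rate: float = 0.10
) -> list[FrequencyRecord]:
    """Keep items with rate >= min_rate (the 10% enrollment filter), order kept.

    The cut is inclusive: no observed value sits on the boundary in practice
    and an inclusive bound avoids float-equality artifacts at exactly 10%.
    """
    return [rec for rec in table if rec.rate >= min_rate]


def pain_share(cases: Sequence[CleanCase], dictionary: TermDictionary) -> PainShare:
    """Split symptom occurrences into pain vs other, per the pain lexicon.

    Occurrence-weighted: each (case, symptom) pair counts once; the fractions
    over all occurrences sum to 1 and ``by_location`` sums to the pain
    fraction.
    """
    if not dictionary.pain_lexicon:
        raise FreqError("pain lexicon is empty")
    total = 0
    pain_counts: Counter[str] = Counter()
    for case in cases:
        total += len(case.symptoms)
        pain_counts.update(s for s in case.symptoms if s in dictionary.pain_lexicon)
    if total == 0:
        raise FreqError("no symptom occurrences")
    by_location = {term: c / total for term, c in sorted(pain_counts.items())}
    return PainShare(sum(pain_counts.values()) / total, by_location)


def category_shares(
    monographs: Mapping[str, HerbMonograph],
    table: Sequence[FrequencyRecord],
    weighting: Literal["frequency", "count"] = "frequency",
) -> dict[str, float]:
    """Percentage of prescriptions (or of herbs) per efficacy category.

    ``frequency`` weighting (default) weights each herb by its prescription
    count — share(c) = sum of counts in c / total counts x 100; ``count``
    weighting gives each herb equal weight. Shares sum to 100.
    """
    for rec in table:
        if rec.item not in monographs:
            raise FreqError(f"no monograph for herb {rec.item!r}")
    shares: dict[str, float] = {}
    if weighting == "frequency":
        total = sum(rec.count for rec in table)
        for rec in table:
            cat = monographs[rec.item].category
            shares[cat] = shares.get(cat, 0.0) + 100.0 * rec.count / total
    elif weighting == "count":
        for rec in table:
            cat = monographs[rec.item].category
            shares[cat] = shares.get(cat, 0.0) + 100.0 / len(table)
    else:
        raise FreqError(f"weighting must be frequency|count, got {weighting!r}")
    return dict(sorted(shares.items()))


def attribute_edges(
    monographs: Iterable[HerbMonograph],
) -> list[tuple[str, str, str]]:
    """Herb-attribute incidence edges for network export.

    One edge per (herb, attribute) pair with the attribute class as relation;
    ordering is (herb, class, attribute) with class order
    property < flavor < meridian, matching the monograph layout.
    """
    edges: list[tuple[str, str, str]] = []
    for m in sorted(monographs, key=lambda m: m.name):
        edges.append((m.name, m.property, "property"))
        edges.extend((m.name, f, "flavor") for f in m.flavors)
        edges.extend((m.name, md, "meridian") for md in m.meridians)
    return edges


# ---------------------------------------------------------------------------
# Monograph I/O
# ---------------------------------------------------------------------------

def load_monographs(path_or_buf) -> dict[str, HerbMonograph]:
    """Read a monograph table (name,property,flavors,meridians,category CSV;
    multi-valued fields ';'-separated)."""
    if isinstance(path_or_buf, str) or hasattr(path_or_buf, "__fspath__"):
        with open(path_or_buf, newline="", encoding="utf-8") as fh:
            rows = list(csv.DictReader(fh))
    else:
        rows = list(csv.DictReader(path_or_buf))
    out: dict[str, HerbMonograph] = {}
    for row in rows:
        m = HerbMonograph(
            name=row["name"],
            property=row["property"],
            flavors=tuple(row["flavors"].split(";")),
            meridians=tuple(row["meridians"].split(";")),
            category=row["category"],
        )
        out[m.name] = m
    return out


def default_monographs() -> dict[str, HerbMonograph]:
    """The packaged 16-herb monograph table."""
    text = resources.files("herbmine.data").joinpath("monographs.csv").read_text("utf-8")
    return load_monographs(io.StringIO(text))


def published_herb_counts() -> dict[str, int]:
    """Published prescription counts of the 16 high-frequency herbs."""
    text = resources.files("herbmine.data").joinpath("monographs.csv").read_text("utf-8")
    return {row["name"]: int(row["count"]) for row in csv.DictReader(io.StringIO(text))}


def published_symptom_counts() -> dict[str, int]:
    """Published case counts of the 18 high-frequency symptoms."""
    text = resources.files("herbmine.data").joinpath("symptom_counts.csv").read_text("utf-8")
    return {row["symptom"]: int(row["count"]) for row in csv.DictReader(io.StringIO(text))}


# -- tabular export ----------------------------------------------------------

def frequency_frame(table: Sequence[FrequencyRecord]) -> pd.DataFrame:
    """Frequency table as a DataFrame with rate on the percent scale."""
    return pd.DataFrame(
        [(r.item, r.count, round(100.0 * r.rate, 2)) for r in table],
        columns=["item", "count", "rate_percent"],
    )


def write_sif(edges: Sequence[tuple[str, str, str]], path) -> None:
    """Write herb-attribute edges as a SIF file (herb <TAB> relation <TAB> attr)."""
    with open(path, "w", encoding="utf-8") as fh:
        for herb, attr, cls in edges:
            fh.write(f"{herb}\t{cls}\t{attr}\n")


def node_attribute_frame(
    monographs: Iterable[HerbMonograph],
    edges: Sequence[tuple[str, str, str]],
) -> pd.DataFrame:
    """Node table (name, node_type) companion to the SIF edge list."""
    rows = [(m.name, "herb") for m in sorted(monographs, key=lambda m: m.name)]
    seen = {name for name, _ in rows}
    for _, attr, cls in edges:
        if attr not in seen:
            rows.append((attr, cls))
            seen.add(attr)
    return pd.DataFrame(rows, columns=["name", "node_type"])
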