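"""End-to-end orchestration: screen -> clean -> frequencies -> classification
-> rule mining -> clustering, with a reproducible on-disk report bundle.

All stages are pure given (inputs, config); the only randomness is the
synthetic generator's seed, so a bundle is byte-identical across runs of the
same configuration. Results go to files; progress goes to the logger.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from . import freqstats, herbcluster, records, rulemine, synthgen
from .freqstats import FrequencyRecord, HerbMonograph
from .herbcluster import Dendrogram
from .records import CleanCase, RawCase, TermDictionary
from .rulemine import AssociationRule, MiningThresholds

logger = logging.getLogger("herbmine")

FLOAT_FORMAT = "%.6g"


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception | str):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one run needs. Either ``cases_path`` or ``synthetic`` must
    be given; dictionary and monographs default to the packaged tables."""

    cases_path: str | None = None
    dictionary_path: str | None = None
    monographs_path: str | None = None
    synthetic: synthgen.SyntheticConfig | None = None
    thresholds: MiningThresholds = field(default_factory=MiningThresholds)
    min_rate: float = 0.10          # high-frequency enrollment cut
    cluster_min_count: int = 50     # incidence-matrix inclusion cut
    cluster_k: int = 3
    cluster_metric: Literal["euclidean", "jaccard"] = "euclidean"
    cluster_method: Literal["complete", "average", "single"] = "complete"
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.cases_path is None) == (self.synthetic is None):
            raise PipelineError(
                "validate", "exactly one of cases_path / synthetic required")
        if not 0 <= self.min_rate <= 1:
            raise PipelineError("validate", f"min_rate {self.min_rate} not in [0, 1]")
        if self.cluster_min_count < 0 or self.cluster_k < 1:
            raise PipelineError("validate", "cluster parameters out of range")
        for path in (self.cases_path, self.dictionary_path, self.monographs_path):
            if path is not None and not Path(path).exists():
                raise PipelineError("validate", f"input file not found: {path}")


@dataclass
class ReportBundle:
    screening: dict[str, int]               # failed-criterion tallies
    n_input: int
    n_eligible: int
    herb_table: list[FrequencyRecord]
    symptom_table: list[FrequencyRecord]
    herb_high: list[FrequencyRecord]
    symptom_high: list[FrequencyRecord]
    pain: freqstats.PainShare
    shares: dict[str, float]
    edges: list[tuple[str, str, str]]
    rules2: list[AssociationRule]
    rules3: list[AssociationRule]
    dendrogram: Dendrogram
    groups: dict[str, int]
    metadata: dict


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                result = fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc
            logger.info("stage %-10s done in %.2fs", name, time.perf_counter() - t0)
            return result
        return inner
    return wrap


def _load_inputs(config: PipelineConfig):
    dictionary = (records.load_term_dictionary(config.dictionary_path)
                  if config.dictionary_path else records.default_dictionary())
    monographs = (freqstats.load_monographs(config.monographs_path)
                  if config.monographs_path else freqstats.default_monographs())
    if config.synthetic is not None:
        raw = synthgen.generate_cases(config.synthetic)
    else:
        path = Path(config.cases_path)
        raw = (records.read_cases_jsonl(path) if path.suffix in (".jsonl", ".ndjson")
               else records.read_cases_csv(path))
    return raw, dictionary, monographs


def bubble_table(rules: Sequence[AssociationRule]) -> pd.DataFrame:
    """Rule list as a bubble-diagram-ready table.

    One row per rule; confidence and support on the percent scale, lift as a
    plain ratio (x = confidence, y = rule, size = support, color = lift).
    """
    rows = [
        (";".join(r.lhs), ";".join(r.rhs),
         round(100.0 * r.confidence, 2), round(100.0 * r.support, 2),
         round(r.lift, 3))
        for r in rules
    ]
    return pd.DataFrame(rows, columns=["lhs", "rhs", "confidence", "support", "lift"])


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute the full analysis in fixed stage order and return the bundle."""
    raw, dictionary, monographs = _stage("load")(_load_inputs)(config)

    def _screen(raw_cases: list[RawCase]):
        clean, tally = records.clean_cases(raw_cases, dictionary)
        if not clean:
            raise ValueError("no eligible cases after screening")
        return clean, tally

    clean, tally = _stage("screen")(_screen)(raw)
    logger.info("screened %d records -> %d eligible", len(raw), len(clean))

    def _freq():
        herb_table = freqstats.frequency_table(clean, "herbs")
        symptom_table = freqstats.frequency_table(clean, "symptoms")
        return (herb_table, symptom_table,
                freqstats.filter_high_frequency(herb_table, config.min_rate),
                freqstats.filter_high_frequency(symptom_table, config.min_rate),
                freqstats.pain_share(clean, dictionary))
    herb_table, symptom_table, herb_high, symptom_high, pain = _stage("frequency")(_freq)()

    def _classify():
        known = [r for r in herb_high if r.item in monographs]
        missing = [r.item for r in herb_high if r.item not in monographs]
        if missing:
            logger.warning("no monograph for %d high-frequency herbs: %s",
                           len(missing), ", ".join(missing))
        shares = freqstats.category_shares(monographs, known) if known else {}
        edges = freqstats.attribute_edges(
            monographs[r.item] for r in known)
        return shares, edges
    shares, edges = _stage("classify")(_classify)()

    def _mine():
        t_herbs = rulemine.build_transactions(clean, "herbs")
        t_both = rulemine.build_transactions(clean, "both")
        return (rulemine.mine_rules(t_herbs, 2, config.thresholds),
                rulemine.mine_rules(t_both, 3, config.thresholds))
    rules2, rules3 = _stage("mine")(_mine)()

    def _cluster():
        matrix = herbcluster.build_incidence(clean, config.cluster_min_count)
        dend = herbcluster.linkage(matrix, config.cluster_metric, config.cluster_method)
        k = min(config.cluster_k, len(dend.leaves))
        return dend, herbcluster.cut_groups(dend, k)
    dend, groups = _stage("cluster")(_cluster)()

    config_digest = hashlib.sha256(repr(config).encode()).hexdigest()[:16]
    return ReportBundle(
        screening=dict(sorted(tally.items())),
        n_input=len(raw), n_eligible=len(clean),
        herb_table=herb_table, symptom_table=symptom_table,
        herb_high=herb_high, symptom_high=symptom_high,
        pain=pain, shares=shares, edges=edges,
        rules2=rules2, rules3=rules3,
        dendrogram=dend, groups=groups,
        metadata={"version": __version__, "seed": config.seed,
                  "config_sha256": config_digest},
    )


def write_bundle(bundle: ReportBundle, outdir: str | Path) -> None:
    """Write the bundle as plain-text tables; float formatting is fixed so
    repeated runs produce byte-identical files."""
    out = Path(outdir)
    created = not out.exists()
    out.mkdir(parents=True, exist_ok=True)
    try:
        kw = {"index": False, "float_format": FLOAT_FORMAT}
        freqstats.frequency_frame(bundle.herb_table).to_csv(out / "herb_frequency.csv", **kw)
        freqstats.frequency_frame(bundle.symptom_table).to_csv(
            out / "symptom_frequency.csv", **kw)
        freqstats.frequency_frame(bundle.herb_high).to_csv(
            out / "herb_high_frequency.csv", **kw)
        freqstats.frequency_frame(bundle.symptom_high).to_csv(
            out / "symptom_high_frequency.csv", **kw)
        pd.DataFrame(
            sorted(bundle.shares.items()), columns=["category", "share_percent"]
        ).to_csv(out / "category_shares.csv", **kw)
        bubble_table(bundle.rules2).to_csv(out / "rules_order2.csv", **kw)
        bubble_table(bundle.rules3).to_csv(out / "rules_order3.csv", **kw)
        freqstats.write_sif(bundle.edges, out / "herb_attributes.sif")
        (out / "dendrogram.nwk").write_text(
            herbcluster.to_newick(bundle.dendrogram) + "\n", encoding="utf-8")
        herbcluster.groups_frame(bundle.groups).to_csv(out / "herb_groups.csv", **kw)
        manifest = {
            "metadata": bundle.metadata,
            "n_input": bundle.n_input,
            "n_eligible": bundle.n_eligible,
            "screening_failures": bundle.screening,
            "pain_fraction": round(bundle.pain.pain_fraction, 6),
            "pain_by_location": {k: round(v, 6)
                                 for k, v in bundle.pain.by_location.items()},
            "n_rules_order2": len(bundle.rules2),
            "n_rules_order3": len(bundle.rules3),
            "cluster_groups": bundle.groups,
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    except Exception as exc:
        if created:
            shutil.rmtree(out, ignore_errors=True)
        raise PipelineError("write", exc) from exc


def config_from_yaml(path: str | Path) -> PipelineConfig:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    thresholds = MiningThresholds(**data.get("thresholds", {}))
    synthetic = (synthgen.config_from_dict(data["synthetic"])
                 if "synthetic" in data else None)
    keys = ("cases_path", "dictionary_path", "monographs_path", "min_rate",
            "cluster_min_count", "cluster_k", "cluster_metric",
            "cluster_method", "seed")
    kwargs = {k: data[k] for k in keys if k in data}
    return PipelineConfig(synthetic=synthetic, thresholds=thresholds, **kwargs)
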