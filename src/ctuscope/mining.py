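"""Selection of marine water-column, environmental, quality-passing sequences.

Records are classified by isolation source with an ordered, case-insensitive
keyword vocabulary (exclusions first, so "marine sediment" can never match a
water-column pattern), flagged as environmental from organism name and strain
conventions, filtered on quality scores and ungapped length, and finally
selected clade-wise: a guide clade is taken wholesale when at least half its
members trace to the marine water column and none is non-marine.
"""
from __future__ import annotations

import re
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import pandas as pd

from .model import Alignment, SequenceRecord, VALID_DOMAINS

MARINE_WATER_COLUMN = "marine_water_column"
OTHER_MARINE = "other_marine"
NON_MARINE = "non_marine"

_DEFAULT_MWC = (
    "seawater",
    "sea water",
    "water column",
    "ocean water",
    "oceanic water",
    "open ocean",
    "pelagic",
    "bathypelagic",
    "mesopelagic",
    "epipelagic",
    "brine-seawater",
)
_DEFAULT_OTHER_MARINE = (
    "sediment",
    "hydrothermal",
    "vent",
    "seafloor",
    "subseafloor",
    "sponge",
    "coral",
    "microbial mat",
    "salt marsh",
)
_DEFAULT_EXCLUSION = (
    "soil",
    "freshwater",
    "fresh water",
    "lake",
    "river",
    "groundwater",
    "gut",
    "feces",
    "faeces",
    "sludge",
    "rumen",
    "rhizosphere",
    "compost",
    "wastewater",
)
_DEFAULT_ENVIRONMENTAL_NAME = (
    "uncultured",
    "unidentified",
    "environmental",
    "metagenome",
    "clone",
)
_DEFAULT_CLONE_STRAIN = ("clone",)


def _compile(patterns: Iterable[str]) -> tuple[re.Pattern, ...]:
    compiled = tuple(re.compile(p, re.IGNORECASE) for p in patterns)
    if not compiled:
        raise ValueError("pattern list must be non-empty")
    return compiled


@dataclass(frozen=True)
class KeywordRuleSet:
    """Ordered keyword vocabularies driving source and origin classification."""

    marine_water_column_patterns: tuple[str, ...] = _DEFAULT_MWC
    other_marine_patterns: tuple[str, ...] = _DEFAULT_OTHER_MARINE
    exclusion_patterns: tuple[str, ...] = _DEFAULT_EXCLUSION
    environmental_name_patterns: tuple[str, ...] = _DEFAULT_ENVIRONMENTAL_NAME
    clone_strain_patterns: tuple[str, ...] = _DEFAULT_CLONE_STRAIN

    def __post_init__(self) -> None:
        for name in (
            "marine_water_column_patterns",
            "other_marine_patterns",
            "exclusion_patterns",
            "environmental_name_patterns",
            "clone_strain_patterns",
        ):
            _compile(getattr(self, name))

    @classmethod
    def default(cls) -> "KeywordRuleSet":
        return cls()


def classify_isolation_source(text: str, rules: KeywordRuleSet) -> str:
    """Classify an isolation-source string; total and deterministic.

    Exclusion patterns win over marine water-column patterns, which win over
    other-marine patterns; no match (or empty text) is non-marine.
    """
    if not text or not text.strip():
        return NON_MARINE
    for pattern in _compile(rules.exclusion_patterns):
        if pattern.search(text):
            return NON_MARINE
    for pattern in _compile(rules.marine_water_column_patterns):
        if pattern.search(text):
            return MARINE_WATER_COLUMN
    for pattern in _compile(rules.other_marine_patterns):
        if pattern.search(text):
            return OTHER_MARINE
    return NON_MARINE


def flag_environmental(record: SequenceRecord, rules: KeywordRuleSet) -> bool:
    """True iff the record looks like an uncultivated environmental clone.

    The organism name must match an environmental pattern, and the strain
    field must be empty or itself look like a clone identifier — a culture
    collection strain overrides an environmental-sounding name.
    """
    name_hit = any(
        p.search(record.organism_name)
        for p in _compile(rules.environmental_name_patterns)
    )
    if not name_hit:
        return False
    if not record.strain.strip():
        return True
    return any(
        p.search(record.strain) for p in _compile(rules.clone_strain_patterns)
    )


@dataclass
class RecordFilter:
    """Per-record filter outcome."""

    id: str
    source_class: str = NON_MARINE
    environmental: bool = False
    pass_pintail: bool = False
    pass_seq_quality: bool = False
    pass_align_quality: bool = False
    pass_length: bool = False
    quality_ok: bool = False
    verdict: bool = False
    reason: str = ""


@dataclass
class FilterReport:
    """Filter outcomes for every record of one alignment."""

    rows: dict[str, RecordFilter] = field(default_factory=dict)

    def __getitem__(self, record_id: str) -> RecordFilter:
        return self.rows[record_id]

    def __iter__(self):
        return iter(self.rows.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [vars(r) for r in self.rows.values()]
        ).set_index("id")


def apply_quality_filters(
    alignment: Alignment,
    min_pintail: float = 75.0,
    min_seq_quality: float = 75.0,
    min_align_quality: float = 90.0,
    min_len_bacteria: int = 1200,
    min_len_archaea: int = 900,
) -> FilterReport:
    """Quality screening: scores are inclusive (>=), lengths strict (>).

    A missing quality score fails its criterion; an unrecognized domain
    fails the length criterion with reason "unknown domain".  Length is
    measured on the ungapped sequence.
    """
    report = FilterReport()
    for rec in alignment:
        rf = RecordFilter(id=rec.id)
        rf.pass_pintail = rec.pintail is not None and rec.pintail >= min_pintail
        rf.pass_seq_quality = (
            rec.seq_quality is not None and rec.seq_quality >= min_seq_quality
        )
        rf.pass_align_quality = (
            rec.align_quality is not None
            and rec.align_quality >= min_align_quality
        )
        if rec.domain not in VALID_DOMAINS:
            rf.pass_length = False
            rf.reason = "unknown domain"
        else:
            cutoff = (
                min_len_bacteria if rec.domain == "Bacteria" else min_len_archaea
            )
            rf.pass_length = rec.ungapped_length > cutoff
        rf.quality_ok = (
            rf.pass_pintail
            and rf.pass_seq_quality
            and rf.pass_align_quality
            and rf.pass_length
        )
        report.rows[rec.id] = rf
    return report


def classify_records(
    alignment: Alignment, rules: KeywordRuleSet, report: FilterReport
) -> FilterReport:
    """Fill source class and environmental flags into an existing report."""
    for rec in alignment:
        rf = report.rows[rec.id]
        rf.source_class = classify_isolation_source(rec.isolation_source, rules)
        rf.environmental = flag_environmental(rec, rules)
    return report


def select_clades_for_trees(
    prior_clades: Mapping[str, Iterable[str]],
    report: FilterReport,
    min_marine_fraction: float = 0.5,
) -> set[str]:
    """Whole-clade selection under the marine-fraction inclusion rule.

    A guide clade is selected entirely iff at least ``min_marine_fraction``
    of its members are marine water-column sequences and every remaining
    member is at least other-marine (a single non-marine member vetoes the
    clade).  Records not covered by any clade are treated as singleton
    clades.  The returned ids are additionally restricted to records that
    pass the quality filters and are environmental.
    """
    clades: dict[str, list[str]] = {
        name: list(members) for name, members in prior_clades.items()
    }
    covered = {rid for members in clades.values() for rid in members}
    for rid in report.rows:
        if rid not in covered:
            clades[f"__singleton__{rid}"] = [rid]

    selected: set[str] = set()
    for members in clades.values():
        classes = [report.rows[rid].source_class for rid in members if rid in report.rows]
        if not classes:
            continue
        n_mwc = sum(c == MARINE_WATER_COLUMN for c in classes)
        any_non_marine = any(c == NON_MARINE for c in classes)
        if any_non_marine:
            continue
        if n_mwc / len(classes) >= min_marine_fraction:
            selected.update(rid for rid in members if rid in report.rows)

    final: set[str] = set()
    for rid in selected:
        rf = report.rows[rid]
        rf.verdict = rf.quality_ok and rf.environmental
        if rf.verdict:
            final.add(rid)
    return final


def mine(
    alignment: Alignment,
    prior_clades: Mapping[str, Iterable[str]],
    rules: KeywordRuleSet | None = None,
    min_marine_fraction: float = 0.5,
    **quality_kwargs,
) -> tuple[set[str], FilterReport]:
    """Run the full mining stage; returns selected ids and the report."""
    rules = rules or KeywordRuleSet.default()
    report = apply_quality_filters(alignment, **quality_kwargs)
    classify_records(alignment, rules, report)
    selected = select_clades_for_trees(
        prior_clades, report, min_marine_fraction=min_marine_fraction
    )
    return selected, report
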