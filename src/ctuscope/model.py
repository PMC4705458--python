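"""Core domain types shared across the pipeline.

The pipeline operates on aligned SSU rRNA sequences carrying database-style
metadata, a phylogeny over the same sequence ids, and per-sample count /
environment tables.  Everything downstream (mining, clustering, clade
recognition, ecology statistics) consumes these types.
"""
from __future__ import annotations

from collections.abc import Iterable, Iterator
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

#: The five taxonomic ranks handled by the pipeline, coarsest first.
RANKS: tuple[str, ...] = ("Phylum", "Class", "Order", "Family", "Genus")

#: Default percent-identity threshold at which each rank is delineated.
DEFAULT_RANK_IDENTITY: dict[str, float] = {
    "Phylum": 75.0,
    "Class": 78.5,
    "Order": 82.0,
    "Family": 86.5,
    "Genus": 94.5,
}

GAP_CHARS = frozenset("-.")

# Base encoding used throughout: unambiguous bases 0..3 (T and U equated),
# everything else (gaps, N, IUPAC ambiguity codes) -1.
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
_CODE_BASE = np.array(list("ACGT"))

VALID_DOMAINS = frozenset({"Bacteria", "Archaea"})


def encode_sequence(seq: str) -> np.ndarray:
    """Encode an aligned sequence as int8 codes (-1 for gap/ambiguous)."""
    out = np.full(len(seq), -1, dtype=np.int8)
    for i, ch in enumerate(seq.upper()):
        out[i] = _BASE_CODE.get(ch, -1)
    return out


@dataclass
class SequenceRecord:
    """One aligned sequence with its database-style metadata.

    Quality scores (``pintail``, ``seq_quality``, ``align_quality``) may be
    ``None`` when absent from the source metadata; absent scores later fail
    the quality filter rather than defaulting to zero.
    """

    id: str
    organism_name: str = ""
    strain: str = ""
    isolation_source: str = ""
    pintail: float | None = None
    seq_quality: float | None = None
    align_quality: float | None = None
    domain: str = ""
    aligned_seq: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record must have a non-empty id")
        for name in ("pintail", "seq_quality", "align_quality"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= float(v) <= 100.0):
                raise ValueError(
                    f"record {self.id!r}: {name}={v} outside [0, 100]"
                )

    @property
    def ungapped_length(self) -> int:
        return sum(1 for c in self.aligned_seq if c not in GAP_CHARS)


@dataclass
class Alignment:
    """An ordered collection of equal-length aligned records."""

    records: list[SequenceRecord]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("alignment has no records")
        seen: set[str] = set()
        width = len(self.records[0].aligned_seq)
        if width < 1:
            raise ValueError(
                f"alignment record {self.records[0].id!r} is empty"
            )
        for rec in self.records:
            if rec.id in seen:
                raise ValueError(f"duplicate sequence id {rec.id!r}")
            seen.add(rec.id)
            if len(rec.aligned_seq) != width:
                raise ValueError(
                    f"ragged alignment: record {rec.id!r} has length "
                    f"{len(rec.aligned_seq)}, expected {width}"
                )

    @property
    def n_columns(self) -> int:
        return len(self.records[0].aligned_seq)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def get(self, record_id: str) -> SequenceRecord:
        for rec in self.records:
            if rec.id == record_id:
                return rec
        raise KeyError(record_id)

    def subset(self, ids: Iterable[str]) -> "Alignment":
        """New alignment restricted to `ids`, preserving record order."""
        wanted = set(ids)
        kept = [r for r in self.records if r.id in wanted]
        missing = wanted - {r.id for r in kept}
        if missing:
            raise KeyError(f"ids not in alignment: {sorted(missing)}")
        return Alignment(kept)

    def encode(self) -> np.ndarray:
        """(n_records, n_columns) int8 matrix of base codes."""
        return np.vstack([encode_sequence(r.aligned_seq) for r in self.records])


@dataclass(frozen=True)
class RankThresholds:
    """Percent-identity thresholds per rank; cut heights are 100 - identity."""

    identity: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RANK_IDENTITY)
    )

    def __post_init__(self) -> None:
        if tuple(self.identity) != RANKS:
            missing = [r for r in RANKS if r not in self.identity]
            if missing:
                raise ValueError(f"missing thresholds for ranks {missing}")
            object.__setattr__(
                self, "identity", {r: self.identity[r] for r in RANKS}
            )
        values = [self.identity[r] for r in RANKS]
        if any(not (0.0 < v < 100.0) for v in values):
            raise ValueError(f"identity thresholds must lie in (0, 100): {values}")
        if any(b <= a for a, b in zip(values, values[1:])):
            raise ValueError(
                f"identity thresholds must strictly increase from "
                f"{RANKS[0]} to {RANKS[-1]}: {values}"
            )

    @property
    def distance_cutoffs(self) -> dict[str, float]:
        return {r: 100.0 - v for r, v in self.identity.items()}


@dataclass
class Phylogeny:
    """A dendropy tree plus the designated outgroup leaf ids."""

    tree: dendropy.Tree
    outgroup_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        labels = self.leaf_ids()
        if len(labels) != len(set(labels)):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise ValueError(f"duplicate leaf labels in tree: {dupes}")
        missing = set(self.outgroup_ids) - set(labels)
        if missing:
            raise ValueError(
                f"outgroup ids are not tree leaves: {sorted(missing)}"
            )
        self.outgroup_ids = frozenset(self.outgroup_ids)

    def leaf_ids(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def ingroup_ids(self) -> list[str]:
        return [x for x in self.leaf_ids() if x not in self.outgroup_ids]

    def as_newick(self) -> str:
        return (
            self.tree.as_string(schema="newick", suppress_rooting=True).strip()
        )

    def bipartitions(self) -> set[frozenset[str]]:
        """Leaf-set bipartitions (smaller side, normalized) — topology key."""
        all_leaves = frozenset(self.leaf_ids())
        out: set[frozenset[str]] = set()
        for node in self.tree.preorder_node_iter():
            below = frozenset(
                lf.taxon.label for lf in node.leaf_iter()
            )
            if 1 < len(below) < len(all_leaves):
                other = all_leaves - below
                out.add(min(below, other, key=lambda s: (len(s), sorted(s))))
        return out

    def restricted_to(self, ids: Iterable[str]) -> "Phylogeny":
        """Prune to the given leaf ids (outgroup flags preserved)."""
        keep = set(ids)
        missing = keep - set(self.leaf_ids())
        if missing:
            raise KeyError(f"ids not in tree: {sorted(missing)}")
        clone = self.tree.clone(depth=1)
        taxa = [t for t in clone.taxon_namespace if t.label in keep]
        clone.retain_taxa(taxa)
        return Phylogeny(clone, frozenset(self.outgroup_ids) & keep)


@dataclass
class SampleTable:
    """Integer counts per (sample, clade); samples are rows."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            bad = self.counts[(self.counts < 0).any(axis=1)].index[0]
            raise ValueError(f"negative count in sample {bad!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def clade_ids(self) -> list[str]:
        return list(self.counts.columns)


#: Numeric environmental variables recognized by the correlation screen.
ENV_NUMERIC_VARS: tuple[str, ...] = (
    "depth",
    "temperature",
    "salinity",
    "dissolved_oxygen",
    "chlorophyll_a",
    "nitrate",
    "phosphate",
)

ENV_CATEGORICAL_VARS: tuple[str, ...] = ("biome", "water_body")


@dataclass
class EnvTable:
    """Per-sample environmental context: numeric variables + categories."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        for var in ENV_NUMERIC_VARS:
            if var in self.data.columns:
                self.data[var] = pd.to_numeric(self.data[var], errors="coerce")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def numeric(self) -> pd.DataFrame:
        cols = [c for c in ENV_NUMERIC_VARS if c in self.data.columns]
        return self.data[cols]

    def category(self, name: str) -> pd.Series:
        if name not in self.data.columns:
            raise KeyError(f"no categorical column {name!r}")
        return self.data[name]
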