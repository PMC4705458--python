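"""Readers and writers for the formats the pipeline touches.

Sequence data travels as aligned FASTA plus a tab-separated metadata sidecar
keyed by sequence id; trees as Newick with outgroup ids listed one per line
in a companion file; count/environment tables as TSV (UTF-8, '.' decimal).
All writers are byte-deterministic for fixed inputs.
"""
from __future__ import annotations

import math
import os
import warnings
from collections.abc import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO

from .model import (
    Alignment,
    EnvTable,
    Phylogeny,
    SampleTable,
    SequenceRecord,
)

METADATA_COLUMNS = (
    "id",
    "organism_name",
    "strain",
    "isolation_source",
    "pintail",
    "seq_quality",
    "align_quality",
    "domain",
)


def _opt_float(value) -> float | None:
    if value is None:
        return None
    s = str(value).strip()
    if s == "" or s.upper() in {"NA", "NAN", "NONE"}:
        return None
    return float(s)


def read_alignment_fasta(path, metadata_path=None) -> Alignment:
    """Read an aligned FASTA, merging the tab-separated metadata sidecar.

    Records absent from the metadata get empty string fields and ``None``
    quality scores (which downstream quality filters treat as failing).
    Metadata rows whose id is not in the FASTA produce a warning and are
    skipped.  Ragged alignments and duplicate ids raise ``ValueError``.
    """
    meta: dict[str, dict] = {}
    if metadata_path is not None:
        table = pd.read_csv(metadata_path, sep="\t", dtype=str, keep_default_na=False)
        if "id" not in table.columns:
            raise ValueError(f"metadata file {metadata_path} lacks an 'id' column")
        for row in table.to_dict("records"):
            meta[row["id"]] = row

    records: list[SequenceRecord] = []
    seen: set[str] = set()
    width: int | None = None
    for seq_rec in SeqIO.parse(str(path), "fasta"):
        rid = seq_rec.id
        if rid in seen:
            raise ValueError(f"duplicate sequence id {rid!r} in {path}")
        seen.add(rid)
        seq = str(seq_rec.seq)
        if width is None:
            width = len(seq)
        elif len(seq) != width:
            raise ValueError(
                f"ragged alignment: record {rid!r} has length {len(seq)}, "
                f"expected {width}"
            )
        row = meta.get(rid, {})
        records.append(
            SequenceRecord(
                id=rid,
                organism_name=row.get("organism_name", ""),
                strain=row.get("strain", ""),
                isolation_source=row.get("isolation_source", ""),
                pintail=_opt_float(row.get("pintail")),
                seq_quality=_opt_float(row.get("seq_quality")),
                align_quality=_opt_float(row.get("align_quality")),
                domain=row.get("domain", ""),
                aligned_seq=seq,
            )
        )
    orphans = sorted(set(meta) - seen)
    if orphans:
        warnings.warn(
            f"{len(orphans)} metadata ids absent from FASTA "
            f"(first: {orphans[0]!r}); skipped",
            stacklevel=2,
        )
    if not records:
        raise ValueError(f"no sequences found in {path}")
    return Alignment(records)


def _fmt_opt(value: float | None) -> str:
    if value is None:
        return "NA"
    return format(float(value), ".10g")


def write_alignment_fasta(alignment: Alignment, path, metadata_path=None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in alignment:
            fh.write(f">{rec.id}\n{rec.aligned_seq}\n")
    if metadata_path is None:
        return
    with open(metadata_path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(METADATA_COLUMNS) + "\n")
        for rec in alignment:
            fh.write(
                "\t".join(
                    (
                        rec.id,
                        rec.organism_name,
                        rec.strain,
                        rec.isolation_source,
                        _fmt_opt(rec.pintail),
                        _fmt_opt(rec.seq_quality),
                        _fmt_opt(rec.align_quality),
                        rec.domain,
                    )
                )
                + "\n"
            )


def read_tree_newick(path, outgroup_ids: Iterable[str] = ()) -> Phylogeny:
    """Parse a Newick tree, preserving branch lengths and polytomies."""
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"failed to parse Newick file {path}: {exc}") from exc
    return Phylogeny(tree, frozenset(outgroup_ids))


def write_tree_newick(phylogeny: Phylogeny, path, outgroup_path=None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(phylogeny.as_newick() + "\n")
    if outgroup_path is not None:
        with open(outgroup_path, "w", encoding="utf-8") as fh:
            for og in sorted(phylogeny.outgroup_ids):
                fh.write(og + "\n")


def read_outgroup_ids(path) -> frozenset[str]:
    with open(path, encoding="utf-8") as fh:
        return frozenset(line.strip() for line in fh if line.strip())


def read_tables(sample_path, env_path) -> tuple[SampleTable, EnvTable]:
    """Read a clade-count TSV (samples x clades) and an environment TSV.

    Missing numeric environment cells become NaN markers; a count table
    sample missing from the environment table triggers a warning; a
    negative count is a hard error.
    """
    counts = pd.read_csv(sample_path, sep="\t", index_col=0)
    counts.index = counts.index.astype(str)
    for col in counts.columns:
        counts[col] = pd.to_numeric(counts[col])
    if counts.isna().any().any():
        raise ValueError(f"non-numeric count cell in {sample_path}")
    sample_table = SampleTable(counts.astype(np.int64))

    env = pd.read_csv(
        env_path, sep="\t", index_col=0, na_values=["NA", ""], keep_default_na=True
    )
    env.index = env.index.astype(str)
    env_table = EnvTable(env)

    missing = sorted(set(sample_table.sample_ids) - set(env_table.sample_ids))
    if missing:
        warnings.warn(
            f"{len(missing)} count-table samples absent from environment "
            f"table (first: {missing[0]!r})",
            stacklevel=2,
        )
    return sample_table, env_table


def write_tables(sample_table: SampleTable, env_table: EnvTable,
                 sample_path, env_path) -> None:
    sample_table.counts.to_csv(sample_path, sep="\t", index_label="sample")
    env_table.data.to_csv(env_path, sep="\t", index_label="sample", na_rep="NA")


def _fmt_num(x) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "NA"
    return format(float(x), ".10g")


def write_outputs(hierarchy, results: dict, out_dir) -> dict[str, str]:
    """Write the taxonomy, lineage, and statistics tables for one run.

    ``results`` may hold ``associations`` (AssociationResult list),
    ``correlations`` (CorrelationResult list) and ``scaled_summary``
    (DataFrame).  Rows are ordered deterministically: the taxonomy follows
    the hierarchy's preorder, statistics tables are sorted lexicographically.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths: dict[str, str] = {}

    tax_path = os.path.join(out_dir, "taxonomy.tsv")
    with open(tax_path, "w", encoding="utf-8") as fh:
        fh.write("name\trank\tparent\tn_members\tstatus\tmembers\n")
        for ctu in hierarchy.all_ctus():
            fh.write(
                f"{ctu.name}\t{ctu.rank}\t{ctu.parent_name}\t"
                f"{len(ctu.members)}\t{ctu.status}\t"
                f"{','.join(ctu.members)}\n"
            )
    paths["taxonomy"] = tax_path

    lin_path = os.path.join(out_dir, "lineages.tsv")
    with open(lin_path, "w", encoding="utf-8") as fh:
        fh.write("id\tlineage\n")
        for leaf, lineage in sorted(hierarchy.leaf_lineages().items()):
            fh.write(f"{leaf}\t{lineage}\n")
    paths["lineages"] = lin_path

    assoc_path = os.path.join(out_dir, "associations.tsv")
    with open(assoc_path, "w", encoding="utf-8") as fh:
        fh.write("clade\tcategory\tstatistic\tn_perm\tp_value\tseed\n")
        for r in sorted(
            results.get("associations", ()), key=lambda r: (r.clade, r.category)
        ):
            fh.write(
                f"{r.clade}\t{r.category}\t{_fmt_num(r.statistic)}\t"
                f"{r.n_perm}\t{_fmt_num(r.p_value)}\t{r.seed}\n"
            )
    paths["associations"] = assoc_path

    corr_path = os.path.join(out_dir, "correlations.tsv")
    with open(corr_path, "w", encoding="utf-8") as fh:
        fh.write("clade\tvariable\trho\tp_value\tn_pairs\treported\n")
        for r in sorted(
            results.get("correlations", ()), key=lambda r: (r.clade, r.variable)
        ):
            fh.write(
                f"{r.clade}\t{r.variable}\t{_fmt_num(r.rho)}\t"
                f"{_fmt_num(r.p_value)}\t{r.n_pairs}\t"
                f"{'yes' if r.reported else 'no'}\n"
            )
    paths["correlations"] = corr_path

    summary = results.get("scaled_summary")
    if summary is not None:
        sum_path = os.path.join(out_dir, "scaled_summary.tsv")
        out = summary.sort_index()
        out = out[sorted(out.columns)]
        with open(sum_path, "w", encoding="utf-8") as fh:
            fh.write("clade\t" + "\t".join(out.columns) + "\n")
            for clade, row in out.iterrows():
                fh.write(
                    f"{clade}\t"
                    + "\t".join(_fmt_num(v) for v in row.to_numpy())
                    + "\n"
                )
        paths["scaled_summary"] = sum_path

    return paths


def write_phylip_distances(ids: Sequence[str], matrix: np.ndarray, path) -> None:
    """Write a square PHYLIP distance matrix (percent distances)."""
    n = len(ids)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{n}\n")
        for i, rid in enumerate(ids):
            row = " ".join(format(matrix[i, j], ".6f") for j in range(n))
            fh.write(f"{rid} {row}\n")


def read_phylip_distances(path) -> tuple[list[str], np.ndarray]:
    with open(path, encoding="utf-8") as fh:
        n = int(fh.readline().strip())
        ids: list[str] = []
        rows = []
        for _ in range(n):
            parts = fh.readline().split()
            ids.append(parts[0])
            rows.append([float(x) for x in parts[1 : n + 1]])
    return ids, np.asarray(rows, dtype=float)


def write_partitions_tsv(partitions, cutoffs: dict[str, float], path) -> None:
    """Write rank partitions as TSV rows (rank, cutoff, otu, member ids)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("rank\tcutoff\totu\tmembers\n")
        for rank, assignment in partitions.items():
            by_otu: dict[int, list[str]] = {}
            for rid, otu in assignment.items():
                by_otu.setdefault(otu, []).append(rid)
            for otu in sorted(by_otu):
                members = ",".join(sorted(by_otu[otu]))
                fh.write(f"{rank}\t{_fmt_num(cutoffs[rank])}\t{otu}\t{members}\n")
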