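"""End-to-end orchestration: mine -> cluster -> recognize -> ecology.

Operates on a fixture directory (as written by the simulator or assembled
by hand in the same layout) and writes deterministic outputs.
"""
from __future__ import annotations

import json
import os

from . import ecology, io as cio, mining, recognition
from .clustering import cluster_at_thresholds
from .model import RankThresholds
from .simulate import read_fixture_bundle


def run_all(
    fixture_dir: str,
    out_dir: str,
    seed: int = 0,
    context_name: str = "",
    n_perm: int = 999,
    alpha: float = 0.05,
    min_conservation: float = 0.10,
    thresholds: RankThresholds | None = None,
    rules: mining.KeywordRuleSet | None = None,
) -> dict:
    """Run every stage on one fixture directory; returns a summary dict."""
    os.makedirs(out_dir, exist_ok=True)
    bundle = read_fixture_bundle(fixture_dir)
    thresholds = thresholds or RankThresholds()

    # --- mining ---------------------------------------------------------
    selected, report = mining.mine(
        bundle.alignment, bundle.prior_clades, rules=rules
    )
    report.to_frame().sort_index().to_csv(
        os.path.join(out_dir, "filter_report.tsv"), sep="\t"
    )
    if len(selected) < 2:
        raise ValueError("fewer than 2 sequences survived mining")

    # --- clustering -----------------------------------------------------
    mined = bundle.alignment.subset(sorted(selected))
    mask, dist, dendro, partitions = cluster_at_thresholds(
        mined, thresholds, min_conservation=min_conservation
    )
    cio.write_phylip_distances(
        dist.ids, dist.values, os.path.join(out_dir, "distances.phylip")
    )
    cio.write_partitions_tsv(
        partitions.assignments,
        thresholds.distance_cutoffs,
        os.path.join(out_dir, "partitions.tsv"),
    )

    # --- recognition ----------------------------------------------------
    pruned = bundle.phylogeny.restricted_to(
        selected | set(bundle.phylogeny.outgroup_ids)
    )
    rooted, hierarchy = recognition.recognize(
        pruned, partitions, context_name=context_name,
        annotations=bundle.annotations,
    )
    cio.write_tree_newick(rooted, os.path.join(out_dir, "rooted_tree.nwk"))

    # --- ecology --------------------------------------------------------
    clade_members = {
        genus: sorted(set(group.index) & selected)
        for genus, group in bundle.truth.groupby("Genus")
    }
    lineage_map = ecology.lineage_map_from_hierarchy(hierarchy, clade_members)
    lineage_map.setdefault("unclassified", ecology.UNCLASSIFIED)
    abundance = ecology.aggregate_relative_abundance(
        bundle.sample_table, lineage_map, rank="Order"
    )
    groups = bundle.env_table.category("water_body")
    associations = ecology.site_association_test(
        abundance, groups, n_perm=n_perm, seed=seed
    )
    correlations = ecology.spearman_screen(abundance, bundle.env_table, alpha=alpha)
    summary_table = ecology.scaled_summary(abundance, groups, scope="all")

    cio.write_outputs(
        hierarchy,
        {
            "associations": associations,
            "correlations": correlations,
            "scaled_summary": summary_table,
        },
        out_dir,
    )

    summary = {
        "n_input": len(bundle.alignment),
        "n_selected": len(selected),
        "n_masked_columns": mask.n_retained,
        "rank_summary": hierarchy.summary(),
        "n_associations_reported": sum(
            r.p_value < alpha for r in associations
        ),
        "n_correlations_reported": sum(r.reported for r in correlations),
    }
    with open(os.path.join(out_dir, "run_summary.json"), "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return summary
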