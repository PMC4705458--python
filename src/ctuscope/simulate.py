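"""Ground-truthed fixture generation for every pipeline stage.

Trees carry planted rank structure: each taxon at each rank is a clade whose
crown height is chosen so that the expected pairwise mismatch distance of
its members falls strictly between the adjacent rank cutoffs.  Sequences
are evolved along the tree under Jukes-Cantor, database-style metadata is
synthesized (with optional contaminants exercising every filter branch),
and clade x sample count tables are drawn with planted category enrichments
and monotone environmental links.  Everything is seed-deterministic.
"""
from __future__ import annotations

import json
import os
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np
import pandas as pd

from . import io as cio
from .model import (
    Alignment,
    EnvTable,
    Phylogeny,
    RankThresholds,
    RANKS,
    SampleTable,
    SequenceRecord,
    _CODE_BASE,
)

N_OUTGROUP = 5

#: Ranges used when drawing numeric environmental variables.
ENV_RANGES = {
    "depth": (5.0, 4000.0),
    "temperature": (-1.0, 28.0),
    "salinity": (32.0, 38.0),
    "dissolved_oxygen": (2.0, 9.0),
    "chlorophyll_a": (0.01, 3.0),
    "nitrate": (0.0, 35.0),
    "phosphate": (0.0, 2.5),
}


@dataclass(frozen=True)
class IndicatorEffect:
    """Planted enrichment: an order's abundance is multiplied by
    ``fold_change`` in samples of ``category``."""

    order: str
    category: str
    fold_change: float


@dataclass(frozen=True)
class EnvLink:
    """Planted monotone link between an order's abundance and a variable."""

    order: str
    variable: str
    direction: int  # +1 or -1
    strength: float


@dataclass
class SimulationParams:
    """Everything needed to regenerate one fixture bit-exactly."""

    seed: int = 0
    n_orders: int = 3
    families_per_order: int = 2
    genera_per_family: int = 2
    leaves_per_genus: int = 10
    # expected percent mismatch distance between leaves whose most recent
    # common ancestor sits at each rank; must interleave the rank cutoffs
    within_genus: float = 2.5
    within_family: float = 9.5
    within_order: float = 15.75
    within_class: float = 19.75
    within_phylum: float = 23.25
    outgroup_divergence: float = 32.0
    sequence_length: int = 1200
    gap_column_rate: float = 0.05
    domain: str = "Archaea"
    contaminant_fraction: float = 0.0
    other_marine_fraction: float = 0.0
    n_samples_per_category: dict[str, int] = field(
        default_factory=lambda: {"LP ocean water": 20, "HP coastal water": 20}
    )
    indicator_effects: tuple[IndicatorEffect, ...] = ()
    env_links: tuple[EnvLink, ...] = ()
    noise_dispersion: float = 0.2
    reads_per_sample: int = 10_000
    env_missing_rate: float = 0.05
    annotate_orders: tuple[str, ...] = ()

    def rank_heights(self, thresholds: RankThresholds | None = None) -> dict[str, float]:
        """Planted crown distances per rank, validated against the cutoffs."""
        thresholds = thresholds or RankThresholds()
        cutoffs = thresholds.distance_cutoffs
        heights = {
            "Genus": self.within_genus,
            "Family": self.within_family,
            "Order": self.within_order,
            "Class": self.within_class,
            "Phylum": self.within_phylum,
        }
        ordered = [heights[r] for r in RANKS[::-1]]  # genus .. phylum
        if any(b <= a for a, b in zip(ordered, ordered[1:])):
            raise ValueError(f"divergence levels must strictly increase: {ordered}")
        fine_cuts = [cutoffs[r] for r in RANKS[::-1]]
        # each rank's crown must sit below its own cutoff and above the next
        # finer cutoff, so the planted taxa are separable by construction
        for i, rank in enumerate(RANKS[::-1]):
            if not heights[rank] < fine_cuts[i]:
                raise ValueError(
                    f"within-{rank} divergence {heights[rank]} must be below "
                    f"the {rank} cutoff {fine_cuts[i]}"
                )
            if i > 0 and not heights[rank] > fine_cuts[i - 1]:
                raise ValueError(
                    f"within-{rank} divergence {heights[rank]} must exceed the "
                    f"{RANKS[::-1][i - 1]} cutoff {fine_cuts[i - 1]}"
                )
        if self.outgroup_divergence <= cutoffs["Phylum"]:
            raise ValueError("outgroup divergence must exceed the Phylum cutoff")
        return heights


def smoke_params(seed: int = 0, **overrides) -> SimulationParams:
    """The default small fixture: 120 in-group leaves, full pipeline < 1 min."""
    return SimulationParams(seed=seed, **overrides)


def large_params(seed: int = 0, **overrides) -> SimulationParams:
    defaults = dict(
        n_orders=5,
        families_per_order=3,
        genera_per_family=2,
        leaves_per_genus=12,
    )
    defaults.update(overrides)
    return SimulationParams(seed=seed, **defaults)


def _p_to_branch(p_percent: float) -> float:
    """Expected substitutions per site for a target mismatch fraction."""
    p = p_percent / 100.0
    if not 0.0 <= p < 0.75:
        raise ValueError(f"mismatch fraction {p} outside [0, 0.75)")
    if p == 0.0:
        return 0.0
    return -0.75 * float(np.log1p(-4.0 * p / 3.0))


def _branch_to_p(t: float) -> float:
    return 0.75 * (1.0 - float(np.exp(-4.0 * t / 3.0)))


@dataclass
class _SimNode:
    height: float  # expected mismatch percent between leaves joined here
    children: list = field(default_factory=list)
    label: str | None = None


def _yule_crown(labels: Sequence[str], crown: float, rng: np.random.Generator) -> _SimNode:
    """Random ultrametric binary topology over labels with crown height."""
    nodes = [_SimNode(height=0.0, label=lab) for lab in labels]
    if len(nodes) == 1:
        return nodes[0]
    heights = np.sort(rng.uniform(0.25 * crown, crown, size=len(nodes) - 1))
    heights[-1] = crown
    for h in heights:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = _SimNode(height=float(h), children=[nodes[i], nodes[j]])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return nodes[0]


def _to_dendropy(root: _SimNode, taxa: dendropy.TaxonNamespace) -> dendropy.Tree:
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = True

    def build(sim: _SimNode, parent_height: float) -> dendropy.Node:
        node = dendropy.Node()
        node.edge.length = round(
            (_p_to_branch(parent_height) - _p_to_branch(sim.height)) / 2.0, 10
        )
        if sim.label is not None:
            node.taxon = taxa.require_taxon(label=sim.label)
        for child in sim.children:
            node.add_child(build(child, sim.height))
        return node

    for child in root.children:
        tree.seed_node.add_child(build(child, root.height))
    tree.seed_node.edge.length = None
    return tree


def planted_ids(params: SimulationParams) -> tuple[list[str], pd.DataFrame]:
    """In-group leaf ids plus their planted five-rank lineage table."""
    rows = []
    k = 0
    for o in range(1, params.n_orders + 1):
        for f in range(1, params.families_per_order + 1):
            for g in range(1, params.genera_per_family + 1):
                for _ in range(params.leaves_per_genus):
                    rows.append(
                        {
                            "id": f"s{k:04d}",
                            "Phylum": "P1",
                            "Class": "C1",
                            "Order": f"O{o}",
                            "Family": f"O{o}.F{f}",
                            "Genus": f"O{o}.F{f}.G{g}",
                        }
                    )
                    k += 1
    truth = pd.DataFrame(rows).set_index("id")
    return list(truth.index), truth


def simulate_tree(params: SimulationParams) -> tuple[Phylogeny, pd.DataFrame]:
    """Rooted tree with planted rank structure plus 5 outgroup leaves."""
    ids, truth = planted_ids(params)
    if len(ids) < 4:
        raise ValueError("need at least 4 in-group leaves")
    heights = params.rank_heights()
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 101]))

    order_nodes = []
    for o in range(1, params.n_orders + 1):
        family_nodes = []
        for f in range(1, params.families_per_order + 1):
            genus_nodes = []
            for g in range(1, params.genera_per_family + 1):
                genus = f"O{o}.F{f}.G{g}"
                labels = list(truth.index[truth["Genus"] == genus])
                genus_nodes.append(_yule_crown(labels, heights["Genus"], rng))
            if len(genus_nodes) == 1:
                family_nodes.append(genus_nodes[0])
            else:
                family_nodes.append(
                    _SimNode(height=heights["Family"], children=genus_nodes)
                )
        if len(family_nodes) == 1:
            order_nodes.append(family_nodes[0])
        else:
            order_nodes.append(
                _SimNode(height=heights["Order"], children=family_nodes)
            )
    if len(order_nodes) == 1:
        ingroup = order_nodes[0]
    else:
        ingroup = _SimNode(height=heights["Class"], children=order_nodes)

    og_ids = [f"og{i}" for i in range(N_OUTGROUP)]
    outgroup = _yule_crown(og_ids, heights["Genus"], rng)
    root = _SimNode(
        height=params.outgroup_divergence, children=[ingroup, outgroup]
    )

    taxa = dendropy.TaxonNamespace()
    tree = _to_dendropy(root, taxa)
    return Phylogeny(tree, frozenset(og_ids)), truth


def evolve_alignment(
    phylogeny: Phylogeny, params: SimulationParams, metadata: bool = False
) -> Alignment:
    """Jukes-Cantor evolution of a root sequence along the tree.

    Branch lengths are expected substitutions per site; each site mutates
    independently.  Optionally injects low-occupancy gap columns (95% gap)
    to exercise the conservation mask; they are appended as extra columns
    at positions drawn once, so the core length stays ``sequence_length``.
    """
    if params.sequence_length < 100:
        raise ValueError("sequence_length must be at least 100")
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 202]))
    length = params.sequence_length
    root_seq = rng.integers(0, 4, size=length, dtype=np.int8)

    seqs: dict[str, np.ndarray] = {}

    def descend(node, seq: np.ndarray) -> None:
        for child in node.child_nodes():
            t = child.edge.length or 0.0
            q = 0.25 * (1.0 - np.exp(-4.0 * t / 3.0))
            child_seq = seq.copy()
            hit = rng.random(length) < 3.0 * q
            if hit.any():
                # mutate to one of the 3 other bases, uniformly
                shift = rng.integers(1, 4, size=int(hit.sum()), dtype=np.int8)
                child_seq[hit] = (child_seq[hit] + shift) % 4
            descend(child, child_seq)
            if child.is_leaf():
                seqs[child.taxon.label] = child_seq

    descend(phylogeny.tree.seed_node, root_seq)

    ids = sorted(seqs)
    matrix = np.stack([seqs[i] for i in ids])
    n_gap_cols = int(round(params.gap_column_rate * length))
    if n_gap_cols:
        gap_block = rng.integers(0, 4, size=(len(ids), n_gap_cols), dtype=np.int8)
        gap_mask = rng.random((len(ids), n_gap_cols)) < 0.95
        positions = np.sort(rng.integers(0, length + 1, size=n_gap_cols))
        chars = _CODE_BASE[matrix]
        gap_chars = _CODE_BASE[gap_block]
        gap_chars[gap_mask] = "-"
        chars = np.insert(chars, positions, gap_chars, axis=1)
    else:
        chars = _CODE_BASE[matrix]

    records = [
        SequenceRecord(id=rid, domain=params.domain, aligned_seq="".join(row))
        for rid, row in zip(ids, chars)
    ]
    return Alignment(records)


_MARINE_SOURCES = (
    "surface seawater, open ocean",
    "marine water column, 200 m",
    "bathypelagic ocean water",
    "mesopelagic zone seawater",
    "coastal seawater, 5 m depth",
    "epipelagic open ocean water",
)
_CONTAMINANT_KINDS = ("low_quality", "cultivated")


def synthesize_metadata(
    alignment: Alignment,
    params: SimulationParams,
    truth: pd.DataFrame,
) -> tuple[Alignment, pd.DataFrame]:
    """Attach database-style metadata; returns alignment + contaminant table.

    In-group records get marine water-column sources, uncultivated clone
    names, and scores above every threshold.  A ``contaminant_fraction`` of
    them instead get metadata that individually fails mining (sub-threshold
    Pintail, or a cultivated name with a strain); a further
    ``other_marine_fraction`` get sediment-type sources, which mining still
    accepts inside a majority-marine clade — exercising the clade-inclusion
    rule.  Outgroup records are cultivated type strains.  The returned
    table lists every non-clean record with its kind.
    """
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 303]))
    og = set()
    contaminants: list[dict] = []
    for rec in alignment:
        is_outgroup = rec.id not in truth.index
        if is_outgroup:
            og.add(rec.id)
            rec.organism_name = f"Marinivirga typica {rec.id}"
            rec.strain = f"DSM {9000 + len(og)}"
            rec.isolation_source = "coastal seawater isolate"
            rec.pintail = 100.0
            rec.seq_quality = 99.0
            rec.align_quality = 99.0
            continue
        kind = "clean"
        u = rng.random()
        if u < params.contaminant_fraction:
            kind = _CONTAMINANT_KINDS[int(rng.integers(0, len(_CONTAMINANT_KINDS)))]
        elif u < params.contaminant_fraction + params.other_marine_fraction:
            kind = "other_marine"
        source = _MARINE_SOURCES[int(rng.integers(0, len(_MARINE_SOURCES)))]
        rec.organism_name = f"uncultured marine {params.domain.lower()} clone {rec.id}"
        rec.strain = ""
        rec.isolation_source = source
        rec.pintail = float(np.round(rng.uniform(80.0, 100.0), 1))
        rec.seq_quality = float(np.round(rng.uniform(85.0, 100.0), 1))
        rec.align_quality = float(np.round(rng.uniform(92.0, 100.0), 1))
        if kind == "low_quality":
            rec.pintail = float(np.round(rng.uniform(10.0, 74.0), 1))
        elif kind == "cultivated":
            rec.organism_name = f"Pelagibacterium cultum {rec.id}"
            rec.strain = f"CCUG {int(rng.integers(1000, 9999))}"
        elif kind == "other_marine":
            rec.isolation_source = "marine sediment core"
        if kind != "clean":
            contaminants.append({"id": rec.id, "kind": kind})
    return alignment, pd.DataFrame(contaminants, columns=["id", "kind"])


def simulate_abundance_env(
    params: SimulationParams,
    order_of_genus: Mapping[str, str],
) -> tuple[SampleTable, EnvTable, pd.DataFrame]:
    """Clade x sample counts and environment with planted effects.

    Count columns are planted genus ids plus an "unclassified" column.
    Returns the tables and the true order-level proportion matrix
    (samples x orders) before multinomial sampling.
    """
    for eff in params.indicator_effects:
        if eff.fold_change <= 0:
            raise ValueError(f"fold-change must be positive: {eff}")
    genera = sorted(order_of_genus)
    orders = sorted(set(order_of_genus.values()))
    if len(orders) < 2:
        raise ValueError("need at least 2 order-level clades")
    if len(params.n_samples_per_category) < 2:
        raise ValueError("need at least 2 sample categories")

    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 404]))
    sample_ids: list[str] = []
    categories: list[str] = []
    for cat in sorted(params.n_samples_per_category):
        for _ in range(params.n_samples_per_category[cat]):
            sample_ids.append(f"smp{len(sample_ids):03d}")
            categories.append(cat)
    n_samples = len(sample_ids)

    env = {}
    for var, (lo, hi) in ENV_RANGES.items():
        env[var] = rng.uniform(lo, hi, size=n_samples)
    biome = ["coastal" if "coastal" in c else "open_ocean" for c in categories]

    baseline = rng.dirichlet(np.ones(len(genera)))
    weights = np.tile(baseline, (n_samples, 1))
    if params.noise_dispersion > 0:
        weights = weights * rng.lognormal(
            0.0, params.noise_dispersion, size=weights.shape
        )
    genus_order = np.array([order_of_genus[g] for g in genera])
    cat_arr = np.array(categories)
    for eff in params.indicator_effects:
        rows = cat_arr == eff.category
        cols = genus_order == eff.order
        weights[np.ix_(rows, cols)] *= eff.fold_change
    for link in params.env_links:
        v = env[link.variable]
        z = (v - v.mean()) / (v.std() or 1.0)
        cols = genus_order == link.order
        weights[:, cols] *= np.exp(link.direction * link.strength * z)[:, None]

    proportions = weights / weights.sum(axis=1, keepdims=True)
    # reserve a stable 5% of each sample for unclassified reads
    unclassified_share = 0.05
    full = np.hstack(
        [
            proportions * (1.0 - unclassified_share),
            np.full((n_samples, 1), unclassified_share),
        ]
    )
    counts = np.stack(
        [rng.multinomial(params.reads_per_sample, full[s]) for s in range(n_samples)]
    )
    count_df = pd.DataFrame(
        counts, index=sample_ids, columns=genera + ["unclassified"]
    )

    env_df = pd.DataFrame(env, index=sample_ids)
    if params.env_missing_rate > 0:
        missing = rng.random(env_df.shape) < params.env_missing_rate
        env_df = env_df.mask(missing)
    env_df = env_df.round(4)
    env_df["biome"] = biome
    env_df["water_body"] = categories

    order_props = pd.DataFrame(
        proportions, index=sample_ids, columns=genera
    ).T.groupby(genus_order).sum().T
    return (
        SampleTable(pd.DataFrame(count_df)),
        EnvTable(env_df),
        order_props,
    )


@dataclass
class FixtureBundle:
    """All fixture artifacts for one simulated dataset."""

    params: SimulationParams
    alignment: Alignment
    phylogeny: Phylogeny
    truth: pd.DataFrame  # planted lineages, in-group ids
    contaminants: pd.DataFrame
    sample_table: SampleTable
    env_table: EnvTable
    true_order_proportions: pd.DataFrame
    annotations: dict[str, str]
    prior_clades: dict[str, list[str]]
    paths: dict[str, str] = field(default_factory=dict)


def make_fixture_bundle(
    params: SimulationParams, out_dir: str | None = None
) -> FixtureBundle:
    """Generate (and optionally write) a complete ground-truthed fixture."""
    phylogeny, truth = simulate_tree(params)
    alignment = evolve_alignment(phylogeny, params)
    alignment, contaminants = synthesize_metadata(alignment, params, truth)

    order_of_genus = {
        genus: group["Order"].iloc[0]
        for genus, group in truth.groupby("Genus")
    }
    sample_table, env_table, order_props = simulate_abundance_env(
        params, order_of_genus
    )

    annotations = {
        leaf: f"Known-{order}"
        for order in params.annotate_orders
        for leaf in truth.index[truth["Order"] == order]
    }
    prior_clades = {
        order: sorted(group.index)
        for order, group in truth.groupby("Order")
    }

    bundle = FixtureBundle(
        params=params,
        alignment=alignment,
        phylogeny=phylogeny,
        truth=truth,
        contaminants=contaminants,
        sample_table=sample_table,
        env_table=env_table,
        true_order_proportions=order_props,
        annotations=annotations,
        prior_clades=prior_clades,
    )
    if out_dir is not None:
        write_fixture_bundle(bundle, out_dir)
    return bundle


def write_fixture_bundle(bundle: FixtureBundle, out_dir: str) -> dict[str, str]:
    os.makedirs(out_dir, exist_ok=True)
    p = {
        "fasta": os.path.join(out_dir, "sequences.fasta"),
        "metadata": os.path.join(out_dir, "metadata.tsv"),
        "tree": os.path.join(out_dir, "tree.nwk"),
        "outgroup": os.path.join(out_dir, "outgroup_ids.txt"),
        "prior_clades": os.path.join(out_dir, "prior_clades.tsv"),
        "annotations": os.path.join(out_dir, "known_annotations.tsv"),
        "counts": os.path.join(out_dir, "counts.tsv"),
        "env": os.path.join(out_dir, "env.tsv"),
        "truth_lineages": os.path.join(out_dir, "truth_lineages.tsv"),
        "truth_contaminants": os.path.join(out_dir, "truth_contaminants.tsv"),
        "truth_proportions": os.path.join(out_dir, "truth_order_proportions.tsv"),
        "truth_params": os.path.join(out_dir, "truth_params.json"),
    }
    cio.write_alignment_fasta(bundle.alignment, p["fasta"], p["metadata"])
    cio.write_tree_newick(bundle.phylogeny, p["tree"], p["outgroup"])
    with open(p["prior_clades"], "w", encoding="utf-8") as fh:
        fh.write("id\tclade\n")
        for clade in sorted(bundle.prior_clades):
            for rid in bundle.prior_clades[clade]:
                fh.write(f"{rid}\t{clade}\n")
    with open(p["annotations"], "w", encoding="utf-8") as fh:
        fh.write("id\tlabel\n")
        for rid in sorted(bundle.annotations):
            fh.write(f"{rid}\t{bundle.annotations[rid]}\n")
    cio.write_tables(bundle.sample_table, bundle.env_table, p["counts"], p["env"])
    bundle.truth.to_csv(p["truth_lineages"], sep="\t", index_label="id")
    bundle.contaminants.to_csv(p["truth_contaminants"], sep="\t", index=False)
    bundle.true_order_proportions.to_csv(
        p["truth_proportions"], sep="\t", index_label="sample", float_format="%.10g"
    )
    with open(p["truth_params"], "w", encoding="utf-8") as fh:
        json.dump(asdict(bundle.params), fh, indent=1, sort_keys=True)
        fh.write("\n")
    bundle.paths = p
    return p


def read_fixture_bundle(out_dir: str) -> FixtureBundle:
    """Reload a previously written fixture directory."""
    with open(os.path.join(out_dir, "truth_params.json"), encoding="utf-8") as fh:
        raw = json.load(fh)
    raw["indicator_effects"] = tuple(
        IndicatorEffect(**e) for e in raw.get("indicator_effects", ())
    )
    raw["env_links"] = tuple(EnvLink(**e) for e in raw.get("env_links", ()))
    raw["annotate_orders"] = tuple(raw.get("annotate_orders", ()))
    params = SimulationParams(**raw)

    alignment = cio.read_alignment_fasta(
        os.path.join(out_dir, "sequences.fasta"),
        os.path.join(out_dir, "metadata.tsv"),
    )
    og = cio.read_outgroup_ids(os.path.join(out_dir, "outgroup_ids.txt"))
    phylogeny = cio.read_tree_newick(os.path.join(out_dir, "tree.nwk"), og)
    sample_table, env_table = cio.read_tables(
        os.path.join(out_dir, "counts.tsv"), os.path.join(out_dir, "env.tsv")
    )
    truth = pd.read_csv(
        os.path.join(out_dir, "truth_lineages.tsv"), sep="\t", index_col=0
    )
    contaminants = pd.read_csv(
        os.path.join(out_dir, "truth_contaminants.tsv"), sep="\t"
    )
    props = pd.read_csv(
        os.path.join(out_dir, "truth_order_proportions.tsv"), sep="\t", index_col=0
    )
    ann = pd.read_csv(
        os.path.join(out_dir, "known_annotations.tsv"), sep="\t", dtype=str
    )
    annotations = dict(zip(ann["id"], ann["label"])) if len(ann) else {}
    pri = pd.read_csv(os.path.join(out_dir, "prior_clades.tsv"), sep="\t", dtype=str)
    prior_clades: dict[str, list[str]] = {}
    for rid, clade in zip(pri["id"], pri["clade"]):
        prior_clades.setdefault(clade, []).append(rid)
    return FixtureBundle(
        params=params,
        alignment=alignment,
        phylogeny=phylogeny,
        truth=truth,
        contaminants=contaminants,
        sample_table=sample_table,
        env_table=env_table,
        true_order_proportions=props,
        annotations=annotations,
        prior_clades=prior_clades,
        paths={},
    )
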