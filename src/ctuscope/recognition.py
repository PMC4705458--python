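"""Reconciling OTU partitions with tree topology into named candidate taxa.

The tree is rooted on the outgroup, each in-group leaf is colored by its OTU
at a rank, and candidate taxonomic units (CTUs) are the maximal
monochromatic clades: tree nodes whose in-group descendant leaves all share
one OTU while their parent's do not.  An OTU that is not monophyletic on the
tree therefore splits into several components, which surface in the naming
scheme as hyphen-suffixed siblings.  CTUs from the five ranks are assembled
into a nested hierarchy, given standardized names, and marked known or
unknown from leaf-level annotations of previously described clades.
"""
from __future__ import annotations

import warnings
from collections.abc import Mapping
from dataclasses import dataclass, field

import dendropy

from .model import Phylogeny, RANKS


@dataclass
class CTU:
    """One candidate taxonomic unit: a maximal monochromatic clade."""

    rank: str
    members: tuple[str, ...]  # sorted in-group leaf ids
    source_otu: int
    component_index: int
    n_components: int = 1
    mrca: object = None  # tree node reference
    name: str = ""
    parent_name: str = ""
    status: str = "unknown"
    known_labels: frozenset[str] = frozenset()


@dataclass
class CTUHierarchy:
    """Nested CTUs for all ranks, with parent links and summary counts."""

    ctus: dict[str, list[CTU]] = field(default_factory=dict)

    def all_ctus(self):
        """All CTUs, coarsest rank first, preorder within a rank."""
        for rank in RANKS:
            yield from self.ctus.get(rank, ())

    def at(self, rank: str) -> list[CTU]:
        return self.ctus[rank]

    def leaf_ids(self) -> set[str]:
        return {m for ctu in self.ctus.get(RANKS[0], ()) for m in ctu.members}

    def by_name(self) -> dict[str, CTU]:
        return {c.name: c for c in self.all_ctus()}

    def leaf_lineages(self) -> dict[str, str]:
        """leaf id -> 'Phylum;Class;Order;Family;Genus' path of CTU names."""
        per_leaf: dict[str, list[str]] = {leaf: [] for leaf in self.leaf_ids()}
        for rank in RANKS:
            for ctu in self.ctus.get(rank, ()):
                for m in ctu.members:
                    per_leaf[m].append(ctu.name)
        return {leaf: ";".join(parts) for leaf, parts in per_leaf.items()}

    def summary(self) -> dict[str, dict[str, int]]:
        out: dict[str, dict[str, int]] = {}
        for rank in RANKS:
            ctus = self.ctus.get(rank, [])
            out[rank] = {
                "total": len(ctus),
                "min2": sum(len(c.members) >= 2 for c in ctus),
                "unknown": sum(c.status == "unknown" for c in ctus),
                "unknown_min2": sum(
                    c.status == "unknown" and len(c.members) >= 2 for c in ctus
                ),
                "unknown_sequences": sum(
                    len(c.members) for c in ctus if c.status == "unknown"
                ),
            }
        return out

    def unknown_report(self) -> dict[str, list[CTU]]:
        return {
            rank: [c for c in self.ctus.get(rank, ()) if c.status == "unknown"]
            for rank in RANKS
        }


def root_with_outgroup(phylogeny: Phylogeny) -> Phylogeny:
    """Root the tree on the edge separating the outgroup from the in-group.

    If the outgroup is not monophyletic in the unrooted tree, the edge that
    best separates outgroup from in-group leaves (most leaves on their
    expected side) is used and a warning is emitted.
    """
    og = set(phylogeny.outgroup_ids)
    leaves = set(phylogeny.leaf_ids())
    if not og:
        raise ValueError("no outgroup leaves designated")
    if og >= leaves:
        raise ValueError("outgroup contains every leaf; nothing to root")

    tree = phylogeny.tree.clone(depth=1)
    tree.is_rooted = True
    n_total = len(leaves)
    n_og = len(og)

    best_edge = None
    best_score = -1
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        below = {lf.taxon.label for lf in edge.head_node.leaf_iter()}
        if not below or below >= leaves:
            continue
        og_below = len(og & below)
        in_below = len(below) - og_below
        # leaves on their expected side if the outgroup sits below this edge
        score = og_below + (n_total - n_og - in_below)
        score = max(score, n_total - score)  # orientation-free
        if score > best_score:
            best_score = score
            best_edge = edge
    if best_edge is None:
        raise ValueError("tree has no internal edge to root on")
    if best_score < n_total:
        warnings.warn(
            "outgroup is not monophyletic; rooting on the best-separating edge",
            stacklevel=2,
        )
    length = best_edge.length
    if length is None:
        tree.reroot_at_edge(best_edge, update_bipartitions=False)
    else:
        tree.reroot_at_edge(
            best_edge,
            length1=length / 2.0,
            length2=length / 2.0,
            update_bipartitions=False,
        )
    tree.is_rooted = True
    return Phylogeny(tree, phylogeny.outgroup_ids)


def recognize_rank_ctus(
    rooted: Phylogeny, partition: Mapping[str, int], rank: str
) -> list[CTU]:
    """Maximal monochromatic clades for one rank's OTU coloring.

    Outgroup leaves are transparent: they carry no color and never join a
    CTU.  Under a polytomy each maximal monochromatic child subtree is its
    own component; nothing is silently resolved.  CTUs are returned in
    preorder of their defining node, and each OTU's components are numbered
    in that order.
    """
    og = rooted.outgroup_ids
    tree = rooted.tree

    colors: dict[int, set[int]] = {}
    ingroup_leaves: dict[int, list[str]] = {}
    for node in tree.postorder_node_iter():
        key = id(node)
        if node.is_leaf():
            label = node.taxon.label
            if label in og:
                colors[key] = set()
                ingroup_leaves[key] = []
            else:
                if label not in partition:
                    raise ValueError(f"leaf {label!r} has no OTU assignment")
                colors[key] = {partition[label]}
                ingroup_leaves[key] = [label]
        else:
            cset: set[int] = set()
            leaves: list[str] = []
            for child in node.child_nodes():
                cset |= colors[id(child)]
                leaves.extend(ingroup_leaves[id(child)])
            colors[key] = cset
            ingroup_leaves[key] = leaves

    def mono(node) -> bool:
        return len(colors[id(node)]) == 1

    ctus: list[CTU] = []
    component_counter: dict[int, int] = {}

    def visit(node, parent_mono: bool) -> None:
        if mono(node) and not parent_mono:
            otu = next(iter(colors[id(node)]))
            component_counter[otu] = component_counter.get(otu, 0) + 1
            ctus.append(
                CTU(
                    rank=rank,
                    members=tuple(sorted(ingroup_leaves[id(node)])),
                    source_otu=otu,
                    component_index=component_counter[otu],
                    mrca=node,
                )
            )
            return  # descendants share the color; nothing more below
        for child in node.child_nodes():
            if colors[id(child)]:
                visit(child, mono(node))

    if colors[id(tree.seed_node)]:
        visit(tree.seed_node, False)

    for ctu in ctus:
        ctu.n_components = component_counter[ctu.source_otu]
    return ctus


def build_hierarchy(per_rank_ctus: Mapping[str, list[CTU]]) -> CTUHierarchy:
    """Assemble per-rank CTUs into a nested hierarchy with parent links.

    Every CTU below the top rank must sit wholly inside exactly one CTU of
    the next coarser rank; a CTU spanning two parents indicates corrupted
    upstream partitions and is a hard error.
    """
    missing = [r for r in RANKS if r not in per_rank_ctus]
    if missing:
        raise ValueError(f"CTUs missing for ranks {missing}")
    hierarchy = CTUHierarchy(ctus={r: list(per_rank_ctus[r]) for r in RANKS})

    for coarse, fine in zip(RANKS, RANKS[1:]):
        leaf_to_parent: dict[str, CTU] = {}
        for parent in hierarchy.ctus[coarse]:
            for m in parent.members:
                leaf_to_parent[m] = parent
        for ctu in hierarchy.ctus[fine]:
            parents = {id(leaf_to_parent[m]) for m in ctu.members}
            if len(parents) != 1:
                raise ValueError(
                    f"{ctu.rank} CTU (otu {ctu.source_otu}) spans "
                    f"{len(parents)} {coarse}-rank parents; upstream "
                    "partitions are not nested"
                )
            ctu._parent = leaf_to_parent[ctu.members[0]]  # resolved to a name later
    return hierarchy


def assign_names(hierarchy: CTUHierarchy, context_name: str = "") -> CTUHierarchy:
    """Standardized names: <Context>.<Rank><otu>[-<component>].

    OTU display numbers restart at 1 per rank and follow the preorder of
    first appearance; the hyphen suffix appears only when an OTU split into
    several tree components.  Without a context name, top-rank CTUs are
    named ``Phylum<k>`` and serve as the context of their descendants
    (giving names like ``Phylum1.Order1``).
    """
    for rank in RANKS:
        display: dict[int, int] = {}
        for ctu in hierarchy.ctus[rank]:
            if ctu.source_otu not in display:
                display[ctu.source_otu] = len(display) + 1
            num = display[ctu.source_otu]
            suffix = f"-{ctu.component_index}" if ctu.n_components > 1 else ""
            if rank == RANKS[0]:
                base = f"{context_name}.{rank}{num}" if context_name else f"{rank}{num}"
            else:
                if context_name:
                    ctx = context_name
                else:
                    node = ctu
                    while getattr(node, "_parent", None) is not None:
                        node = node._parent
                    ctx = node.name
                base = f"{ctx}.{rank}{num}"
            ctu.name = base + suffix
            parent = getattr(ctu, "_parent", None)
            ctu.parent_name = parent.name if parent is not None else ""

    names = [c.name for c in hierarchy.all_ctus()]
    if len(names) != len(set(names)):
        raise AssertionError("CTU name collision")  # impossible by construction
    return hierarchy


def flag_known_clades(
    hierarchy: CTUHierarchy, annotations: Mapping[str, str]
) -> CTUHierarchy:
    """Mark CTUs containing any annotated leaf as known clades."""
    leaves = hierarchy.leaf_ids()
    unknown_ids = sorted(set(annotations) - leaves)
    if unknown_ids:
        warnings.warn(
            f"{len(unknown_ids)} annotations reference non-leaf ids "
            f"(first: {unknown_ids[0]!r}); ignored",
            stacklevel=2,
        )
    usable = {k: v for k, v in annotations.items() if k in leaves}
    for ctu in hierarchy.all_ctus():
        labels = frozenset(usable[m] for m in ctu.members if m in usable)
        ctu.known_labels = labels
        ctu.status = "known" if labels else "unknown"
    return hierarchy


def recognize(
    phylogeny: Phylogeny,
    partitions,
    context_name: str = "",
    annotations: Mapping[str, str] | None = None,
) -> tuple[Phylogeny, CTUHierarchy]:
    """Full recognition stage: root, per-rank CTUs, hierarchy, names, flags."""
    rooted = root_with_outgroup(phylogeny)
    per_rank = {
        rank: recognize_rank_ctus(rooted, partitions.assignments[rank], rank)
        for rank in RANKS
    }
    hierarchy = build_hierarchy(per_rank)
    assign_names(hierarchy, context_name)
    flag_known_clades(hierarchy, annotations or {})
    return rooted, hierarchy
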