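import dendropy
import numpy as np
import pytest

from ctuscope.clustering import RankPartitions, cut_partitions, furthest_neighbor_dendrogram, DistanceMatrix
from ctuscope.model import Phylogeny, RANKS
from ctuscope.recognition import (
    assign_names,
    build_hierarchy,
    flag_known_clades,
    recognize,
    recognize_rank_ctus,
    root_with_outgroup,
)
from .conftest import random_distance_matrix
from .oracles import enumerate_clades


def phylo(newick: str, og=()) -> Phylogeny:
    tree = dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )
    return Phylogeny(tree, frozenset(og))


def ctu_member_sets(ctus):
    return {frozenset(c.members) for c in ctus}


class TestRooting:
    def test_root_separates_outgroup(self):
        rooted = root_with_outgroup(
            phylo("((A:1,B:1):1,(C:1,D:1):1,(O1:1,O2:1):1);", og=("O1", "O2"))
        )
        children = rooted.tree.seed_node.child_nodes()
        sides = [
            {lf.taxon.label for lf in ch.leaf_iter()} for ch in children
        ]
        assert {"O1", "O2"} in sides

    def test_five_leaf_outgroup_clade(self):
        og = [f"O{i}" for i in range(5)]
        nwk = f"((A:1,B:1):1,(C:1,D:1):1,({','.join(x + ':1' for x in og)}):1);"
        rooted = root_with_outgroup(phylo(nwk, og=og))
        assert sorted(rooted.ingroup_ids()) == ["A", "B", "C", "D"]

    def test_non_monophyletic_outgroup_warns(self):
        with pytest.warns(UserWarning, match="not monophyletic"):
            rooted = root_with_outgroup(
                phylo("((O1:1,A:1):1,(O2:1,B:1):1,C:1);", og=("O1", "O2"))
            )
        assert sorted(rooted.leaf_ids()) == ["A", "B", "C", "O1", "O2"]

    def test_no_outgroup_error(self):
        with pytest.raises(ValueError, match="outgroup"):
            root_with_outgroup(phylo("((A:1,B:1):1,C:1);"))

    def test_outgroup_is_everything_error(self):
        with pytest.raises(ValueError):
            root_with_outgroup(phylo("(A:1,B:1);", og=("A", "B")))


class TestRecognizeRankCtus:
    def test_two_clean_clades(self):
        rooted = phylo("(((A:1,B:1):1,C:1):1,(D:1,E:1):1);")
        otus = {"A": 1, "B": 1, "C": 1, "D": 2, "E": 2}
        ctus = recognize_rank_ctus(rooted, otus, "Order")
        assert ctu_member_sets(ctus) == {
            frozenset("ABC"),
            frozenset("DE"),
        }
        assert all(c.n_components == 1 for c in ctus)

    def test_interleaved_otus_split_into_components(self):
        rooted = phylo("((A:1,C:1):1,(B:1,D:1):1);")
        otus = {"A": 1, "B": 1, "C": 2, "D": 2}
        ctus = recognize_rank_ctus(rooted, otus, "Order")
        assert ctu_member_sets(ctus) == {
            frozenset("A"),
            frozenset("B"),
            frozenset("C"),
            frozenset("D"),
        }
        assert all(c.n_components == 2 for c in ctus)
        # components numbered in preorder
        comp = {tuple(c.members): c.component_index for c in ctus}
        assert comp[("A",)] == 1 and comp[("B",)] == 2
        assert comp[("C",)] == 1 and comp[("D",)] == 2

    def test_single_otu_gives_ingroup_root_clade(self):
        rooted = phylo("(((A:1,B:1):1,C:1):1,(O1:1,O2:1):1);", og=("O1", "O2"))
        ctus = recognize_rank_ctus(rooted, {x: 1 for x in "ABC"}, "Phylum")
        assert ctu_member_sets(ctus) == {frozenset("ABC")}

    def test_polytomy_children_not_silently_grouped(self):
        rooted = phylo("(A:1,B:1,C:1,D:1);")
        otus = {"A": 1, "B": 1, "C": 2, "D": 2}
        ctus = recognize_rank_ctus(rooted, otus, "Genus")
        # strict monophyly: each child leaf stands alone under the polytomy
        assert ctu_member_sets(ctus) == {
            frozenset("A"), frozenset("B"), frozenset("C"), frozenset("D")
        }

    def test_missing_assignment_error(self):
        rooted = phylo("(A:1,B:1);")
        with pytest.raises(ValueError, match="B"):
            recognize_rank_ctus(rooted, {"A": 1}, "Genus")

    def test_outgroup_leaves_never_join(self):
        rooted = root_with_outgroup(
            phylo("((A:1,B:1):1,(O1:1,O2:1):1);", og=("O1", "O2"))
        )
        ctus = recognize_rank_ctus(rooted, {"A": 1, "B": 1}, "Genus")
        assert ctu_member_sets(ctus) == {frozenset("AB")}

    def test_idempotence_partition_of_clades(self):
        rooted = phylo("(((A:1,B:1):1,(C:1,D:1):1):1,(E:1,F:1):1);")
        otus = {"A": 1, "B": 1, "C": 2, "D": 2, "E": 3, "F": 3}
        ctus = recognize_rank_ctus(rooted, otus, "Family")
        assert all(c.n_components == 1 for c in ctus)
        assert len(ctus) == 3

    def test_maximality_against_brute_force(self):
        rooted = phylo("(((A:1,B:1):1,C:1):1,((D:1,E:1):1,F:1):1);")
        otus = {"A": 1, "B": 1, "C": 1, "D": 2, "E": 2, "F": 3}
        ctus = recognize_rank_ctus(rooted, otus, "Order")
        # oracle: enumerate all clades, keep monochromatic ones that are
        # maximal under set inclusion
        clades = [ls for _, ls in enumerate_clades(rooted.tree)]
        mono = [
            ls for ls in clades if len({otus[x] for x in ls}) == 1
        ]
        maximal = {
            ls for ls in mono if not any(ls < other for other in mono)
        }
        assert ctu_member_sets(ctus) == maximal


def make_nested_partitions(otus_by_rank):
    return RankPartitions(assignments=otus_by_rank)


def toy_hierarchy():
    nwk = "((((A:1,B:1):1,(C:1,D:1):1):1,((E:1,F:1):1,G:1):1):1,(O1:1,O2:1,O3:1,O4:1,O5:1):1);"
    rooted = root_with_outgroup(phylo(nwk, og=[f"O{i}" for i in range(1, 6)]))
    leaves = list("ABCDEFG")
    assignments = {
        "Phylum": {x: 1 for x in leaves},
        "Class": {x: 1 for x in leaves},
        "Order": {x: (1 if x in "ABCD" else 2) for x in leaves},
        "Family": {x: (1 if x in "ABCD" else 2) for x in leaves},
        "Genus": {
            "A": 1, "B": 1, "C": 2, "D": 2, "E": 3, "F": 3, "G": 4
        },
    }
    per_rank = {
        rank: recognize_rank_ctus(rooted, assignments[rank], rank)
        for rank in RANKS
    }
    return rooted, build_hierarchy(per_rank)


class TestHierarchy:
    def test_counts_and_parents(self):
        _, h = toy_hierarchy()
        s = h.summary()
        assert s["Phylum"]["total"] == 1
        assert s["Order"]["total"] == 2
        assert s["Genus"]["total"] == 4
        assert s["Genus"]["min2"] == 3  # singleton G excluded

    def test_singleton_present_but_not_in_min2(self):
        _, h = toy_hierarchy()
        sizes = sorted(len(c.members) for c in h.at("Genus"))
        assert sizes == [1, 2, 2, 2]

    def test_partition_at_each_rank(self):
        _, h = toy_hierarchy()
        for rank in RANKS:
            members = [m for c in h.at(rank) for m in c.members]
            assert sorted(members) == list("ABCDEFG")

    def test_parent_links_rank_adjacent(self):
        _, h = toy_hierarchy()
        assign_names(h)
        by_name = h.by_name()
        for rank, parent_rank in zip(RANKS[1:], RANKS):
            for ctu in h.at(rank):
                parent = by_name[ctu.parent_name]
                assert parent.rank == parent_rank
                assert set(ctu.members) <= set(parent.members)

    def test_spanning_parent_is_hard_error(self):
        nwk = "((A:1,B:1):1,(C:1,D:1):1);"
        rooted = phylo(nwk)
        # non-nested on purpose: the Class CTU {A,B} is a clade but its
        # members sit in two different Phylum CTUs
        bad = {
            "Phylum": recognize_rank_ctus(
                rooted, {"A": 1, "B": 2, "C": 3, "D": 4}, "Phylum"
            ),
            "Class": recognize_rank_ctus(
                rooted, {"A": 1, "B": 1, "C": 2, "D": 2}, "Class"
            ),
        }
        for rank in ("Order", "Family", "Genus"):
            bad[rank] = recognize_rank_ctus(
                rooted, {"A": 1, "B": 2, "C": 3, "D": 4}, rank
            )
        with pytest.raises(ValueError, match="span"):
            build_hierarchy(bad)

    def test_missing_rank_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            build_hierarchy({"Phylum": []})


class TestNames:
    def test_context_and_suffixes(self):
        rooted = phylo("((A:1,C:1):1,(B:1,D:1):1);")
        assignments = {rank: {x: 1 for x in "ABCD"} for rank in RANKS[:4]}
        assignments["Genus"] = {"A": 3, "B": 3, "C": 5, "D": 5}
        per_rank = {
            rank: recognize_rank_ctus(rooted, assignments[rank], rank)
            for rank in RANKS
        }
        h = assign_names(build_hierarchy(per_rank), "Thaumarchaeota")
        genus_names = sorted(c.name for c in h.at("Genus"))
        # both genus OTUs split into two components -> hyphen suffixes;
        # display numbers follow preorder (A's OTU first)
        assert genus_names == [
            "Thaumarchaeota.Genus1-1",
            "Thaumarchaeota.Genus1-2",
            "Thaumarchaeota.Genus2-1",
            "Thaumarchaeota.Genus2-2",
        ]
        assert [c.name for c in h.at("Phylum")] == ["Thaumarchaeota.Phylum1"]

    def test_unsuffixed_when_single_component(self):
        _, h = toy_hierarchy()
        assign_names(h, "Acidobacteria")
        order_names = sorted(c.name for c in h.at("Order"))
        assert order_names == ["Acidobacteria.Order1", "Acidobacteria.Order2"]

    def test_context_free_uses_phylum_as_context(self):
        _, h = toy_hierarchy()
        assign_names(h)
        assert [c.name for c in h.at("Phylum")] == ["Phylum1"]
        assert sorted(c.name for c in h.at("Order")) == [
            "Phylum1.Order1",
            "Phylum1.Order2",
        ]

    def test_names_unique(self):
        _, h = toy_hierarchy()
        assign_names(h, "X")
        names = [c.name for c in h.all_ctus()]
        assert len(names) == len(set(names))


class TestKnownFlags:
    def test_partial_annotation(self):
        _, h = toy_hierarchy()
        assign_names(h)
        flag_known_clades(h, {"A": "SAR11"})
        order_status = {c.name: c.status for c in h.at("Order")}
        assert order_status["Phylum1.Order1"] == "known"
        assert order_status["Phylum1.Order2"] == "unknown"
        assert h.summary()["Order"]["unknown"] == 1

    def test_no_annotations_all_unknown(self):
        _, h = toy_hierarchy()
        flag_known_clades(h, {})
        assert all(c.status == "unknown" for c in h.all_ctus())

    def test_every_leaf_annotated_zero_unknown(self):
        _, h = toy_hierarchy()
        flag_known_clades(h, {x: "MGI" for x in "ABCDEFG"})
        s = h.summary()
        assert all(s[rank]["unknown"] == 0 for rank in RANKS)
        assert all(s[rank]["unknown_sequences"] == 0 for rank in RANKS)

    def test_non_leaf_annotation_warns(self):
        _, h = toy_hierarchy()
        with pytest.warns(UserWarning, match="ZZ"):
            flag_known_clades(h, {"ZZ": "SAR202"})

    def test_known_labels_recorded(self):
        _, h = toy_hierarchy()
        flag_known_clades(h, {"A": "SAR11", "C": "SAR202"})
        phylum = h.at("Phylum")[0]
        assert phylum.known_labels == {"SAR11", "SAR202"}


def random_phylogeny(rng, leaf_ids, og_ids):
    """Random binary tree over leaves by sequential joins, plus outgroup."""
    nodes = [f"{x}:1.0" for x in leaf_ids]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = f"({nodes[i]},{nodes[j]}):1.0"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    og = ",".join(f"{x}:1.0" for x in og_ids)
    return phylo(f"({nodes[0]},({og}):2.0);", og=og_ids)


class TestRandomTreeInvariants:
    def test_monophyly_coverage_nesting(self, rng):
        for _ in range(30):
            n = int(rng.integers(6, 20))
            ids = [f"s{i}" for i in range(n)]
            og = ["og1", "og2"]
            phy = random_phylogeny(rng, ids, og)
            m = random_distance_matrix(rng, n)
            parts = cut_partitions(
                furthest_neighbor_dendrogram(
                    DistanceMatrix(ids=tuple(ids), values=m)
                )
            )
            rooted, h = recognize(phy, parts)
            clade_sets = {
                ls - set(og) for _, ls in enumerate_clades(rooted.tree)
            }
            for rank in RANKS:
                covered = []
                for ctu in h.at(rank):
                    assert set(ctu.members) in clade_sets  # monophyly
                    otus = {parts.assignments[rank][m_] for m_ in ctu.members}
                    assert len(otus) == 1  # OTU consistency
                    covered.extend(ctu.members)
                assert sorted(covered) == sorted(ids)  # partition
            for rank in RANKS:
                for ctu in h.at(rank):
                    comps = [
                        c for c in h.at(rank) if c.source_otu == ctu.source_otu
                    ]
                    union = {m_ for c in comps for m_ in c.members}
                    assert union == set(
                        rid for rid, o in parts.assignments[rank].items()
                        if o == ctu.source_otu
                    )
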