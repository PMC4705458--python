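"""Conservation masking, pairwise identity, and furthest-neighbor clustering.

Alignment columns are retained when the most frequent unambiguous base
reaches the conservation fraction over all records (gaps count in the
denominator; T and U are equated).  Percent identity is computed over the
comparable masked columns of each pair — columns where both sequences carry
an unambiguous base — so internal gap columns and ambiguity codes never
count as mismatches, and terminal gap runs vanish for the same reason.
Complete-linkage (furthest-neighbor) agglomeration then yields a monotone
dendrogram that is cut at the rank-specific distance cutoffs into nested
partitions.
"""
from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np

from .model import Alignment, RankThresholds, RANKS

#: Tolerance applied when comparing merge heights to distance cutoffs.
CUT_TOLERANCE = 1e-9


@dataclass(frozen=True)
class ColumnMask:
    """Boolean column filter produced by the conservation screen."""

    keep: np.ndarray  # bool, length n_columns

    @property
    def n_retained(self) -> int:
        return int(self.keep.sum())


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric percent distances (0..100) over record ids."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError(f"distance matrix shape {v.shape} != ({n}, {n})")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if v.min() < 0 or v.max() > 100:
            raise ValueError("distances must lie in [0, 100]")


@dataclass(frozen=True)
class Merge:
    a: frozenset[str]
    b: frozenset[str]
    height: float


@dataclass(frozen=True)
class Dendrogram:
    """Complete-linkage merge history; heights in percent distance."""

    ids: tuple[str, ...]
    merges: tuple[Merge, ...]


@dataclass(frozen=True)
class RankPartitions:
    """Nested OTU partitions, one per rank; OTU ids are 1-based integers."""

    assignments: Mapping[str, Mapping[str, int]]  # rank -> record id -> otu

    def otus(self, rank: str) -> dict[int, frozenset[str]]:
        out: dict[int, set[str]] = {}
        for rid, otu in self.assignments[rank].items():
            out.setdefault(otu, set()).add(rid)
        return {k: frozenset(v) for k, v in out.items()}


def build_conservation_mask(
    alignment: Alignment, min_fraction: float = 0.10
) -> ColumnMask:
    """Retain columns whose majority base reaches ``min_fraction`` of records.

    The fraction is inclusive and computed over ALL records (gap and
    ambiguous characters count in the denominator but never as the majority
    base).  Raises if every column would be removed.
    """
    if len(alignment) < 2:
        raise ValueError("conservation mask needs at least 2 records")
    codes = alignment.encode()
    n = codes.shape[0]
    counts = np.stack([(codes == b).sum(axis=0) for b in range(4)])
    top = counts.max(axis=0)
    keep = top >= (min_fraction * n - CUT_TOLERANCE)
    if not keep.any():
        raise ValueError("empty mask: all alignment columns removed")
    return ColumnMask(keep=keep)


def pairwise_identity_matrix(
    alignment: Alignment, mask: ColumnMask | None = None
) -> DistanceMatrix:
    """Percent distance = 100 - percent identity over comparable columns.

    Comparable columns are masked columns where both sequences carry an
    unambiguous base; a pair with no comparable column gets distance 100.
    """
    if len(alignment) < 2:
        raise ValueError("need at least 2 records for pairwise distances")
    codes = alignment.encode()
    if mask is not None:
        codes = codes[:, mask.keep]
    n = codes.shape[0]
    valid = codes >= 0
    dist = np.zeros((n, n), dtype=float)
    for i in range(n - 1):
        comp = valid[i] & valid[i + 1 :]
        match = comp & (codes[i] == codes[i + 1 :])
        n_comp = comp.sum(axis=1).astype(float)
        n_match = match.sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            identity = np.where(n_comp > 0, 100.0 * n_match / n_comp, 0.0)
        dist[i, i + 1 :] = 100.0 - identity
        dist[i + 1 :, i] = dist[i, i + 1 :]
    return DistanceMatrix(ids=tuple(alignment.ids), values=dist)


def _tie_key(members_a: frozenset[str], members_b: frozenset[str]) -> tuple[str, str]:
    a, b = min(members_a), min(members_b)
    return (a, b) if a <= b else (b, a)


def furthest_neighbor_dendrogram(dist: DistanceMatrix) -> Dendrogram:
    """Agglomerative complete linkage with a deterministic tie-break.

    At each step the pair of clusters with the smallest inter-cluster
    distance (the MAXIMUM pairwise member distance) is merged; among ties
    the pair whose smallest member ids sort lexicographically least wins.
    Merge heights are monotone non-decreasing.
    """
    n = len(dist.ids)
    if n < 2:
        raise ValueError("need at least 2 items to cluster")
    members: list[frozenset[str]] = [frozenset({rid}) for rid in dist.ids]
    d = dist.values.astype(float).copy()
    np.fill_diagonal(d, np.inf)
    active = list(range(n))
    merges: list[Merge] = []
    last_height = 0.0
    while len(active) > 1:
        sub = d[np.ix_(active, active)]
        height = sub.min()
        best: tuple[str, str] | None = None
        best_pair: tuple[int, int] | None = None
        pos = np.argwhere(sub == height)
        for pi, pj in pos:
            if pi >= pj:
                continue
            i, j = active[pi], active[pj]
            key = _tie_key(members[i], members[j])
            if best is None or key < best:
                best = key
                best_pair = (i, j)
        assert best_pair is not None
        i, j = best_pair
        if height < last_height - CUT_TOLERANCE:
            raise AssertionError("complete linkage produced a height inversion")
        last_height = max(last_height, height)
        merges.append(Merge(a=members[i], b=members[j], height=float(height)))
        members[i] = members[i] | members[j]
        # Lance-Williams update for complete linkage: new row is the max.
        new_row = np.maximum(d[i], d[j])
        d[i, :] = new_row
        d[:, i] = new_row
        d[i, i] = np.inf
        active.remove(j)
    return Dendrogram(ids=dist.ids, merges=tuple(merges))


def cut_partitions(
    dendrogram: Dendrogram, thresholds: RankThresholds | None = None
) -> RankPartitions:
    """Cut the dendrogram at each rank's distance cutoff (inclusive).

    Two records share an OTU at a rank iff their merge height does not
    exceed the cutoff (within ``CUT_TOLERANCE``).  OTU integers are assigned
    in order of each OTU's first member under the input record order.
    """
    thresholds = thresholds or RankThresholds()
    cutoffs = thresholds.distance_cutoffs
    ids = dendrogram.ids
    index = {rid: k for k, rid in enumerate(ids)}

    assignments: dict[str, dict[str, int]] = {}
    for rank in RANKS:
        cutoff = cutoffs[rank] + CUT_TOLERANCE
        parent = list(range(len(ids)))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for merge in dendrogram.merges:
            if merge.height > cutoff:
                break
            ra = find(index[next(iter(merge.a))])
            rb = find(index[next(iter(merge.b))])
            if ra != rb:
                parent[rb] = ra
        otu_of_root: dict[int, int] = {}
        assignment: dict[str, int] = {}
        for k, rid in enumerate(ids):
            root = find(k)
            if root not in otu_of_root:
                otu_of_root[root] = len(otu_of_root) + 1
            assignment[rid] = otu_of_root[root]
        assignments[rank] = assignment
    return RankPartitions(assignments=assignments)


def cluster_at_thresholds(
    alignment: Alignment,
    thresholds: RankThresholds | None = None,
    min_conservation: float = 0.10,
) -> tuple[ColumnMask, DistanceMatrix, Dendrogram, RankPartitions]:
    """Convenience wrapper running the whole clustering stage."""
    mask = build_conservation_mask(alignment, min_fraction=min_conservation)
    dist = pairwise_identity_matrix(alignment, mask)
    dendro = furthest_neighbor_dendrogram(dist)
    parts = cut_partitions(dendro, thresholds)
    return mask, dist, dendro, parts
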