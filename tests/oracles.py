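"""Independent brute-force oracles used to cross-check the package.

These deliberately share no code with the implementation: the clustering
oracle recomputes every inter-cluster distance from the raw matrix by
nested loops at each step, and the correlation oracle is Pearson on
midranks computed from first principles.
"""
from __future__ import annotations

import numpy as np


def brute_force_complete_linkage_partition(ids, matrix, cutoff):
    """Greedy furthest-neighbor agglomeration stopped at a cutoff.

    Repeatedly merges the pair of clusters whose maximum pairwise member
    distance is smallest, as long as that distance is <= cutoff (+1e-9);
    the tie-break picks the pair whose smallest member ids are
    lexicographically least.  Returns a set of frozensets.
    """
    index = {rid: k for k, rid in enumerate(ids)}
    clusters = [{rid} for rid in ids]
    while len(clusters) > 1:
        best = None
        best_key = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                dmax = max(
                    matrix[index[a], index[b]]
                    for a in clusters[i]
                    for b in clusters[j]
                )
                lo, hi = sorted((min(clusters[i]), min(clusters[j])))
                key = (dmax, lo, hi)
                if best_key is None or key < best_key:
                    best_key = key
                    best = (i, j)
        if best_key[0] > cutoff + 1e-9:
            break
        i, j = best
        clusters[i] = clusters[i] | clusters[j]
        del clusters[j]
    return {frozenset(c) for c in clusters}


def midrank(values):
    """Average ranks (1-based) with midranks for ties, from scratch."""
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values), dtype=float)
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_oracle(x, y):
    """Pearson correlation of midranks, computed from the definition."""
    rx, ry = midrank(x), midrank(y)
    dx, dy = rx - rx.mean(), ry - ry.mean()
    return float((dx * dy).sum() / np.sqrt((dx**2).sum() * (dy**2).sum()))


def enumerate_clades(tree):
    """All (node, in-group leafset) pairs of a dendropy tree, brute force."""
    out = []
    for node in tree.preorder_node_iter():
        leaves = frozenset(lf.taxon.label for lf in node.leaf_iter())
        out.append((node, leaves))
    return out
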