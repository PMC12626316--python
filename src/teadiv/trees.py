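"""UPGMA agglomeration, cophenetic distances and tree cutting.

The height convention is pinned so that "cutting the dendrogram at genetic
distance x" means cutting at height x: a pair at distance d joins at height
d/2, and every leaf's root-to-tip path length equals the final merge height.
Ties are broken on the lexicographically smallest pair of cluster
representatives (each cluster represented by its smallest leaf label), which
makes the merge list invariant to input label order.
"""

from __future__ import annotations

import itertools

import numpy as np

from .core import Dendrogram, DistanceMatrix, MergeStep

__all__ = ["upgma", "cophenetic", "cut_tree"]


def upgma(d: DistanceMatrix) -> Dendrogram:
    """Unweighted pair-group (average linkage) clustering of a distance matrix.

    At each step the pair of clusters with the smallest average inter-cluster
    distance is joined at height = distance / 2; the distance from the merged
    cluster to any other is the size-weighted average of its members'
    distances (i.e. the plain average over all leaf pairs).
    """
    n = len(d.labels)
    if n < 2:
        raise ValueError("UPGMA requires at least 2 leaves")

    # active clusters keyed by sorted leaf tuple; distances kept between keys
    clusters: list[tuple[str, ...]] = [(lab,) for lab in d.labels]
    index = {lab: i for i, lab in enumerate(d.labels)}
    dist: dict[frozenset, float] = {}
    for a, b in itertools.combinations(d.labels, 2):
        dist[frozenset(((a,), (b,)))] = d.values[index[a], index[b]]

    merges: list[MergeStep] = []
    while len(clusters) > 1:
        best_key = None
        best_pair = None
        for ca, cb in itertools.combinations(clusters, 2):
            dd = dist[frozenset((ca, cb))]
            rep = tuple(sorted((ca[0], cb[0])))
            key = (dd, rep)
            if best_key is None or key < best_key:
                best_key, best_pair = key, (ca, cb)
        ca, cb = best_pair  # type: ignore[misc]
        if ca[0] > cb[0]:
            ca, cb = cb, ca
        d_ab = best_key[0]  # type: ignore[index]
        merged = tuple(sorted(ca + cb))
        merges.append(MergeStep(ca, cb, d_ab / 2.0))
        clusters.remove(ca)
        clusters.remove(cb)
        for other in clusters:
            da = dist.pop(frozenset((ca, other)))
            db = dist.pop(frozenset((cb, other)))
            dist[frozenset((merged, other))] = (len(ca) * da + len(cb) * db) / (
                len(ca) + len(cb)
            )
        del dist[frozenset((ca, cb))]
        clusters.append(merged)

    return Dendrogram(sorted(d.labels), merges)


def cophenetic(dend: Dendrogram) -> DistanceMatrix:
    """Leaf-pair distance implied by the tree: twice the height of the lowest
    merge uniting the pair (back on the input distance scale)."""
    labels = sorted(dend.leaves)
    n = len(labels)
    idx = {lab: i for i, lab in enumerate(labels)}
    vals = np.zeros((n, n))
    for step in dend.merges:
        for a in step.left:
            for b in step.right:
                vals[idx[a], idx[b]] = vals[idx[b], idx[a]] = 2.0 * step.height
    return DistanceMatrix(labels, vals)


def cut_tree(
    dend: Dendrogram,
    height: float | None = None,
    k: int | None = None,
) -> dict[str, int]:
    """Group leaves by removing merges above a height, or into exactly k groups.

    Exactly one of ``height``/``k`` must be given. Returns leaf -> group id,
    with groups numbered 0,1,... in order of each group's first leaf under
    sorted label order.
    """
    if (height is None) == (k is None):
        raise ValueError("supply exactly one of height or k")
    n = len(dend.leaves)
    if k is not None:
        if not 1 <= k <= n:
            raise ValueError(f"k must be in [1, {n}]")
        kept = dend.merges[: n - k]
    else:
        kept = [m for m in dend.merges if m.height <= height + 1e-12]

    parent = {leaf: leaf for leaf in dend.leaves}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step in kept:
        ra, rb = find(step.left[0]), find(step.right[0])
        if ra != rb:
            parent[rb] = ra

    groups: dict[str, int] = {}
    labels: dict[str, int] = {}
    for leaf in sorted(dend.leaves):
        root = find(leaf)
        if root not in groups:
            groups[root] = len(groups)
        labels[leaf] = groups[root]
    return labels
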