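"""Hierarchical co-prescription clustering of high-count herbs.

Herbs are clustered as binary row vectors over cases (1 = prescribed in that
case), restricted to herbs whose cumulative prescription count is strictly
above a cut (50 by default). Agglomerative clustering with complete linkage
and Euclidean distance is the default — single/average linkage and Jaccard
distance are available — with a deterministic lexicographic tie-break so the
dendrogram is invariant to input row order.

The merge sequence is stored explicitly (clusters identified by their sorted
leaf-name tuples), which makes group extraction and ultrametric Newick export
straightforward and exactly testable.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .records import CleanCase


class ClusterError(ValueError):
    pass


Node = tuple[str, ...]  # a cluster, identified by its sorted leaf names


@dataclass(frozen=True)
class Dendrogram:
    leaves: tuple[str, ...]
    merges: tuple[tuple[Node, Node, float], ...]

    def __post_init__(self) -> None:
        if len(self.merges) != len(self.leaves) - 1:
            raise ClusterError("a binary merge tree has |leaves| - 1 merges")


def build_incidence(
    cases: Sequence[CleanCase], min_count: int = 50
) -> pd.DataFrame:
    """Binary herbs x cases matrix over herbs with count strictly > min_count.

    The strict cut mirrors the "occurrences higher than 50" inclusion rule.
    Rows are sorted by herb name, columns follow case order.
    """
    if not cases:
        raise ClusterError("no cases")
    counts: dict[str, int] = {}
    for case in cases:
        for herb in case.herbs:
            counts[herb] = counts.get(herb, 0) + 1
    herbs = sorted(h for h, c in counts.items() if c > min_count)
    if not herbs:
        raise ClusterError(f"no herb occurs in more than {min_count} cases")
    data = np.zeros((len(herbs), len(cases)), dtype=np.int8)
    index = {h: i for i, h in enumerate(herbs)}
    for j, case in enumerate(cases):
        for herb in case.herbs:
            if herb in index:
                data[index[herb], j] = 1
    return pd.DataFrame(data, index=herbs, columns=[c.case_id for c in cases])


def linkage(
    matrix: pd.DataFrame,
    metric: Literal["euclidean", "jaccard"] = "euclidean",
    method: Literal["complete", "average", "single"] = "complete",
) -> Dendrogram:
    """Agglomerative clustering of the incidence rows.

    Starts from singletons and repeatedly merges the pair of clusters at
    minimal inter-cluster distance (complete linkage: the maximum pairwise
    row distance; single: minimum; average: unweighted mean). Ties are broken
    by the lexicographically smallest pair of cluster labels, so the result
    does not depend on input row order.
    """
    if matrix.shape[0] < 2:
        raise ClusterError("need at least 2 rows to cluster")
    if metric not in ("euclidean", "jaccard"):
        raise ClusterError(f"unknown metric {metric!r}")
    if method not in ("complete", "average", "single"):
        raise ClusterError(f"unknown method {method!r}")

    order = np.argsort(matrix.index.to_numpy())
    names = [str(matrix.index[i]) for i in order]
    base = squareform(pdist(matrix.to_numpy()[order].astype(float), metric=metric))

    clusters: dict[Node, list[int]] = {(n,): [i] for i, n in enumerate(names)}
    merges: list[tuple[Node, Node, float]] = []

    def cluster_distance(a: Node, b: Node) -> float:
        block = base[np.ix_(clusters[a], clusters[b])]
        if method == "complete":
            return float(block.max())
        if method == "single":
            return float(block.min())
        return float(block.mean())

    while len(clusters) > 1:
        keys = sorted(clusters)
        best: tuple[float, Node, Node] | None = None
        for i, a in enumerate(keys):
            for b in keys[i + 1:]:
                d = cluster_distance(a, b)
                if best is None or d < best[0]:
                    best = (d, a, b)  # first hit at a given d is the lexicographic min
        d, a, b = best
        merged = tuple(sorted(a + b))
        clusters[merged] = clusters.pop(a) + clusters.pop(b)
        merges.append((a, b, d))
    return Dendrogram(tuple(names), tuple(merges))


def cut_groups(dend: Dendrogram, k: int) -> dict[str, int]:
    """Cut the tree into k groups by removing the k-1 highest merges.

    Heights are non-decreasing along the merge sequence for the supported
    linkages, so the k-1 highest merges are the last ones. Group ids 1..k are
    assigned in first-leaf order.
    """
    n = len(dend.leaves)
    if not 1 <= k <= n:
        raise ClusterError(f"k must be in 1..{n}, got {k}")
    parent = {leaf: leaf for leaf in dend.leaves}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b, _ in dend.merges[: n - k]:
        parent[find(a[0])] = find(b[0])

    groups: dict[str, int] = {}
    assignment: dict[str, int] = {}
    for leaf in dend.leaves:
        root = find(leaf)
        if root not in groups:
            groups[root] = len(groups) + 1
        assignment[leaf] = groups[root]
    return assignment


# ---------------------------------------------------------------------------
# Newick export / import (ultrametric: leaf-to-node path length = height / 2)
# ---------------------------------------------------------------------------

def to_newick(dend: Dendrogram) -> str:
    """Serialize the dendrogram as an ultrametric Newick string.

    Every cluster node sits at half its merge height above the leaves, so the
    two children of a merge at height h get branch lengths (h - h_child) / 2.
    """
    heights: dict[Node, float] = {(leaf,): 0.0 for leaf in dend.leaves}
    text: dict[Node, str] = {(leaf,): leaf for leaf in dend.leaves}
    root: Node = (dend.leaves[0],) if dend.leaves else ()
    for a, b, h in dend.merges:
        merged = tuple(sorted(a + b))
        parts = []
        for child in (a, b):
            bl = (h - heights[child]) / 2.0
            parts.append(f"{text[child]}:{bl!r}")  # repr: exact float round-trip
        text[merged] = "(" + ",".join(parts) + ")"
        heights[merged] = h
        root = merged
    return text[root] + ";"


def from_newick(newick: str) -> Dendrogram:
    """Parse an ultrametric Newick string back into a merge sequence.

    Node heights are recovered as twice the node-to-leaf path length; merges
    are ordered by (height, cluster size, labels), which reproduces the
    original merge order for trees produced by :func:`linkage`.
    """
    tree = dendropy.Tree.get(data=newick, schema="newick")
    records: list[tuple[float, int, Node, Node]] = []

    def walk(node) -> tuple[Node, float]:
        children = node.child_nodes()
        if not children:
            return (node.taxon.label,), 0.0
        if len(children) != 2:
            raise ClusterError("dendrogram trees must be binary")
        sides = []
        height = 0.0
        for child in children:
            leaves, h_child = walk(child)
            bl = child.edge.length or 0.0
            height = h_child + 2.0 * bl
            sides.append((leaves, h_child))
        (la, _), (lb, _) = sides
        a, b = sorted((tuple(sorted(la)), tuple(sorted(lb))))
        records.append((height, len(a) + len(b), a, b))
        return tuple(sorted(la + lb)), height

    all_leaves, _ = walk(tree.seed_node)
    records.sort(key=lambda r: (r[0], r[1], r[2], r[3]))
    merges = tuple((a, b, h) for h, _, a, b in records)
    return Dendrogram(tuple(all_leaves), merges)


def groups_frame(assignment: Mapping[str, int]) -> pd.DataFrame:
    return pd.DataFrame(
        sorted(assignment.items(), key=lambda kv: (kv[1], kv[0])),
        columns=["herb", "group"],
    )
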