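"""Divisive clustering of residue correlation profiles.

Each residue's row of the residue correlation matrix is its "correlation
profile": how strongly it couples to every other residue.  Two residues
belong in the same cluster when they correlate with similar *subsets* of
residues — they need not correlate with each other.  Clustering these
profiles with DIANA-style average-linkage divisive hierarchical clustering
yields cross-sections ("onion skins") of the correlation network rather
than discrete pathways: the cut typically orders clusters from the network
core outward to the surface.

The row distance is Euclidean with the two residues' own columns masked
from both rows, so trivial self-similarity never leaks into the metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

from .correlation import ResidueCorrelationMatrix


def _values(M) -> np.ndarray:
    if isinstance(M, ResidueCorrelationMatrix):
        return M.values
    return np.asarray(M, dtype=float)


def profile_distance(M, i: int, j: int, metric: str = "euclidean") -> float:
    """Distance between correlation profiles of residues i and j (1-based).

    Columns i and j are masked from both rows before comparison.
    """
    v = _values(M)
    if i == j:
        raise ValueError("profile distance needs two distinct residues")
    mask = np.ones(v.shape[0], dtype=bool)
    mask[[i - 1, j - 1]] = False
    a, b = v[i - 1, mask], v[j - 1, mask]
    if metric == "euclidean":
        return float(np.linalg.norm(a - b))
    if metric == "correlation":
        if a.std() == 0 or b.std() == 0:
            return 1.0
        return float(1.0 - np.corrcoef(a, b)[0, 1])
    raise ValueError(f"unknown metric {metric!r}")


def profile_distance_matrix(M, metric: str = "euclidean") -> np.ndarray:
    """All pairwise profile distances, with per-pair self-column masking."""
    v = _values(M)
    n = v.shape[0]
    if metric == "euclidean":
        # full squared row distance minus the two masked columns; with a
        # zero diagonal the masked terms are M_ji^2 and M_ij^2
        full_sq = squareform(pdist(v, metric="sqeuclidean"))
        d2 = full_sq - 2.0 * v * v
        return np.sqrt(np.maximum(d2, 0.0))
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = profile_distance(M, i + 1, j + 1, metric)
    return out


@dataclass
class ClusterNode:
    """A node of the divisive tree; members are 1-based residue indices."""

    members: tuple[int, ...]
    dissimilarity: float                 # average within-cluster distance
    split_order: int | None = None       # step at which this node was split
    children: tuple["ClusterNode", "ClusterNode"] | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None


@dataclass
class ClusterTree:
    """Binary divisive hierarchy over residues with flat cuts at any k."""

    root: ClusterNode
    n_residues: int

    def cut(self, n_clusters: int) -> list[tuple[int, ...]]:
        """Cluster memberships after n_clusters - 1 splits, in split order."""
        if not 1 <= n_clusters <= self.n_residues:
            raise ValueError("n_clusters out of range")
        active = [self.root]
        while len(active) < n_clusters:
            splittable = [c for c in active if c.children is not None]
            if not splittable:
                break
            nxt = min(splittable, key=lambda c: c.split_order)
            active.remove(nxt)
            active.extend(nxt.children)
        return [c.members for c in active]

    def labels(self, n_clusters: int) -> np.ndarray:
        """Flat labels (0-based cluster ids) per residue, shape (N,)."""
        out = np.empty(self.n_residues, dtype=int)
        for lab, members in enumerate(self.cut(n_clusters)):
            for m in members:
                out[m - 1] = lab
        return out

    def to_newick(self) -> str:
        """Newick string of the full divisive hierarchy."""
        def _fmt(node: ClusterNode) -> str:
            if node.is_leaf and len(node.members) == 1:
                return f"r{node.members[0]}"
            if node.is_leaf:
                inner = ",".join(f"r{m}" for m in node.members)
                return f"({inner})"
            left, right = node.children
            return f"({_fmt(left)},{_fmt(right)}):{node.dissimilarity:.6g}"
        return _fmt(self.root) + ";"


def _avg_within(d: np.ndarray, members: list[int]) -> float:
    if len(members) < 2:
        return 0.0
    sub = d[np.ix_(members, members)]
    n = len(members)
    return float(sub.sum() / (n * (n - 1)))


def _split_cluster(d: np.ndarray, members: list[int]) -> tuple[list[int], list[int]]:
    """DIANA splinter step on one cluster (0-based member indices)."""
    rest = list(members)
    # seed: member with maximal average dissimilarity to its cluster mates,
    # ties broken by the lowest residue index
    avg = [(d[m, [x for x in rest if x != m]].mean(), m) for m in rest]
    seed = min(avg, key=lambda t: (-t[0], t[1]))[1]
    splinter = [seed]
    rest.remove(seed)
    while len(rest) > 1:
        to_move = []
        for m in rest:
            d_spl = d[m, splinter].mean()
            d_rest = d[m, [x for x in rest if x != m]].mean()
            if d_spl < d_rest:
                to_move.append(m)
        if not to_move:
            break
        for m in to_move:
            if len(rest) == 1:
                break
            splinter.append(m)
            rest.remove(m)
    return sorted(splinter), sorted(rest)


def divisive_cluster(M, n_clusters: int = 6,
                     metric: str = "euclidean") -> ClusterTree:
    """DIANA-style divisive hierarchical clustering of residue profiles.

    Starting from one cluster of all residues, the cluster with the
    greatest average within-cluster dissimilarity is split at each step:
    the member with maximal average dissimilarity to its mates seeds a
    splinter group, then members whose average dissimilarity to the
    splinter is smaller than to the remainder migrate, iterating to
    convergence.  Splitting continues to singletons so a flat cut exists
    at every cluster count; ``n_clusters`` only validates the default cut.
    Fully deterministic: ties are broken by the lowest residue index.
    """
    v = _values(M)
    n = v.shape[0]
    if not 1 <= n_clusters <= n:
        raise ValueError("n_clusters out of range")
    d = profile_distance_matrix(M, metric)
    root = ClusterNode(tuple(range(1, n + 1)), _avg_within(d, list(range(n))))
    active: list[ClusterNode] = [root]
    step = 0
    while any(len(c.members) > 1 for c in active):
        candidates = [c for c in active if len(c.members) > 1]
        # greatest internal dissimilarity; ties -> lowest member index
        target = min(candidates,
                     key=lambda c: (-c.dissimilarity, c.members[0]))
        members0 = [m - 1 for m in target.members]
        left, right = _split_cluster(d, members0)
        kids = tuple(
            ClusterNode(tuple(m + 1 for m in part), _avg_within(d, part))
            for part in (left, right))
        target.children = kids
        target.split_order = step
        step += 1
        active.remove(target)
        active.extend(kids)
    return ClusterTree(root, n)


def layer_summary(tree: ClusterTree, complex, center_residues,
                  n_clusters: int = 6) -> pd.DataFrame:
    """Order flat clusters by mean member distance to a center residue set.

    For each cluster of the flat cut, computes the mean over members of the
    minimum centroid distance to the center set, then sorts ascending
    (stable, so equal-distance clusters keep cluster-id order).  In a
    core-to-surface ("onion-skin") network the layers come out in that
    geometric order.
    """
    centers = [int(c) for c in center_residues]
    if not centers:
        raise ValueError("empty center residue set")
    cents = complex.centroids()
    center_xyz = cents[[c - 1 for c in centers]]
    records = []
    for cid, members in enumerate(tree.cut(n_clusters)):
        xyz = cents[[m - 1 for m in members]]
        dmin = np.linalg.norm(xyz[:, None, :] - center_xyz[None, :, :],
                              axis=-1).min(axis=1)
        records.append((cid, len(members), float(dmin.mean()), members))
    df = pd.DataFrame(records, columns=["cluster", "size",
                                        "mean_center_distance", "members"])
    return df.sort_values("mean_center_distance", kind="stable",
                          ignore_index=True)


def write_labels(tree: ClusterTree, n_clusters: int, path) -> None:
    """TSV of residue index and flat cluster label."""
    labels = tree.labels(n_clusters)
    pd.DataFrame({"residue": np.arange(1, tree.n_residues + 1),
                  "cluster": labels}).to_csv(path, sep="\t", index=False)
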