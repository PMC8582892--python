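"""Cluster structure on a trained map: Ward clustering of the codebook
vectors, the unified-distance-matrix (U-matrix) alternative, and the data
behind per-node code plots.

A trained map has no visible cluster boundaries; agglomerative Ward
clustering of the codebook vectors draws them. The merge cost between
clusters r and s is

    d_rs = n_r n_s / (n_r + n_s) * ||w_r - w_s||^2,

the increase in within-cluster sum of squares caused by the merge, where
w_r, w_s are cluster centroids (pooled means of member codebooks) and n_r,
n_s the member counts. An unsquared-centroid-distance variant is available
via ``squared=False``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InvalidConfigError
from .grid import SOMGrid

__all__ = [
    "CodebookCluster",
    "WardClustering",
    "ward_distance",
    "ward_cluster_codebooks",
    "u_matrix",
    "code_plot_data",
]


@dataclass
class CodebookCluster:
    """A cluster of map nodes: member linear indices, size, and the centroid
    (mean of member codebooks)."""

    members: tuple[int, ...]
    centroid: np.ndarray

    @property
    def size(self) -> int:
        return len(self.members)


def ward_distance(r: CodebookCluster, s: CodebookCluster, squared: bool = True) -> float:
    """Ward merge cost between two disjoint clusters.

    d_rs = (n_r n_s / (n_r + n_s)) * ||w_r - w_s||^2 (default), or with the
    unsquared centroid distance when ``squared=False``.
    """
    if r.size == 0 or s.size == 0:
        raise InvalidConfigError("clusters must be non-empty")
    if set(r.members) & set(s.members):
        raise InvalidConfigError("clusters must be disjoint")
    gap = np.linalg.norm(np.asarray(r.centroid, float) - np.asarray(s.centroid, float))
    factor = r.size * s.size / (r.size + s.size)
    return float(factor * (gap * gap if squared else gap))


@dataclass
class WardClustering:
    """Result of agglomerative Ward clustering of codebooks.

    labels : per-node cluster label, 0..n_clusters-1, numbered by each
        cluster's smallest member node index.
    merge_costs : the Ward cost of every merge performed, in merge order.
    clusters : the surviving clusters.
    """

    labels: np.ndarray
    merge_costs: list[float]
    clusters: list[CodebookCluster]


def ward_cluster_codebooks(
    codebooks: np.ndarray, n_clusters: int, squared: bool = True
) -> WardClustering:
    """Agglomerate codebook vectors down to ``n_clusters`` clusters.

    Starts from singletons, repeatedly merges the pair with the smallest
    Ward cost, and updates the merged centroid as the pooled mean. Ties are
    broken toward the pair with the lexicographically smallest (smallest
    member index of r, smallest member index of s).
    """
    W = np.atleast_2d(np.asarray(codebooks, dtype=float))
    n = W.shape[0]
    if not 1 <= n_clusters <= n:
        raise InvalidConfigError(
            f"n_clusters must be in [1, {n}], got {n_clusters}"
        )
    clusters = [CodebookCluster(members=(i,), centroid=W[i].copy()) for i in range(n)]
    merge_costs: list[float] = []
    while len(clusters) > n_clusters:
        best = None
        best_key = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = ward_distance(clusters[a], clusters[b], squared=squared)
                key = (d, min(clusters[a].members), min(clusters[b].members))
                if best_key is None or key < best_key:
                    best_key = key
                    best = (a, b)
        a, b = best
        ca, cb = clusters[a], clusters[b]
        merged = CodebookCluster(
            members=tuple(sorted(ca.members + cb.members)),
            centroid=(ca.size * ca.centroid + cb.size * cb.centroid) / (ca.size + cb.size),
        )
        merge_costs.append(best_key[0])
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)] + [merged]
    ordered = sorted(clusters, key=lambda c: min(c.members))
    labels = np.empty(n, dtype=int)
    for lab, c in enumerate(ordered):
        labels[list(c.members)] = lab
    return WardClustering(labels=labels, merge_costs=merge_costs, clusters=ordered)


def u_matrix(grid: SOMGrid, codebooks: np.ndarray) -> np.ndarray:
    """Per-node mean Euclidean distance between its codebook and each direct
    lattice neighbour's codebook; large values mark cluster boundaries."""
    W = np.atleast_2d(np.asarray(codebooks, dtype=float))
    values = np.zeros(grid.n_nodes)
    for node in range(grid.n_nodes):
        nbrs = grid.neighbours(node)
        if nbrs.size:
            values[node] = np.mean(np.linalg.norm(W[nbrs] - W[node], axis=1))
    return values


def code_plot_data(codebooks: np.ndarray, feature_names: list[str]) -> pd.DataFrame:
    """Fan weights for a per-node code plot.

    Each feature's codebook component is rescaled to [0, 1] across the map
    (a feature that is constant across all nodes gets the midpoint 0.5), so
    the fan size shows how strongly that variable characterizes the node.
    Nodes are reported 1-based in reading order (node 1 = bottom-left).
    """
    W = np.atleast_2d(np.asarray(codebooks, dtype=float))
    lo = W.min(axis=0)
    hi = W.max(axis=0)
    span = hi - lo
    weights = np.full_like(W, 0.5)
    nz = span > 0
    weights[:, nz] = (W[:, nz] - lo[nz]) / span[nz]
    records = [
        {"node": node + 1, "feature": feature_names[f], "weight": weights[node, f]}
        for node in range(W.shape[0])
        for f in range(W.shape[1])
    ]
    return pd.DataFrame.from_records(records, columns=["node", "feature", "weight"])
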