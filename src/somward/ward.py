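"""Topology-constrained Ward agglomeration of SOM nodes (SOM-Ward).

Classical Ward clustering merges, at every step, the pair of clusters
whose fusion least increases the total within-cluster sum of squares;
for clusters with centroids ``mu_a, mu_b`` and weights ``w_a, w_b`` that
increase is

    cost(a, b) = w_a * w_b / (w_a + w_b) * ||mu_a - mu_b||^2 .

SOM-Ward superimposes this on the map topology: only clusters that are
adjacent on the lattice may merge, so every cluster is a connected
region of the map and inherits the SOM's ordering. Weights are the
record counts mapped to each node — the algorithm clusters people, not
nodes — and record labels follow from each record's BMU.

Because of the adjacency constraint the sequence of accepted merge
costs need not be monotone, unlike unconstrained Ward; when the
unconstrained-optimal merge happens to be adjacent at every step (for
instance monotone one-dimensional layouts) the two dendrograms coincide.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .som import NodeAssignment, SomGrid, SomModel

__all__ = [
    "ClusterModel",
    "node_adjacency",
    "ward_cost",
    "som_ward_cluster",
    "choose_k",
    "label_records",
    "save_clusters",
]


def node_adjacency(grid: SomGrid, connectivity: int = 4) -> set[tuple[int, int]]:
    """Lattice neighbor pairs (i < j). 4-connectivity: horizontal and
    vertical neighbors; 8 adds the diagonals."""
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    edges: set[tuple[int, int]] = set()
    steps = [(0, 1), (1, 0)]
    if connectivity == 8:
        steps += [(1, 1), (1, -1)]
    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            i = r * grid.n_cols + c
            for dr, dc in steps:
                rr, cc = r + dr, c + dc
                if 0 <= rr < grid.n_rows and 0 <= cc < grid.n_cols:
                    j = rr * grid.n_cols + cc
                    edges.add((min(i, j), max(i, j)))
    return edges


def ward_cost(mu_a: np.ndarray, w_a: float, mu_b: np.ndarray, w_b: float) -> float:
    """Increase in total within-cluster SSE caused by merging (a, b)."""
    if w_a <= 0 or w_b <= 0:
        raise ValueError("ward_cost requires positive cluster weights")
    diff = np.asarray(mu_a, float) - np.asarray(mu_b, float)
    return float(w_a * w_b / (w_a + w_b) * (diff @ diff))


@dataclass
class ClusterModel:
    """Result of a SOM-Ward run: node labels, merge history, final k."""

    node_labels: np.ndarray  # (n_nodes,) cluster ids 0..k-1
    dendrogram: list[tuple[int, int, float, int]]  # (a, b, cost, resulting_size)
    k: int
    cluster_weights: np.ndarray  # records per cluster, descending

    def __post_init__(self) -> None:
        labels = set(int(l) for l in self.node_labels)
        if labels != set(range(self.k)):
            raise ValueError("node labels must be contiguous 0..k-1")


def _nearest_nonempty(
    grid: SomGrid, empty_idx: np.ndarray, nonempty_idx: np.ndarray
) -> np.ndarray:
    """For each empty node, the nearest non-empty node by lattice distance
    (ties -> lowest node index)."""
    xy = grid.coordinates.astype(float)
    d = np.sqrt(((xy[empty_idx][:, None, :] - xy[nonempty_idx][None, :, :]) ** 2).sum(-1))
    # nonempty_idx ascending, so argmin's first-hit rule = lowest node index
    return nonempty_idx[d.argmin(axis=1)]


def som_ward_cluster(
    model: SomModel,
    assignment: NodeAssignment,
    k: int,
    connectivity: int = 4,
) -> ClusterModel:
    """Agglomerate map nodes to *k* clusters under the adjacency constraint.

    Every non-empty node starts as a singleton cluster (centroid = its
    codebook vector, weight = mapped record count); empty nodes are
    pre-attached with zero weight to their nearest non-empty node so
    regions stay connected without distorting Ward costs. Merging is
    deterministic: minimal cost first, ties broken by the
    lexicographically smallest pair of lowest member-node indices.
    Final labels are 0..k-1 in order of decreasing cluster weight.
    """
    counts = assignment.node_counts.astype(float)
    n_nodes = model.grid.n_nodes
    nonempty = np.flatnonzero(counts > 0)
    if len(nonempty) == 0:
        raise ValueError("cannot cluster a map with no mapped records")
    if not (1 <= k <= len(nonempty)):
        raise ValueError(
            f"k={k} out of range: map has {len(nonempty)} non-empty nodes"
        )

    # cluster bookkeeping: one active cluster per non-empty node
    owner = np.empty(n_nodes, dtype=int)  # node -> current cluster id
    owner[nonempty] = np.arange(len(nonempty))
    empty = np.flatnonzero(counts == 0)
    if len(empty):
        owner[empty] = owner[_nearest_nonempty(model.grid, empty, nonempty)]

    centroids = {ci: model.codebook[node].copy() for ci, node in enumerate(nonempty)}
    weights = {ci: counts[node] for ci, node in enumerate(nonempty)}
    members: dict[int, list[int]] = {ci: [] for ci in range(len(nonempty))}
    for node in range(n_nodes):
        members[owner[node]].append(node)
    min_node = {ci: min(m) for ci, m in members.items()}

    # cluster-level adjacency from node-level lattice edges
    node_edges = node_adjacency(model.grid, connectivity)
    adj: dict[int, set[int]] = {ci: set() for ci in range(len(nonempty))}
    for i, j in node_edges:
        a, b = owner[i], owner[j]
        if a != b:
            adj[a].add(b)
            adj[b].add(a)

    dendrogram: list[tuple[int, int, float, int]] = []
    active = set(range(len(nonempty)))
    next_id = len(nonempty)

    while len(active) > k:
        best = None  # (cost, min_node_a, min_node_b, a, b)
        for a in active:
            for b in adj[a]:
                if b <= a:
                    continue
                cost = ward_cost(centroids[a], weights[a], centroids[b], weights[b])
                lo, hi = sorted((min_node[a], min_node[b]))
                key = (cost, lo, hi)
                if best is None or key < best[0]:
                    best = (key, a, b)
        if best is None:  # disconnected map cannot happen on a lattice
            raise RuntimeError("no adjacent cluster pair available to merge")
        (cost, _, _), a, b = best

        w = weights[a] + weights[b]
        centroids[next_id] = (weights[a] * centroids[a] + weights[b] * centroids[b]) / w
        weights[next_id] = w
        members[next_id] = members.pop(a) + members.pop(b)
        min_node[next_id] = min(min_node.pop(a), min_node.pop(b))
        neigh = (adj.pop(a) | adj.pop(b)) - {a, b}
        adj[next_id] = neigh
        for c in neigh:
            adj[c].discard(a)
            adj[c].discard(b)
            adj[c].add(next_id)
        for node in members[next_id]:
            owner[node] = next_id
        active.discard(a)
        active.discard(b)
        active.add(next_id)
        dendrogram.append((a, b, cost, len(members[next_id])))
        del centroids[a], centroids[b], weights[a], weights[b]
        next_id += 1

    # relabel by descending record weight (ties -> lowest member node)
    order = sorted(active, key=lambda ci: (-weights[ci], min_node[ci]))
    relabel = {ci: rank for rank, ci in enumerate(order)}
    node_labels = np.array([relabel[owner[node]] for node in range(n_nodes)])
    cluster_weights = np.array([weights[ci] for ci in order])
    return ClusterModel(
        node_labels=node_labels,
        dendrogram=dendrogram,
        k=len(active),
        cluster_weights=cluster_weights,
    )


def choose_k(
    dendrogram: Sequence[tuple[int, int, float, int]],
    k_min: int = 2,
    k_max: int = 30,
) -> int:
    """Suggested cluster count: the k whose next merge cost jumps most,
    relative to the preceding merge, searched over k in [k_min, k_max].

    The dendrogram must have been run down to one cluster. A user-chosen
    k always overrides this suggestion. Ties (including perfectly
    uniform costs) resolve to the smallest k in range.
    """
    if len(dendrogram) < 2:
        raise ValueError("choose_k needs a dendrogram with at least 2 merges")
    costs = [m[2] for m in dendrogram]
    n_initial = len(dendrogram) + 1  # merges run clusters from n_initial down to 1
    best_k, best_ratio = None, -np.inf
    for k in range(k_min, min(k_max, n_initial - 1) + 1):
        # merging k -> k-1 clusters is dendrogram entry n_initial - k
        c_next = costs[n_initial - k]
        c_prev = costs[n_initial - k - 1]
        if c_prev > 0:
            ratio = c_next / c_prev
        else:
            ratio = np.inf if c_next > 0 else 1.0
        # strict > keeps the smallest k on ties
        if ratio > best_ratio:
            best_k, best_ratio = k, ratio
    if best_k is None:
        raise ValueError("no k candidate in the search range")
    return best_k


def label_records(assignment: NodeAssignment, clusters: ClusterModel) -> np.ndarray:
    """Per-record cluster label = cluster of the record's BMU node."""
    return clusters.node_labels[assignment.bmu]


def save_clusters(
    clusters: ClusterModel,
    grid: SomGrid,
    assignment: NodeAssignment,
    nodes_path: str | Path,
    dendrogram_path: str | Path | None = None,
) -> None:
    """Export node memberships (and optionally the merge history) as CSV."""
    coords = grid.coordinates
    with open(nodes_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["node_id", "row", "col", "cluster_label", "node_count"])
        for node in range(grid.n_nodes):
            w.writerow(
                [
                    node,
                    coords[node, 0],
                    coords[node, 1],
                    int(clusters.node_labels[node]),
                    int(assignment.node_counts[node]),
                ]
            )
    if dendrogram_path is not None:
        with open(dendrogram_path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["cluster_a", "cluster_b", "ward_cost", "resulting_size"])
            for a, b, cost, size in clusters.dendrogram:
                w.writerow([a, b, repr(cost), size])
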