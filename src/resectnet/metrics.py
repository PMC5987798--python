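"""Weighted graph measures and pre/post-operative change metrics.

All measures treat the connectome as a weighted undirected graph, exclude
self-connections, and use edge length 1/weight for shortest-path measures
(heavier connections are shorter).  Betweenness is left unnormalised;
clustering is the Onnela geometric-mean form with max-weight normalisation;
communicability is the matrix exponential of the strength-normalised
adjacency D^{-1/2} W D^{-1/2}.

Change rules: properties that can only shrink under resection (region
volume, region strength, connection strength) are summarised as post/pre
ratios (0/0 := 1); properties that can move either way (node and edge
betweenness, clustering, communicability) as post - pre differences.
Global efficiency is reported pre, post, and as a ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.linalg
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from .network import ConnectivityMatrix

__all__ = [
    "NetworkMetrics",
    "ChangeMetrics",
    "strength",
    "shortest_path_lengths",
    "betweenness",
    "clustering",
    "global_efficiency",
    "communicability",
    "compute_metrics",
    "change_metrics",
    "ratio_change",
]


def _offdiag(W: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    if isinstance(W, ConnectivityMatrix):
        return W.offdiagonal()
    A = np.asarray(W, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("weight matrix must be square")
    if np.any(A < 0):
        raise ValueError("negative weights")
    A = A.copy()
    np.fill_diagonal(A, 0.0)
    return A


def strength(W: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    """Region strength: sum of weights incident to each region
    (self-connections excluded)."""
    return _offdiag(W).sum(axis=1)


def shortest_path_lengths(W: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    """All-pairs weighted shortest-path distances on edge lengths 1/w.

    Absent edges are unreachable directly; disconnected pairs get +inf.
    """
    A = _offdiag(W)
    with np.errstate(divide="ignore"):
        L = np.where(A > 0, 1.0 / A, np.inf)
    np.fill_diagonal(L, 0.0)
    # csgraph treats 0 as absent; pass lengths with infs masked out
    Lg = np.where(np.isfinite(L), L, 0.0)
    D = _csgraph_shortest_path(Lg, method="D", directed=False, unweighted=False)
    return D


def _to_length_graph(A: np.ndarray) -> nx.Graph:
    G = nx.Graph()
    G.add_nodes_from(range(A.shape[0]))
    ii, jj = np.nonzero(np.triu(A, k=1))
    for i, j in zip(ii.tolist(), jj.tolist()):
        G.add_edge(i, j, weight=A[i, j], length=1.0 / A[i, j])
    return G


def betweenness(W: ConnectivityMatrix | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unnormalised node and edge betweenness on the 1/weight length graph.

    Node value: over all unordered pairs s != t, the fraction of shortest
    s-t paths passing through the node (excluding endpoints), summed.  Edge
    value: analogous fraction of shortest paths traversing the edge.
    """
    A = _offdiag(W)
    G = _to_length_graph(A)
    R = A.shape[0]
    nb = nx.betweenness_centrality(G, weight="length", normalized=False)
    eb = nx.edge_betweenness_centrality(G, weight="length", normalized=False)
    node = np.array([nb[i] for i in range(R)])
    edge = np.zeros((R, R))
    for (i, j), v in eb.items():
        edge[i, j] = edge[j, i] = v
    return node, edge


def clustering(W: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    """Onnela weighted clustering: geometric-mean triangle intensity with
    weights normalised by the network-wide maximum; 0 for degree < 2."""
    A = _offdiag(W)
    G = _to_length_graph(A)
    c = nx.clustering(G, weight="weight")
    return np.array([c[i] for i in range(A.shape[0])])


def global_efficiency(W: ConnectivityMatrix | np.ndarray) -> float:
    """Mean inverse shortest-path distance over ordered region pairs."""
    D = shortest_path_lengths(W)
    R = D.shape[0]
    if R < 2:
        raise ValueError("global efficiency requires at least 2 regions")
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(D) & (D > 0), 1.0 / D, 0.0)
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (R * (R - 1)))


def communicability(W: ConnectivityMatrix | np.ndarray, return_matrix: bool = False):
    """Regional communicability: row sums of expm(D^{-1/2} W D^{-1/2}).

    D is the diagonal strength matrix; zero-strength regions get a unit
    normaliser so isolated nodes contribute the identity (row sum 1).
    """
    A = _offdiag(W)
    s = A.sum(axis=1)
    d = np.where(s > 0, s, 1.0)
    inv_sqrt = 1.0 / np.sqrt(d)
    An = A * inv_sqrt[:, None] * inv_sqrt[None, :]
    C = scipy.linalg.expm(An)
    rows = C.sum(axis=1)
    return (rows, C) if return_matrix else rows


@dataclass
class NetworkMetrics:
    """Bundle of every measure for one network."""

    connectivity: ConnectivityMatrix
    strength: np.ndarray
    node_betweenness: np.ndarray
    edge_betweenness: np.ndarray
    clustering: np.ndarray
    communicability: np.ndarray
    global_efficiency: float

    @property
    def region_ids(self) -> list[int]:
        return self.connectivity.region_ids


def compute_metrics(W: ConnectivityMatrix) -> NetworkMetrics:
    nb, eb = betweenness(W)
    return NetworkMetrics(
        connectivity=W,
        strength=strength(W),
        node_betweenness=nb,
        edge_betweenness=eb,
        clustering=clustering(W),
        communicability=communicability(W),
        global_efficiency=global_efficiency(W),
    )


def ratio_change(pre, post) -> np.ndarray:
    """Elementwise post/pre with the 0/0 := 1 convention."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    safe_pre = np.where(pre != 0, pre, 1.0)
    # pre == 0, post > 0 means grown from nothing -> +inf
    return np.where(pre != 0, post / safe_pre, np.where(post != 0, np.inf, 1.0))


@dataclass
class ChangeMetrics:
    """Pre -> predicted-post change summary for one subject."""

    region_ids: list[int]
    connection_strength_ratio: np.ndarray  # R x R, post/pre on counts
    region_strength_ratio: np.ndarray  # R, post/pre on counts
    volume_ratio: np.ndarray | None  # R, tissue remaining in [0, 1]
    node_betweenness_diff: np.ndarray
    edge_betweenness_diff: np.ndarray
    clustering_diff: np.ndarray
    communicability_diff: np.ndarray
    efficiency_pre: float
    efficiency_post: float
    efficiency_ratio: float


def change_metrics(
    pre: NetworkMetrics,
    post: NetworkMetrics,
    *,
    pre_counts: ConnectivityMatrix | None = None,
    post_counts: ConnectivityMatrix | None = None,
    volume_remaining: dict[int, float] | None = None,
) -> ChangeMetrics:
    """Combine two metric bundles into the change summary.

    Ratio-type features (connection strength, region strength) are computed
    from ``pre_counts``/``post_counts`` when given (raw streamline counts,
    giving ratios in [0, 1] under resection), otherwise from the bundles'
    own weight matrices.
    """
    if pre.region_ids != post.region_ids:
        raise ValueError("pre and post metrics use different region sets")
    pc = pre_counts if pre_counts is not None else pre.connectivity
    qc = post_counts if post_counts is not None else post.connectivity
    if pc.region_ids != qc.region_ids or pc.region_ids != pre.region_ids:
        raise ValueError("count matrices use a different region set")

    vol = None
    if volume_remaining is not None:
        vol = np.array([volume_remaining[rid] for rid in pre.region_ids], dtype=float)

    return ChangeMetrics(
        region_ids=list(pre.region_ids),
        connection_strength_ratio=ratio_change(pc.offdiagonal(), qc.offdiagonal()),
        region_strength_ratio=ratio_change(strength(pc), strength(qc)),
        volume_ratio=vol,
        node_betweenness_diff=post.node_betweenness - pre.node_betweenness,
        edge_betweenness_diff=post.edge_betweenness - pre.edge_betweenness,
        clustering_diff=post.clustering - pre.clustering,
        communicability_diff=post.communicability - pre.communicability,
        efficiency_pre=pre.global_efficiency,
        efficiency_post=post.global_efficiency,
        efficiency_ratio=float(ratio_change(pre.global_efficiency, post.global_efficiency)),
    )
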