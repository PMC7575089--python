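"""Clustering-coefficient machinery with O(d) incremental updates.

The graph container is a :class:`networkx.Graph` restricted to simple,
loopless, undirected graphs (validated on entry).  Around it this module
builds a :class:`ClusteringState`: cached degrees, per-node triangle
counts, local clustering coefficients and their mean, kept consistent
under single-link insertion so that optimizers can score and commit many
candidate links without ever recomputing the clustering from scratch.

Notation used throughout the package: for a node ``w``, ``N(w)`` is its
neighbour set, ``d_w = |N(w)|`` its degree and ``T(w)`` the number of
links among its neighbours (equivalently, the number of triangles through
``w``).  The local clustering coefficient is

    C(w) = 2 T(w) / (d_w (d_w - 1))   if d_w > 1, else 0

and the graph clustering coefficient ``C_G`` (Watts–Strogatz) is the
arithmetic mean of ``C(w)`` over all ``n`` nodes.

Adding a missing link ``(u, v)`` with ``k = |N(u) ∩ N(v)|`` common
neighbours changes the clustering of ``u``, ``v`` and of each common
neighbour only, so

    C_{G+uv} = C_G + ( ΔC(u) + ΔC(v) + Σ_{w ∈ N(u,v)} 2/(d_w (d_w-1)) ) / n

with ΔC(u) = (2 k (d_u - 1) - 4 T(u)) / (d_u (d_u² - 1)) for d_u > 1.
For the degenerate degrees the recomputation-exact values are used:
ΔC(u) = k when d_u = 1 (the new neighbourhood {old neighbour, v} is
complete iff they are linked, i.e. iff k = 1) and ΔC(u) = 0 when
d_u = 0 (a degree-1 node has clustering 0 both before and after).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable

import networkx as nx
import numpy as np

Node = Hashable

#: absolute tolerance for clustering-value comparisons (ties, oracle checks)
CLUSTERING_ATOL = 1e-12


# ---------------------------------------------------------------------------
# graph validation and ordering
# ---------------------------------------------------------------------------

def validate_graph(graph: nx.Graph) -> nx.Graph:
    """Check that *graph* is a simple, loopless, undirected graph.

    Returns the graph unchanged; raises ``ValueError`` otherwise.
    """
    if graph.is_directed() or graph.is_multigraph():
        raise ValueError("graph must be simple and undirected")
    loops = list(nx.selfloop_edges(graph))
    if loops:
        raise ValueError(f"self-loops are not allowed: {loops[:3]}")
    return graph


def sorted_nodes(graph: nx.Graph) -> list[Node]:
    """Nodes in the package's canonical total order.

    Natural sort when labels are mutually comparable, string sort as a
    fallback; this order is used wherever ordering matters (candidate
    enumeration, tie-breaking, array layouts).
    """
    nodes = list(graph.nodes)
    try:
        return sorted(nodes)
    except TypeError:
        return sorted(nodes, key=str)


def ordered_pair(u: Node, v: Node) -> tuple[Node, Node]:
    """Canonical (sorted) representation of an unordered node pair."""
    try:
        return (u, v) if u <= v else (v, u)
    except TypeError:
        return (u, v) if str(u) <= str(v) else (v, u)


def coordinates(graph: nx.Graph) -> np.ndarray:
    """Per-node metric coordinates, aligned with :func:`sorted_nodes`.

    Nodes must carry ``x``/``y`` attributes (metres).  Raises
    ``ValueError`` when any node lacks them.
    """
    coords = np.empty((graph.number_of_nodes(), 2), dtype=float)
    for i, node in enumerate(sorted_nodes(graph)):
        data = graph.nodes[node]
        if "x" not in data or "y" not in data:
            raise ValueError(f"node {node!r} has no x/y coordinates")
        coords[i] = (data["x"], data["y"])
    return coords


# ---------------------------------------------------------------------------
# clustering state
# ---------------------------------------------------------------------------

@dataclass
class ClusteringState:
    """Cached clustering bookkeeping for one graph.

    Arrays are aligned with ``nodes`` (canonical order).  ``adj`` is the
    boolean adjacency matrix — affordable at habitat-network scales and
    the basis of the vectorised candidate scoring in
    :func:`pair_score_matrix`.
    """

    nodes: list[Node]
    index: dict[Node, int] = field(repr=False)
    adj: np.ndarray = field(repr=False)
    degree: np.ndarray = field(repr=False)
    triangles: np.ndarray = field(repr=False)
    node_c: np.ndarray = field(repr=False)
    mean_c: float = 0.0

    @classmethod
    def from_graph(cls, graph: nx.Graph) -> "ClusteringState":
        validate_graph(graph)
        nodes = sorted_nodes(graph)
        n = len(nodes)
        if n < 1:
            raise ValueError("clustering is undefined on an empty node set")
        index = {node: i for i, node in enumerate(nodes)}
        adj = np.zeros((n, n), dtype=bool)
        for u, v in graph.edges:
            i, j = index[u], index[v]
            adj[i, j] = adj[j, i] = True
        degree = adj.sum(axis=1).astype(np.int64)
        # T(v) = number of links among N(v); (A @ A)[i, j] counts common
        # neighbours, and summing it over j in N(i) double-counts each link
        tri = (adj.astype(np.int64) @ adj.astype(np.int64) * adj).sum(axis=1) // 2
        node_c = _local_clustering(degree, tri)
        return cls(nodes, index, adj, degree, tri, node_c, float(node_c.mean()))

    @property
    def n(self) -> int:
        return len(self.nodes)

    def copy(self) -> "ClusteringState":
        return ClusteringState(
            list(self.nodes), dict(self.index), self.adj.copy(),
            self.degree.copy(), self.triangles.copy(), self.node_c.copy(),
            self.mean_c,
        )

    def to_graph(self) -> nx.Graph:
        graph = nx.Graph()
        graph.add_nodes_from(self.nodes)
        ii, jj = np.nonzero(np.triu(self.adj))
        graph.add_edges_from((self.nodes[i], self.nodes[j]) for i, j in zip(ii, jj))
        return graph

    def _idx(self, v: Node) -> int:
        try:
            return self.index[v]
        except KeyError:
            raise KeyError(f"unknown node {v!r}") from None


def _local_clustering(degree: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    c = np.zeros(len(degree), dtype=float)
    mask = degree > 1
    d = degree[mask].astype(float)
    c[mask] = 2.0 * triangles[mask] / (d * (d - 1.0))
    return c


# ---------------------------------------------------------------------------
# basic quantities
# ---------------------------------------------------------------------------

def node_clustering(state: ClusteringState, v: Node) -> float:
    """Local clustering coefficient C(v) ∈ [0, 1]."""
    return float(state.node_c[state._idx(v)])


def graph_clustering(graph: nx.Graph) -> float:
    """Graph clustering coefficient C_G: the mean of C(v) over all nodes."""
    return ClusteringState.from_graph(graph).mean_c


def triangle_counts(graph: nx.Graph) -> dict[Node, int]:
    """Per-node triangle counts T(v) by neighbour-pair enumeration."""
    state = ClusteringState.from_graph(graph)
    return {node: int(t) for node, t in zip(state.nodes, state.triangles)}


def common_neighbours(graph: nx.Graph, u: Node, v: Node) -> set[Node]:
    """N(u, v) = N(u) ∩ N(v) for two distinct nodes."""
    if u == v:
        raise ValueError("common neighbours require two distinct nodes")
    if u not in graph or v not in graph:
        raise KeyError(f"unknown node in pair ({u!r}, {v!r})")
    return set(graph.adj[u]) & set(graph.adj[v])


# ---------------------------------------------------------------------------
# single-link update
# ---------------------------------------------------------------------------

def delta_node_clustering(state: ClusteringState, u: Node, k: int) -> float:
    """Exact change of C(u) when one link with *k* common neighbours is
    added at *u*.

    ``k`` must be the size of the common-neighbour set of the candidate
    pair; it cannot exceed ``d_u``.
    """
    i = state._idx(u)
    d = int(state.degree[i])
    if k < 0 or k > d:
        raise ValueError(f"common-neighbour count k={k} outside [0, d_u={d}]")
    if d > 1:
        t = int(state.triangles[i])
        return (2.0 * k * (d - 1) - 4.0 * t) / (d * (d * d - 1.0))
    if d == 1:
        # new neighbourhood is {old neighbour, v}: complete iff k = 1
        return float(k)
    return 0.0


@dataclass(frozen=True)
class LinkDelta:
    """Decomposition of the clustering change caused by one candidate link."""

    u: Node
    v: Node
    k: int
    delta_u: float
    delta_v: float
    neighbour_terms: tuple[float, ...]
    new_c: float


def link_delta(state: ClusteringState, u: Node, v: Node) -> LinkDelta:
    """Score the missing link (u, v): the clustering of G+uv plus the
    per-term breakdown, without mutating *state*."""
    i, j = state._idx(u), state._idx(v)
    if i == j:
        raise ValueError("cannot add a self-loop")
    if state.adj[i, j]:
        raise ValueError(f"link ({u!r}, {v!r}) is already present")
    common = np.nonzero(state.adj[i] & state.adj[j])[0]
    k = len(common)
    terms = tuple(
        2.0 / (state.degree[w] * (state.degree[w] - 1.0)) for w in common
    )
    du = delta_node_clustering(state, u, k)
    dv = delta_node_clustering(state, v, k)
    new_c = state.mean_c + (du + dv + sum(terms)) / state.n
    return LinkDelta(u, v, k, du, dv, terms, new_c)


def updated_graph_clustering(state: ClusteringState, u: Node, v: Node) -> float:
    """Clustering coefficient of G+uv, via the O(d) update (no mutation)."""
    return link_delta(state, u, v).new_c


def apply_link(state: ClusteringState, u: Node, v: Node) -> ClusteringState:
    """Commit the link (u, v) into *state* (in place) and return it.

    Degrees of u and v grow by one, their triangle counts by k, each
    common neighbour's by one; clustering values follow.  The result is
    indistinguishable from rebuilding the state from the extended graph.
    """
    i, j = state._idx(u), state._idx(v)
    if i == j:
        raise ValueError("cannot add a self-loop")
    if state.adj[i, j]:
        raise ValueError(f"link ({u!r}, {v!r}) is already present")
    common = np.nonzero(state.adj[i] & state.adj[j])[0]
    k = len(common)
    state.adj[i, j] = state.adj[j, i] = True
    state.degree[[i, j]] += 1
    state.triangles[[i, j]] += k
    state.triangles[common] += 1
    touched = np.concatenate((common, [i, j])).astype(np.intp)
    state.node_c[touched] = _local_clustering(
        state.degree[touched], state.triangles[touched]
    )
    state.mean_c = float(state.node_c.mean())
    return state


# ---------------------------------------------------------------------------
# vectorised all-pairs scoring
# ---------------------------------------------------------------------------

def pair_score_matrix(state: ClusteringState) -> np.ndarray:
    """Clustering coefficient of G+ij for every missing pair, at once.

    Returns an (n, n) symmetric array with entry [i, j] = C_{G+ij} for
    each non-adjacent pair i ≠ j and NaN elsewhere.  Two boolean matrix
    products give the common-neighbour counts and the rescue terms of
    every pair simultaneously; the per-endpoint ΔC terms broadcast.
    Exhaustive enumeration and the greedy round both reduce to reading
    this matrix.
    """
    a = state.adj.astype(np.float64)
    d = state.degree.astype(np.float64)
    t = state.triangles.astype(np.float64)
    n = state.n

    k = a @ a  # k[i, j] = number of common neighbours of i and j
    g = np.zeros(n)
    mask = d > 1
    g[mask] = 2.0 / (d[mask] * (d[mask] - 1.0))
    rescue = (a * g) @ a.T  # Σ_{w ∈ N(i,j)} 2/(d_w (d_w - 1))

    # ΔC for endpoint i as a function of k (row-broadcast)
    delta = np.zeros((n, n))
    hi = d > 1
    dh = d[hi][:, None]
    delta[hi, :] = (2.0 * k[hi, :] * (dh - 1.0) - 4.0 * t[hi][:, None]) / (
        dh * (dh * dh - 1.0)
    )
    delta[d == 1, :] = k[d == 1, :]

    score = state.mean_c + (delta + delta.T + rescue) / n
    score[state.adj] = np.nan
    np.fill_diagonal(score, np.nan)
    return score
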