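"""Link-selection strategies for clustering-coefficient maximisation.

Given a graph and a candidate set of admissible missing links, the task
is to pick ``m`` of them so that the extended graph has maximum
clustering coefficient.  Four strategies are provided:

* :func:`exhaustive_best` — complete enumeration over all m-subsets of
  candidates (the exact optimum; exponential in m, budget-guarded);
* :func:`greedy` — m rounds, each committing the single best link for
  the *current* graph (scores are re-derived after every commit, since
  an added link changes the common-neighbour counts of other pairs);
* :func:`lazy_greedy` — scores every candidate once against the
  original graph and takes the top m in one pass;
* :func:`random_links` — uniform sampling without replacement, the
  baseline.

Tie-breaking is deterministic everywhere: the first maximizer in
candidate order (lexicographic by ordered label pair) wins, and for
exhaustive search the lexicographically smallest optimal subset wins.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, dist
from typing import Sequence

import networkx as nx
import numpy as np

from .graph_core import (
    CLUSTERING_ATOL,
    ClusteringState,
    Node,
    apply_link,
    coordinates,
    ordered_pair,
    pair_score_matrix,
    sorted_nodes,
    validate_graph,
)

Pair = tuple[Node, Node]

#: refuse exhaustive enumeration beyond this many subsets
DEFAULT_SUBSET_BUDGET = 2_000_000


# ---------------------------------------------------------------------------
# candidate sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CandidateSet:
    """Ordered collection of admissible missing links.

    ``provenance`` records how the set was built: ``"all-missing"`` or
    ``"distance-restricted(<threshold> m)"``.
    """

    pairs: tuple[Pair, ...]
    provenance: str = "all-missing"

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def without(self, pair: Pair) -> "CandidateSet":
        pair = ordered_pair(*pair)
        return CandidateSet(
            tuple(p for p in self.pairs if p != pair), self.provenance
        )


def all_missing_links(graph: nx.Graph) -> CandidateSet:
    """All non-adjacent unordered node pairs, in canonical order."""
    validate_graph(graph)
    nodes = sorted_nodes(graph)
    pairs = tuple(
        (u, v) for u, v in combinations(nodes, 2) if not graph.has_edge(u, v)
    )
    return CandidateSet(pairs)


def distance_restricted_links(graph: nx.Graph, max_dist: float = 2500.0) -> CandidateSet:
    """Missing links whose Euclidean endpoint distance is strictly below
    *max_dist* (metres).  All nodes must carry coordinates."""
    coordinates(graph)  # raises if any node lacks x/y
    base = all_missing_links(graph)
    pairs = tuple(
        (u, v)
        for u, v in base.pairs
        if dist(
            (graph.nodes[u]["x"], graph.nodes[u]["y"]),
            (graph.nodes[v]["x"], graph.nodes[v]["y"]),
        )
        < max_dist
    )
    return CandidateSet(pairs, f"distance-restricted({max_dist:g} m)")


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OptimizationResult:
    """Chosen links in insertion order plus the clustering trajectory."""

    links: tuple[Pair, ...]
    clustering_trajectory: tuple[float, ...]
    strategy: str
    seed: int | None = None

    @property
    def final_c(self) -> float:
        return self.clustering_trajectory[-1]

    @property
    def m(self) -> int:
        return len(self.links)


def _trajectory(state: ClusteringState, links: Sequence[Pair]) -> tuple[float, ...]:
    """Commit *links* in order on a copy of *state*; C_G after each."""
    work = state.copy()
    out = []
    for u, v in links:
        apply_link(work, u, v)
        out.append(work.mean_c)
    return tuple(out)


def _check_candidates(state: ClusteringState, candidates: CandidateSet, m: int) -> None:
    if m < 1:
        raise ValueError("m must be at least 1")
    if len(candidates) < m:
        raise ValueError(
            f"candidate set has {len(candidates)} pairs, fewer than m={m}"
        )


def _score_candidates(state: ClusteringState, candidates: CandidateSet) -> np.ndarray:
    """Vector of C_{G+e} over the candidate list, via the all-pairs matrix."""
    score = pair_score_matrix(state)
    idx = np.array(
        [(state.index[u], state.index[v]) for u, v in candidates.pairs]
    )
    return score[idx[:, 0], idx[:, 1]]


# ---------------------------------------------------------------------------
# strategies
# ---------------------------------------------------------------------------

def best_single_link(
    state: ClusteringState, candidates: CandidateSet
) -> tuple[Pair, float, tuple[Pair, ...]]:
    """The single candidate maximising the updated clustering.

    Returns ``(pair, value, all_maximizers)``: the first maximizer in
    candidate order, the maximum C_{G+e}, and every candidate tied with
    it (within the package's clustering tolerance).
    """
    if len(candidates) == 0:
        raise ValueError("candidate set is empty")
    scores = _score_candidates(state, candidates)
    best = float(np.max(scores))
    tied = tuple(
        p for p, s in zip(candidates.pairs, scores) if s >= best - CLUSTERING_ATOL
    )
    return tied[0], best, tied


def greedy(
    state: ClusteringState, candidates: CandidateSet, m: int
) -> OptimizationResult:
    """m rounds of best-single-link, committing each winner.

    Scores are recomputed against the current (already extended) graph
    every round — a committed link raises the common-neighbour count of
    other pairs, so cached scores would go stale.
    """
    _check_candidates(state, candidates, m)
    work = state.copy()
    remaining = candidates
    links: list[Pair] = []
    trajectory: list[float] = []
    for _ in range(m):
        pair, value, _ = best_single_link(work, remaining)
        apply_link(work, *pair)
        remaining = remaining.without(pair)
        links.append(pair)
        trajectory.append(work.mean_c)
    return OptimizationResult(tuple(links), tuple(trajectory), "greedy")


def lazy_greedy(
    state: ClusteringState, candidates: CandidateSet, m: int
) -> OptimizationResult:
    """One scoring pass over the original graph; take the top m.

    The sort is stable with ties broken by candidate order, so the top-1
    link always coincides with :func:`best_single_link`.
    """
    _check_candidates(state, candidates, m)
    scores = _score_candidates(state, candidates)
    order = np.argsort(-scores, kind="stable")[:m]
    links = tuple(candidates.pairs[i] for i in order)
    return OptimizationResult(links, _trajectory(state, links), "lazy_greedy")


def exhaustive_best(
    state: ClusteringState,
    candidates: CandidateSet,
    m: int,
    subset_budget: int = DEFAULT_SUBSET_BUDGET,
) -> OptimizationResult:
    """Complete enumeration over all C(|candidates|, m) subsets.

    Exact but exponential in m; refuses when the subset count exceeds
    *subset_budget* rather than degrading silently.  Ties resolve to the
    lexicographically smallest subset.  The m = 2 case — the scale used
    for optimality audits — runs one vectorised all-pairs scoring per
    committed first link instead of a Python-level double loop.
    """
    _check_candidates(state, candidates, m)
    n_subsets = comb(len(candidates), m)
    if n_subsets > subset_budget:
        raise ValueError(
            f"{n_subsets} subsets exceed the enumeration budget "
            f"{subset_budget}; restrict the candidate set or lower m"
        )
    if m == 1:
        pair, value, _ = best_single_link(state, candidates)
        return OptimizationResult((pair,), (value,), "exhaustive")
    if m == 2:
        links = _exhaustive_pairs(state, candidates)
    else:
        links = _exhaustive_generic(state, candidates, m)
    return OptimizationResult(links, _trajectory(state, links), "exhaustive")


def _exhaustive_pairs(state: ClusteringState, candidates: CandidateSet) -> tuple[Pair, ...]:
    best_value = -np.inf
    best_links: tuple[Pair, ...] | None = None
    pairs = candidates.pairs
    idx = [(state.index[u], state.index[v]) for u, v in pairs]
    for a in range(len(pairs) - 1):
        work = state.copy()
        apply_link(work, *pairs[a])
        score = pair_score_matrix(work)
        rest = np.array(idx[a + 1 :])
        values = score[rest[:, 0], rest[:, 1]]
        b_rel = int(np.argmax(values))  # first maximizer → lexicographic tie-break
        value = float(values[b_rel])
        if value > best_value + CLUSTERING_ATOL:
            best_value = value
            best_links = (pairs[a], pairs[a + 1 + b_rel])
    assert best_links is not None
    return best_links


def _exhaustive_generic(
    state: ClusteringState, candidates: CandidateSet, m: int
) -> tuple[Pair, ...]:
    best_value = -np.inf
    best_links: tuple[Pair, ...] | None = None
    for subset in combinations(candidates.pairs, m):
        work = state.copy()
        for u, v in subset:
            apply_link(work, u, v)
        if work.mean_c > best_value + CLUSTERING_ATOL:
            best_value = work.mean_c
            best_links = subset
    assert best_links is not None
    return best_links


def random_links(
    candidates: CandidateSet,
    m: int,
    seed: int,
    state: ClusteringState | None = None,
) -> OptimizationResult:
    """m distinct candidates sampled uniformly without replacement.

    Reproducible from *seed*.  When *state* is given the clustering
    trajectory of the draw is attached (empty otherwise).
    """
    if m < 1:
        raise ValueError("m must be at least 1")
    if len(candidates) < m:
        raise ValueError(
            f"candidate set has {len(candidates)} pairs, fewer than m={m}"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(candidates), size=m, replace=False)
    links = tuple(candidates.pairs[i] for i in chosen)
    trajectory = _trajectory(state, links) if state is not None else ()
    return OptimizationResult(links, trajectory, "random", seed=seed)
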