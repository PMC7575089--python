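"""Candidate sets and the four link-selection strategies."""

import itertools

import networkx as nx
import numpy as np
import pytest
from scipy import stats

import patchlink as pl
from conftest import random_graph


def brute_force_best(graph, candidates):
    """Independent oracle: rebuild G+e from scratch for every candidate."""
    best = {}
    for u, v in candidates:
        g2 = graph.copy()
        g2.add_edge(u, v)
        best[(u, v)] = pl.graph_clustering(g2)
    return best


# ---------------------------------------------------------------------------
# candidate sets
# ---------------------------------------------------------------------------

def test_all_missing_links_worked_example(example_graph):
    cand = pl.all_missing_links(example_graph)
    assert len(cand) == 8 * 7 // 2 - 10 == 18
    assert all(not example_graph.has_edge(u, v) for u, v in cand)
    assert list(cand.pairs) == sorted(cand.pairs)


def test_all_missing_links_extremes():
    assert len(pl.all_missing_links(nx.complete_graph(6))) == 0
    assert len(pl.all_missing_links(nx.empty_graph(7))) == 21


def _spatial_graph(rng, n=20):
    g = nx.gnm_random_graph(n, 30, seed=int(rng.integers(2**31)))
    for v in g:
        g.nodes[v]["x"] = float(rng.uniform(0, 5000))
        g.nodes[v]["y"] = float(rng.uniform(0, 5000))
    return g


def test_distance_restriction_matches_brute_force_filter():
    rng = np.random.default_rng(3)
    g = _spatial_graph(rng)
    cand = pl.distance_restricted_links(g, 2500.0)
    expected = [
        (u, v)
        for u, v in pl.all_missing_links(g)
        if np.hypot(
            g.nodes[u]["x"] - g.nodes[v]["x"], g.nodes[u]["y"] - g.nodes[v]["y"]
        )
        < 2500.0
    ]
    assert list(cand.pairs) == expected
    assert "2500" in cand.provenance


def test_distance_restriction_unbounded_equals_all_missing():
    rng = np.random.default_rng(4)
    g = _spatial_graph(rng)
    assert (
        pl.distance_restricted_links(g, np.inf).pairs
        == pl.all_missing_links(g).pairs
    )


def test_distance_restriction_boundary_is_strict():
    g = nx.Graph()
    g.add_node("a", x=0.0, y=0.0)
    g.add_node("b", x=2500.0, y=0.0)  # exactly at the cutoff: excluded
    g.add_node("c", x=2499.0, y=0.0)
    cand = pl.distance_restricted_links(g, 2500.0)
    assert ("a", "b") not in cand.pairs
    assert ("a", "c") in cand.pairs


def test_distance_restriction_requires_coordinates(example_graph):
    with pytest.raises(ValueError):
        pl.distance_restricted_links(example_graph, 2500.0)


# ---------------------------------------------------------------------------
# single link
# ---------------------------------------------------------------------------

def test_best_single_link_worked_example(example_state, example_graph):
    pair, value, ties = pl.best_single_link(
        example_state, pl.all_missing_links(example_graph)
    )
    assert value == pytest.approx(0.5, abs=1e-12)
    assert set(ties) == {("u", "v"), ("d", "e")}
    assert pair == ("d", "e")  # first maximizer in candidate order


def test_best_single_link_empty_candidates(example_state):
    with pytest.raises(ValueError):
        pl.best_single_link(example_state, pl.CandidateSet(()))


def test_best_single_link_against_brute_force():
    rng = np.random.default_rng(17)
    for _ in range(25):
        g = random_graph(rng, n_max=25)
        cand = pl.all_missing_links(g)
        if len(cand) == 0:
            continue
        state = pl.ClusteringState.from_graph(g)
        _, value, _ = pl.best_single_link(state, cand)
        oracle = brute_force_best(g, cand)
        assert value == pytest.approx(max(oracle.values()), abs=1e-12)


# ---------------------------------------------------------------------------
# multi-link strategies
# ---------------------------------------------------------------------------

def test_single_round_strategies_agree(example_state, example_graph):
    cand = pl.all_missing_links(example_graph)
    pair, value, _ = pl.best_single_link(example_state, cand)
    for strategy in (pl.greedy, pl.lazy_greedy, pl.exhaustive_best):
        result = strategy(example_state, cand, 1)
        assert result.links == (pair,)
        assert result.final_c == pytest.approx(value, abs=1e-12)


def test_exhaustive_worked_example(example_state, example_graph):
    result = pl.exhaustive_best(example_state, pl.all_missing_links(example_graph), 2)
    assert set(result.links) == {("b", "e"), ("d", "e")}
    assert result.final_c == pytest.approx(0.625, abs=1e-12)


def test_exhaustive_all_candidates_completes_graph(example_state, example_graph):
    cand = pl.all_missing_links(example_graph)
    result = pl.exhaustive_best(example_state, cand, len(cand))
    assert result.final_c == pytest.approx(1.0, abs=1e-12)


def test_exhaustive_budget_guard(example_state, example_graph):
    with pytest.raises(ValueError, match="budget"):
        pl.exhaustive_best(
            example_state, pl.all_missing_links(example_graph), 2, subset_budget=10
        )


def test_exhaustive_pair_path_matches_generic_enumeration():
    """The vectorised m=2 enumeration equals naive subset enumeration."""
    rng = np.random.default_rng(29)
    for _ in range(10):
        g = random_graph(rng, n_max=12, density_range=(0.2, 0.6))
        cand = pl.all_missing_links(g)
        if len(cand) < 2:
            continue
        state = pl.ClusteringState.from_graph(g)
        fast = pl.exhaustive_best(state, cand, 2)
        best = -1.0
        for e1, e2 in itertools.combinations(cand.pairs, 2):
            g2 = g.copy()
            g2.add_edges_from([e1, e2])
            best = max(best, pl.graph_clustering(g2))
        assert fast.final_c == pytest.approx(best, abs=1e-12)


def test_greedy_trajectory_and_candidate_consumption(example_state, example_graph):
    cand = pl.all_missing_links(example_graph)
    result = pl.greedy(example_state, cand, 2)
    assert len(result.clustering_trajectory) == 2
    assert result.final_c == result.clustering_trajectory[-1]
    assert len(set(result.links)) == 2
    # on this instance greedy reaches the exhaustive optimum
    assert result.final_c == pytest.approx(0.625, abs=1e-12)


def test_greedy_can_be_non_optimal():
    """There exist graphs where greedy's m=2 result is strictly below the
    exhaustive optimum (found by seeded randomized search)."""
    rng = np.random.default_rng(1234)
    for _ in range(400):
        g = random_graph(rng, n_max=12, density_range=(0.1, 0.5))
        cand = pl.all_missing_links(g)
        if len(cand) < 2:
            continue
        state = pl.ClusteringState.from_graph(g)
        gr = pl.greedy(state, cand, 2).final_c
        opt = pl.exhaustive_best(state, cand, 2).final_c
        if gr < opt - 1e-9:
            return
    pytest.fail("no witness of greedy non-optimality found")


def test_lazy_greedy_worked_example(example_state, example_graph):
    cand = pl.all_missing_links(example_graph)
    result = pl.lazy_greedy(example_state, cand, 2)
    # the two top-scored single links, committed in score order
    scores = {p: pl.updated_graph_clustering(example_state, *p) for p in cand}
    top2 = sorted(cand.pairs, key=lambda p: (-scores[p], cand.pairs.index(p)))[:2]
    assert list(result.links) == top2
    assert result.final_c <= 0.625 + 1e-12


def test_heuristics_never_beat_exhaustive():
    rng = np.random.default_rng(31)
    for _ in range(25):
        g = random_graph(rng, n_max=16, density_range=(0.05, 0.3))
        cand = pl.all_missing_links(g)
        if len(cand) < 2:
            continue
        state = pl.ClusteringState.from_graph(g)
        opt = pl.exhaustive_best(state, cand, 2).final_c
        assert pl.greedy(state, cand, 2).final_c <= opt + 1e-12
        assert pl.lazy_greedy(state, cand, 2).final_c <= opt + 1e-12


def test_final_c_matches_rebuilt_graph():
    """No stale-cache drift: every strategy's final_C equals the clustering
    of the graph rebuilt with the returned links."""
    rng = np.random.default_rng(37)
    g = random_graph(rng, n_max=30, density_range=(0.05, 0.3))
    cand = pl.all_missing_links(g)
    state = pl.ClusteringState.from_graph(g)
    results = [
        pl.greedy(state, cand, 3),
        pl.lazy_greedy(state, cand, 3),
        pl.exhaustive_best(state, cand, 2),
        pl.random_links(cand, 3, seed=9, state=state),
    ]
    for result in results:
        g2 = g.copy()
        g2.add_edges_from(result.links)
        assert result.final_c == pytest.approx(pl.graph_clustering(g2), abs=1e-12)


# ---------------------------------------------------------------------------
# random baseline
# ---------------------------------------------------------------------------

def test_random_links_deterministic(example_graph):
    cand = pl.all_missing_links(example_graph)
    a = pl.random_links(cand, 4, seed=99)
    b = pl.random_links(cand, 4, seed=99)
    assert a.links == b.links
    assert a.seed == 99


def test_random_links_all_candidates(example_graph):
    cand = pl.all_missing_links(example_graph)
    result = pl.random_links(cand, len(cand), seed=1)
    assert set(result.links) == set(cand.pairs)


def test_random_links_insufficient_candidates(example_graph):
    cand = pl.all_missing_links(example_graph)
    with pytest.raises(ValueError):
        pl.random_links(cand, len(cand) + 1, seed=1)


def test_random_links_uniform_selection(example_graph):
    """Selection frequencies over 10,000 single-link draws from the 18
    candidates are consistent with the uniform distribution."""
    cand = pl.all_missing_links(example_graph)
    counts = {p: 0 for p in cand.pairs}
    rng = np.random.default_rng(55)
    n_draws = 10_000
    for _ in range(n_draws):
        (link,) = pl.random_links(cand, 1, seed=int(rng.integers(2**31))).links
        counts[link] += 1
    chi2 = stats.chisquare(list(counts.values()))
    assert chi2.pvalue > 1e-4
    expected = n_draws / len(cand)
    se = np.sqrt(expected * (1 - 1 / len(cand)))
    assert all(abs(c - expected) < 3.9 * se for c in counts.values())
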