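"""Metapopulation robustness under random habitat loss.

A habitat network's robustness is probed by removing a fraction of its
patches at random, running a stochastic patch-occupancy model (SPOM) on
the surviving network until quasi-stationarity, and recording the mean
fraction of occupied (colonised) patches.  Sweeping the loss fraction
over [0, 1] yields a robustness curve; its area under the curve (AUC)
is the scalar robustness measure.  Comparing AUC before and after link
addition quantifies how much a restoration strategy buys.

The SPOM is a synchronous two-phase process on patch-occupancy states,
started from all patches occupied:

* extinction phase — an occupied patch goes locally extinct with
  probability ``max(0, e − rescue · k)`` where ``k`` is its number of
  occupied neighbours (the rescue effect: immigration from occupied
  neighbouring patches lowers extinction risk);
* colonisation phase — an empty patch is recolonised with probability
  ``1 − (1 − c)^k``, each occupied neighbour providing an independent
  colonisation chance ``c``.

Stationarity is operationalised as a fixed burn-in followed by a
time-averaging window, for determinism.  Occupancy is the fraction of
*surviving* patches occupied.  All randomness is driven by per-patch,
per-step uniform draws indexed independently of the link structure, so
running baseline and augmented networks from the same seed yields a
monotone coupling: adding links can only increase occupancy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .graph_core import ClusteringState, sorted_nodes, validate_graph
from .optimizers import (
    CandidateSet,
    OptimizationResult,
    distance_restricted_links,
    greedy,
    lazy_greedy,
    random_links,
)

logger = logging.getLogger(__name__)

DEFAULT_LOSS_GRID = tuple(np.round(np.arange(0.0, 1.01, 0.1), 10))


@dataclass(frozen=True)
class SPOMParams:
    """Parameters of the extinction–recolonisation dynamics.

    ``extinction_risk`` (e): baseline per-step local-extinction
    probability of an occupied patch.  ``rescue_strength``: reduction of
    e per occupied neighbour.  ``colonization_prob`` (c): per-occupied-
    neighbour recolonisation probability of an empty patch.  Times are
    in steps (one step = one extinction plus one colonisation phase).
    """

    extinction_risk: float = 0.2
    rescue_strength: float = 0.02
    colonization_prob: float = 0.3
    burn_in: int = 200
    window: int = 100
    replicates: int = 50
    #: report occupancy relative to "surviving" patches (default) or to the
    #: "original" patch count of the intact network
    occupancy_basis: str = "surviving"

    def __post_init__(self):
        if self.occupancy_basis not in ("surviving", "original"):
            raise ValueError("occupancy_basis must be 'surviving' or 'original'")
        if not 0.0 <= self.extinction_risk <= 1.0:
            raise ValueError("extinction_risk must be in [0, 1]")
        if not 0.0 <= self.colonization_prob <= 1.0:
            raise ValueError("colonization_prob must be in [0, 1]")
        if self.rescue_strength < 0:
            raise ValueError("rescue_strength must be non-negative")
        if min(self.burn_in, self.window, self.replicates) < 1:
            raise ValueError("burn_in, window and replicates must be >= 1")


@dataclass(frozen=True)
class RobustnessCurve:
    """Occupancy as a function of the fraction of lost patches."""

    loss_fractions: tuple[float, ...]
    occupancy: tuple[float, ...]
    dispersion: tuple[float, ...]  # standard error per point
    auc: float


# ---------------------------------------------------------------------------
# habitat loss
# ---------------------------------------------------------------------------

def remove_random_patches(graph: nx.Graph, fraction: float, seed: int) -> nx.Graph:
    """Remove round(fraction · n) uniformly chosen patches (and their links)."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("loss fraction must be in [0, 1]")
    validate_graph(graph)
    nodes = sorted_nodes(graph)
    n_remove = int(np.floor(fraction * len(nodes) + 0.5))  # round half up
    rng = np.random.default_rng(seed)
    doomed = rng.choice(len(nodes), size=n_remove, replace=False)
    out = graph.copy()
    out.remove_nodes_from(nodes[i] for i in doomed)
    return out


# ---------------------------------------------------------------------------
# occupancy dynamics
# ---------------------------------------------------------------------------

def stationary_occupancy(graph: nx.Graph, params: SPOMParams, seed: int) -> float:
    """Mean occupied fraction at quasi-stationarity, from all-occupied.

    Averaged over ``params.window`` post-burn-in steps and
    ``params.replicates`` independent replicates.  An empty graph has
    occupancy 0 by convention.
    """
    n = graph.number_of_nodes()
    if n == 0:
        return 0.0
    adj = nx.to_numpy_array(graph, nodelist=sorted_nodes(graph))
    e = params.extinction_risk
    rescue = params.rescue_strength
    log_miss = np.log1p(-params.colonization_prob) if params.colonization_prob < 1 else -np.inf
    steps = params.burn_in + params.window
    rng = np.random.default_rng(seed)
    totals = []
    for _ in range(params.replicates):
        u_ext = rng.random((steps, n))
        u_col = rng.random((steps, n))
        occ = np.ones(n, dtype=bool)
        acc = 0.0
        for t in range(steps):
            k = adj @ occ
            e_eff = np.clip(e - rescue * k, 0.0, 1.0)
            occ = occ & (u_ext[t] >= e_eff)
            k2 = adj @ occ
            # P(recolonised) = 1 - (1-c)^k2, monotone in k2
            p_col = 1.0 - np.exp(k2 * log_miss) if np.isfinite(log_miss) else (k2 > 0).astype(float)
            occ = occ | (~occ & (u_col[t] < p_col))
            if t >= params.burn_in:
                acc += occ.mean()
        totals.append(acc / params.window)
    return float(np.mean(totals))


# ---------------------------------------------------------------------------
# robustness curves
# ---------------------------------------------------------------------------

def robustness_curve(
    graph: nx.Graph,
    params: SPOMParams,
    loss_grid: Sequence[float] = DEFAULT_LOSS_GRID,
    seed: int = 0,
    removal_replicates: int = 10,
) -> RobustnessCurve:
    """Occupancy under increasing habitat loss, with AUC.

    For each loss fraction, *removal_replicates* independent removals
    are each followed by the full occupancy simulation; the point value
    is their mean.  Sub-seeds depend only on (seed, grid position,
    replicate), never on the graph, preserving the coupled-comparison
    property between a baseline network and an augmented one.
    """
    loss = np.asarray(loss_grid, dtype=float)
    if len(loss) < 1 or np.any(np.diff(loss) <= 0):
        raise ValueError("loss_grid must be strictly increasing")
    if loss[0] < 0 or loss[-1] > 1:
        raise ValueError("loss_grid must lie within [0, 1]")
    seed_rng = np.random.default_rng(seed)
    sub_seeds = seed_rng.integers(0, 2**31 - 1, size=(len(loss), removal_replicates, 2))
    occupancy, dispersion = [], []
    for li, frac in enumerate(loss):
        vals = []
        for ri in range(removal_replicates):
            rm_seed, dyn_seed = (int(s) for s in sub_seeds[li, ri])
            remaining = remove_random_patches(graph, float(frac), rm_seed)
            occ = stationary_occupancy(remaining, params, dyn_seed)
            if params.occupancy_basis == "original" and graph.number_of_nodes():
                occ *= remaining.number_of_nodes() / graph.number_of_nodes()
            vals.append(occ)
        occupancy.append(float(np.mean(vals)))
        dispersion.append(float(np.std(vals, ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0)
    curve = RobustnessCurve(
        tuple(float(f) for f in loss), tuple(occupancy), tuple(dispersion), auc=np.nan
    )
    return replace(curve, auc=auc(curve))


def auc(curve: RobustnessCurve) -> float:
    """Trapezoidal area under the robustness curve over loss ∈ [0, 1].

    The curve is extended to the boundaries with its end-point values
    (constant extension, no extrapolation).
    """
    loss = list(curve.loss_fractions)
    occ = list(curve.occupancy)
    if len(loss) < 2:
        raise ValueError("AUC needs at least two curve points")
    if loss[0] > 0.0:
        loss.insert(0, 0.0)
        occ.insert(0, occ[0])
    if loss[-1] < 1.0:
        loss.append(1.0)
        occ.append(occ[-1])
    return float(np.trapezoid(occ, loss))


# ---------------------------------------------------------------------------
# strategy comparison
# ---------------------------------------------------------------------------

def compare_strategies(
    graph: nx.Graph,
    params: SPOMParams,
    m_values: Iterable[int] = (5, 10, 15, 20, 25, 30),
    strategies: Iterable[str] = ("greedy", "lazy_greedy", "random"),
    seed: int = 0,
    max_dist: float = 2500.0,
    loss_grid: Sequence[float] = DEFAULT_LOSS_GRID,
    removal_replicates: int = 10,
) -> pd.DataFrame:
    """ΔAUC of each (strategy, m) against the unmodified baseline.

    Candidate links are restricted to patch pairs closer than *max_dist*
    (Euclidean, metres).  The robustness simulation of every augmented
    network reuses the baseline's seeds, so ΔAUC is a coupled
    comparison.  Rows whose m exceeds the candidate count are skipped
    (and logged).
    """
    candidates = distance_restricted_links(graph, max_dist)
    state = ClusteringState.from_graph(graph)
    master = np.random.default_rng(seed)
    rob_seed = int(master.integers(0, 2**31 - 1))
    baseline = robustness_curve(
        graph, params, loss_grid, rob_seed, removal_replicates
    )
    records = []
    for strategy in strategies:
        for m in m_values:
            draw_seed = int(master.integers(0, 2**31 - 1))
            if len(candidates) < m:
                logger.warning(
                    "skipping %s m=%d: only %d candidate links",
                    strategy, m, len(candidates),
                )
                continue
            result = _run_strategy(state, candidates, strategy, m, draw_seed)
            augmented = graph.copy()
            augmented.add_edges_from(result.links)
            after = robustness_curve(
                augmented, params, loss_grid, rob_seed, removal_replicates
            )
            records.append(
                {
                    "strategy": strategy,
                    "m": m,
                    "auc_baseline": baseline.auc,
                    "auc_after": after.auc,
                    "delta_auc": after.auc - baseline.auc,
                    "seed": draw_seed if strategy == "random" else rob_seed,
                }
            )
    return pd.DataFrame.from_records(
        records, columns=["strategy", "m", "auc_baseline", "auc_after", "delta_auc", "seed"]
    )


def _run_strategy(
    state: ClusteringState,
    candidates: CandidateSet,
    strategy: str,
    m: int,
    seed: int,
) -> OptimizationResult:
    if strategy == "greedy":
        return greedy(state, candidates, m)
    if strategy in ("lazy_greedy", "lazy"):
        return lazy_greedy(state, candidates, m)
    if strategy == "random":
        return random_links(candidates, m, seed, state)
    raise ValueError(f"unknown strategy {strategy!r}")
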