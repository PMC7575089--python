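"""Network ensembles: standard graphs and synthetic landscape habitat networks.

Two kinds of test-bed networks are produced.

**Standard networks** (random, regular, small-world) come straight from
networkx generators, in a sparse regime (~4% of possible links, the
density typical of habitat networks) and a dense regime (~75%), with
node counts in [50, 111].

**Landscape-based habitat networks** emulate stream-dwelling habitat in
a 10 km × 10 km landscape tile rasterised at 25 m: a mosaic of open
agricultural land, forestry and urban area with per-cell traversal costs
(50 / 150 / 500), a synthetic tree-like stream skeleton grown on the
grid, habitat patches placed on 10% of the stream cells under one of
three spatial allocation regimes (random, clustered, contiguous), and
links created between patch pairs whose least-cost path over the
cost raster stays below a maximum dispersal cost (900 / 650 / 400
respectively — thresholds chosen per regime so the three ensembles have
comparable link counts).  Grid movement is 8-connected; an orthogonal
step costs the mean of the two cell costs, a diagonal step √2 times
that mean.  Nodes carry metric coordinates (cell centres).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

from .graph_core import validate_graph

Family = Literal["random", "regular", "small_world"]
Regime = Literal["sparse", "dense"]
Allocation = Literal["random", "clustered", "contiguous"]

#: target link densities per regime
REGIME_DENSITY: dict[str, float] = {"sparse": 0.04, "dense": 0.75}

#: maximum dispersal cost per allocation regime
DEFAULT_MAX_COST: dict[str, float] = {
    "random": 900.0,
    "clustered": 650.0,
    "contiguous": 400.0,
}

#: fraction of patches placed uniformly (the rest grow around them)
SEED_FRACTION: dict[str, float] = {"clustered": 0.5, "contiguous": 0.2}

#: acceptable habitat-patch counts; generation retries outside this window
PATCH_COUNT_RANGE = (54, 111)


# ---------------------------------------------------------------------------
# standard networks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StandardNetworkConfig:
    family: Family = "random"
    regime: Regime = "sparse"
    n: int = 60
    rewiring_prob: float = 0.1  # small-world only
    seed: int = 0

    @property
    def density(self) -> float:
        return REGIME_DENSITY[self.regime]


def generate_standard(config: StandardNetworkConfig) -> nx.Graph:
    """A simple graph of the requested family, size and density regime."""
    n, d = config.n, config.density
    if not 1 <= n:
        raise ValueError("n must be positive")
    if config.family == "random":
        m = round(d * n * (n - 1) / 2)
        graph = nx.gnm_random_graph(n, m, seed=config.seed)
    elif config.family == "regular":
        k = max(1, round(d * (n - 1)))
        if (n * k) % 2:  # a k-regular graph needs n·k even
            k += 1
        if k >= n:
            raise ValueError(f"regular degree {k} infeasible for n={n}")
        graph = nx.random_regular_graph(k, n, seed=config.seed)
    elif config.family == "small_world":
        k = max(2, 2 * round(d * (n - 1) / 2))  # ring degree, even
        if k >= n:
            raise ValueError(f"ring degree {k} infeasible for n={n}")
        graph = nx.watts_strogatz_graph(n, k, config.rewiring_prob, seed=config.seed)
    else:
        raise ValueError(f"unknown family {config.family!r}")
    return validate_graph(graph)


# ---------------------------------------------------------------------------
# landscape rasters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LandscapeConfig:
    tile_size_m: float = 10_000.0
    cell_size_m: float = 25.0
    # per-cell traversal costs by land-use class
    cost_open: float = 50.0
    cost_forest: float = 150.0
    cost_urban: float = 500.0
    # land-use mixture (fractions of tile area)
    mix: tuple[float, float, float] = (0.7, 0.2, 0.1)
    n_landuse_seeds: int = 60
    # stream skeleton: cell-count window chosen so that 10% of stream
    # cells lands inside PATCH_COUNT_RANGE
    stream_cells_range: tuple[int, int] = (560, 1080)
    habitat_fraction: float = 0.10
    allocation: Allocation = "random"
    cluster_radius_m: float = 1000.0
    max_cost: float | None = None  # default depends on allocation
    seed: int = 0

    @property
    def grid_shape(self) -> tuple[int, int]:
        n = int(round(self.tile_size_m / self.cell_size_m))
        return (n, n)

    @property
    def effective_max_cost(self) -> float:
        if self.max_cost is not None:
            return self.max_cost
        return DEFAULT_MAX_COST[self.allocation]


@dataclass(frozen=True)
class CostRaster:
    """Per-cell traversal costs plus the stream-cell mask."""

    costs: np.ndarray
    stream_mask: np.ndarray
    cell_size_m: float

    def __post_init__(self):
        if not np.all(self.costs > 0):
            raise ValueError("all traversal costs must be strictly positive")


def _grow_stream(rng: np.random.Generator, shape: tuple[int, int], target: int) -> np.ndarray:
    """Grow a connected, tree-like, 8-connected stream skeleton.

    A main stem marches across the whole tile with lateral jitter
    (drainage-like), and tributaries branch off existing stream cells,
    marching in a perpendicular-ish direction with jitter.  Every new
    cell is 8-adjacent to the previous one and every branch starts on an
    existing cell, so the skeleton spans the tile and stays connected.
    """
    rows, cols = shape
    mask = np.zeros(shape, dtype=bool)
    cells: list[tuple[int, int]] = []

    def march(r: int, c: int, axis: int, direction: int, length: int) -> None:
        for _ in range(length):
            if axis == 1:
                c += direction
                r += int(rng.integers(-1, 2))
            else:
                r += direction
                c += int(rng.integers(-1, 2))
            if not (0 <= r < rows and 0 <= c < cols):
                return  # branch leaves the tile and ends
            if not mask[r, c]:
                mask[r, c] = True
                cells.append((r, c))

    r0 = int(rng.integers(rows // 4, 3 * rows // 4))
    mask[r0, 0] = True
    cells.append((r0, 0))
    march(r0, 0, axis=1, direction=1, length=cols - 1)  # west → east stem
    while np.count_nonzero(mask) < target:
        base = cells[int(rng.integers(len(cells)))]
        axis = 0 if rng.random() < 0.7 else 1
        direction = 1 if rng.random() < 0.5 else -1
        length = int(rng.integers(20, 80))
        march(base[0], base[1], axis, direction, length)
    return mask


def synthesize_cost_raster(config: LandscapeConfig) -> CostRaster:
    """Voronoi land-use mosaic plus a synthetic stream skeleton."""
    rng = np.random.default_rng(config.seed)
    rows, cols = config.grid_shape
    seeds = rng.uniform(0, [rows, cols], size=(config.n_landuse_seeds, 2))
    classes = rng.choice(3, size=config.n_landuse_seeds, p=np.asarray(config.mix))
    rr, cc = np.mgrid[0:rows, 0:cols]
    cell_centres = np.column_stack([rr.ravel() + 0.5, cc.ravel() + 0.5])
    _, nearest = cKDTree(seeds).query(cell_centres)
    class_grid = classes[nearest].reshape(rows, cols)
    cost_by_class = np.array([config.cost_open, config.cost_forest, config.cost_urban])
    costs = cost_by_class[class_grid]
    target = int(rng.integers(config.stream_cells_range[0], config.stream_cells_range[1] + 1))
    stream = _grow_stream(rng, (rows, cols), target)
    return CostRaster(costs, stream, config.cell_size_m)


# ---------------------------------------------------------------------------
# habitat patches
# ---------------------------------------------------------------------------

def allocate_patches(
    raster: CostRaster, config: LandscapeConfig, rng: np.random.Generator | None = None
) -> list[tuple[int, int]]:
    """Place habitat patches on 10% of the stream cells.

    ``random``: uniform over stream cells.  ``clustered`` /
    ``contiguous``: a seed fraction (0.5 / 0.2) is placed uniformly and
    the remainder grows uniformly among stream cells within
    ``cluster_radius_m`` of an already-placed patch, so the contiguous
    regime strings most of its patches along short stream stretches.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    stream_cells = np.argwhere(raster.stream_mask)  # row-major, deterministic
    n_stream = len(stream_cells)
    if n_stream == 0:
        raise ValueError("stream mask is empty")
    n_patches = int(round(config.habitat_fraction * n_stream))
    if n_patches > n_stream:
        raise ValueError("more patches requested than stream cells")
    if config.allocation == "random":
        chosen = rng.choice(n_stream, size=n_patches, replace=False)
        return [tuple(stream_cells[i]) for i in sorted(chosen)]
    seed_frac = SEED_FRACTION[config.allocation]
    n_seed = max(1, int(round(seed_frac * n_patches)))
    radius_cells = config.cluster_radius_m / raster.cell_size_m
    tree = cKDTree(stream_cells)
    selected = list(rng.choice(n_stream, size=min(n_seed, n_patches), replace=False))
    selected_set = set(selected)
    while len(selected) < n_patches:
        pool: set[int] = set()
        for i in selected:
            pool.update(tree.query_ball_point(stream_cells[i], radius_cells))
        pool -= selected_set
        if not pool:  # cluster saturated: fall back to a fresh uniform seed
            pool = set(range(n_stream)) - selected_set
        pick = int(rng.choice(sorted(pool)))
        selected.append(pick)
        selected_set.add(pick)
    return [tuple(stream_cells[i]) for i in sorted(selected_set)]


# ---------------------------------------------------------------------------
# least-cost-path links
# ---------------------------------------------------------------------------

def _grid_graph(costs: np.ndarray) -> sparse.csr_matrix:
    """8-connected grid graph; step weight = mean of the two cell costs,
    times √2 for diagonal steps."""
    rows, cols = costs.shape
    idx = np.arange(rows * cols).reshape(rows, cols)
    src, dst, wgt = [], [], []
    for dr, dc, diag in ((0, 1, False), (1, 0, False), (1, 1, True), (1, -1, True)):
        r0 = slice(0, rows - dr)
        r1 = slice(dr, rows)
        if dc >= 0:
            c0, c1 = slice(0, cols - dc), slice(dc, cols)
        else:
            c0, c1 = slice(-dc, cols), slice(0, cols + dc)
        a = idx[r0, c0].ravel()
        b = idx[r1, c1].ravel()
        w = 0.5 * (costs[r0, c0].ravel() + costs[r1, c1].ravel())
        if diag:
            w = w * np.sqrt(2.0)
        src.append(a)
        dst.append(b)
        wgt.append(w)
    src, dst, wgt = np.concatenate(src), np.concatenate(dst), np.concatenate(wgt)
    return sparse.csr_matrix(
        (wgt, (src, dst)), shape=(rows * cols, rows * cols)
    )


def least_cost_costs(
    raster: CostRaster,
    patches: Sequence[tuple[int, int]],
    limit: float = np.inf,
) -> np.ndarray:
    """Pairwise minimal cumulative traversal costs between patches.

    Costs beyond *limit* are reported as inf (and the search is pruned
    there, which keeps the per-patch Dijkstra local).
    """
    rows, cols = raster.costs.shape
    grid = _grid_graph(raster.costs)
    ids = np.array([r * cols + c for r, c in patches])
    dist = dijkstra(grid, directed=False, indices=ids, limit=limit)
    return dist[:, ids]


def least_cost_links(
    raster: CostRaster,
    patches: Sequence[tuple[int, int]],
    max_cost: float,
) -> nx.Graph:
    """Habitat network: patches linked iff least-cost path < max_cost."""
    if max_cost < 0:
        raise ValueError("max_cost must be non-negative")
    cost = least_cost_costs(raster, patches, limit=max_cost)
    graph = nx.Graph()
    width = max(3, len(str(len(patches))))
    labels = [f"p{i:0{width}d}" for i in range(len(patches))]
    for label, (r, c) in zip(labels, patches):
        graph.add_node(
            label,
            x=(c + 0.5) * raster.cell_size_m,
            y=(r + 0.5) * raster.cell_size_m,
        )
    for i in range(len(patches)):
        for j in range(i + 1, len(patches)):
            if cost[i, j] < max_cost:  # strict, per the dispersal-cost cutoff
                graph.add_edge(labels[i], labels[j])
    return graph


def generate_landscape(config: LandscapeConfig, max_attempts: int = 20) -> nx.Graph:
    """Full landscape pipeline: raster → patches → least-cost links.

    Retries with fresh sub-seeds until the patch count falls inside
    ``PATCH_COUNT_RANGE``.
    """
    lo, hi = PATCH_COUNT_RANGE
    master = np.random.default_rng(config.seed)
    attempts = []
    for _ in range(max_attempts):
        sub_seed = int(master.integers(0, 2**31 - 1))
        sub = _with_seed(config, sub_seed)
        raster = synthesize_cost_raster(sub)
        rng = np.random.default_rng(sub_seed + 1)
        patches = allocate_patches(raster, sub, rng)
        attempts.append(len(patches))
        if lo <= len(patches) <= hi:
            graph = least_cost_links(raster, patches, sub.effective_max_cost)
            return validate_graph(graph)
    raise RuntimeError(
        f"could not reach a patch count in [{lo}, {hi}] after "
        f"{max_attempts} attempts (got {attempts})"
    )


def _with_seed(config: LandscapeConfig, seed: int) -> LandscapeConfig:
    from dataclasses import replace

    return replace(config, seed=seed)


# ---------------------------------------------------------------------------
# ensembles
# ---------------------------------------------------------------------------

def generate_ensemble(
    config: StandardNetworkConfig | LandscapeConfig,
    count: int,
    base_seed: int,
    n_range: tuple[int, int] | None = None,
) -> tuple[list[nx.Graph], pd.DataFrame]:
    """*count* independent replicates with recorded per-replicate seeds.

    For standard networks a node count may be drawn uniformly from
    *n_range* per replicate (the habitat-network size window [50, 111]
    being the natural choice); landscape replicates vary only by seed.
    Returns the graphs and a manifest (replicate, seed, n, links,
    density).
    """
    if count < 1:
        raise ValueError("count must be at least 1")
    from dataclasses import replace

    rng = np.random.default_rng(base_seed)
    seeds = rng.integers(0, 2**31 - 1, size=count)
    graphs, records = [], []
    for rep, seed in enumerate(seeds):
        seed = int(seed)
        if isinstance(config, StandardNetworkConfig):
            n = config.n
            if n_range is not None:
                n = int(rng.integers(n_range[0], n_range[1] + 1))
            graph = generate_standard(replace(config, n=n, seed=seed))
        else:
            graph = generate_landscape(replace(config, seed=seed))
        n = graph.number_of_nodes()
        links = graph.number_of_edges()
        graphs.append(graph)
        records.append(
            {
                "replicate": rep,
                "seed": seed,
                "n": n,
                "links": links,
                "density": links / (n * (n - 1) / 2) if n > 1 else 0.0,
            }
        )
    return graphs, pd.DataFrame.from_records(records)
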