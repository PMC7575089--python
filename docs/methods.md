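# Methods

This note records the models implemented in `patchlink`, the parameter
choices that matter, and what the synthetic test beds do and do not
establish about real habitat networks.

## Clustering coefficient and the single-link update

All clustering quantities use the Watts–Strogatz definition: the local
coefficient C(v) = 2T(v)/(d_v(d_v−1)) (0 for degree ≤ 1) and the graph
coefficient C_G as the unweighted mean over all n nodes, including
isolated ones. Global transitivity (the triangle/triplet ratio) is a
different statistic and is deliberately not provided.

Adding one missing link (u, v) with k common neighbours changes the
clustering of u, v and of each common neighbour only. The update

    C_{G+uv} = C_G + (ΔC(u) + ΔC(v) + Σ_{w∈N(u,v)} 2/(d_w(d_w−1))) / n

uses ΔC(u) = (2k(d_u−1) − 4T(u))/(d_u(d_u²−1)) for d_u > 1. For the
degenerate degrees we use the *recomputation-exact* values: ΔC(u) = k
when d_u = 1 (after the insertion u has two neighbours, whose
neighbourhood is complete iff they are linked, i.e. iff k = 1) and
ΔC(u) = 0 when d_u = 0 (a degree-1 node has C = 0 both before and
after). A simpler convention that assigns ΔC(u) = 1 unconditionally at
d_u = 1 is only correct when k = 1; the recomputation-exact choice is
forced by the invariant we test everywhere: the incremental update must
equal a from-scratch rebuild to within 1e-12 on arbitrary graphs.

Triangle counting is by adjacency intersection (effectively one boolean
matrix product), not fast matrix multiplication — ample at the package's
target scales (n ≤ a few hundred). `ClusteringState` caches degrees,
triangle counts, local coefficients and the boolean adjacency matrix;
`apply_link` maintains all of them exactly under insertion.

### Vectorised candidate scoring

`pair_score_matrix` evaluates C_{G+ij} for *every* missing pair at once:
one matrix product gives all common-neighbour counts k[i,j], a second
gives every pair's Σ 2/(d_w(d_w−1)) term, and the per-endpoint ΔC terms
broadcast. This is what makes complete enumeration of all two-link
subsets affordable (cost proportional to the candidate count, one
vectorised scoring pass per committed first link) and it is
cross-checked against the scalar single-pair update and against
from-scratch recomputation in the tests.

## Optimizers and tie-breaking

Candidates are either all non-adjacent pairs or, for spatial networks,
the pairs strictly closer than a Euclidean cutoff (default 2500 m — a
species' maximum dispersal distance over ideal terrain; the boundary is
exclusive). Candidate order is the canonical lexicographic order of
ordered label pairs, and every tie anywhere resolves to the first
maximizer in that order; single-link search additionally reports the
full tied set. Exhaustive search returns the lexicographically smallest
optimal subset and refuses beyond a subset budget (default 2·10⁶
subsets) rather than degrading silently; callers that use the
vectorised m = 2 path (whose cost does not grow with the subset count)
raise the budget explicitly.

Greedy re-scores candidates against the current graph every round,
because a committed link raises the common-neighbour count of other
pairs; Lazy Greedy deliberately skips that re-scoring (one pass, stable
sort, top m) and is the faster but weaker heuristic. Neither carries an
approximation guarantee; the test suite instead demonstrates a concrete
witness instance (found by seeded randomised search over small sparse
graphs) where greedy is strictly suboptimal at m = 2.

Random insertion uses one `numpy` generator per invocation, seeded
explicitly and recorded in the result.

## Network ensembles

**Standard networks** come from networkx: G(n, M) random graphs, random
regular graphs and Watts–Strogatz small-world graphs (rewiring
probability 0.1), with node counts drawn from [50, 111] and link
density targeted at 4% (sparse) or 75% (dense) of possible links —
regular and ring degrees round to the nearest feasible parity, so
realised sparse densities sit slightly below 4% for small n.

**Landscape-based habitat networks** emulate stream-dwelling habitat in
a 10 km × 10 km tile rasterised at 25 m (400 × 400 cells):

* a land-use mosaic of open agricultural (cost 50 per cell), forestry
  (150) and urban (500) cells, generated as a nearest-seed (Voronoi)
  tessellation of 60 class-labelled seed points with area mixture
  0.7 / 0.2 / 0.1. Only the open-land cost is externally anchored; the
  forest and urban costs encode the ordering "open < forest < urban"
  and are configurable;
* a connected, tree-like stream skeleton: a main stem marching across
  the tile with lateral jitter plus jittered tributaries branching off
  existing stream cells, grown to a target of 560–1080 cells so that
  10% of stream cells yields 54–111 habitat patches (the window is also
  enforced by retry);
* habitat patches on 10% of stream cells: uniformly (random
  allocation), or with a seed fraction placed uniformly and the rest
  grown within 1000 m of already-placed patches (seed fraction 0.5 for
  clustered, 0.2 for contiguous — the smaller the seed fraction, the
  more contiguous the arrangement);
* links between patch pairs whose least-cost path over the 8-connected
  cost grid stays strictly below a maximum dispersal cost: 900 (random
  allocation), 650 (clustered), 400 (contiguous), thresholds per regime
  so the three ensembles have comparable link counts. An orthogonal
  step costs the mean of the two cell costs; a diagonal step √2 times
  that mean. Shortest paths are Dijkstra searches pruned at the cost
  threshold.

These synthetic tiles reproduce the *structural* regime of real
stream-based habitat networks — patch counts, ~2–6% link densities,
spatially clustered links, metric coordinates — but not any particular
real landscape: stream geometry, land-use autocorrelation and patch
quality are all idealised. Ensemble results on them support qualitative
statements (orderings, signs, trends), not quantitative predictions for
a specific landscape.

## Robustness simulation

Habitat loss removes ⌊fraction·n + 1/2⌋ patches uniformly at random
with all incident links. On the survivors a stochastic patch-occupancy
model (SPOM) runs from all-occupied in synchronous two-phase steps:

* extinction: an occupied patch goes extinct with probability
  max(0, e − rescue·k), k = occupied neighbours (rescue effect);
* colonisation: an empty patch is recolonised with probability
  1 − (1−c)^k, each occupied neighbour an independent chance c.

Defaults: e = 0.2, rescue = 0.02, c = 0.3 per step, burn-in 200 steps,
averaging window 100 steps, 50 replicates. Stationarity is
operationalised as burn-in + window averaging (not a convergence test)
for determinism. Occupancy is reported relative to surviving patches
(an `occupancy_basis="original"` alternative rescales by the survivor
fraction). The robustness curve sweeps a loss grid (default 0, 0.1, …,
1.0); its AUC is the trapezoidal integral over [0, 1] with constant
extension to the boundaries. By construction occupancy of an empty
survivor set is 0, so a grid containing loss = 1.0 cannot reach AUC = 1
even with zero extinction risk; the zero-extinction sanity check
therefore uses a grid whose levels all leave survivors.

All uniform draws are indexed by (replicate, step, patch) and never by
the link structure, giving a monotone coupling: with common seeds,
adding links can only increase occupancy, and augmented-vs-baseline
ΔAUC comparisons are coupled (same removal and dynamics seeds).

The exact extinction/recolonisation functional forms used in the
robustness-simulation literature this module follows are not uniquely
determined by their verbal description; the forms above are a standard,
fully documented choice, and every form and parameter is configurable.

## Problem sizes

The default experiment and the ensemble-scale tests run deliberately
reduced but seeded study sizes, chosen so a full run stays in CPU
minutes: 30 networks per ensemble for clustering-gain comparisons (100
for the optimality audit), m = 2 for exhaustive audits, and for
robustness sweeps 20 networks × m ∈ {5,…,30} with burn-in 60, window
30, 2 dynamics replicates, 3 removals per loss level and a 6-point loss
grid. All scales are single config knobs; enlarging them changes
variance, not methodology.

## Known limitations

* The optimality audit is exhaustive only at m = 2 (beyond that the
  subset budget bites); greedy's high match rate at m = 2 need not
  persist at large m.
* Clustering maximisation is a *proxy* objective. Under the default
  SPOM calibration the proxy is imperfect in a specific, instructive
  way: per-neighbour colonisation at c = 0.3 is strong enough that
  randomly placed long links act as recolonisation highways and yield a
  larger mean AUC gain than greedy's clustering-optimised links, even
  though greedy reliably increases clustering and robustness
  (ΔAUC > 0, increasing in m). In dispersal-limited calibrations (e.g.
  c = 0.05), where persistence hinges on local redundancy rather than
  re-invasion, the ordering reverses and clustering-optimised links
  beat random ones. Which regime a real species occupies is an
  empirical question; users comparing strategies should calibrate e,
  rescue and c to their system before trusting the ordering.
* The SPOM ignores distance-dependent dispersal within the link
  topology, patch area/quality, and correlated (non-random) habitat
  loss — all stated non-goals.
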