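# Methods

`landconn` is a simulation laboratory for asking how well the three dominant
resistance-based connectivity models — factorial least-cost paths (FLCP),
resistant kernels (RK) and circuit-theory current density (CS) — predict the
"true" connectivity that emerges from individual movement. Truth is defined
operationally: many stochastic walkers are released on a resistance surface,
and their aggregated per-pixel visitation counts form a density-of-movement
surface against which each model's prediction is scored.

## The landscape model

A resistance surface is a strictly positive raster; the value `r` of a pixel
is the cost per unit distance of moving through it. The experiment uses a
suite of seven synthetic surfaces of graded spatial complexity, all rescaled
to `[1, 100]`:

* **Surface 0** — uniform background (`r = 1`) crossed by three vertical
  barriers (`r = 100`), each with a 3-pixel traversable gap. The simplest
  landscape: movement is free except at the barriers.
* **Surfaces 1–6** — Gaussian random fields synthesised with isotropic
  power-law spectra (amplitude `k^(-gamma/2)`), with the spectral exponent
  stepping down `3.0, 2.5, 2.0, 1.5, 1.0, 0.5` so each surface carries more
  fine-scale structure than the last. Each field is rank-quantised onto an
  increasing number of equal-mass resistance levels (`4, 8, 16, 32, 64,
  256`), mapped to the centres of equal sub-intervals of `[1, 100]`.

The two knobs make the complexity ladder checkable rather than merely
visual: the 32-bin value-histogram entropy is non-decreasing *by
construction* (equal-mass levels at sub-interval centres occupy
`min(levels, 32)` bins uniformly), and the mean absolute neighbour
difference rises with both knobs. The exact geometry of the original seven
surfaces is unrecoverable from their published images; this generator
reproduces the qualitative ladder, not the pixels.

Source points are sampled uniformly over all pixels without replacement
(resistance-blind, since nothing in the experiment's definition restricts
starting locations to hospitable terrain).

## The movement model

A walker occupies a pixel and moves to one of its in-bounds Moore (8-)
neighbours each step. Three mechanisms, active in any combination, shape the
walk; two directionality parameters modulate it.

**Step distribution.** With `C` the autocorrelation weight, `D` the
destination-bias weight and `C' = C(1 - D)`:

    P = (1 - C' - D) * P_mech + C' * P_persist + D * P_dest

* `P_mech` is proportional to `1/r_j` over admissible neighbours `j` when
  the *attraction* mechanism is active, uniform otherwise.
* `P_persist` is a point mass on the continuation of the previous move; when
  there is no previous direction, or its continuation is off-grid, its mass
  folds back into `P_mech`.
* `P_dest` is a point mass on the admissible neighbour closest (Euclidean)
  to the destination, ties broken by the fixed neighbour ordering.

Off-grid neighbours are removed and the distribution renormalised
(reflection by exclusion), so walks can never leave the raster. The walk
sampler draws from this mixture hierarchically (destination branch, then
persistence, then the mechanism distribution via precomputed cumulative
weights); this is an exact draw from the mixture, verified against the
explicit distribution in tests.

**Step cost and energy.** Moving from `i` to `j` costs
`dist(i,j) * (r_i + r_j)/2`, with `dist` 1 for cardinal and sqrt(2) for
diagonal moves — the standard cost-distance convention, shared with all
three connectivity models so budgets and thresholds are commensurable. With
the *energy* mechanism active the walk carries a budget `E`; a sampled step
whose cost would reach the remaining budget terminates the walk *without
moving* (so a walker that cannot afford any move dies on its source pixel).
Default `E = (max_steps/2) * median(scaled resistance)`: the cost of roughly
half the step cap on typical terrain, so energy termination bites before the
cap without dominating.

**Risk.** With the *risk* mechanism active, after each move the walker dies
with probability `1 - exp(-beta * risk/risk_max)` at the new pixel. The risk
surface defaults to the resistance surface itself. Default `beta` makes a
`max_steps/2`-step walk on median-risk terrain survive with probability one
half — mortality is a real force without truncating everything.

**Scales and caps.** Both resistance and risk may first be focal-scaled
(n x n mean/max/min window, truncated at edges), modelling coarser
perception; the walk then reads only the scaled surfaces. Every walk is
capped at `max_steps = 500` moves.

**Aggregation.** A density surface counts every pixel visit of every path,
revisits included (raw visitation counts; the alternative — counting each
path's pixels once — flattens the strong recurrence of 2-D walks near their
source and was rejected as less faithful to "density of movement").

**Seeding.** RNG streams are hierarchical: experiment seed -> scenario seed
-> (source index, replicate) seed via `numpy` `SeedSequence` spawn keys, so
any individual path is reproducible in isolation and aggregate results are
independent of iteration order.

## The three connectivity models

All three share one discretisation: pixels are nodes, Moore-adjacent pixels
are edges weighted `dist * (r_i + r_j)/2`.

* **FLCP** extracts one minimum-cost path per unordered source pair
  (multi-source Dijkstra with deterministic predecessors; pairs processed in
  canonical node order so the output is invariant to source ordering) and
  counts, per pixel, the paths crossing it.
* **RK** sums per-source kernels `max(0, 1 - cd_s/T)` of the single-source
  cost distance `cd_s`, i.e. a linear decay truncated at the dispersal
  threshold `T` (the simplest thresholded dispersal function; a Gaussian
  variant would be an easy extension).
* **CS** inverts edge weights into conductances, builds the graph Laplacian,
  and for every unordered source pair injects unit current at one terminal
  and grounds the other. Per-pixel current is half the sum of absolute
  incident edge currents, with the full injected current (1.0) assigned at
  the two terminals. The reduced Laplacian (one node per component pinned)
  is factorised once per surface by sparse LU and reused across all pairs;
  the direct solve's residual is checked against the nominal 1e-8 tolerance
  in tests, and a conjugate-gradient path would honour it explicitly.
  Pairwise mode is the default (it is the mode commensurate with FLCP); an
  all-to-one mode is available.

**Kernel threshold calibration.** The dispersal threshold is the one free
parameter of RK, and the naive tie — set `T` equal to the walker's energy
budget `E` — is wrong in an instructive way: `E` is a *straight-line* cost
budget, but a diffusing walker's occupied region scales with the square root
of its lifetime, so `T = E` (reach ~250 pixels on median terrain) produces a
kernel that is nearly flat over the whole raster and, after normalisation,
the worst prediction of all three models everywhere. Instead `T` is matched
to the walker's occupancy statistics: for an unbiased Moore walk of expected
lifetime `N` steps, a pixel visit sampled uniformly over the walk's life
lies at median distance `0.633 sqrt(N)` pixels from the source (the median
of the Rayleigh mixture `|X_t|`, `t ~ U(0, N)`, with per-step mean squared
displacement 1.5). That displacement priced at the median resistance gives

    T = median(scaled r) * 0.633 * sqrt(N),

with `N` the expected lifetime implied by the active mechanisms (energy
budget over mean step cost, mean time to a mortality event, the step cap —
whichever binds first). This keeps the kernel footprint the size of the
region walkers actually occupy.

## Scoring

Truth and prediction are min–max normalised to `[0, 1]` (removing each
model's arbitrary output scale), then compared by: per-pixel RMSE (bounded
by 1); Pearson correlation over all pixels; and the overlap of the top-q
(default 10%) highest-valued pixel sets, as the shared fraction of the
`K = floor(qN)` top pixels with deterministic index-order tie-breaking.
Constant normalised surfaces are a degenerate case: correlation is defined
as 1 for an exact match and 0 otherwise.

## The factorial experiments

* **First analysis** (no destination bias): 7 surfaces x 7 mechanism
  combinations x 4 focal scales x 3 focal functions x 3 autocorrelation
  levels (0, 0.35, 0.75) = 1,764 scenarios.
* **Second analysis** (destination bias): scale and autocorrelation fixed
  (1x1 mean, C = 0.2), 7 surfaces x 7 mechanisms x 3 bias levels (0.1, 0.3,
  0.6) = 147 scenarios. Destinations are unspecified in the experiment's
  definition; here each path's destination is an independently drawn *other*
  source point (from the path's own stream), which uses only in-experiment
  locations and keeps destinations heterogeneous.

At full replication each scenario aggregates 100 paths from each of 100
sources (10,000 paths). Predictions depend only on surface, sources and
threshold, so they are computed once per surface and reused, with the kernel
threshold recomputed per scenario. Runs are resumable: completed scenario
rows are detected in the output CSV and skipped.

## Synthesis

The scenario table (one row per scenario x model, responses rmse/pearson/
overlap) is synthesised with machinery implemented directly on the linear
algebra and cross-checked against R `vegan` and `statsmodels` in the test
suite:

* **RDA**: responses column-standardised (they have unlike units), factors
  dummy-coded as treatment contrasts; constrained axes are singular axes of
  the fitted values of the multivariate least-squares fit.
* **CCA**: responses min-shifted per column to non-negativity (the Pearson
  column can be negative; the shift preserves ordering), chi-square
  standardised, and regressed with row-mass weights.
* **Variance partitioning**: adjusted R² (Ezekiel) of every subset of the
  factor groups, with unique/shared components recovered by solving the
  inclusion–exclusion system exactly; components plus residual sum to 1 by
  construction. Factors with few sampled levels (scale, C, D) are coded
  categorically.
* **Factorial ANOVA**: main effects and two-way interactions; for the
  balanced scenario grids the sums of squares are orthogonal and unique,
  with sequential (Type I) SS as the warned fallback. Saturated higher-order
  models are not estimable at these replication levels and are not offered.

## Problem sizes, what the reduced profile shows — and what it cannot

Tests and the acceptance script run a reduced profile chosen for a desk
machine: 64 x 64 surfaces, 25 sources, 100 paths per source, with the first
analysis restricted to its 7 x 7 x 3 (surface x mechanism x autocorrelation)
slice at the native 1 x 1 scale and the second analysis at its complete
147-scenario grid. Determinism, oracle equivalence and invariants are
scale-free. The comparative findings are partly scale-dependent, and the
reduced profile changes two things that matter:

* **Source geometry.** 25 sources on a 64² grid is four times the
  full-profile source density, so kernel footprints overlap heavily and
  their summed surface acquires spurious maxima *between* sources, while
  walk lifetimes (unchanged caps and budgets) are large relative to the
  raster.
* **Truth sparsity.** Even at full per-source replication a 64² truth
  surface is relatively sparse and peaked once normalised; a sparse
  prediction raster (FLCP is near-zero almost everywhere) is then
  structurally rewarded on RMSE, and strongly source-peaked current maps are
  rewarded on overlap.

Consequently the reduced profile robustly reproduces the *correlation*
ordering RK > CS > FLCP, the D-bias degradation trend, CS as the
least-error model, and model choice as the dominant variance-partition
factor — but it puts FLCP's RMSE below RK's (reported: FLCP worst) and CS's
overlap above RK's (reported: RK highest). These inversions are properties
of the reduced geometry, not of the models; the corresponding acceptance
tests assert the reported full-scale orderings and are expected to fail at
this profile rather than being weakened. The full 256² profile is available
via `ExperimentConfig.preset("full")` (hours on one CPU).

Passing tests at the reduced profile demonstrate internal correctness and
the robust subset of the comparative conclusions; they do not demonstrate
anything about empirical animal movement, which the walk model (static
resistance, memoryless mechanisms, pixel-scale choices) does not attempt to
capture.

## Numerical details and edge cases

* Dijkstra on the sparse cost graph for all cost distances; predecessor
  reconstruction for FLCP paths; sparse LU for circuit solves.
* A 1 x 1 raster has no admissible neighbours: the step distribution raises
  a degenerate-state error.
* Top-K ties (common in sparse rasters) are broken by pixel index via a
  stable sort, making overlap deterministic.
* Collinear design columns are dropped greedily left-to-right with a
  warning; rank is tracked for the adjusted R².
* Surfaces are validated strictly positive and finite; the Moore grid is
  therefore always connected, and the disconnected-terminal branch of the
  circuit solver (skip with warning) is defensive.

## Known limitations

* The movement simulator is a re-specification from the mechanisms'
  published descriptions, not a port of the original software; its exact
  functional forms (mixture weights, energy accounting, hazard form) are
  this package's own, stated above.
* The seven surfaces reproduce a qualitative complexity ladder; no claim is
  made about the original rasters.
* CCA on min-shifted bounded statistics inherits the shift's arbitrariness;
  RDA on standardised responses is the more defensible ordination here, and
  both are provided.
* The linear kernel is the only built-in decay; the threshold calibration
  above is derived for unbiased walks and is only an approximation under
  strong autocorrelation or destination bias.
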