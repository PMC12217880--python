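# Methods

This note records the models implemented in `ecorisk`, the assumptions and
numerical choices behind them, what the synthetic-data generator does and
does not emulate, and the limits of what the test suite shows.

## Landscape ecological risk

Risk is computed on a fishnet of square evaluation units rather than a
moving window: disjoint units are what the area-weight form
ERI_k = Σ_i (A_ki/A_k)·C_i presupposes, and they make every unit's metrics
independent of its neighbours. `unit_size` (default 10 cells) is a free
parameter; there is no canonical value in the literature, and results at
very small units (< ~5 cells) are dominated by patch-count quantization.
Partial edge tiles are kept but flagged, and units whose landscape area
falls below `min_unit_area_fraction` (default 0.5) of a full tile are
excluded downstream so sliver units cannot contribute unstable metrics.

Within a unit, patches are connected components of same-class cells
(connectivity 8 by default, the common landscape-metrics convention;
4 available) **relabelled inside the unit window**. A patch crossing a
unit boundary therefore counts once in every unit it intersects. The
alternative — counting global patches fractionally — would break the
partition property Σ L_i = 1 that the dominance index relies on.

Index definitions, per unit k and class i (areas in km², so densities are
patches/km²):

| symbol | definition | notes |
|---|---|---|
| n_i | patches of class i / A_k | patch-count density |
| p_i | A_ki / A_k | area share, Σ p_i = 1 |
| L_i | patches of i / total patches in unit | Σ L_i = 1 |
| H_i | ≡ n_i | see below |
| N_i | sqrt(n_i / 2 p_i) | separation |
| D_i | 0.6 L_i + 0.4 p_i | dominance |
| E_i | 0.5 H_i + 0.3 N_i + 0.2 D_i | disturbance |
| Y_i | (F_i − F_min)/(F_max − F_min) | normalized fragility |
| C_i | E_i · Y_i | loss |

Two deliberate resolutions of ambiguities in the standard index set:

* **H_i ≡ n_i.** The verbal definitions of patch-count density and patch
  density in the source literature of this index family are identical
  ("number of patches of type i over total area"); we implement them as
  one quantity rather than invent a distinction.
* **Y_i uses the table-wide fragility range** (for the shipped scores
  1–5: construction 0, water 0.25, forest 0.5, grassland 0.75, cropland
  1), not the per-unit range. Per-unit normalization would let identical
  compositions score differently depending on which other classes happen
  to be present.

Absent classes get zeros for every index; they carry zero weight in the
ERI sum regardless, and N_i is undefined at p_i = 0. Consequently ERI is
a convex combination of the C_i of the classes present — the bound
min C_i ≤ ERI ≤ max C_i is property-tested.

The disturbance weights (0.5/0.3/0.2) and dominance weights (0.6/0.4) are
fixed constants of this index family, taken as given, not estimated.

**Scale caveat.** Because n_i and N_i carry units of 1/km², ERI values
depend on cell size. The shipped fixed breakpoints (0.243/0.404/0.550/
0.643) presume the 1 km cells the synthetic generator defaults to; with
other resolutions use Jenks mode (the default) or supply your own breaks.

## Carbon stock

Pure lookup: cell density = Σ of the class's four pools (t/km²); totals by
class-area bookkeeping. The shipped pool table is a plausible
temperate-coastal parameterization preserving the ordering forest >
grassland > cropland > water > construction; real studies must substitute
regional values (CSV: `code,name,fragility,c_above,c_below,c_soil,c_dead`).
Change maps are cellwise differences; the aggregate equals
Σ_i Δarea_i × density_i exactly when both dates share one table (tested).

## Scenario simulation

The simulator is a transparent Markov + greedy-CA stand-in for
patch-based land-use simulation software, built for testability:

* **Demand**: P̂[i,j] = n(i→j)/n(i) from two dates (identity rows for
  classes absent at t0). Demand = counts @ P̂ with **largest-remainder
  rounding**, so Σ demand equals the valid cell count exactly. Cells under
  the restriction mask are excluded from the Markov step and re-enter
  demand as fixed counts — the only convention under which "frozen cells
  never change" and "counts match demand" can hold simultaneously.
* **Scenario adjustment**: for an adjustment (s → t, ±D) the entry becomes
  p_st·(1±D) clipped to [0,1]; the remaining entries of row s are rescaled
  by the common factor X = (1 − Σ adjusted)/(Σ unadjusted). Multiplicative
  adjustment was chosen over additive percentage points; a raise on a zero
  entry is a no-op, and clipping can at most drive X to 0 (all mass on the
  target). Joint adjustments whose sum exceeds 1 are an error. Presets: UD
  raises grassland/forest/cropland→construction by 20 % and reduces
  construction→{water,forest,grassland} by 30 %; CP reduces
  cropland→construction by 60 % and cropland→grassland by 40 %; ND adjusts
  nothing.
* **Suitability**: a random forest (60 trees, min leaf 5, ≤20 000 sampled
  cells) on driver vectors → t1 class; classes with <10 samples get
  uniform surfaces with a warning; per-cell probabilities renormalized to
  sum to 1. Any probabilistic classifier would do; the forest needs no
  tuning and is deterministic given the seed.
* **Allocation**: deficit classes (largest first) claim candidate cells
  ranked by suitability × (3×3 neighbourhood enrichment + 1e-6), with
  seeded jitter (1e-12 scale) breaking ties; candidates must be donated by
  classes above their demand, permitted by the binary transfer-cost
  matrix, unfrozen and not already converted this step. Infeasible demand
  is allocated as far as possible and the shortfall logged. This replaces
  the land-expansion analysis and multi-seed patch engines of full CA
  simulators — the main deliberate simplification of the package.
* **Transfer-cost presets** encode which conversions each scenario
  permits; the natural-development matrix holds grassland and cropland in
  place, the urban matrix locks construction except reversion to cropland,
  the cropland-protection matrix additionally allows grassland→cropland.
  Diagonals are always 1 (staying is never forbidden). Note that under
  strict scenario matrices some Markov demand can be infeasible by
  construction; conservation audits therefore use the permissive matrix
  plus the water restriction mask.
* **Validation**: OA = trace/total and κ = (p_o − p_e)/(1 − p_e) from the
  5×5 confusion matrix; cross-checked against scikit-learn's
  `cohen_kappa_score` in tests.
* Multi-horizon projection = successive one-step allocations with the same
  adjusted matrix.

## Bivariate spatial autocorrelation

Global statistic: I_hk = n ΣΣ W_ij z_h(i) z_k(j) / ((n−1) ΣΣ W_ij), where
z are z-scores using **population standard deviations** (divisor n;
`ddof=1` switchable). With row-standardized weights this equals
Σ I_i/(n−1) for the local values I_i = z_h(i)·lag_i(z_k) — note the
(n−1), a consequence of the n/(n−1) normalization of this form of the
statistic. The cross term pairs unit i on the first variable with
neighbours j on the second; that is the only form in which W enters
non-trivially.

Weights: rook or queen contiguity on the fishnet, binary or
row-standardized (default queen/row). Units excluded by the area filter
are removed before building the graph; units left neighbourless are
flagged islands and dropped.

Inference: local p-values by **conditional permutation** (unit i holds its
values; its neighbours' z_k are redrawn without replacement from the other
n−1 units), two-sided, pseudo-p = (#{|I*| ≥ |I|} + 1)/(B + 1), never
exactly zero; 999 permutations and α = 0.05 by default. The global test
permutes the neighbour variable wholesale. The two-sided global test runs
slightly conservative (empirical size ≈ 0.03–0.05 at α = 0.05 in the null
battery) because the null distribution of Moran-type statistics is not
centred at zero; the calibration band [0.03, 0.07] is asserted in the
acceptance suite.

Labels: significant units fall in the quadrant of (z_h, lag z_k):
high–high (conflict hotspot), low–low, high–low, low–high.

## Classification

Jenks natural breaks by Fisher's optimal-partition dynamic programming
(O(k·n²), prefix-sum costs) — deterministic, exact, verified against
exhaustive partition enumeration for n ≤ 25. Above 20 000 finite values a
seeded subsample feeds the DP; every surface the pipeline itself produces
(hundreds to thousands of unit values) stays below the cap, so the exact
path is the one exercised end-to-end. Intervals are upper-closed
((−∞,t1], (t1,t2], …), matching the convention of the shipped risk
breakpoints; a value exactly at a threshold falls in the lower class.

## Synthetic landscapes

`generate_landscape` thresholds a Gaussian random field (correlation
length = `smoothness`, in cells) at the rank quantiles of the requested
class proportions: realized shares are exact up to rounding, and patch
size grows with smoothness. `evolve_landscape` redraws each cell
independently from its class's transition-matrix row — transitions are
ground truth by construction, making matrix recovery a clean estimation
problem. `generate_drivers` produces smoothed fields scaled to [0,1].
All three are deterministic given seeds.

What this does **not** emulate: anisotropic or linear features (roads,
coasts), spatially correlated transition noise (real conversion happens at
patch edges, not independently per cell), class-dependent patch geometry,
classification error in the input maps, and any calibration to a real
study area. Passing tests therefore demonstrate correctness of the
computations and internal consistency of the pipeline on realistic patchy
mosaics — not predictive skill for any particular landscape.

Defaults: 200×200 grid of 1 km cells, class shares
(0.18, 0.10, 0.30, 0.17, 0.25) for construction/water/forest/grassland/
cropland — a mixed peri-urban mosaic with forest dominant and water
scarce — smoothness 12 cells, and a mildly urbanizing transition matrix
(diagonals 0.89–0.96, net flow toward construction, water nearly inert).

## Problem sizes and determinism

Unit tests run landscapes of 50–150 squared; oracle comparisons use 60×60
(risk) and fishnets up to n = 100 units (Moran); statistical checks use
300×300 (matrix recovery, tolerance 0.02), 320×320 (κ of independent
maps) and 1 000 null replicates at n = 36 with 199 permutations; the
end-to-end run uses a 200×200 fixture, 400 units, three scenarios × two
horizons. These sizes give comfortable statistical margins while keeping
the full suite around a minute on one core. Every stochastic step takes an
explicit seed; the pipeline derives per-stage seeds from one master seed
by hashing, and reruns are bit-identical.

## Known limitations

* The CA allocator is order-dependent (largest deficit first) and greedy;
  it guarantees demand conservation, not spatial optimality.
* ERI magnitudes are resolution-dependent (see scale caveat); comparisons
  are meaningful only across maps sharing cell size and unit size.
* The suitability model is static: one fit from the observed pair is
  reused for all horizons and scenarios.
* Raster georeferencing is carried as a simple (cell size, top-left
  origin) pair in a JSON sidecar next to each TIFF (plus plain-text ESRI
  ASCII grids); there is no CRS handling, reprojection or resampling —
  inputs must be pre-aligned.
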