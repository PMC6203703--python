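# Methods

`climrefugia` re-implements, as a tested pipeline, the standard
ecological-niche-modeling workflow used to map relict-species richness and
identify long-term climatically stable refugia: per-species maximum-entropy
suitability models fitted on presence/background data, projected across past
(LGM, mid-Holocene), present, and future (2070) climate scenarios, thresholded
into binary maps, stacked into richness surfaces, and intersected over time to
isolate the areas that stay suitable for the *same* species throughout.

## The suitability model

For one species with presence feature vectors `f(x_i)` and a background
sample, the model is the Gibbs distribution over background cells

    P(x) = exp(λ·f(x)) / Z(λ),   Z(λ) = Σ_background w(x) exp(λ·f(x)),

with λ chosen to maximize the per-presence penalized log-likelihood

    L(λ) = mean_i [λ·f(x_i)] − ln Z(λ) − Σ_j β_j |λ_j|.

This is the maximum-entropy (MaxEnt) estimator restricted to **linear and
quadratic** features: each climate variable `v` contributes
`(v − min)/(max − min)` and `(v² − min v²)/(max v² − min v²)`, with bounds
learned from the training background and projection values clamped to those
bounds. The problem is convex; we solve it by split-variable L-BFGS-B
(`λ = u − v`, `u,v ≥ 0`, making the L1 penalty smooth) and, when `β = 0`,
polish with damped Newton steps until the KKT gap
`|E_model[f_j] − mean_presence[f_j]|` is below 1e−10. The optimizer is
therefore exact at the tolerance the tests assert (1e−5), and the fitted
model is start-point independent.

Per-feature regularization follows the published MaxEnt default schedule for
linear/quadratic features: `β_j = βmult · b(m) · s_j/√m`, where `s_j` is the
presence standard deviation of feature `j`, `m` the presence count, and
`b(m)` interpolates (10, 1.0), (17, 0.6), (30, 0.5), (100, 0.25). The global
multiplier `βmult` is a tuning constant (below).

Outputs: **raw** = the normalized Gibbs density; **logistic**
= `σ(λ·f + H − ln Z)` with `H` the entropy of the raw distribution over the
training background — a per-cell monotone transform of raw that equals 0.5
everywhere under the uniform model and is well defined on projections.

## Model and variable selection

1. A 5000-point background sample is drawn from the sampling-bias surface;
   candidate variable subsets are all subsets (size ≥ 2) that contain no
   pair with |Pearson r| ≥ 0.70 and whose within-subset variance inflation
   factors are all < 5. A hard cap (default 10,000 candidates) guards
   combinatorial blowup.
2. Each candidate is fitted at `βmult = 0` (no penalty) and scored by AICc,
   `2K − 2 lnL + 2K(K+1)/(n−K−1)` with `K` the number of nonzero
   coefficients; `n − K − 1 ≤ 0` marks the model inadmissible (+∞). The
   AICc-argmin wins; ties break to the smaller, lexicographically first
   subset.
3. The global multiplier is then selected by AICc over the 31-value grid
   0, 0.5, …, 15, refitting the chosen subset at each value (warm-started;
   ties go to the smaller multiplier).

## Replication, thresholds, evaluation

Species with 5–29 occurrences (after collapsing duplicates within a grid
cell) are replicated by leave-one-out; species with ≥ 30 by 10-fold
cross-validation (10 replicates). The boundary case n = 30 goes to
cross-validation, since 10 folds need at least 3 points each. Species with
fewer than 5 occupied cells are excluded, never fitted.

Each replicate gets its own **MSS threshold**: the value maximizing
sensitivity (fraction of its training presences at or above the threshold)
plus specificity (fraction of background below it), over candidate
thresholds at the observed scores; ties take the smallest threshold.

Significance of small-sample models follows the leave-one-out test: the
count of left-out points that their replicate predicts suitable is compared
with the exact **Poisson-binomial** upper tail under the null that each point
independently lands in the predicted-suitable area with probability equal to
that area's fraction of the region (computed by dynamic programming; exact
to enumeration for all n ≤ 12). For cross-validated species the same
statistic is computed over the 10 held-out folds — the full leave-one-out
variant would cost n extra fits per species for no extra information at
these sample sizes.

Cross-validated species additionally get a **continuous Boyce index**: the
Spearman correlation between the predicted-to-expected ratio
`F = P(presence in window)/P(background in window)` and the window midpoint,
over 101 windows of width one-tenth of the observed score range. Windows
with no background mass are undefined and dropped; windows with zero
presence mass (F = 0) are also dropped, so the index ranks only the windows
where the ratio is informative — the convention under which a model that
concentrates presences in its top suitability decile scores ≈ 1, and which
preserves exact sign reversal when the suitability ranking is inverted.

## Refinement, stacking, refugia

Replicate logistic maps are combined into a **refined** map: the replicate
mean with every pixel removed (set to 0) where fewer than 95% of replicates
call it suitable at their own thresholds — with 10 replicates, unanimity.
The refined map is binarized at the mean replicate threshold (≥ keeps the
pixel), thresholds learned at present are reused on projections so
scenarios stay comparable, and per-species binary maps are stacked (summed)
into richness maps per scenario.

Refugia are strict intersections: for each species, a cell belongs to the
refugium of a time combination iff it is suitable in *every* member
scenario, including every circulation-model variant (a consensus mode —
suitable in ≥ k of a period's variants — exists behind a flag but is not
the default). The five standard combinations are Present–Past (6 past
scenarios), Present–Future at each pathway (3 each), and Present–Past–Future
at each pathway. Stacked refugia maps are summarized by area (per-cell
spherical-rectangle approximation, `(111.32·Δlat)·(111.32·Δlon·cos lat)` km²)
and by the fraction of refugium area outside a protected-area mask.

Observed patterns use a 1° cell grid: richness (species per cell),
rarity-weighted richness (RWR; each species contributes 1/#occupied-cells to
each of its cells, so total RWR mass equals the species count exactly), and
core areas = connected components (rook adjacency by default, queen by
config) of qualifying cells — the top 20% of occupied cells for richness
("top" by the 80th percentile of occupied-cell values), cells ≥ 0.7 for RWR
— with at least two cells, ranked by summed value.

## Spatially corrected correlation

Richness and RWR maps are correlated by Pearson's r with the modified
(effective-sample-size) t-test: distance-class correlograms
(equal-width classes, class count by Sturges' rule on the pair count;
Moran-type estimates) for each map give

    σ̂²_r = n⁻² [n + 2 Σ_pairs ρ̂_X(d_ij) ρ̂_Y(d_ij)],   M̂ = 1 + 1/σ̂²_r,

with `M̂` clamped to (2, n]; `t = r√((M̂−2)/(1−r²))` is referred to Student's
t with `M̂ − 2` degrees of freedom. Distances between 1° cell centers are
great-circle. The implementation is validated by its limiting behavior
(white noise: `M̂ ≈ n` and p ≈ classical p; strongly co-autocorrelated
smooth fields: `M̂ ≪ n`), not by bit-compatibility with any particular
package.

## The synthetic study system

No real occurrence compilation or gridded climate product is bundled;
`synthetic_data` fabricates a seeded study system with known truth:

* **Climate**: 6 bioclimatic variables on a 60×60 grid of 0.5° cells,
  spatially autocorrelated Gaussian fields (white noise smoothed with a
  Gaussian kernel, autocorrelation length 8 cells), whitened on the grid and
  recolored so the pairwise inter-variable correlation equals the configured
  value (0.3 by default) exactly. 13 scenarios: present; 3 circulation-model
  variants × {mid-Holocene, LGM}; 3 variants × 2 emission pathways for 2070.
  Non-present scenarios add a spatially uniform drift per variable plus
  fresh small-scale noise (SD 0.1).
* **Species**: 10 species; each has a Gibbs log-intensity
  `η = −((v−c)/w)²` on 1–2 variables, centers `c ~ N(0, 0.8)`, widths
  `w ~ U(0.35, 0.6)` SD. These widths give strongly discriminated niches;
  the MSS threshold is an argmax estimator with cube-root convergence, so
  weakly discriminated niches would make every replicated,
  unanimity-refined map erode systematically and the ground-truth closure
  check meaningless. The cost, stated plainly: the fixture's models
  validate better (mean leave-one-out success ≈ 0.91, Boyce ≈ 0.96) than is
  typical for real herbarium-scale data.
* **Drifts** (temperature-like variables): mid-Holocene −0.084, LGM −0.21,
  2070 +0.126 (low pathway) / +0.315 (high pathway) SD, variant offsets
  ±0.035, with smaller mixed-sign drifts on precipitation-like variables.
  These are calibrated so per-period suitable-area changes fall in the
  ranges reported for East Asian relict flora — a few percent for the
  mid-Holocene, tens of percent for the LGM, strongest losses under the
  high-emission pathway — while refugia stay nonempty (roughly 25–65% of
  present suitable area).
* **Sampling**: occurrence counts log-uniform in [100, 400] per species,
  cells drawn ∝ exp(η) × bias (a west–east collection-effort gradient by
  default), points jittered within their cell. Background sampling from the
  same bias surface cancels the bias in the Gibbs estimate, as in the
  target-group-background method.
* **Truth**: per (species, scenario) the true suitability in logistic form
  (normalizer and entropy from the present scenario, so one cutoff applies
  across scenarios); the truth threshold is the *population-level* MSS
  cutoff on the present map (presence mass ∝ exp(η)·bias, background mass
  ∝ bias) — the exact noiseless analogue of the estimator the pipeline
  applies, making ground-truth closure well-posed: as n grows, the
  pipeline's recovered refugium converges to the truth by construction.

What the synthetic system does **not** emulate: topography and coastlines,
spatially heterogeneous climate drift (real refugia often exist because
mountains buffer change locally; here refugia arise from the geometry of the
fields), presence-record spatial error beyond within-cell jitter, nodata
regions, and niche non-stationarity. Passing tests therefore demonstrate
correctness of the machinery under the model's own assumptions, not skill on
real data.

## Numerical and design choices

* Point-in-cell assignment is half-open (closed on the south/west edge);
  cell (0,0) is the north-west cell; grids are georeferenced by the
  lower-left corner, as in the ASCII-grid standard.
* Extraction is containing-cell (nearest-cell), not bilinear.
* "Suitable iff value ≥ threshold" everywhere (boundary included).
* Duplicate presences within one grid cell collapse to one before counting.
* Candidate enumeration returns *all* independent subsets of size ≥ 2;
  single-variable models are never candidates, so a species whose true
  niche uses one variable always carries at least one extra variable.
* The one-per-stage CLI layout was collapsed to `simulate`, `run-all`, and
  `correlate`: every intermediate product is written by `run-all`, and
  per-stage subcommands would have required bespoke intermediate formats
  with no users. The library functions are the finer-grained interface.
* Problem sizes in the test-suite calibration experiments (50 optimizer
  instances, 5 recovery seeds, 200 null repeats, 50 white-noise fields) are
  chosen to bound the Monte-Carlo error of each check well below its
  asserted tolerance.

## Known limitations

* The unanimity (≥95%) refinement combined with per-replicate thresholds is
  conservative by design: recovered suitable areas are systematically
  nested inside the population-threshold truth, and intersecting many
  scenarios compounds this. With weakly discriminated niches or small
  samples the recovered refugium can be much smaller than the truth even
  when every fitted map is accurate.
* AICc over unpenalized fits tends to admit 1–2 spurious variables at large
  n; the β-multiplier stage only partially prunes them.
* The modified t-test uses fractional degrees of freedom and equal-width
  distance classes; with very few valid cells (< ~25) the correlogram
  estimates are unstable and `M̂` is noisy.
* `reserve_gap_fraction` treats any cell with refugia value ≥ 1 as refugium
  area regardless of how many species share it.
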