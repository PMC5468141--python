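# Methods

This note documents the models, the synthetic data-generating process,
the numerical choices, and the known limitations of `pumaconnect`. It
states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Telemetry screening

Three stages in fixed order, all tunable through `RunConfig`:

1. **PDOP filter** — fixes with positional dilution of precision
   strictly greater than 10 are dropped (10.0 itself is retained).
2. **Stationary-cluster removal** (den/kill-site proxy) — a fix is
   removed when it lies within 200 m of *both* its currently retained
   temporal neighbors (endpoints: their single neighbor); removal is
   one fix at a time, earliest first, repeated to stability. This
   interior-removal reading collapses multi-fix clusters while keeping
   each cluster's entry and exit fix, so slow directed travel is never
   deleted wholesale. The alternative (either-neighbor) reading would
   remove legitimate short steps; the choice is deliberate and the rule
   is pinned by a brute-force oracle test.
3. **Step segmentation** — consecutive retained fixes more than 24 h
   apart contribute no bridge (large gaps distort the mobility
   estimate), but both fixes remain available to their other neighbors.

Screening is idempotent; the per-stage counts are written to the filter
report.

## Brownian bridge movement model

Each step is a Brownian bridge conditioned on its endpoints, elapsed
time `T` (h), the Brownian motion variance `sigma2_m` (m²/h) and the
per-coordinate location-error SD `delta` (m, default 26.2). The
location error enters as the SD of a normal error on each coordinate;
the published 26.2 m figure originates from a circular-error-probable
convention, and adopting it directly as the normal SD is the
conservative documented conversion.

* **Mobility estimation** — leave-one-out ML: every odd-indexed fix is
  scored under the bridge spanned by its even-indexed neighbors
  (variance `T a(1-a) sigma2_m + ((1-a)^2 + a^2) delta^2`); only
  triples whose two spanning lags are each ≤ 24 h are used; 1-D bounded
  maximization of the summed log-density over `log sigma2_m` in
  [1e-3, 1e7] m²/h. Units are m²/h throughout; magnitudes are therefore
  not comparable across parameterizations that use minutes or seconds.
* **Bridge density** — midpoint quadrature over the time fraction with
  25 slices (default); each slice is an isotropic bivariate normal
  evaluated at cell centers times the cell area, computed on a bounding
  box of the step padded by 6 SD of the widest slice, then normalized
  to sum 1. Refining 25 → 100 slices moves the surface by < 0.5% total
  variation on the tested tracks.
* **Occurrence surface** — bridge densities averaged with weights
  `T_i / sum(T)`, re-normalized, then cells at or below the 1e-5 extent
  threshold are zeroed (applied per cell; the surviving mass fraction
  is recorded, typically > 0.999).
* **Degenerate input** — a zero-length step with zero variance is an
  error; a zero-mass bounding box (possible only for variances far
  below the cell size) is an error rather than a silent zero surface.

## Habitat quality model

**Response.** Natural log of the BBMM cell probability at points
sampled uniformly over the individual's buffered surface (buffer = the
animal's greatest step length), floored at the 1e-5 extent threshold so
buffer-only points score `ln(1e-5)`. One point per filtered location.
The analysis never states its regression response in closed form
anywhere in the lineage of such studies; UD-height regression at random
points is the reconstruction used, and it is what the end-to-end
recovery test validates.

**Model.** `y = X beta + b(animal) + eps` with marginal per-animal
covariance `sigma2_u J + tau2 I + sigma2_s exp(-D/rho)`; distances are
planar meters within an animal's own sampled points; cross-animal
residual correlation is assumed zero.

* Variance components `(sigma2_u, sigma2_s, rho, tau2)` are estimated
  once under the global fixed-effects model by Nelder–Mead on the log
  scale (2 restarts) and held fixed across all candidate fits. The
  profile objective carries the REML adjustment
  `+ 0.5 log det(X' Sigma^-1 X)` by default: with ~10 animals and five
  animal-level fixed effects, plain ML shrinks `sigma2_u` by roughly
  the fraction of cluster-level parameters and the ±2-SE coverage of
  animal-level coefficients falls below nominal; with the adjustment,
  coverage is nominal in the recovery simulations.
* Candidate likelihoods and AIC are full ML evaluated at those fixed
  components, so the 192 fits reduce to GLS on per-animal
  Cholesky-whitened data (the whitened global design is built once;
  each subset is a column selection). `AIC = -2 loglik + 2(p + 4)`,
  counting all fixed effects and the four variance parameters.
* Candidate set: all subsets of the 7 linear habitat terms
  {ruggedness, shrub, human_mod, riparian, dist_water, forest, tpi},
  the ruggedness quadratic allowed only with its linear term
  (2^7 + 2^6 = 192); intercept and the four indicators (young adult,
  male, two capture-area dummies) forced into every model. Forcing the
  indicators is a design choice; their unit weight of evidence is then
  structural.
* Averaging: Akaike weights from ΔAIC (ties broken by enumeration
  order); `w+(v)` sums weights over models containing `v`; `beta~(v)`
  is the natural average (renormalized within those models, not
  zero-substituted); unconditional SE folds between-model coefficient
  spread into within-model sandwich variances. The sandwich estimator
  is clustered by animal: `A^-1 (sum_a g_a g_a') A^-1` with per-animal
  GLS scores; it warns when clusters ≤ fixed effects.
* Global-vs-null adequacy: the global model must beat the
  intercept+random-effect null by more than 10 AIC units.

**Quality → conductance.** The averaged linear predictor (indicators at
reference level, random effect at zero) is min–max rescaled to
(epsilon, 1] with epsilon = 1e-3, then water/canal cells are set to
epsilon. The monotone identity transform reflects the premise that
movement-based habitat quality *is* conductance; epsilon keeps the
resistor network strictly positive. The transform's shape beyond
monotonicity is a free choice and other monotone maps would change
absolute, not relative, current patterns.

## Circuit model

Cells are nodes; 8-neighbor edges carry the arithmetic mean of the two
cell conductances, diagonals divided by √2 (center-to-center distance).
These are the common defaults of circuit-based connectivity software;
the 4-neighbor variant is available. Strip terminals (single-cell-wide
rectangle edges) are collapsed to supernodes; the ground supernode is
eliminated and the reduced SPD Laplacian solved by sparse LU
factorization, with a conjugate-gradient fallback (rtol 1e-12).
Source–ground connectivity is checked explicitly first. Per-cell
current is half the sum of absolute incident edge currents; effective
resistance is the source supernode voltage per injected ampere.

Omnidirectional protocol: fill cells outside the irregular study
boundary with draws from Normal(mean, SD) of in-boundary conductances
truncated to (1e-6, max]; run west→east and north→south; sum the two
current maps over in-boundary cells. Oblique runs are omitted — the
literature the protocol follows found they do not change the spatial
patterns. The desk-scale study boundary used in synthetic mode is the
rectangle minus clipped corners, which exercises the fill without
changing the rectangle's terminals.

## Risk overlay

Pinch points: cells ≥ the 95th percentile (linear interpolation) of
summed in-boundary current. Development risk: among pinch cells with a
positive projected impervious-surface increase, those ≥ the 90th
percentile of that same subset (so growth outside pinch points cannot
shift the selection). Traffic rules: markers on segments with current
AADT > 5,000 vehicles/day whose 1-km disc (cell-center distance)
touches the pinch mask are current barriers and take the disc's maximum
current; future risk requires start < 3,000 ending > 3,000, or start in
the closed band [3,000, 5,000] ending > 5,000, with exposure = the AADT
change. Under one consistent pair of epochs the current-barrier and
future-risk classes are disjoint by construction.

## Synthetic data

The generator emulates the statistical structure the analysis assumes —
not real geography.

* **Landscape** — 64×64 cells of 270 m by default; each layer an
  independent stationary Gaussian random field with exponential
  covariance (range 1,500 m), synthesized by FFT circulant-spectrum
  coloring; cover layers mapped into [0, 1] (clip of 0.5 + 0.25·field)
  and human modification from a [0, 1] intensity field before
  z-scoring; `dist_water` is the distance transform of a ~3% water
  mask. Stacks are redrawn (bounded attempts) until all pairwise
  |Pearson r| ≤ 0.5, mirroring the screening outcome the analysis
  expects of its real covariates.
* **Tracks** — discrete redistribution kernel: from the current cell,
  the next cell is drawn within radius 3× the 600-m step scale with
  weight Gaussian(distance) × exp(Σ coef · layer). The kernel is
  discrete precisely so single-step expectations are exactly computable
  by brute force in tests. Default selection coefficients (standardized
  scale): ruggedness +1.5, shrub +1.0, human modification −1.0 —
  fixed a priori to mirror the qualitative ranking the analysis is
  meant to recover (two strong positive terms, one moderate negative).
  Fix interval 4.15 h; 5% of fixes draw PDOP > 10; stationary clusters
  injected at 2 per 100 fixes, all cluster fixes within 80 m of the
  anchor (pairwise < 200 m, hence removable); attributes assigned
  round-robin so the indicator design is balanced.
* **Roads/projections** — three segments spanning the <3,000,
  3,000–5,000 and >5,000 vehicles/day classes, with one crossing from
  low to high by 2030; markers every 1.6 km along each segment;
  impervious percent rasters with 2030 ≥ 2010 everywhere and growth
  concentrated on the top 30% of human-modification intensity.

What the generator does *not* emulate: home-range fidelity and
territoriality, temporally varying behavior states, fix-success bias,
real road network topology, autocorrelated attribute effects. Passing
recovery tests therefore demonstrates the estimation machinery is
correct under its own assumptions, not that those assumptions hold for
any particular field dataset.

## Problem sizes and determinism

Desk-scale defaults (64×64 grid, 8 animals × 300 fixes) complete a full
pipeline run in well under a minute on one CPU; the recovery
simulations in the test suite use 10 such runs, 50 mixed-model
replicates of 2,000 points, and 10⁵ Monte Carlo bridge paths. All
randomness flows through named per-stage seeds derived from one base
seed by hashing, so identical configs produce byte-identical artifacts
(verified by manifest content hash).

## Known limitations

* Single global Brownian variance per animal (no behavioral
  change-point variants).
* Variance components are not re-estimated per candidate model;
  AIC differences therefore compare fixed-effects structures only.
* The 1e-5 extent threshold is applied per cell, not cumulatively; at
  desk scale this trims < 0.1% of mass.
* The conductance map inherits the reference-class prediction
  (adult female, reference area); indicator effects shift individuals'
  intercepts, not the landscape ranking.
* ESRI ASCII grids carry no CRS; the CRS tag is advisory and no
  reprojection is performed.
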