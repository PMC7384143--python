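# Methods

This note documents the models, conventions and design choices behind
`leafprod`, in the order the pipeline applies them.

## Grid and community means

Analysis happens on a planar grid of square cells (default 50 km,
kilometre coordinates, no CRS handling — the method is
projection-agnostic and real-data work should project upstream).  Cell
membership is half-open (a point on a shared edge belongs to the
higher-index cell), indices are 0-based, and `cell_id = j·nx + i`; these
conventions are fixed so tests can be bit-exact.

Floras report leaf dimensions as min–max ranges.  The per-species
"median" is taken as the range midpoint — the defensible reading when no
measurement sets exist — and "maximum" as the upper bound; both are
supported so robustness to the choice can be checked.  Leaf area is
approximated by (2/3)·length·width, the standard elliptical-shape
correction (3/4 is available for more rhomboid leaves).  The community
value of the length–width product is the mean over species of
species-level products, not the product of community means.

Community means are unweighted arithmetic means over the species present
in a cell: fossil assemblages carry no abundances, so an
abundance-weighted mean would not transfer to the palaeo use case.
Life-form subsets filter on habit (tree/shrub/liana) and phenology
(deciduous/evergreen); a species with unknown phenology still counts in
habit-only subsets.  Cells with fewer than 20 species are removed before
any regression (the boundary cell with exactly 20 is kept), to avoid
small-sample noise in the community means.

Ranked-year aggregation (mean of the m highest/lowest yearly values,
m ∈ {2, 4, 8}) sorts each cell's year stack; ties are broken by year
order, which cannot change the mean.

## Model families

Five candidate families link a predictor to a response: linear
y = a + b·x, sqrt-linear √y = a + b·x (whose R² is reported on the sqrt
scale and flagged), exponential y = a·bˣ, power y = a·xᵇ, and logistic
y = K/(1 + e^(α − r·x)).  Nonlinear families are fitted by least squares
from a log-linearised warm start (logistic: K₀ = 1.05·max y, then
regress ln(K₀/y − 1) on x), with three jittered, seeded starts for the
logistic and the best SSE kept; the fitted SSE never exceeds the warm
start's.  During optimisation K is bounded below by max(y)·(1 + 10⁻⁶)
(keeping the linearisation defined) and above by 50·max(y): an
asymptote far above the data means the logistic is indistinguishable
from its rising limb on the observed range, and an unbounded K sends
the optimiser down a flat valley.  Both multipliers are module
constants.  R² is 1 − SSE/SST on the raw response scale (except
sqrt-linear) and may be negative for non-nested predictions, e.g. a
fixed model applied to another region.  The logistic family only rises
(r > 0); where a relationship is decreasing (e.g. leaf size vs.
radiation) the pipeline falls back to the linear family and carries the
correlation's sign.

## Transfer functions

The transfer function is the functional inverse of the logistic trait
response: y = (1/r)(α − ln(K/x − 1)) for 0 < x < K, so K is an upper
bound on the *trait*.  Cells whose trait reaches the fitted K are
excluded and the model refitted, up to five rounds, with the exclusion
count reported — so the usable-cell count can differ between rows, and
whether exclusion is one-shot or iterative is a documented choice here
(iterative).  Out-of-domain predictions return missing values with a
warning, never a clamp to the asymptote.  Accuracy metrics are
SE = √(Σ(y_est − y_real)²/(n − 1)) and SE% = 100·SE/range(y_real);
cross-region comparison regresses *observed on predicted*, so an
unbiased transfer has slope 1 against the 1:1 line even when the
observations are noisy (the reverse regression would be attenuated by
the noise in the conditioning variable).  Models serialise to JSON and
can be fitted in one region/run and applied in another.

## Spatial statistics

Significance of trait–climate and trait–productivity correlations uses
the modified t-test: effective sample size
M̂ = 1 + tr(BΣ̂_A)·tr(BΣ̂_B)/tr(BΣ̂_A BΣ̂_B) with B = I − 11ᵀ/n, then
t = r·√((M̂−2)/(1−r²)) on M̂−2 degrees of freedom.  Σ̂ are filled from
distance-class correlograms: pairwise distances binned into equal-width
classes (default count by Sturges' rule on the number of pairs; empty
classes merge into their lower neighbour), a Moran-type autocorrelation
estimated per class, negative estimates retained, diagonal 1.  M̂ is
clamped to (2, n] with a flag; identity covariances recover the
classical test (M̂ = n) exactly.  The class count and maximum lag are
configuration, since no canonical values exist.  Fig-1-style correlation
grids apply a Bonferroni-corrected α = 0.05/48 by default (divisor
configurable).

Hierarchical partitioning fits all 2^k − 1 subset regressions (k ≤ 8
enforced — beyond that the cost doubles per predictor and an
approximation would be silent); the independent effect of predictor i
averages, over subset sizes, the mean R² increment from adding i.  The
independent effects sum exactly to the full-model R².  The three-way
commonality (Venn) decomposition solves the 7×7 linear system expressing
each subset R² as the sum of the components its predictors touch;
components can be negative under suppression and are reported as-is, and
they always sum to the full R².  The soil composite is the first
principal component of z-scored pH, organic carbon and cation exchange
capacity, with the organic-carbon loading constrained non-negative.

## Phylogenetic signal

Blomberg's K uses the phylogenetic covariance matrix V of shared
root-to-MRCA path lengths: with GLS mean â, K is the observed
MSE0/MSE ratio divided by its Brownian expectation
(tr V − n/ΣV⁻¹)/(n − 1).  K is affine- and tip-order-invariant; a star
tree returns exactly 1; the implementation matches an independent
phylogenetics reference (R `phytools::phylosig`) to 10 significant
digits on a fixed 5-taxon case.  Significance is a permutation test of
trait values across tips, p = (1 + #{K_perm ≥ K_obs})/(n_perm + 1).
Zero-length terminal branches receive ε = 10⁻⁸ Myr before inversion.
Clade ages are stem ages read from node heights; per-cell mean clade age
averages over *species* (three congeners of a 40-Myr genus contribute 40
three times).  The age × leaf-size interaction model z-scores all
predictors before building the product term, so the interaction sign is
directly interpretable.

## Piecewise SEM

Each endogenous node of a DAG is fitted by OLS on its parents after
transforms (GPP/NPP square-root by default) and z-standardisation, so
single-parent coefficients equal Pearson correlations.  The three study
topologies are saturated, so no d-separation goodness-of-fit is run;
inference is on path coefficients, with classical OLS p-values (a
spatially corrected variant is a possible extension, off by default
since the convention is unsettled).  Indirect effects are exact sums of
path products over all directed paths of length ≥ 2; total = direct +
indirect, and for a correctly specified chain the total matches the
simple regression coefficient at large n.

## Synthetic generator

The generator is the package's stand-in for floras, atlases and
remote sensing, and its defaults define the study conditions:

* **Climate**: Gaussian random fields with exponential covariance
  C(d) = sill·e^(−d/range), simulated exactly by Cholesky on the
  cell-centre distance matrix (fine to ~5000 cells; an FFT-based
  simulator would be the upgrade path for larger grids).  Defaults: MAT
  8 ± 7 °C (range 400 km), MAP 800 ± 450 mm (500 km), SRAD 1.5 ± 0.35
  kJ cm⁻² day⁻¹, three soil fields at 250 km.  Derived surfaces:
  PET = 58.93·max(MAT, 1) (a Holdridge-style energy-demand proxy),
  AET = min(MAP, PET) — deterministic and monotone in both supply and
  demand — and AI = MAP/PET.
* **Species pool** (400 species): median leaf length log-normal
  (median 5 cm, log-sd 0.4), truncated above at 11 cm so that every
  community mean stays strictly inside the x < K domain of the
  generating transfer function; flora-style min–max ranges are the
  median ± a uniform 20–60% fraction; width = length × 0.45 with 0.15
  log-sd ratio noise.  The AET niche optimum rises 300 mm per sd of
  log leaf length plus 100 mm noise — encoding selection for small
  leaves where water or energy is scarce — with Gaussian niche kernels
  of 250 mm breadth.
* **Ranges**: Bernoulli presence with kernel probability; every species
  is guaranteed ≥ 1 cell (resampled, then pinned to its best cell).
  Presence is sampled, not thresholded, to create realistic richness
  gradients; the ≥ 20-species filter is *not* pre-enforced so the
  downstream filter has real work to do.
* **Productivity**: GPP and NPP from community mean leaf length through
  the published transfer parameters (K = 11.602, α = 1.470, r = 0.002
  for GPP–length, etc.), plus Gaussian noise with sd = 8% of the
  noiseless range — the level that reproduces SE% near 8–9% and refit
  R² near 0.8.  The noise structure (additive Gaussian on the
  productivity scale) is an assumption, exposed as configuration.  NPP
  is capped at GPP and both floored at 0.  Optional 16-year stacks add
  i.i.d. year effects (no temporal autocorrelation — ranked-year means
  don't need it).  LAI is a saturating, noisy function of AET.
* **Phylogeny**: birth–death trees (0.15/0.05 per Myr) via dendropy;
  tip traits are w·(Brownian motion) + (1−w)·(white noise) with both
  components variance-matched, so w = 1 gives E[K] ≈ 1 and w = 0 gives
  K ≈ 0.  The species pool's leaf sizes themselves carry no tree
  structure, so the pipeline's signal test on them correctly finds
  none — matching the expectation that leaf size is evolutionarily
  labile; the tunable-signal trait simulator exists to calibrate the
  K machinery itself.
* A second region is an independent draw from the same scenario with a
  different seed; all randomness flows from the scenario's master seed
  through named substreams.

Zero-noise validation generates each transfer row's productivity from
that row's own trait measure: the three trait measures are not exact
functions of one another across cells (community composition varies),
so only the generating trait can refit to R² = 1 — per-row generation
is what makes the round trip a sharp test of the fitter rather than of
composition noise.

## What the synthetic tests do and do not show

Passing tests demonstrate that the estimators recover what the
generator put in, at realistic autocorrelation, noise and sample sizes
— not that real floras behave this way.  The generator omits abundance
structure, intraspecific trait variation, range-map polygon error,
spatially structured productivity retrieval error, temporal
autocorrelation, and real floristic/phylogenetic composition.  The
trait–climate coupling it induces is cleaner than nature's (logistic
R² ≈ 0.99 for length–AET vs. high-0.8s in real compilations), so
absolute R² values are generator properties; the recovery,
calibration and identity results are the transferable content.  K of
the transfer function is weakly identified when community means stay
well below the asymptote — refits at the 8% noise level scatter a few
per cent around the generating K, which is inherent, not a fitter
defect.

## Problem sizes

Default grids are 40 × 30 cells (1 200) for the pipeline and tests,
60 × 50 (3 000) for transfer recovery and 50 × 40 (2 000) per region
for cross-region checks; calibration runs use 1 000 field pairs on a
15 × 15 grid and 200 trees of 100 tips.  These sizes put every
Monte-Carlo band well inside its tolerance while keeping a full run in
minutes on one CPU.
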