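# Methods

This note documents the models, conventions and numerical choices behind
`betascale`, in the spirit of a statistical package's methods appendix. It
states no empirical claim that the test suite or `scripts/acceptance.py`
does not itself compute.

## Study design

The package analyzes a stem-mapped rectangular plot at a series of square
sampling grains, holding the extent fixed. The default study conditions are
a 260 × 200 m (5.2 ha) plot and grain sizes 20, 30, 40 and 50 m, which tile
the plot into 130, 48, 30 and 20 grains covering 5.2, 4.32, 4.8 and 5.0 ha
respectively (grain widths other than 20 m do not divide the plot exactly;
the remainder strips at the high-x/high-y edges are discarded, lower-left
anchoring being chosen for determinism). Coordinates are half-open in every
grain, `[x0, x0+g) × [y0, y0+g)`, so each stem belongs to exactly one grain.
Only stems with dbh ≥ 1 cm are admitted (the census rule of large
forest-dynamics plots); the analysis itself is abundance-based and never
uses dbh.

## Beta diversity as total variance

Abundances are Hellinger-transformed row-wise and beta diversity is the
unbiased total variance `BD_Total = SS_Total/(n−1)`, with local
contributions `LCBD_i = SS_i/SS_Total`. Two algebraically equivalent forms
of `SS_Total` (column-centered deviations, and the mean of squared pairwise
Euclidean distances over n) are both implemented and asserted equal to
1e-10 in the tests. Grains with zero stems have no defined transform; they
are dropped with a warning by default (`on_empty="drop"`; an `"error"`
policy is available). Dense plots make this moot, but sparse synthetic
communities can produce empty grains. LCBD significance is not computed —
the package maps raw LCBD values only.

## Spatial eigenvectors (PCNM)

The PCNM basis follows the classical construction: truncation distance t
defaults to the longest edge of the Euclidean minimum spanning tree of the
grain centroids (the smallest t keeping the site graph connected);
distances above t are replaced by 4t; the matrix −½D*² is Gower-centered
and eigendecomposed. Retained vectors must have an eigenvalue above
1e-8 × the largest eigenvalue and Moran's I (binary connectivity weights
within t) above the permutation-null expectation −1/(n−1). Eigenvector sign
is fixed by making the largest-magnitude loading positive, so outputs are
reproducible across linear-algebra backends; columns are unit norm. The
eigenvalues and positive-eigenvalue set are cross-checked against an
independent reference implementation in the test suite.

## Constrained ordination and inference

RDA is multivariate least squares of the column-centered community table on
standardized predictors; `R²` is measured against the total variance of Y
and adjusted with the Ezekiel formula. Partial RDA residualizes both Y and
X on the conditioning set and reports the semipartial `R²` (still against
the total variance of Y). Permutation tests permute rows of Y directly, or
residuals of Y under the reduced model when a condition is present, with
the add-one p-value estimator `(1 + #{F* ≥ F})/(1 + n_perm)`. `n_perm`
defaults to 999 and every stochastic routine takes an explicit seed.
Degenerate fits (zero residual variance) report `p = 1/(1+n_perm)` with a
flag.

Forward selection uses the double-stopping rule: a global permutation test
of the full candidate set gates the procedure (nothing is selected when the
global p exceeds α); each step adds the candidate with the largest
additional explained variance if its residual-permutation partial test
passes α; and, with the ceiling enabled (the default), a candidate pushing
the cumulative adjusted R² past the global model's adjusted R² is rejected
and selection stops. Ties in partial R² break by candidate input order.

One caveat discovered while validating the ceiling rule, and worth knowing
before reusing it: when a small true predictor set explains nearly all
variance and the remaining candidates are noise, the global model's
adjusted R² is *diluted* by the noise candidates and sits, in expectation,
exactly at the true model's adjusted R² — so the ceiling rejects the final
informative variable about half the time. The condition is scale-free in
R² (it reduces to whether the noise share of the residual falls below
m_noise/(n − m_true − 1), whose expectation equals that threshold). The
package therefore exposes `use_ceiling` and the recovery tests of the
α-stopping rule run with the ceiling disabled; the ceiling keeps its own
behavioral test and remains on by default in the pipeline, where explained
variance is far from saturation and the rule acts as intended (a guard
against overfitting the selection).

Environmental predictors are standardized (z-scores) before selection and
ordination; PCNM vectors are used as produced (centered, unit norm). When
the selected environmental and spatial sets would saturate the joint model
(n ≤ m_E + m_S + 1, possible at the 50 m grain with only 20 grains), the
spatial set, then the environmental set, is trimmed in selection order with
a warning.

## Variation partitioning

Fractions are computed on the adjusted-R² scale from three plain fits
(ab, bc, abc) and differenced; additivity `a + b + c + d = 1` is exact by
construction. Environment is read as `[a+b]` and space as `[c]`, with both
raw fractions also reported. Fraction `[b]` has no standalone test and may
be negative (an adjusted-R² artifact); it is reported as computed and only
floored at zero in bar-chart rendering, with the raw value annotated.
Tested fractions: `[a+b]` (rows of Y permuted against E), `[c]` and `[a]`
(residual permutation under the other set), and the joint model.
Significance codes follow the usual convention (\*\*\* p < .001,
\*\* p < .01, \* p < .05). Forward selection runs separately within the
environmental candidates and within the PCNM candidates, not on the pooled
set, mirroring the study design the package implements.

The multi-grain driver derives a deterministic random substream per grain
size from (master seed, grain size), so any grain size reruns identically
regardless of which others are requested.

## Synthetic data: what it emulates, and what it does not

The generator stands in for field data from a temperate montane forest
census plot. Defaults: 40 species, 15,000 stems on 260 × 200 m (within the
10,000–30,000 stems and 20–70 species range typical of such plots), six
soil surfaces (organic matter %, pH, total N, P, K in p.p.m., rootable
depth in cm, clipped to 10–130 cm) and an elevation surface. Surfaces are
stationary Gaussian random fields with exponential correlation
`exp(−d/range)` (e-folding ranges: 60 m for soil chemistry, 80 m for
rootable depth, 150 m for elevation, plus a gentle planar trend on
elevation so slope and aspect are informative), simulated by Cholesky
factorization on a 10 m lattice and evaluated by bilinear interpolation.

Stem placement mixes two processes per species with weight `w`
(`mixture_weight`): an environmental-filtering intensity
`exp(Σ_v β_sv z_v(x,y))` with coefficients `β_sv ~ N(0, niche_strength²)`
on the standardized environment, and a Thomas cluster density (Poisson
parents at 4 × 10⁻⁴ per m², Gaussian kernel sd 12 m — heavy-seeded,
gravity-dispersed trees cluster at about this scale). Species totals follow
a lognormal abundance distribution (σ = 1); dbh is exponential with mean
8 cm shifted to the 1 cm census floor. `w = 0, niche_strength = 0` is
complete spatial randomness. Canonical scenarios: `random` (0, 0),
`pure_env` (niche 1.2, w 0), `pure_dispersal` (niche 0, w 1), `mixed`
(niche 1.0, w 0.5). All outputs are pure functions of (parameters, seed).

Not emulated: demography between censuses, interspecific interactions,
topography-dependent dispersal, measurement error in soil chemistry, and
core-level soil replication (the environment table stores per-grain
averages only). Passing tests on these data show the *method* recovers
known structure of this generative family; they cannot show how large the
fractions would be in any real forest.

## Environment upscaling

Soil variables measured per 20 m grain are carried to coarser grains either
by `block_mean` (average of the base samples whose centers fall in the
target grain — the default, exactly mean-conserving on nested designs) or
by `kriging`: a first-order polynomial trend is removed, the residual
empirical semivariogram (12 distance bins up to half the maximum distance)
is fitted with a nugget + exponential model by weighted least squares
(Cressie weights, pair counts over squared model values), residuals are
ordinary-kriged to the target grain centers, and the trend is added back.
Coincident sample/target points pass through exactly. The kriging module is
a documented in-package implementation, configurable rather than canonical:
on these smooth fields its RMSE advantage over block averaging is real but
small (the tests assert the ordering on exactly-simulated exponential
fields). Topography per grain follows large-plot conventions: mean of the
four vertex elevations; slope as the mean angle of the four
drop-one-vertex triangular planes; aspect as the downslope bearing of the
least-squares plane, degrees clockwise from north, with flat grains
encoded as 0 plus a flag (the flag is excluded from predictors); convexity
as the grain's mean elevation minus the mean of its up-to-8 neighbors.
Vertices absent from the 20 m lattice (30 and 50 m designs) are
bilinearly interpolated.

## Problem sizes and tolerances in the test suite

Structural and algebraic identities are tested exactly (1e-10 to 1e-12).
Stochastic properties use fixed seeds and deliberately modest Monte-Carlo
sizes chosen to keep the default run short while leaving comfortable
margins: 20 replicate communities for the BD-vs-grain monotonicity and the
two process-recovery directions (thresholds at 18/20), 100/50 seeds for
forward-selection behavior, 500 null simulations × 199 permutations for the
type-I calibration (accepted band 0.03–0.07 at α = 0.05), and 50 replicate
fields for the kriging comparison. Permutation counts inside the heavier
end-to-end checks use 199 permutations rather than the 999 default; the
add-one estimator keeps the tests valid at either count.

## Known limitations

* The RDA machinery covers explained variance and permutation inference
  only — no canonical axes, site/species scores, or biplots.
* PCNM weighting is fixed to the classical binary-truncation form;
  asymmetric or general-weight Moran eigenvector maps are out of scope.
* The variogram model is fixed to nugget + exponential; anisotropy is not
  modeled.
* Aspect enters the predictor set in raw degrees; on strongly structured
  terrain a sine/cosine decomposition would be preferable.
* With 20 grains at the 50 m grain, selection and partitioning run but are
  small-sample; the driver warns below 10 grains and trims saturated
  selections as described above.
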