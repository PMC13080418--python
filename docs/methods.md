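# Methods

## Model

Responses are ordinal categories from a multidimensional normal-ogive
graded response model on the underlying-variable metric. Item *i* with
loadings `lambda_i` (factor 1 = general), thresholds `tau_i1 < ... <
tau_i,K-1`, factor correlations `Phi` and uniqueness
`psi_i = 1 - lambda_i' Phi lambda_i` has boundary curves

    P(X_i >= c | theta) = Phi((lambda_i' theta - tau_ic) / sqrt(psi_i)).

This is exactly the model implied by a factor analysis of polychoric
correlations, which is why the pipeline estimates thresholds and loadings
on that metric throughout and converts to logistic parameters (scaling
constant D = 1.702) only for reporting.

### Marginalization

Conditioning on the general factor t, the specific factors are normal
with mean `Phi_21 t` and covariance `Phi_22 - Phi_21 Phi_12`. Because the
ogive link is a normal CDF, integrating them out is closed-form: the
marginal boundary curve is again an ogive with slope `alpha = lambda_g +
lambda_s' Phi_21` and scale `sigma^2 = psi + lambda_s' (Phi_22 - Phi_21
Phi_12) lambda_s`, reported as discrimination `a* = alpha/sigma` and
locations `b*_c = tau_c / alpha`. With orthogonal factors the marginal
discrimination is strictly smaller than the conditional one whenever
specific loadings are nonzero — the practically important "shrinkage"
that makes marginalization necessary before comparing inventories.
Items with `alpha < 0` are reverse-coded (negated slope, reversed
thresholds); Fisher information is invariant to that recoding. The
closed form is verified against a Gauss–Hermite quadrature oracle
(nuisance factors collapsed to their single sufficient direction) to
well below 1e-6 across random items with 2–9 correlated factors.

### Information statistics

For marginal category probabilities `pi_c(t)`, point item information is
`I(t) = sum_c (d pi_c/dt)^2 / pi_c`; test information adds items; total
information is the Gauss–Legendre integral of a point curve over
[-6, 6] (101 nodes by default; both are config keys, and widening to
[-8, 8] moves totals for centrally located items by well under 0.5%);
averaged total information divides by the item count; StdEM(t) =
1/sqrt(I(t)). Tail category probabilities are computed on the survival
side of the link so that near-cancelling CDF differences cannot
underflow to zero while their derivatives remain finite.

## Estimation pipeline

* **Polychorics.** Two-step ML: thresholds from inverse-normal cumulative
  margins, then a bounded 1-D likelihood optimization (|rho| <= 0.999,
  tolerance 1e-8) of the bivariate-normal rectangle probabilities,
  computed from the arcsin single-integral representation of the
  bivariate normal CDF with rho-adaptive Gauss–Legendre quadrature
  (machine-precision against reference CDF values up to |rho| = 0.999).
  Pairwise-complete observations; per-pair n recorded. A top category
  with fewer than 3 observations is merged downward before estimation
  (the convention applied to rarely endorsed extreme categories, e.g. an
  aggression item with two observations in its top category); the rule
  is applied uniformly to every item rather than ad hoc. If the
  assembled matrix is not PSD it is repaired by eigenvalue clipping at
  1e-6 and rescaling to unit diagonal, flagged `smoothed`.
* **Dimensionality.** Eigendecomposition of the polychoric matrix as %
  covariance explained. Parallel analysis builds null data by
  independently permuting each item's column — preserving every ordinal
  margin exactly — and re-estimating the polychoric matrix per replicate
  (default 100, criterion = component-wise mean; 95th percentile
  optional). Change scores (post minus pre) take up to 2K-1 levels and
  are treated as numeric: their correlation matrix and parallel analysis
  use Pearson correlations.
* **Bifactor EFA.** Minres extraction (L-BFGS-B over uniquenesses with
  loadings profiled out via the reduced-matrix eigendecomposition;
  communalities capped at 0.995 with a Heywood warning). Rotation
  minimizes the bifactor-geomin criterion — geomin complexity
  (epsilon = 0.01) on the specific columns, column 1 unpenalized — by
  oblique gradient projection, taking the best of 30 seeded random
  orthonormal starts (identity first) since geomin-type criteria have
  local minima. The general factor is identified post hoc as the column
  with the most absolute loadings >= 0.20, moved first, and all columns
  sign-aligned to positive loading sums. The stability screen flags
  items with any |loading| > 1.5 or communality >= 0.97 and the pipeline
  refits without them. The general factor's covariance share
  orthogonalizes oblique columns by the Cholesky factor of Phi with the
  general factor ordered first, which credits general–specific overlap
  to the general factor — the same attribution the marginalization makes.
* **Bootstrap.** Persons resampled with replacement; polychorics through
  the information profile recomputed per resample with k fixed at the
  point estimate (re-running factor-count selection would conflate model
  and sampling uncertainty). Each resample's factors are matched to the
  point-estimate loadings by maximal absolute Tucker congruence
  (Hungarian assignment) with sign correction, because rotation
  indeterminacy would otherwise invalidate percentile intervals.
  Resample rotations use 2 starts (the criterion surface near the
  point estimate is well explored by the 30-start point fit). 95%
  percentile CIs; a statistic is flagged skewed when its point estimate
  falls outside the central third of its interval. Items degenerating to
  a single observed category in a resample are dropped from that
  resample and logged.

## Synthetic cohort

The generator emulates a psychotherapy quality-registry item pool:
51 unique ordinal items — 34 five-category CORE-OM items (10 of them the
embedded CORE-10 subset), 9 four-category PHQ-9 items, 5 five-category
OASIS items, 3 five-category AUDIT-C items — with n = 5000 pretreatment
respondents, 59% of whom complete posttreatment. The generating model is
an orthogonal bifactor structure: one general internalizing factor plus
eight specific factors (anxiety — loading all OASIS items, depression,
alcohol, risk, functioning, wellbeing, social, somatic). General loadings
of loading items are uniform on [0.4, 0.85]; AUDIT-C and the two
CORE-OM aggression items have zero general loading. Specific loadings
take 0.65–0.9 of the admissible residual scale sqrt(0.9 - lambda_g^2)
and alternate in sign within each block. The mixed polarity emulates
wording/method effects (the long form mixes problem- and
wellbeing-phrased items) and is also what keeps all nine generating
dimensions mutually distinguishable: with uniformly positive specifics
the "general minus average specific" direction becomes near-degenerate
and no estimator — parallel analysis included — could see the ninth
dimension. All loadings and thresholds were drawn once under a fixed
build seed and are frozen in code, so the true model is a deterministic
package constant. Thresholds sit near equal category occupancy with
mild dispersion; the alcohol items are skewed toward zero and the
aggression-item analogue has an essentially empty top category at
cohort sizes, exercising the truncation rule.

Posttreatment, the general factor shifts by -(0.8 + 0.5 Z) SD per person
(mean effect plus normal heterogeneity); residuals are redrawn; specific
factors do not change; dropout and any item-level missingness are
completely at random. Consequently change scores contain exactly one
systematic dimension, and the change-score analyses on synthetic data
show a single, relatively weak first component — weaker than real
registries, where specific symptoms also change. Other features of real
data the generator does not emulate: informative dropout, demographic
heterogeneity, cross-loadings, local item dependence, and longitudinal
parameter drift. Passing recovery tests therefore show the estimation
chain is correct under its own model, not that the model captures every
property of registry responses.

## Scale of the shipped analyses

The analysis scripts and acceptance checks run at n = 5000 for the
recovery chain (matching the registry's order of magnitude) and use a
reduced design — n = 500 persons, the 20-item short-form/OASIS/PHQ
subset, B = 100 — for the bootstrap demonstration, with B = 1000 and the
full pool available by flag; these sizes are the package's default
desk-scale configuration.

## Known limitations

* Only oblique bi-geomin rotation is implemented (orthogonal bifactor
  solutions arise as the special case Phi = I that the rotation reaches
  when the data support it); there are no target or Schmid–Leiman
  rotations and no confirmatory models.
* The fitted k counts the general factor among its columns (a
  "nine-factor" model is one general plus eight specifics).
* No standard errors for individual polychoric correlations; inference
  is carried entirely by the bootstrap.
* `stability_screen` is a heuristic for extreme/Heywood estimates; it
  does not detect every form of instability (e.g. sign-flipping across
  resamples shows up in the bootstrap congruence instead).
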