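# Methods

This note documents the statistical procedures implemented in `qsarws`,
the conventions adopted where the workflow's published description leaves
details open, and what the synthetic-data tests do and do not demonstrate.

## Endpoint and data model

The activity endpoint is pIC50 = −log10(IC50 · 10⁻⁶) for IC50 given in
micromolar; higher values mean more potent inactivation. A compound either
carries a positive IC50 or is *censored* (it failed to inactivate the
target at the highest tested concentration): exactly one of the two, never
both. Censored compounds keep their descriptors and serve as query-only
(true external) material. Missing descriptor cells are a hard error — the
workflow performs no imputation. Duplicate compound ids are rejected at
load time; de-duplication of salts/hydrates is the data preparer's job.

Activity-cliff response outliers are supplied as an explicit id list, not
auto-detected. The workflow that motivated this package identified them
iteratively as compounds that were persistently response outliers across
splitting schemes; no closed-form criterion exists, so guessing one would
create false confidence.

## Descriptor pruning

Two filters, in order: (1) columns whose modal value occurs in strictly
more than 80% of compounds; (2) scanning column pairs in input order,
whenever |Pearson r| > 0.95 the *later* column is dropped. The tie-break
(drop the later column) is a convention chosen for reproducibility; the
result is idempotent and leaves no surviving pair above the cut.

## Splitting schemes

All three schemes target ~3:1 training:prediction and force the extreme
compounds into training so that prediction is interpolation:

- **ORes** sorts by decreasing pIC50 and sends every fourth compound,
  starting from the second, to prediction; a selected compound holding the
  global maximum or minimum response is moved back to training.
- **OStr** first sets the two response extremes aside into training, then
  sorts the remainder by PC1 score (correlation PCA of the autoscaled
  descriptor matrix) and selects every fourth from the second; selected
  PC1 extremes are moved back. Setting the response extremes aside *before*
  sorting — rather than moving them back after selection — makes the
  prediction-set size independent of where those extremes happen to land in
  PC1 order, so a 370-compound set always yields 278/92.
- **Random** forces the four extremes (max/min response, max/min PC1) into
  training and draws a fixed-size prediction set of floor((n − 4)/4)
  compounds without replacement; at n = 370 this gives 279/91. Fixed size
  (rather than per-compound Bernoulli sampling) reproduces those counts
  deterministically.

PC1 uses the correlation (autoscaled) form throughout, with the component
sign fixed so the largest-magnitude loading is positive.

## Regression and subset search

Models are ordinary least squares with intercept. Leave-one-out Q² is
computed through the deleted-residual identity e/(1 − h); the test suite
verifies the identity against a literal n-refit loop at 10⁻¹⁰.

The QUIK rule uses Todeschini's multivariate K index of a column block —
K = Σ|λⱼ/Σλ − 1/m| / (2(m−1)/m) over eigenvalues of the correlation
matrix — and accepts a candidate iff K of the descriptors-plus-response
block exceeds K of the descriptor block by at least 0.05. For two columns
K reduces to |r|, which the tests exploit as a closed form. A one-column
block has K = 0 by convention and the rule is skipped.

Variable selection seeds with an exhaustive scan of all two-descriptor
models, then runs a per-size genetic algorithm: tournament selection of
size 2 on Q²_LOO, uniform crossover over the union of the parents,
per-gene mutation at 20% by default, elitism of one, QUIK failures
discarded with fitness −inf. The headline parameters (generations per
size, population size, mutation percentage) default to 2000/200/20; the
remaining operators are this package's fixed conventions, since the
original tool does not publish its internals — no claim of
bit-compatibility is made. The p < n/5 descriptor cap is enforced at the
search level (and surfaced as `MLRModel.descriptor_cap_ok`), not inside
`fit_ols`, so that small diagnostic fits remain possible.

## Validation battery

- R² = 1 − RSS/TSS; R²_adj = 1 − (1−R²)(n−1)/(n−p−1); RMSE uses the 1/n
  convention so a perfect fit is exactly 0.
- Q²_LMO holds out 30% per iteration (2000 iterations by default), scores
  held-out predictions against the *retained*-set mean, and averages; this
  per-iteration reference is a convention, chosen because the published
  description names no formula.
- Y-scrambling permutes the response, refits, and reports the *means* of
  R² and Q²_LOO across iterations; slightly negative mean Q² is the
  expected signature of a real model.
- External metrics: Q²_F1 scales the prediction error by the external
  deviance about the training mean, Q²_F2 about the external mean, Q²_F3
  compares per-compound error variances between sets; R²_pr is the squared
  Pearson correlation of predicted and observed external values; CCC is
  the concordance correlation coefficient with the conventions CCC = 1 for
  two identical constant vectors and 0 for constant-vs-varying.
- Golbraikh–Tropsha: k = Σyŷ/Σŷ², k′ = Σyŷ/Σy², through-origin
  determination coefficients R²₀ (observed on predicted) and R′²₀
  (predicted on observed); acceptability requires Q²_LOO > 0.5, R² and
  R²_pr > 0.6, at least one slope in [0.85, 1.15], and |R²₀ − R′²₀| < 0.3.

## Applicability domain

Leverage h = [1,x](XᵀX)⁻¹[1,x]ᵀ against the intercept-augmented training
design; warning leverage h\* = 3(p+1)/n counts the p+1 fitted parameters.
Standardized residuals divide by the training-fit RMSE (the scale
estimator is unspecified in the source description; training RMSE is
simple, reproducible, and consistent with the ±3 SD convention).
The Insubria graph applies the leverage criterion to queries without
experimental values and reports the coverage fraction. The PCA domain is a
rectangular PC1 × PC2 bounding box of the training scores (correlation
PCA); the box is this package's declared boundary for what the original
analysis showed only as a scatter plot.

## MCDM ranking

Each criterion maps to a linear desirability anchored at the best and
worst values across the candidate set (1 = best); the score is the
geometric mean. Fitting score: maximize R², R²_adj, CCC_tr, minimize
R² − R²_adj. External score: maximize Q²_F1/F2/F3 and CCC_pr. The
geometric mean preserves the 0/1 anchors and is the documented convention
of the QSARINS family of tools; a single candidate scores 1 by convention.

## Read-across and q-RASAR

Similarities are computed on descriptors autoscaled by training mean/SD:

- ED: s = 1/(1+d) with d the Euclidean distance — bounded, monotone, and
  1 at d = 0; the exact transform used by the original tool is unpublished,
  so this is a package convention, stated prominently;
- GK: s = exp(−d²/2σ²), default σ = 1;
- LK: s = exp(−γ·d₁) on the L1 distance, default γ = 1.

The prediction is the similarity-weighted mean of the six most similar
eligible training compounds (a convex combination, hence always within the
neighbour response range). Eligibility: distance at most
(distance threshold) × (maximum training–training distance), or similarity
at least the similarity threshold; the defaults (1 and 0) make both
non-binding, matching the published settings. Queries that *are* training
compounds are featurised leave-self-out, so a compound never borrows its
own response. Hyperparameter optimisation splits the training set 3:1
(seeded) and minimises subtest RMSE over a grid, ties keeping grid order.

q-RASAR concatenates the read-across features (RA prediction per kernel,
neighbour-similarity summaries) with selected 2D descriptors and refits by
the same OLS + validation machinery. The pipeline pairs the RA(ED) feature
with the leading descriptors of the selected structural subset, echoing
the published three-term q-RASAR structure, rather than re-running the
full subset search on the combined pool; callers who want the full search
can pass the combined feature table to `ga_vss` directly.

## Reliability scoring

Three rules per query: (a) leverage ≤ h\*; (b) similarity-weighted mean
absolute leave-one-out error of the six nearest training neighbours at
most 1.5× the training MAE; (c) predicted value inside the training
response range. All three → 3 ("Good"); at most one → 1 ("Bad or
Unreliable"); otherwise 2 ("Moderate"). The external tool that inspired
this composite does not publish its internals; this three-rule surrogate
is deliberately built only from quantities the other modules already
compute, and is monotone in every threshold.

## Synthetic data generator

The generator emulates the study-shaped dataset: 436 compounds = 370
modeling + 49 censored + 17 activity cliffs; nine descriptors named and
ranged like the published model's (continuous uniforms, bounded counts,
one binary); a planted linear response on MATS6i, maxHBd and MDEN-12.
Coefficients (3.74, 3.20, 0.92) and intercept 2.78 are calibrated so the
*empirical* noiseless response span over 10⁴ draws is ≈ [2.2, 8.7] pIC50
units (a sum of bounded variables cannot reach its theoretical corners, so
the corner span is set ~3% wider per side). The default noise SD of 0.95
puts the planted model's population R² near 0.6, the regime the validation
statistics are designed to discriminate. Cliff compounds have their
response displaced by 3–5 noise SDs in a random direction — response
outliers, not structural ones. Censored compounds keep descriptors and no
endpoint.

What the generator does **not** emulate: inter-descriptor correlation
structure (columns are independent, so descriptor pruning is rarely
triggered on synthetic data), non-linear structure–activity relationships,
heteroscedastic assay noise, and chemically meaningful descriptor joint
distributions. Passing tests on this generator therefore demonstrate the
correctness and calibration of the *statistical machinery*, not predictive
performance on real chemistry.

## Numerical choices and degenerate inputs

- Stable sorts everywhere ties can occur (splitting, neighbour ranking),
  so input order is the deterministic tie-break.
- PCA signs fixed by the largest-magnitude loading.
- Rank-deficient designs raise rather than silently pseudo-inverting.
- Leverage 1 makes a deleted residual undefined and raises.
- Zero-variance response raises for any Q²-type statistic; zero-variance
  descriptor columns are dropped (with a warning) before scaling.
- Degenerate leave-many-out subsamples are skipped and the iteration count
  reduced accordingly; an all-degenerate run raises.
- One global seed fans out to per-stage seeds through a fixed affine map,
  so each pipeline stage is independently reproducible.

## Problem sizes

The default test and acceptance runs use the study-scale dataset (n = 436)
with the genetic algorithm at 15–30 generations and populations of 30–40
over the nine-descriptor pool — ample for a pool where the size-3 subset
space has only 84 elements — and 200–2000 resampling iterations depending
on the statistic. These sizes are the package's defaults for its own
verification; production use on larger descriptor pools should restore the
2000/200 GA settings.

## Known limitations

- The GA operators and the MCDM desirability shapes are this package's
  documented conventions, not reverse-engineered reproductions of the
  commercial tools' internals.
- The registry equations predict only for compounds whose descriptors are
  computed by the same external software (Dragon/PaDEL conventions);
  descriptor calculation itself is out of scope.
- The leverage AD assumes the linear model's design geometry; it does not
  detect interpolation gaps inside the descriptor hull.
- Read-across thresholds are calibrated for autoscaled spaces; mixing
  unscaled features will silently distort neighbourhoods (the API prevents
  this by scaling internally).
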