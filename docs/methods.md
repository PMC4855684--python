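# Methods

`dyadqap` implements a staged analysis of resource allocation within
small, completely mapped social networks (classrooms): questionnaire
scoring into valued sociomatrices, bootstrap comparison of network
descriptives, permutation-based dyadic regression within and across
networks, and directional backward elimination. This note documents the
statistical model, the permutation constructions, the synthetic-data
generator, and the numerical conventions, together with their known
limitations.

## Data model

All dyadic quantities live in a `DyadicMatrix`: an n×n valued matrix over
an ordered actor list with a structurally masked (NaN) diagonal.
Self-ties are never analysed; self-allocations are carried separately as
a per-actor scalar. Off-diagonal NaN means *missing*, which is distinct
from zero — zero is a meaningful point on the link-weight scale, so dyads
absent from a response table are never silently zero-filled.

Relationship strength is scored by summing an ego's strength-item
responses toward an alter and dividing by the maximum possible summed
score (the schema divisor): 8 for the five-item schema (three binary
items, relationship nature in −1…4, relative trust in −1…1), 9 for the
six-item schema that adds a conflict-resolution item in −1…1. Link
weights therefore span [−0.25, 1] and [−1/3, 1] respectively. The
reciprocation matrix is R = Sᵀ − S: cell (i, j) is positive when the
alter reports a stronger tie toward ego than ego reports back. R is
antisymmetric by construction, so its off-diagonal total is identically
zero. Actor attributes enter as "giving" matrices (value broadcast along
rows: a sender effect) and "receiving" matrices (along columns: a
receiver effect).

Vectorization stacks the n(n−1) ordered off-diagonal dyads in fixed
row-major order. Rows with any missing value are dropped listwise with a
reported count before model fitting; the original handling of incomplete
attribute data in the source software is unknown, so listwise deletion is
this package's own convention.

## Density comparison

The valued density of a network is the mean of its off-diagonal cells.
Because every actor contributes to 2(n−1) cells, cell-level standard
errors are invalid; SEs come from the vertex bootstrap: each replicate
resamples n actors with replacement, the cell for a resampled pair
mapping back to distinct originals (i, j) is the observed cell, and a
*diagonal collision* (the same original actor in both slots) is filled by
a uniform draw from that actor's own off-diagonal row and column values.
The cited bootstrap method does not fix the collision rule; this fill
keeps replicate matrices fully valued and replicate densities unbiased
for the observed density on complete matrices. Two networks are compared
with t = (d₁ − d₂)/√(SE₁² + SE₂²) on the dyad-count degrees of freedom
n₁(n₁−1) + n₂(n₂−1) − 2 (e.g. 846 for classes of 23 and 19); variances
are unpooled because each SE is already network-specific. With more than
two networks all pairs are tested and the significance level is divided
by the number of pairs (Bonferroni), alpha/m applied literally.

Default n_boot = 1000 (overridable); bootstrap SEs for networks of this
size stabilise well below that. Seeds are mandatory in the CLI.

## Single-network MRQAP with double semipartialing

Point estimates are ordinary least squares on the vectorized dyads and
are interpreted as in OLS; only the inference changes. Standardized
coefficients are b·sd(x)/sd(y) over dyad vectors; adjusted
R² = 1 − (1 − R²)(N − 1)/(N − k − 1) with N the retained dyad count.

The permutation null respects actor exchangeability: matrices are
permuted by relabelling actors, i.e. one permutation applied jointly to
rows and columns (`permute_square`), which maps off-diagonal cells to
off-diagonal cells and preserves the dyadic dependence structure. For
each focal predictor the double-semipartialing (DSP) construction is
used: residualize the focal predictor on all other predictors (plus
intercept) over the observed dyad rows; reshape the residuals to a
matrix; for each of n_perm draws relabel that matrix's actors and
re-estimate the focal coefficient of the outcome on {other predictors,
permuted residual matrix}. The description of the procedure in the
applied literature ("residuals resulting from the regression are
permuted") is ambiguous about *which* residuals; residualizing the focal
predictor is the variant of the original methods work and of the widely
used network-analysis software, and is what is implemented here. Where
dyads are missing, residual matrices carry 0 (the residual mean) in
unobserved cells so permutation stays well defined, and inference uses
only the originally observed rows.

P-values follow the exact-test convention p = (1 + #exceedances)/(n_perm
+ 1), so p is never 0 and is bounded below by 1/(n_perm + 1); with the
10,000-permutation default the floor is ~.0001, consistent with
"p < .001" reporting. Two-tailed tests compare |b*| with |b|; one-tailed
tests (applied exactly to the terms with a directional hypothesis:
strength +, reciprocation +, gender-giving −, Machiavellianism-giving −,
empathy-giving +, and flagged interactions) compare s·b* with s·b.
The model-level p compares the observed R² with R² under whole-matrix
relabellings of the outcome (classical QAP-Y), reusing the same
permutation stream as the term tests. Identity permutations drawn by
chance are kept, not redrawn. The batched implementation computes the
focal coefficient through the Frisch–Waugh–Lovell identity
b = ⟨ẽ, ỹ⟩/⟨ẽ, ẽ⟩ after projecting out the non-focal columns; a unit
test verifies exact agreement with a naive per-permutation loop.

## Multigroup MRQAP

Several classrooms are pooled: dyad rows stacked, one fixed-effect
intercept per class (a reference intercept plus 0/1 offsets, reported
"reference = first group"), slopes pooled. Group-level moderation is
tested by interaction predictors formed by multiplying a dyadic predictor
by the class's scalar code (0/1 for two classes; 0/1/2 across three year
groups, making the interaction slope linear in year group). Random
(variance-component) formulations are deliberately out of scope — the
design is fixed effects by class.

The null distribution permutes, independently within each class, the
rows and columns of that class's *dependent* matrix while all predictors
and intercept dummies stay fixed (block-restricted QAP-Y). The source
description ("permuting each of the two matrices", "a more efficient
permutation method … that tends to overestimate the size of the standard
errors") does not pin the scheme down; block-restricted outcome
permutation matches the description, respects the nesting of actors in
classes, and is measurably conservative in the package's own null
simulations (interaction rejection ≈ .01–.02 at nominal .05), consistent
with the stated conservatism. A within-block DSP variant
(`method="dsp"`) is provided for sensitivity analysis of the term tests.

Standardized coefficients are not reported for multigroup models: the
pooled outcome variance mixes between- and within-class variation, which
makes standardization misleading.

Caveat: block-restricted outcome permutations preserve each class's
outcome mean exactly, so the permutation "test" of an intercept is
near-degenerate (the reference intercept's p is ≈ 1 by construction).
Intercept p-values are reported only for table completeness; they are
never eligible for elimination and should not be interpreted as tests of
a zero intercept.

## Backward elimination

From the full model, the droppable term whose **two-tailed** p is closest
to 1 is removed and the model refit with a fresh permutation stream
(derived per step from a master seed); the drop criterion is two-tailed
even for directional terms, while the *significance* check
that stops elimination uses each term's assigned tail at alpha (.05
default). Two protections apply: a main effect is never dropped while
its group interaction is in the model, and terms named in
`forced_retention` (e.g. a reciprocation main effect kept so its group
interaction stays interpretable) are never dropped. Ties in the drop
criterion — possible at coarse permutation counts — are broken by
removing the term entered later in the initial ordering. Selection is
pure backward: no term re-enters. If every term is eliminated and the
engine cannot fit an empty model, the trace ends with no final model
rather than an error.

Re-fitting with full permutation inference after every drop is the
expensive-but-faithful choice (published footnotes report refit
p-values); a reduced n_perm is available for exploratory passes.

## Synthetic data

No real questionnaire data are available, so the generator produces
classroom studies with known ground truth. Its structure:

* **Latent affinities.** z_ij = a_i + b_j + d_ij with sender effect a_i,
  receiver effect b_j (15% of latent variance each) and a dyadic
  component d_ij (70%). The actor effects are essential: repeated
  involvement of each actor in 2(n−1) dyads is precisely the
  nonindependence that QAP and the vertex bootstrap exist to handle, and
  without it both procedures face a degenerate inference problem.
* **Reciprocity control.** The two directions of a dyad are correlated
  through the within-actor sender–receiver correlation and the dyadic
  pair correlation. Discretizing latents into items attenuates
  correlation, so the latent correlation is solved (bisection against a
  fixed 20,000-draw panel, deterministic internal seed) such that the
  *scored* link weights attain the requested reciprocity correlation; an
  unattainable request is clamped with a warning reporting the achievable
  value.
* **Items.** Every strength item is a fixed equal-probability
  quantile-threshold discretization of the dyad's latent, so weights
  always respect the schema bounds. Non-strength binary items are rare
  confounds (5% base rate); duration-type items are uniform.
* **Attributes.** Gender ~ Bernoulli(.5) coded 0/1; Machiavellianism
  total ~ round(N(54, 8)), matching the adolescent scale location and
  spread.
* **Allocations.** Y(i,j) = intercept_g + b_S·S + b_R·R + Σ b_a·A + ε,
  ε ~ N(0, noise_sd²), truncated below at 0 because point allocations are
  non-negative; each `name:group` beta shifts that predictor's slope by
  beta × group code. An optional 100-point budget renormalizes rows that
  exceed it and stores budget − row-sum as points-to-self; it is off by
  default because the regression models do not model the budget
  constraint.

Default conditions for the two-classroom study: n = 23 and 19 with codes
0/1; true coefficients at the published pooled point estimates (strength
4.82, reciprocation −0.17, reciprocation×group 2.64, gender-giving
−1.18; intercepts 2.58 / 2.35); reciprocity 0.5; noise SD 2 points.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: empirical link-weight distributions (real
weights are likely skewed and zero-inflated; the generator's are
quantile-symmetric), allocation zero-inflation beyond what truncation
induces, item-level measurement structure (items are deterministic
functions of one latent per dyad), missing-data mechanisms, and any
transitivity/clustering beyond what actor effects induce. Realized
synthetic fits are also cleaner than the published ones (R²_adj ≈ .5–.6
versus ≈ .24–.36) because real allocations carry unmodelled
heterogeneity; recovery and calibration results should be read as
properties of the estimators under the stated generative model, not as
reproductions of the published coefficients, which are not derivable
without the raw data.

Truncation at 0 attenuates recovered slopes by a few percent at the
default intercept scale (weak-tie dyads sit near the floor). This bias
is measured, not assumed away: the recovery tests bound it at three
estimator SEs, and the module-level unbiasedness test runs at an
intercept where truncation is rare (bias < 5%).

## Numerical conventions and degenerate inputs

* Rank deficiency raises an error naming the collinear columns (pivoted
  QR); constant predictors are rejected before fitting. Requesting a
  group interaction when every class shares one code is caught this way.
* Both-SEs-zero density comparisons: equal densities give t = 0, p = 1;
  unequal densities are an error (no sampling variability to compare).
* Degenerate permutation denominators (a residual matrix permuted into
  the span of the other predictors) contribute a null coefficient of 0.
* All randomness flows through numpy `SeedSequence` spawning: one master
  seed yields independent, reproducible streams per stage, per group and
  per elimination step. Identical configuration + seed reproduces report
  files byte-for-byte.

## Problem sizes used in the test suite

Calibration and recovery tests run at the sizes the methods target:
20-actor networks with 500 replicates × 500 permutations for the DSP
type-I-error check; the 23+19 two-class study with 200 replicates ×
2,000 permutations for multigroup recovery and power; 100 replicates for
elimination survival; bootstrap checks at 2,000–20,000 replicates. These
sizes keep the full suite under a few minutes while leaving Monte-Carlo
error well inside the asserted bands.

## Known limitations

* The multigroup permutation scheme is a reasoned reconstruction, not a
  verified reimplementation of the original R routine; its conservatism
  is characterized empirically.
* Intercept p-values in multigroup tables are structurally uninformative
  (see caveat above).
* One-tailed/two-tailed assignments are configuration, not inference:
  the package applies whatever directional hypotheses it is given.
* Only linear MRQAP is implemented — no logistic/ordinal variants and no
  network autocorrelation models.
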