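# Methods notes

This note records the statistical model behind `radsurv`, the numerical
and design choices that were genuinely open, what the synthetic-data
generator does and does not emulate, and the package's known limitations.

## Data model and assumptions

The analysis consumes a cases × features table of radiomic values and a
per-case cohort table (overall-survival days, death-event flag,
adjuvant-therapy flag, optional recurrence flag and reference
recommendation). It assumes:

- survival follows a proportional-hazards model whose log relative hazard
  is linear in (transformed) features and feature × augmented-feature
  interactions;
- censoring is non-informative;
- the joint behaviour of radiomic features differs between the
  adjuvant-therapy and control arms, so second-order summaries of the
  features carry information about therapy likelihood.

All association and model computations operate on rank-based inverse
normal scores, zᵢ = Φ⁻¹((rᵢ − c)/(n − 2c + 1)). The offset convention is
not fixed by the method itself; the package uses Blom's c = 3/8 with
mid-ranks for ties (the most common choice), and the offset is a
parameter of `inverse_normal_transform`. Constant features are rejected
rather than silently dropped: the transform is undefined for them and the
caller should curate the panel.

## Augmented features

`z1_raw = (Σᵢ zᵢ)²` and `z2_raw = (Σᵢ |zᵢ|)²` are computed over all m
features by default. Whether the sums should instead run over the
screened subset is ambiguous in principle; since the augmented features
are meant to summarize the whole panel, all features is the default and
`feature_subset` exposes the alternative. The map to [0, 1] is cohort-wise
min–max rescaling of z′₁ and z′₂ independently — the simplest map
achieving the required range; note this makes the rescaled values (and
therefore G_T, risk scores through interaction terms, and
recommendations) cohort-relative. The association-structure comparison
uses the p(p−1)/2 upper-triangle off-diagonal entries of each arm's
|mean cross-product| matrix as the two KS samples: diagonal entries are
variance terms, not pairwise associations. The G_T–therapy association
test dichotomizes at the median (strictly above = high, ties low) and
uses the Pearson chi-square without continuity correction (correction
available by flag) plus Spearman correlation of the dichotomized value
with the therapy flag.

## Survival statistics

The concordance index follows the AUC(τ) definition: a pair (i, j) is
comparable iff tᵢ < tⱼ, case i failed (not censored), and tᵢ < τ;
concordant iff the earlier failure has the higher risk; tied risks credit
0.5; tied times are not comparable. τ defaults to +∞, i.e. Harrell's C —
an observe-period truncation is exposed as a parameter but not used by
default since nothing in the method requires it. Kaplan–Meier curves and
the two-sample log-rank test are delegated to lifelines behind the module
surface. Calibration compares the mean predicted survival
S₀(t)^exp(y) — with S₀ from the Breslow baseline-hazard estimator —
against the Kaplan–Meier estimate at fixed horizons, defaulting to 730
and 1825 days (2 and 5 years); horizons beyond follow-up are flagged and
evaluated at the last observed time.

## Cox fitting and selection

The partial likelihood is maximized by Newton–Raphson with step-halving;
convergence at max |score| < 1e-8 or 50 iterations. Tied event times are
handled by Breslow's approximation by default (Efron by flag). A
coefficient escaping |B| > 20 flags monotone likelihood and the fit is
marked non-converged; a singular information matrix raises. The fitter is
implemented in-package because the stepwise machinery needs exact
log-partial-likelihood bookkeeping for likelihood-ratio tests and the
Breslow baseline under the chosen tie convention; it is cross-checked in
the test suite against lifelines (Efron) and scikit-survival (Breslow)
and against brute-force maximization of the written-out likelihood on
small fixtures.

Screening fits one univariate Cox model per feature and ranks by training
C-index of the fitted risk score; a non-converged univariate fit falls
back to the raw feature values as the ranking risk (logged). Top-k
selection is tie-inclusive: every feature sharing the boundary C-index is
kept, so k_effective ≥ k. The candidate set contributes, per screened
feature, a main effect and one interaction with each augmented feature,
plus the two augmented main effects — 3m + 2 terms. The count dictates
that the augmented main effects belong to the candidate set; this is the
unique composition giving 611 candidates from 203 screened features.

Stepwise selection is forward with likelihood-ratio entry (p < 0.05) and
backward removal (p > 0.10), iterated to a fixed point with ties broken
by candidate order (reproducibility) and a step cap of 2 × |candidates|
against cycling. Candidates whose fit diverges or is singular are skipped
for that step. The empty model is a valid outcome. No covariate centering
is applied anywhere: the linear predictor is the raw Σ B_k x_k and the
baseline hazard absorbs location.

## Permutation null

(time, event) pairs are permuted jointly across cases with covariate rows
fixed, and the fixed term panel is refitted per replicate — generating
null *models*, not just null scores. The training C-index of each refit
is recorded; with k > 0 predictors its null mean exceeds 0.5 (refit
optimism), which is the reason the method calibrates significance against
a simulated null instead of 0.5. The empirical p-value uses add-one
smoothing, p = (1 + #{null ≥ observed})/(R + 1), so "empirically zero" is
reported as the smallest attainable value together with the raw
exceedance count.

## Recommendation and benefit

y(z′₁, z′₂) is evaluated at (0, 0) and (1, 1) only — by linearity of the
model in the augmented variables the argmin over [0, 1]² is at a corner
of the diagonal, and the two anchor settings correspond to "therapy" /
"no therapy" on the G_T scale. A tie recommends no therapy: given the
toxicity of adjuvant therapy, indifference abstains from treatment. Plain
main effects cancel in the contrast, so the decision depends only on the
augmented-dependent terms.

McNemar's statistic uses the continuity correction
χ² = (|b − c| − 1)²/(b + c) with no clamping at |b − c| ≤ 1 (so b = c
gives 1/(b + c), documenting the convention rather than hiding it). The
benefit group is cases with no therapy and no recurrence; cases with a
missing recurrence flag are excluded and reported, mirroring how missing
reference decisions must be excluded in practice.

## Published reference model

A five-predictor Cox model with published coefficients (0.940, −1.957,
3.981, −2.373, −2.122; one wavelet-HHH IMC1 main effect and four
augmented-feature interactions) ships as a versioned JSON fixture. Its
source prints −1.957 for the z′₁ × HHL-skewness interaction in the model
equation but −1.951 in the accompanying coefficient table; the fixture
stores the equation value and records the table value as an annotated
alternative. The fixture has no baseline hazard (the source cohort is not
distributable), so it supports risk scores and recommendations but not
absolute survival prediction.

## Synthetic-data generator

The generator emulates exactly the structure the method assumes:
features are blockwise-equicorrelated multivariate normal with
equicorrelation ρ_therapy within the therapy arm and ρ_control within the
control arm (the shared-factor construction keeps every implied
covariance positive definite); survival times are exponential with rate
h₀·exp(lp) where the linear predictor is a sparse combination of
transformed features and their products with the generator's own
augmented features; censoring is independent exponential.

Defaults are fixed once and emulate the published study's conditions
where stated: 123 cases; therapy prevalence 0.30 (≈ the training cohort's
22/76); baseline hazard ln 2/1286 per day (median overall survival 1286
days); censoring rate 2 × 10⁻⁴ per day (roughly a quarter censored). The
feature dimension defaults to 60 in blocks of 10 — a desk-scale stand-in
for the 851-feature panel that keeps simulation-heavy tests fast; 851
catalog-named columns are available via `n_features=851, block_size=23`.
ρ_therapy = 0.10 < ρ_control = 0.45 so that the control arm's stronger
correlation inflates (Σz)², orienting high G_T toward no-therapy — the
direction reported for real cohorts. The default generating effects mix
one main effect (coefficient 1.0) with one interaction per augmented
feature (∓1.5); interaction coefficients are larger because the
[0, 1]-rescaled augmented factors attenuate the interaction regressor's
variance, keeping the three effects on a comparable hazard scale. The
reference-recommendation column is set to the therapy actually assigned,
playing the role a clinician's or decision-support system's advice plays
for real data.

What the generator does **not** emulate: realistic radiomic marginal
distributions (real features are heavy-tailed and bounded, not normal —
immaterial here because the pipeline rank-transforms first), measured
inter-feature correlation structure beyond equicorrelated blocks,
segmentation noise, cohort heterogeneity, and any causal effect of
therapy on survival or recurrence (recurrence is independent Bernoulli).
Passing tests therefore demonstrate correctness of the machinery and
recoverability under the assumed model, not clinical validity on real
cohorts.

## Problem sizes used in the test suite

Simulation-based tests choose sizes where the checked property is
comfortably identifiable: parameter recovery at n = 400, p = 60 over 25
seeds; single-coefficient recovery at n = 2000; permutation nulls at
n = 150 with R = 200; type-I-error checks over 200 replicates;
calibration self-consistency at n = 2000. The full-scale analysis
(n_permutations = 1000, k_screen = 203) remains the pipeline default.

## Known limitations

- The concordance screening and stepwise selection reuse the training
  data; reported training C-indices are optimistic by construction, which
  is precisely why the permutation null is part of the chain. No internal
  cross-validation is provided.
- Min–max rescaling of the augmented features makes risk scores
  cohort-relative; applying a fitted model to a new cohort recomputes the
  rescaling on that cohort.
- The stepwise LR p-values are conditional on the selection path; they
  are selection criteria, not honest hypothesis tests.
- Feature extraction from images (segmentation, bin width, wavelet
  filtering) is out of scope; the package consumes feature tables.
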