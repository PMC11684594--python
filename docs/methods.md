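# Methods

`drcate` estimates average and heterogeneous treatment effects from
observational data with a binary exposure and a continuous outcome, and
learns interpretable treatment-targeting rules from the same doubly robust
machinery.  This note documents the statistical procedures, the synthetic
benchmark that exercises them, and the numerical choices that were
genuinely open.

## Identification and the doubly robust score

For unit *i* with covariates `X_i`, treatment `W_i ∈ {0,1}` and outcome
`Y_i`, the package works under the standard trio of assumptions:
consistency (`Y_i = W_i·Y_i(1) + (1−W_i)·Y_i(0)`), ignorability
(`(Y(0), Y(1)) ⫫ W | X`), and positivity (`0 < p(X) < 1` where
`p(x) = P(W=1 | X=x)`).  Positivity is the one testable member of the trio,
so the pipeline checks it (propensity histogram, min/max, clipped share)
and refuses to continue on violation unless forced.

Nuisances — the arm-wise outcome regressions `μ(x, w) = E[Y | X=x, W=w]`
and the propensity `p(x)` — are fitted with K-fold cross-fitting (default
K=5, folds stratified by arm, shared between the outcome and propensity
models): unit *i*'s predictions come from models that never saw fold(*i*).
The default learners are random forests (500 trees, scikit-learn defaults
otherwise, outcome fitted separately per arm); plain linear/logistic
learners are available for smoke runs, and an oracle mode passes the
synthetic generator's truth through for benchmarking.  Estimated
propensities are clipped to `[0.01, 0.99]` with a warning when more than
2% of units are touched.

Each unit then receives the augmented inverse-propensity scores

    Γ̂₁ᵢ = μ̂(Xᵢ,1) + Wᵢ/p̂(Xᵢ) · (Yᵢ − μ̂(Xᵢ,1))
    Γ̂₀ᵢ = μ̂(Xᵢ,0) + (1−Wᵢ)/(1−p̂(Xᵢ)) · (Yᵢ − μ̂(Xᵢ,0))

whose difference `Dᵢ = Γ̂₁ᵢ − Γ̂₀ᵢ` is the per-unit effect score: `mean(D)`
is the AIPW ATE, consistent when either nuisance model is correct.  Its
standard error is the empirical sd of `D` over √n — the usual
influence-function variance; the package reports normal 95% intervals.
The observed-arm branch of the score, `Y^AIPW_i` (Γ̂₁ for treated units,
Γ̂₀ for controls), is retained as a transformed outcome.  The naive
difference-in-means estimator (Welch SE) is always reported alongside as
the confounded baseline.

## Honest causal trees and forests

A causal tree is grown honestly: a 50/50 treatment-stratified split
divides the sample into a *structure* half (chooses the partition) and an
*estimation* half (supplies leaf effects), removing adaptive-selection
bias from the leaf estimates.  All covariates are ordered integer codes;
every split is `feature ≤ threshold` with thresholds at midpoints of
consecutive distinct structure-half values, ties routed left, and
deterministic tie-breaks (lowest feature index, then lowest threshold).
A split is admissible only if both children retain `min_leaf` structure
units of *each* arm (defaults: `min_leaf=50`, `max_depth=4`); growth stops
when no admissible split strictly improves the criterion.  Leaves whose
estimation half lacks an arm are merged with their sibling.

**Split statistic.** The node criterion is `Σ_c n_c·τ̂_c²` over children
*c*.  Two child-effect statistics are implemented:

* `effect_score` (default): `τ̂_c = mean(D | c)`.  Because
  `E[D | X] = τ(X)` under either correct nuisance, child means are
  unbiased child CATEs whatever the treatment mix inside the child.
* `aipw_arm_means`: `τ̂_c = mean(Y^AIPW | W=1, c) − mean(Y^AIPW | W=0, c)`,
  i.e. treating the transformed data as randomised.  The transform fixes
  each arm's conditional *level* (`E[Y^AIPW | W=w, X] = μ_w(X)`) but not
  the compositional difference in `X` between arms within a child, so
  under confounding this statistic partly tracks covariates that drive
  *assignment* rather than effect modification.  On our confounded
  benchmark it reliably prefers propensity covariates at the root, which
  is why it is not the default; on randomised data the two statistics
  agree in expectation.

Leaf effects default to estimation-half means of `D` with `sd/√n` SEs
(doubly robust); arm-wise means of `Y^AIPW` are available as an
alternative estimator for comparison.

A causal forest grows `B` honest trees (default `B=2000`, desk-scale runs
use 150–500), each on an independent without-replacement subsample of
fraction 0.5, with `mtry = ⌈√d⌉` candidate features redrawn at every
split.  Out-of-bag (OOB) CATEs average only trees whose subsample
excluded the unit — an absolute exclusion, enforced structurally — so a
unit's OOB prediction is independent of its own outcome.  Variable
importance is plain split frequency normalised to sum to one; no
per-prediction confidence intervals are offered (interval inference is
delegated to group means of `D`).

## Heterogeneity inference

* **Calibration test**: regress `Dᵢ` on the two regressors
  `(mean(τ̂), τ̂ᵢ − mean(τ̂))` without intercept (τ̂ the forest OOB CATE),
  HC1 robust SEs; the one-sided test of the differential coefficient
  `β > 0` detects heterogeneity the forest actually ranks correctly.
  Constant predictions leave β undefined and are flagged.
* **Group CATEs**: `τ̂(g) = mean(D | G=g)`, SE `sd/√n_g`; groups with
  fewer than two units are dropped with a warning.  Weighted group CATEs
  aggregate exactly to the ATE over any partition.
* **Pairwise contrasts**: normal z-tests on `τ̂(g) − τ̂(g′)` with
  `se = √(se_g² + se_g′²)`.  Multiplicity control by Bonferroni or by
  Romano–Wolf stepdown: units are resampled with replacement within each
  group, each group's bootstrap means are recentred at its observed mean
  (imposing the global null), studentised max-statistics give stepdown
  adjusted p-values with enforced monotonicity (default 1000 bootstrap
  draws, minimum 500).  A single hypothesis is never adjusted.
* **Leaf report**: each tree leaf is contrasted against the
  largest-magnitude-effect reference leaf, with raw and Romano–Wolf
  adjusted p-values, using estimation-half scores only.

## Policy learning and evaluation

A policy `π(x) ∈ [0,1]` is valued by `mean_i[π(xᵢ)Γ̂₁ᵢ + (1−π(xᵢ))Γ̂₀ᵢ]`;
the treat-all vs treat-none contrast equals the AIPW ATE identically.
Directions are explicit: for outcomes where lower is better (BMI-like),
the non-parametric rule treats units with OOB `τ̂(x) < 0` (strict), while
under maximisation the boundary `τ̂(x) ≥ 0` is treated — the two printed
inequalities differ on the boundary and are implemented exactly.
In-sample CATEs are refused for policy construction unless explicitly
overridden.

Policy trees (depth 1–3) are found by exact exhaustive search over
axis-aligned threshold trees with leaf actions in {0,1}, maximising (or
minimising) the summed per-unit policy scores on the training half.
Candidate thresholds are midpoints of consecutive distinct training
values, thinned to at most 20 per-feature quantiles (exact below the cap,
a documented approximation above it).  Tie-breaks: constant action beats
an equal-valued split, then lowest feature, lowest threshold, action 0
before 1.  Depth > 3 is rejected (exhaustive-search complexity guard),
and depth-3 searches are quadratic in the grid — use them on modest
training sizes.  The evaluation harness fits learned policies on a
treatment-stratified half and values *all* policies (treat-all,
treat-none, random(0.5), the observed assignment valued as
`mean(Y^AIPW)`, the non-parametric rule, and the trees) on the held-out
half, reporting estimate, SE and treated fraction.

## The synthetic benchmark generator

The generator emulates a national health-survey covariate layout: age
group (15 ordered levels), sex (binary), income decile, weekly working
time (7 bands), education (4 levels), socio-economic decile, remoteness
(3 levels), fruit/vegetable guideline adherence (binary), and weekly
sweet-drink cups (Poisson count).  Factor levels are sampled uniformly
unless overridden; the sweet-drink mean defaults to 0.7 so that about
half the population reports zero cups, which makes the three cells of the
benchmark effect surface (below) occupy ≈ 0.20 / 0.20 / 0.60 of the
population — matching the near-equal occupancy of the three data-driven
subgroups the tree machinery is expected to find.  Covariate marginals
beyond that are deliberately simple and make no claim of demographic
realism.

Treatment assignment is logistic in theoretically standardised covariates
scaled by a single confounding dial γ (γ=0 gives a randomised design);
the default coefficients make younger, higher-SES, guideline-adherent
individuals *both* likelier to exercise and lower in baseline BMI, so the
naive contrast is biased by construction (≈ −1.2 outcome units at γ=1
against a true constant effect).  Propensities are clamped to
`[ε, 1−ε]` (default ε=0.05) — clamping rather than rejection sampling, so
the covariate law is untouched and positivity holds by construction.  The
outcome is a linear baseline (intercept 27, BMI-like) plus an additive
effect and Gaussian noise (default sd 1.0 — a benchmark signal-to-noise
choice, smaller than real BMI residual spread, chosen so that recovery
failures indicate method defects rather than noise).  Both potential
outcomes, the true propensity, the true per-unit effect and the noiseless
baseline are stored, enabling oracle-nuisance runs in which every
residual term of the AIPW construction is exact.

Effect surfaces: `constant(τ₀)`, `linear` (coefficients on raw codes),
and `step` (piecewise-constant over threshold cells, validated to be
exhaustive and mutually exclusive by enumeration).  The benchmark step
surface plants −1.2 for high-SES non-consumers of sweet drinks, −0.13 for
high-SES consumers, and +0.176 for everyone else; `true_ate` is exact for
all three spec families (closed form or cell enumeration, Monte-Carlo
fallback otherwise).

What the generator does **not** model: survey weights, household
clustering, missingness, measurement error, hidden confounding, and
non-additive outcome noise.  Green tests therefore certify the
estimators' statistical behaviour under correct identification
assumptions, not robustness to their violation.

## Problem sizes and numerical choices

Benchmark runs use n=4000 (ATE recovery, tree recovery, calibration
power, policy learning), n=1000 (calibration size, 200 replicates),
n=800 (family-wise error, 500 replicates, 500 bootstrap draws) — sizes at
which every recovery quantity is comfortably resolved on a single CPU.
Honest forests attenuate rare-cell CATEs: with 0.5-fraction subsampling
and honest halving, each tree estimates leaves from ~n/4 rows, so the
rare strong-effect cell (population share ≈ 0.20) recovers to within
≈ 0.2 absolute error at n=4000 while the two large cells recover to
within ≈ 0.05; the single honest tree, which splits on the full
structure half, recovers all three leaf constants to ≈ 0.09 mean absolute
error.  Floating-point ties in split search are resolved with a 1e-12
tolerance toward the earlier candidate; all stochastic components
(sampling, fold assignment, honest halves, subsampling, mtry draws,
bootstrap) are driven by explicit seeds, and the pipeline derives one
seed per stage from its root seed via `numpy.random.SeedSequence`, making
whole reports byte-reproducible.

## Known limitations

* Forest CATEs carry no per-unit uncertainty; use group means of `D`.
* The depth-3 policy search is exhaustive and therefore slow on large
  training sets with fine threshold grids.
* The Romano–Wolf implementation resamples within groups independently;
  it does not model cross-group dependence induced by shared nuisance
  estimates (negligible for cross-fitted scores at the benchmark sizes).
* Time complexity: one tree costs `O(d · m log m)` per node on `m`
  structure rows with `O(2^depth)` nodes; a forest multiplies by `B`.
  OOB prediction is `O(B · n · depth)`.
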