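# Methods

This note documents the statistical models implemented in `testeval`, the
choices made where the methodology is genuinely open, and what the
simulation-based tests do and do not demonstrate.

## Bivariate random-effects meta-analysis (`dta_core`)

Study *i* contributes a 2×2 table at a threshold; its empirical
(logit Se, logit Sp) pair **y**ᵢ is modelled as

  **y**ᵢ ~ N(**μ**, Σ + Sᵢ),  Sᵢ = diag(1/tp + 1/fn, 1/fp + 1/tn),

the normal–normal approximation to the bivariate logistic random-effects
model. If any cell is zero, 0.5 is added to all four cells *for the logit and
variance computation only*; raw counts are retained so that NI, SI and MIDC
remain comparable. Estimation profiles the fixed effects out by GLS and
maximises the restricted likelihood (default; full ML and a fixed-effect
closed form are options) over the Cholesky factor of Σ, which enforces
positive semidefiniteness and allows the τ² → 0 boundary. Three
deterministic starts (method-of-moments, zero heterogeneity, inflated
heterogeneity) guard against the convergence problems this model is known
for; non-convergence is flagged and boundary estimates are returned rather
than erroring. In the τ² → 0 limit the estimates coincide with
inverse-variance fixed-effect pooling, and for small K the maximiser agrees
with a brute-force grid search of the same likelihood to 10⁻³ (tested).
Confidence intervals are Wald on the logit scale, back-transformed.

The summary ROC line uses the between-study regression implied by Σ: with
logit FPR = −logit Sp, the slope is −σ_{Se,Sp}/τ²_Sp and the line passes
through the summary point. τ²_Sp ≈ 0 makes the slope undefined; a constant
logit-Se line is returned with a warning. Positivity is fixed as *positive
iff marker ≥ threshold* (exposed as a flag): sensitivity is non-increasing
and specificity non-decreasing in the threshold.

Meta-regression places the same covariate design on both logit means
(e.g. assay type, directness and their interaction) with a shared residual
between-study covariance; per-coefficient Wald tests are reported without
any multiplicity adjustment, and the output says so.

Not implemented by design: the exact binomial GLMM likelihood, the
Rutter–Gatsonis HSROC parameterisation, and copula-based models.

## Missing thresholds: NI, SI, MIDC (`thresholds`)

*SI* interpolates logit Se and logit Sp linearly in threshold between two
observed bounding thresholds of the same study, converts back to counts by
rounding half away from zero, and clips to the bounding counts so the
completed study stays monotone. At an observed threshold SI is the identity.

*MIDC* treats the feasible completions as the set of integer (tp, fp) pairs
lying in the rectangle between the bounding tables (count =
(Δtp+1)·(Δfp+1)). Each imputation draws uniformly from that set — tp and fp
independently, which is the minimal assumption given that the sampling
distribution is unspecified in the method's description — sequentially in
increasing threshold order with the previous draw replacing the lower bound,
which preserves within-study monotonicity by construction. Targets not
bracketed by two observed thresholds contribute nothing for that study
(logged, never extrapolated). Each of the M completed datasets is
meta-analysed per threshold and the M logit-scale estimates are combined
with Rubin's rules:

  q̄ = mean, W = mean within-variance, B = between-imputation variance,
  T = W + (1 + 1/M)·B, ν = (M−1)(1 + W/((1+1/M)B))², ν = ∞ when B = 0.

Points and t-intervals are back-transformed; variances are not. With no
missing data all M completions are identical, B = 0 and the output is
bitwise equal to NI.

Measured behaviour at K = 20 studies, 30 % thresholds missing at random,
M = 5, 300 replicates: MIDC's pooled logit-Se estimates are uniformly at
least as precise as NI's (empirical SE 0.127 vs 0.162 at the middle
threshold) and its CI coverage is at least NI's everywhere (0.947 vs 0.913
there). MIDC's *intervals* are wider than NI's at imputed thresholds — the
between-imputation variance widens them exactly where NI's Wald interval
undercovers, which is the mechanism of the coverage gain; SI's intervals are
narrower than NI's everywhere. Uniform rectangle sampling also induces a
modest negative logit-Se bias at interior thresholds (imputation mass
centres between the bounds), so the bias advantage of imputation is
situation-dependent; under *selective* reporting with logit-linear truth the
imputed analyses have absolute summary bias no larger than NI's (tested
directionally at 120 replicates).

## Distribution-function multi-threshold model (`thresholds`)

Assuming a location–scale marker distribution per disease group
(normal/probit or logistic/logit; thresholds optionally log-transformed),
the cumulative proportion below threshold c — tn/n₀ in non-diseased, fn/n₁
in diseased, continuity-corrected as (k+0.5)/(n+1) — satisfies
F⁻¹(P) = (c − μ_g)/σ_g, i.e. a straight line in c. Each group is fitted by a
weighted random-intercept linear mixed model (study-level intercepts capture
between-study heterogeneity and the within-study dependence of the repeated
proportions; weights are inverse delta-method variances of the transformed
proportions), written in-package because no installed mixed-model routine
accepts known heteroscedastic residual weights. Group parameters follow as
μ_g = −a_g/b_g, σ_g = 1/b_g; a non-positive slope (negative scale) raises a
convergence error. Se(c) and Sp(c) are monotone by construction, and
Sp(μ₀) = ½ exactly.

The Youden-optimal threshold maximises J(c) = Se(c) + Sp(c) − 1: midpoint of
the means for equal normal scales, the admissible root of the equal-density
quadratic for unequal scales, and a grid-plus-refinement search otherwise
(always cross-checked against the grid); identical group distributions give
the degenerate J ≡ 0 result with an explicit flag.

Random intercepts are per study × group with group-specific variances —
independent across groups by default, a pragmatic structure chosen because
the random-effects specification is otherwise open.

## New populations (`newpop`)

The predictive distribution for a new study's (logit Se, logit Sp) is
bivariate normal with covariance Σ + cov(μ̂); t-scaling with K − 2 degrees
of freedom is applied marginally only (no bivariate t). Prediction
intervals therefore require K ≥ 3 and contain the confidence interval
whenever τ² > 0. Joint statements P(Se > a, Sp > b) come either from Monte
Carlo over that distribution (default n = 200,000, seeded, with a standard
error) or from the numeric bivariate-normal orthant probability; the two
agree within Monte-Carlo error (tested across random configurations).

Post-test probabilities use Bayes' theorem at the pooled point,
PPV = Se·π/(Se·π + (1−Sp)(1−π)) and NPV = Sp(1−π)/(Sp(1−π) + (1−Se)π), with
predictive intervals obtained by propagating predictive draws; the
prevalence π is held fixed rather than treated as random. The
leave-one-study-out check refits the model without each study and compares
predicted with observed PPV/NPV, *tailored* (held-out study's own
prevalence) and *untailored* (pooled training prevalence) in the same pass;
"within 10 %" is read as an absolute difference ≤ 0.10 on the probability
scale (a parameter). When study prevalences vary widely, tailored
predictions have smaller mean absolute PPV error (tested directionally).

## Decision curves (`utility`)

NB(p_t) = TP/n − (FP/n)·p_t/(1−p_t); ties at the threshold classify
positive. The default grid is 0.05–0.50 in steps of 0.01, the range usually
considered clinically reasonable for this application. Treat-none is
identically 0; treat-all equals prevalence − (1−prevalence)·odds(p_t) and is
strictly decreasing. Optional subject-level bootstrap (percentile intervals,
seeded; 2,000 draws recommended). ΔNB/prevalence converts a net-benefit
difference into a sensitivity gain at constant specificity.

## Calibration and multilevel validation (`calibration`)

The calibration hierarchy is computed as: O/E = event rate / mean predicted
risk and the calibration-in-the-large intercept from a logistic model with
offset logit(p); weak calibration from the logistic recalibration
y ~ logit(p); moderate calibration from a restricted-cubic-spline logistic
smoother (5 knots at logit(p) quantiles — deterministic and robust at small
n, unlike local smoothers) evaluated on a predicted-risk grid, suppressed
with a warning below 50 subjects; and a strong-calibration table of event
rate vs mean risk per covariate pattern only when discrete pattern labels
are supplied — full strong calibration is not certified, since it amounts
to requiring a completely correct model. Risks at exactly 0 or 1 are
clipped to [10⁻⁶, 1−10⁻⁶] with a warning.

The random-intercept logistic model logit P(y=1|x, c) = x'β + u_c,
u_c ~ N(0, σ²_u), is fitted by adaptive Gauss–Hermite maximum likelihood:
each cluster's integral is evaluated on Hermite nodes recentred at the
cluster's posterior mode and rescaled by its curvature (fixed nodes are
badly inaccurate for the sharply peaked integrands of large clusters).
The latent-scale ICC is σ²_u/(σ²_u + π²/3). Three prediction types follow:
center-specific (posterior-mean û_c added; unavailable for new clusters,
returned as missing), average-center (u = 0) and population-averaged
(50-node Gauss–Hermite integral of expit(lp + u); agrees with Monte Carlo
and with the attenuation approximation expit(lp/√(1 + 0.346σ²_u)) within
0.01 for σ²_u ≤ 1).

Validation reports both levels: population-level calibration slope/intercept
from y ~ logit(p) (offset model for the intercept) and the overall
c-statistic; within-cluster slope from fixed cluster-specific intercepts
with one common slope (stable in small clusters; per-cluster pooling would
be noisier), within-cluster intercept as the size-weighted mean of
per-cluster offset intercepts, and within-cluster C as the pairs-weighted
mean of per-cluster c-statistics. Clusters lacking an event or non-event
are excluded from within-cluster metrics with a log message. The
characteristic marginal-vs-conditional pattern — average-center predictions
well calibrated within clusters but too extreme marginally (slope ≈
1/√(1 + 0.346σ²_u) ≈ 0.88 at ICC 0.20), population-averaged predictions the
mirror image, center-specific predictions calibrated at both levels with
the highest population-level C, and identical within-cluster C for all
three — is reproduced by the test suite and the acceptance script.

## Agreement (`agreement`)

Measurements are decomposed as value = fixed effects + Σ_f u_f + e with a
variance component per declared random factor (subject always included).
REML estimation profiles the fixed effects and residual variance
analytically and optimises the variance ratios on the log scale; on balanced
one-way layouts it reproduces the ANOVA expected-mean-squares estimates to
~10⁻⁹, and a closed-form ANOVA option is provided there (negative
method-of-moments components truncated at zero and flagged). The
within-condition SD σ_w sums the residual plus whichever components the
caller declares as varying between repeated measurements taken under
"identical conditions" — making explicit, for example, the difference
between a same-scanner and a different-scanner repeatability coefficient.
RC = 1.96·√2·σ_w (the conventional rounding is 2.77·σ_w) is the limit
within which 95 % of test–retest differences are expected to lie, and
equals the Bland–Altman half-width when the bias is zero (verified by
simulation).

## Synthetic data (`simulate`)

The accuracy generator draws per-study group means (between-study SD 0.3 by
default, heterogeneity on the distribution means; a logit-scale
heterogeneity option exists), then one latent marker value per subject, so
counts are monotone across thresholds by construction. Default study
conditions: 20 studies of 200 subjects at prevalence 0.5 (a per-study
diseased-fraction parameter covers low-prevalence settings), N(0,1) vs
N(2,1) marker distributions, five equally spaced thresholds. Reporting
mechanisms: *all*; *missing at random* with a stated fraction (at least one
threshold per study always survives); *selective*, keeping thresholds
within a window of each study's empirical Youden-maximising cutoff (ties
resolved toward the lowest cutoff) — and, by default, also the study's
extreme thresholds, emulating conventionally reported cutoffs alongside the
data-driven optimum; without that, interior missing thresholds would never
be bracketed and imputation could not engage at all. The stored truth is
the accuracy curve at the average study parameters.

The clustered generator draws cluster intercepts from N(0, σ²_u) with
σ²_u = ICC/(1−ICC)·π²/3, equal cluster sizes, standard-normal predictors and
Bernoulli outcomes. The harness applies named estimators to replicate
datasets and aggregates bias, RMSE, 95 % CI coverage and width against the
stored truth, recording estimator failures per replicate; everything is
reproducible from the supplied generator.

Problem sizes in the shipped tests and acceptance script — 300 replicates
for the missing-at-random comparison, 120 for the selective-reporting bias
check, 500 for interval-coverage checks, 10 seeded populations for the
multilevel-calibration experiment — were chosen as the package's own
desk-scale defaults; they give Monte-Carlo errors comfortably inside the
stated tolerances.

What the generators do *not* emulate: real marker distributions are rarely
exactly location–scale normal/logistic, real reporting is not exactly
uniform-window selective, cluster sizes are unequal in practice, and
predictors are correlated. Passing tests therefore demonstrate correctness
of the estimators under their assumed data-generating processes and the
direction of the documented phenomena, not field performance on any
particular clinical dataset.

## Numerical notes

* Between-study covariances are parameterised via Cholesky factors with
  bounded log-diagonals; τ² can reach the zero boundary.
* The intercept-only bivariate likelihood has a compiled (numba) kernel with
  a pure-numpy fallback; results agree to ~10⁻⁸ and estimates are invariant
  to study order up to float summation order.
* Imputed/interpolated counts round half away from zero, then clip to the
  bounding counts: deterministic and monotone-safe.
* Rubin degrees of freedom use the ν = ∞ sentinel at B = 0, so the interval
  reduces to the Wald z-interval and MIDC ≡ NI holds exactly.
* All Monte-Carlo routines take an explicit `numpy.random.Generator`; no
  global random state is used anywhere.
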