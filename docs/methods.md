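# Methods

## Data model and cell semantics

A survey dataset is a subjects × ordered-items binary matrix,
`answered[i, q] = 1` when subject *i* answered analyzed item *q* (items are
positions in the analyzed sequence; conditional/branched items are expected
to be removed by the caller, with original question labels preserved in a
label map).  Every not-answered cell is classified:

- **skip** — an answered item exists strictly later for that subject;
- **dropout** — no answered item at or after that position.

The **dropout point** is `last_answered + 1`; a subject whose last answered
item is the final one is a **completer** (dropout point `n_items + 1`,
treated as censoring at `n_items` in survival analyses).  Subjects who
answered nothing never started (that is nonresponse, a different
phenomenon) and are excluded at load time with a logged count.  Any
answered item counts as having started, including subjects whose first
answer comes after item 1.

One ambiguity is structural: a subject who skips every item from some point
onward is indistinguishable from one who dropped out there.  The classified
dropout point is therefore biased early for such subjects;
`simulate.trailing_skip_misclassification_rate` quantifies the rate under
any generator configuration (about 2–4% per unit of sporadic skip
probability at moderate hazards; exactly 0 without skips).

## Stage 1 — attrition summaries and the phase heuristic

Per-item counts and percentages of respondents, skips, and
incremental/cumulative dropouts use the **starter count** as the
denominator (an option switches to previous-item respondents).  Percentages
are reported to 2 decimals.  At every item,
`pct_respondents + pct_skips + pct_cumulative_dropouts = 100` up to
rounding, and stratified tables sum exactly to the pooled one.

The three-phase segmentation (curiosity plateau → attrition phase → stable
participation) is a *labeled heuristic*, not an inference: an item belongs
to the attrition phase when its incremental dropout proportion exceeds a
threshold (default 0.05 per item, configurable); the phase is the longest
contiguous run of exceedances bridging single-item gaps; the stable rate is
the mean respondent percentage afterwards.  Degenerate cases (no
exceedance, or a spike at the final item) are flagged rather than forced
into three phases.  No formal changepoint inference is attempted.

## Stage 2 — the pairwise random-intercept logistic model

For sequential items (q, q′), every starter contributes the pair
(y₁, y₂) of answered indicators, modeled as
`logit P(y_k = 1 | u) = β₀ + β₁·1[k=2] + u`, `u ~ N(0, σ_u²)`.  All
starters enter every pairwise fit, so fitted proportions are fractions of
the full cohort.  Estimation details:

- **Likelihood.** Subjects collapse onto the four response patterns, and
  each pattern's marginal likelihood is integrated by adaptive
  Gauss–Hermite quadrature (default 25 nodes) re-centered at the pattern's
  posterior mode (found by Newton steps on a strictly concave integrand).
  A dense trapezoidal grid evaluation (`marginal_loglik_grid`) exists
  purely as an independent numerical cross-check; the two agree to well
  below 1e-4 per subject in the test suite.
- **Optimization.** Quasi-Newton (L-BFGS-B) on (β₀, β₁, log σ_u) from fixed
  deterministic starts (marginal logits, σ = 0.5); |β| is capped at 15 on
  the logit scale, log σ_u is bounded in [log 1e-6, 5].
- **Degenerate pattern tables.** When a discordant cell ((0,1) or (1,0)) is
  nearly empty — pure monotone dropout with no skips — the likelihood is
  maximized along a ridge running to σ_u → ∞, where the model saturates the
  three occupied cells.  Under the logit cap the constrained maximum sits
  at finite σ_u with β at the cap.  A cold start is unreliable there, so
  whenever a discordant cell has fewer than 5 subjects the fitter profiles
  over a log-spaced σ grid with warm-started two-parameter fits and then
  polishes jointly.  Such fits carry `separation_warning` /
  `sigma_boundary` / `converged` flags and should be read qualitatively:
  the model is weakly identified on one-sided discordance, which is an
  inherent property of a 2-observation random-intercept model, not of this
  implementation.
- **Separation.** An item answered by everyone (proportion exactly 1) is
  handled by plain ML under the cap, yielding the characteristic unstable
  estimate with an extremely wide CI, flagged rather than penalized; a
  Firth-style penalty is deliberately *not* the default so that the
  reported intervals reflect the data's actual information.
- **Reported scale.** p₁ = expit(β₀) and p₂ = expit(β₀+β₁) are
  *subject-specific* (random effect 0) proportions; `scale="population"`
  integrates expit over the fitted frailty instead.  With large σ_u the two
  scales differ substantially — conditional proportions can look far from
  the raw fractions; this is the usual marginal/conditional divergence of
  logistic mixed models.
- **Inference.** The difference p₁ − p₂ gets a delta-method SE,
  `grad = [p₁(1−p₁) − p₂(1−p₂), −p₂(1−p₂)]`, CI = diff ± 1.96·SE, not
  clipped to [−1, 1].  The p-value is a Wald z-test of β₁ with a normal
  reference; mixed-model software sometimes uses t references with
  estimated degrees of freedom, but DF-estimation methods differ between
  packages and the normal reference is both simple and, per the calibration
  suite, accurate (type-I error ≈ 0.04–0.05 at nominal 0.05 with N = 1000).
  The covariance of (β₀, β₁) is the corresponding block of the inverse
  observed information (finite differences, validated against an
  independent grid Hessian); when σ_u sits at its boundary the 2-parameter
  information at fixed σ_u is used, and inverses are projected onto the PSD
  cone to absorb rounding on near-flat ridges.
- **Scan.** One fit per adjacent pair, no multiplicity adjustment by
  default (Bonferroni/Holm optional); a failed pair is reported with
  `converged = False` rather than aborting.

## Stage 3 — factors and discrete survival

Contingency analyses use Pearson's chi-square without continuity
correction (Yates optional); a 2×2 table with any expected count below 5
falls back to Fisher's exact test.  No exact test for larger sparse tables
is available in the stack, so r×c tables keep the chi-square with a
`low_expected` flag.  "Dropout at the next item" is operationalized as the
*observed* answered indicator — a skipper of the next item counts as a
non-respondent, exactly as a respondent-count table would show.

Survival analyses put dropout time on the discrete item scale (time ∈
[2, n_items], event = dropped; completers censored at n_items).  The
log-rank test uses the standard hypergeometric observed-minus-expected
sums with tied events pooled per time point; Kaplan–Meier curves are
product-limit estimates.  The Cox model maximizes the partial likelihood
by damped Newton–Raphson with Efron's tie correction (Breslow available),
SEs from the observed information; categorical covariates are dummy-coded,
interactions are products of encoded columns, and collinear designs raise
an error naming the dependent columns.  Item-boundary event times produce
massive ties, which is why Efron is the default.  The
proportional-hazards check adds, one covariate at a time, a
covariate × log(t) time-varying term evaluated at each event time and
Wald-tests it (joint chi-square for multi-column covariates); residual-based
diagnostics are out of scope.  `screen_then_adjust` reproduces the common
epidemiological sequence — bivariate screening at α, then a multivariate
model with exposure × covariate interactions, dropping non-significant
interactions — and labels covariates "effect modifier" (significant
interaction) or "confounding candidate" (significant main effect); these
are descriptive labels, not causal claims.  Both log-rank and Cox are
implemented in-package and verified against lifelines to 1e-4 in the test
suite, keeping the implementation and its oracle separate.

## The synthetic generator

Each subject passes item boundaries j = 1..n_items−1 and drops after item
j with probability `expit(logit(h_j) + u + γ_group + xᵀβ)`, where
`h_j ∈ [0,1)` is the baseline boundary hazard, `u ~ N(0, frailty_sd²)` is a
subject frailty on the continuation logit (mirroring the stage-2 random
intercept so recovery tests are well-posed), γ are group log hazard-odds
shifts, and covariates contribute linearly.  Active subjects skip item q
independently with probability `s_q`; dropout occurs only at item
boundaries (discrete times).  An optional binary outcome is drawn with
different probabilities for completers and noncompleters.  Each subject
consumes a pseudorandom stream derived from (master seed, subject index),
so enlarging a group never perturbs existing subjects and fixed seeds give
bit-identical output.

With frailty 0 and no shifts the marginal respondent proportion at item q
is `(1 − s_q)·Π_{j<q}(1 − h_j)` exactly; `expected_proportions` generalizes
this by Gauss–Hermite integration over the frailty and exact enumeration
of the group/covariate mixture, and `calibrate_hazard` inverts it — solving
one boundary logit at a time — so a preset can hit a target marginal curve
exactly in expectation.

Presets (the package's standing study conditions):

- **paper_like** — three cohorts of 638/1249/468 subjects (2355 starters),
  12 items, frailty SD 0.75, cohort hazard shifts ±0.3, gender and
  recruitment-phase effects (0.15 / {0, +0.15, −0.10}), an inert age
  covariate, and a completion-linked outcome (22.37% vs 17.42%).  Baseline
  hazards are calibrated so the pooled expected respondent proportions are
  (1.00, .97, .76, .56, .52, .54, .49, .47, .45, .44, .43, .42) — steep
  early attrition converging to ~42% with a skip-induced rise at item 6.
  The target curve is decomposed into a non-increasing activity-survival
  component and per-item skip probabilities with a sporadic skip floor of
  0.02 at items 2–12 (item 1's target of 1.00 forces skip 0 there); the
  floor reflects how skip-enabled instruments behave — skips occur at many
  items, not only where the curve visibly rises — and keeps pairwise
  pattern tables two-sided.
- **null** — two equal groups of 500, constant hazard 0.05, skip 0.02,
  frailty SD 1, no group differences; for size checks.
- **cliff** — 3000 subjects, 6 items, boundary hazards
  (0.01, **0.25**, 0.01, 0.01, 0.01), frailty SD 1, skip 0.02; a single
  engineered attrition point entering item 3.  Note the off-cliff hazard of
  0.01 is a *real* effect: at this sample size an efficient paired test has
  non-trivial power against it, so detection claims concern the engineered
  pair, not exclusivity.

What the generator does **not** emulate: question content and answer
values (only categories needed for factor tests), paradata/timing,
learned or time-varying skip behavior (skips are independent given
activity), dependence between skipping and frailty, and item-level
measurement error.  Passing tests therefore demonstrate correctness of the
estimators under a faithful-but-idealized dropout mechanism, not
robustness to every behavior of real respondents.

## Problem sizes and numerical defaults

Key defaults: 25 quadrature nodes; optimizer tolerance ftol 1e-12 relative;
logit cap 15; σ boundary flag below 1e-3; Wald CIs at 1.96; phase threshold
0.05; Fisher fallback below expected count 5; Cox Newton tolerance 1e-10
with step halving; PH check via log(t) interactions.

The test suite runs the calibration experiments at the sizes that give
stable Monte-Carlo verdicts on one CPU in a few minutes: type-I error over
1000 null replicates at N = 1000; cliff detection over 200 preset
replicates; survival parity over 20 random datasets; simulator calibration
at N = 10,000; mixed-model recovery at N = 5000.  The acceptance script
reruns the same experiments from a user seed, pooling five preset
replicates for curve-level quantities (a single draw's per-item deviations
are strongly correlated along the survey, so pooling gives the 3-SE
comparison its nominal behavior) and using 4000 subjects per arm for the
hazard-ratio recovery (two arms with literally proportional discrete
hazards h and 2h, whose grouped-data Cox estimand is ≈ 2.05 at h = 0.05).

## Known limitations

- The pairwise model is weakly identified on monotone (skip-free) pairs;
  flags mark such fits, and a whole-survey joint model with structured
  dependence is deliberately out of scope.
- Discrete-time survival *regression* (e.g. logistic hazard models) is out
  of scope; the Cox model treats item indices as event times with ties.
- Phase segmentation is heuristic; treat boundaries as annotation, not
  inference.
- Conditional (u = 0) proportions can be far from raw fractions when
  heterogeneity is large; use `scale="population"` when a marginal reading
  is wanted.
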