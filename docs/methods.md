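# Methods

## The problem

A latent class exposure X (k = 4 trajectory classes measured by p = 5
binary indicators U), a binary mediator M and a binary outcome Y, with
an exposure–mediator interaction. The estimands are the total effect
(TE), total natural indirect effect (TNIE) and pure natural direct
effect (PNDE) of each risk class versus the reference class, on the log
risk-ratio scale. Because X is never observed, the analysis must link
the measurement model (class indicators) to the structural models
(logistic regressions for M and Y) without either ignoring
classification error or letting the distal outcomes redefine the
classes.

## Measurement model

`BinaryLCA` fits P(U | X=x) = Π_j p_xj^{u_j}(1−p_xj)^{1−u_j},
P(X=x) = π_x by EM.

* **Pattern compression.** All computation runs on the distinct response
  patterns (≤ 3^p including missing codes), so n = 10^6 costs the same
  as n = 10^3.
* **Missing indicators** contribute their observed cells only (FIML
  under MAR). Mediator, outcome and confounders must be complete;
  complete-case selection is the caller's responsibility.
* **Restarts.** 20 random starts, each run for 100 iterations; the best
  is continued to convergence (relative log-likelihood change < 1e-8,
  cap 5,000 iterations). Starts are near-one-hot Dirichlet(0.2)
  responsibilities per pattern: flat random starts systematically merge
  classes when the indicators are strongly class-determined, while
  sharp starts behave like random partitions and reach the global
  optimum across all presets in our checks.
* **Boundary handling.** Item probabilities are clamped to
  [1e-6, 1−1e-6]. Parameters estimated at the clamp carry no usable
  curvature: they are treated as fixed when the observed-information
  matrix is inverted (their SE is reported as NaN and flagged), instead
  of producing astronomically inflated SEs through a floored eigenvalue.
  The same treatment applies to the one-step model's joint information.
* **Label switching.** After fitting, classes are aligned to reference
  item-probability profiles (the generating profiles in simulations) by
  minimizing the total absolute profile difference over all k!
  permutations; without a reference, classes are ordered by ascending
  size so the largest class is last and serves as the reference level of
  the structural models.
* **Parameter covariance** is the inverse of the numerically
  differentiated observed-data information at the estimate (central
  differences), with the boundary profiling above. A dataset-level
  "inflated" flag fires when any free-parameter SE exceeds 25 on the
  logit scale or the information has a near-zero eigenvalue — an
  indication of a likelihood ridge (weakly identified classes), seen
  mainly at poor separation.

`CovariateLCA` adds a multinomial-logit structural model
P(X=x | z) = softmax(γ_x + δ_x'z) (reference class last), fit by EM with
a damped-Newton partial M-step (generalized EM). It backs the inclusive
pseudo-class-draw estimator with z = (M, Y, confounders).

## Structural models and effects

Both logistic models are fit by Newton–Raphson ML with frequency
weights. A hand-rolled fitter is used because the BCH estimator requires
negative weights and separation is handled by an automatic Firth
(Jeffreys-penalty) refit; the implementation is verified against
statsmodels GLM on ordinary fits in the test suite. Separation is
declared when a fitted probability is within 1e-8 of 0/1 and a
coefficient exceeds 12 in absolute value.

Effects are computed by direct application of the mediation formula.
With confounders, the formula is evaluated per confounder row of the
analysis sample and averaged (marginal standardization), so reported
effects are marginal. Standard errors are delta-method: central
finite-difference gradients (step 1e-5, relative) of each log-RR effect
with respect to the stacked (α, β), sandwiched with the coefficient
covariance — block-diagonal for separately fitted models, the full joint
(α, β) block of the inverse observed information for the one-step model
so class-derivation uncertainty propagates. The delta SEs agree with a
10,000-draw parametric simulation within 10% on the population fit.

## Linking estimators

* **Modal** assigns each person to the posterior-modal class (ties to
  the lowest class index) and ignores misclassification.
* **BCH** expands each person into k pseudo-rows weighted by
  inv(D)[w, ·], where D[x, w] = P(W=w | X=x) is estimated from the
  posterior matrix. Negative weights are retained; a condition number
  above 1e8 triggers an unreliability warning.
* **nPCD / incPCD** draw 40 imputations of class membership from the
  unconditional / conditional posterior, fit the structural models per
  draw, and pool each log-RR effect (not the coefficients) by Rubin's
  rules: total variance = within + (1 + 1/m)·between; the Monte Carlo
  error of the pooled estimate is sqrt(between/m) and is reported as a
  ratio to the pooled SE so the ≤10% imputation-count rule can be
  checked. A draw that leaves a class empty is redrawn from a fresh
  substream.
* **One-step** maximizes the joint likelihood in which M and Y act as
  additional class indicators. The M-step updates (α, β) by short
  warm-started Newton steps (generalized EM; the observed log-likelihood
  is still monotone). The within-class threshold SEs from its joint
  information feed the exclusion rule.
* **uPCD** (`UpdatedPCDMediation`): after an unconditional LCA (step 0)
  and null structural fits (step 1), each cycle perturbs (γ, τ) with a
  zero-mean Gaussian draw from their joint sampling covariance, forms
  P(X | U, M, Y) from the perturbed measurement parameters and the
  current perturbed (α, β), draws W, refits both logistic models, and
  perturbs the new (α, β). After a burn-in of 100 cycles, the current W
  is stored every 20 cycles until 80 imputations exist; per-imputation
  mediation fits are pooled by Rubin's rules. Defaults follow the study
  design (burn-in 100, thinning 20, m = 80; m = 80 keeps the Monte Carlo
  error below 10% of the pooled SE in our runs). Design choices where
  the procedure was open:
  - the chain continues with thinning rather than re-running burn-in per
    imputation (an `independent_restarts` switch offers the other
    reading);
  - the measurement parameters are re-perturbed every cycle;
  - boundary-flagged measurement parameters are not perturbed (their
    perturbation variance is zero by the profiling above), a controlled
    form of the perturbation that would otherwise destabilize the chain;
  - convergence is monitored rather than adaptively stopped: the
    diagnostics report Mann–Kendall trend tests on the (α, β) traces
    (Bonferroni at 1%), empty cells in the W×M×Y cross-tab, and the
    threshold-SE exclusion verdict. Two consecutive empty-class draws
    raise a dataset-level error.

## Synthetic-data generator

`SimScenario` encodes the study population: class prevalences
8/10/12/70% (EOP/AO/CL/Low), P(M=1|X) = (0.325, 0.350, 0.208, 0.163) and
P(Y=1|X,M) fixed by a 4×2×2 cross-tabulation, giving marginal
P(M=1) = 0.20 and P(Y=1) = 0.378 and the closed-form log-RR estimands
(TE 0.3567 / TNIE 0.0570 / PNDE 0.2996 for EOP vs Low, etc.).
Indicators are conditionally independent given class; M depends only on
X; Y only on (X, M).

The three study conditions differ only in measurement separation. Base
trajectory shapes (EOP high 0.8 throughout; AO increasing 0.1→0.8; CL
decreasing 0.8→0.1; Low flat 0.1) are scaled on the logit scale around
each item's across-class midpoint by one scalar, chosen by bisection so
the **exact population relative entropy** — enumerated over all 2^5
patterns, hence deterministic — hits 0.90 / 0.80 / 0.70 (±1e-4). The
poorest pairwise separation is AO and CL versus Low, matching the
intended qualitative structure.

What the generator does **not** emulate: the original study's exact
per-indicator thresholds (only total entropy and shape topology are
matched). Pairwise separation is underdetermined by total entropy; with
these shapes the large-n attenuation of the TE (EOP vs Low) is −18.4%
(modal) and −24.8% (nPCD) at entropy 0.70, a few points milder than the
attenuation reported for the original profiles. Passing tests therefore
demonstrate the direction and approximate size of the method ordering,
not digit-level equality of bias percentages. Real cohort data also
carry missingness, confounding and indicator dependence that the
generator omits by design.

## Simulation harness

`run_replicates` seeds each replicate independently from one root
`SeedSequence` (results are order-independent), shares the unconditional
LCA fit across the methods that start from it, and records per-replicate
estimates, model SEs, failure reasons and the threshold-SE statistics.
`apply_exclusions` implements the non-convergence rule: a replicate is
excluded for all methods when the unconditional or one-step model either
(a) raised the inflated-SE flag, or (b) has a largest within-class
threshold SE strictly greater than twice the cohort average of the
per-replicate maxima among non-flagged replicates. Stage (a) exists
because ridge replicates can produce SEs orders of magnitude large,
which would otherwise dominate the stage-(b) average and defeat the
rule. `performance` computes bias, percentage bias (flagged unreliable
when |truth| < 0.02), coverage and bias-eliminated coverage of 95% Wald
intervals (normal reference, also for Rubin-pooled estimates), empirical
SE and average model SE, each with the standard Monte Carlo SEs.

Problem sizes: the packaged study test uses 100 replicates per scenario
for the fast estimators and 60 for the one-step/incPCD/uPCD arm at
n = 5,000, chosen so a full run completes on one CPU in minutes; the
percentage-bias summaries are plain means over all generated replicates,
while the exclusion rule is exercised separately.

## Known limitations

* Binary mediator and outcome only; no latent class mediators or
  outcomes; no bootstrap or Monte Carlo confidence intervals.
* Class enumeration is out of scope: k is assumed known.
* Confounder handling uses marginal standardization over the empirical
  confounder distribution; weights other than frequency weights are not
  supported in the structural fits.
* Rubin pooling uses the large-sample normal reference without a
  small-sample degrees-of-freedom correction.
* At poor separation a non-negligible share of replicates sits on a
  likelihood ridge; their SEs are flagged and excluded rather than
  repaired, and the exclusion share exceeds what better-identified
  measurement designs would produce.
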