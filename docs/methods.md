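# Methods

`matchedcv` estimates how well tabulated multimodal markers (neuroimaging
panels plus physical-health measures) classify a rare, demographically
confounded binary outcome, while preventing the demographics themselves from
inflating the estimate. This note documents the model, the defaults, the
synthetic-data generator, and the numerical and design choices.

## The estimation problem

The target population is a large pediatric cohort (~8,500 children aged
9–10) in which ~1.4% carry the outcome label and cases are strongly
sex-skewed (~82% male vs ~49% among controls), with additional age and
race/ethnicity imbalance. Two things go wrong with a naive classifier on
such data: (i) extreme class imbalance makes accuracy-type metrics
degenerate, and (ii) any marker correlated with sex or age acquires apparent
predictive value that is demographic, not biological. The pipeline addresses
both with propensity-score matching *inside* a cross-validation loop.

## Pipeline

One run of `run_condition` executes, for each of R repetitions:

1. **Stratified K-fold partition** (default K=5) preserving the
   case:control ratio per fold.
2. Per CV iteration, on the training folds only:
   - **Standardization** of each marker to training mean 0 / SD 1
     (population SD, ddof=0).
   - **Correlation pruning**: while any retained marker pair has training
     |Pearson r| > P (default 0.90), one violating pair is picked at random
     and one member dropped uniformly at random. Zero-variance markers are
     dropped first. Within a redundant pair the two members are
     interchangeable, so the random choice is unbiased across seeds; the
     iterative re-scan terminates because each step removes one marker.
   - **Bagged matched ensemble**: N (default 10) independent 1:1 matched
     cohorts are drawn by stochastic k-nearest-neighbor matching in
     propensity-score space (default k=10); each trains one ridge-penalized
     logistic member.
3. **Matched validation**: exactly one matched realization is drawn from the
   held-out fold and scored with the mean member probability. Out-of-fold
   predictions are pooled across the K folds, and AUC-ROC, AUC-PR (average
   precision), accuracy, sensitivity and specificity (decision threshold
   0.5) are computed once per repetition.
4. Summaries report the median across repetitions with a nonparametric 95%
   interval (2.5th/97.5th percentiles, linear interpolation).

Because training and validation folds are disjoint, a participant can never
appear in both a training matched set and the validation matched set of the
same iteration; `run_condition(audit=True)` records the id sets so the
guarantee can be asserted rather than assumed.

### Matching details

Distance is the absolute difference of propensity scores; no caliper. Cases
are visited in random order; each receives one control drawn uniformly from
its k nearest remaining controls, and the control leaves the pool (no reuse
within a realization). Distance ties are broken by participant id before
sampling, so a seeded generator fully determines the realization. The
no-reuse rule guarantees distinct 1:1 membership; random case order removes
systematic order bias across realizations. Balance is diagnosed with
standardized mean differences (group mean difference over pooled SD,
categoricals as indicators); on the reference confounded simulation the mean
|SMD| over demographics drops from ~0.28 to ~0.03 after matching.

### Ridge-logistic members

Each member minimizes

J(w, b) = (1/n) Σᵢ log(1 + exp(−sᵢ(xᵢᵀw + b))) + (λ/2n)‖w‖²,

with sᵢ = ±1, intercept unpenalized (on a 1:1 matched cohort it is a
base-rate term that should float), and λ = 1 by default — the per-sample
scaling makes λ the reciprocal of the usual C parameter. The objective is
strictly convex, so the solution is unique; a damped Newton iteration with
backtracking drives the gradient infinity-norm below 10⁻¹⁰, making fits
reproducible to well under 10⁻⁶ regardless of initialization. Ensemble
aggregation is the arithmetic mean of member probabilities (standard bagging
for probabilistic classifiers; majority vote and mean-logit were the
alternatives, rejected because the mean probability keeps the output an
interpretable probability and is the convention for bagged classifiers).

### Unmatched diagnostic pathway

`run_condition(matched=False)` trains a single ridge member per fold on the
full imbalanced training fold and scores the full held-out fold. It exists
to quantify confounding: on a cohort where demographics drive both outcome
and markers (and markers have no direct effect), the unmatched estimator
reads AUC ≈ 0.63 while the matched estimator sits at chance.

### Shapley importance

For the linear log-odds margin f(x) = wᵀx + b with features treated as
independent (interventional background), the Shapley value has the exact
closed form φᵢ = wᵢ(xᵢ − rᵢ) against a reference point r; local accuracy
(Σφ = f(x) − f(r)) holds to machine precision, and the test suite checks the
closed form against exhaustive 2^M coalition enumeration. Each member uses
its own matched training cohort's standardized means as the reference;
member attributions are averaged per validation row; a marker's importance
is the mean of |ensemble φ| over all validation rows, folds and repetitions.
Markers pruned in some folds are averaged over the folds where they were
retained, with the coverage fraction reported. Direction signs come from the
mean fitted weight (not the signed mean φ), mirroring the convention of
reporting regression-coefficient signs next to importance ranks. Attribution
on the probability scale has no closed form for logistic models and is
deliberately out of scope, as are conditional-expectation backgrounds; with
correlated features the independence assumption spreads credit across
correlated markers, which the pruning step mitigates but does not remove.

## Synthetic cohort generator

The generator produces, in order: demographics (age ~ N(9.93, 0.63²) years;
sex ~ Bernoulli with the control male fraction 0.493; race/ethnicity
5-level categorical at frequencies 0.544/0.204/0.132/0.018/0.102); the
outcome from a logistic model in those demographics; markers; and the true
propensity score.

- **Prevalence is a contract**: the outcome-model intercept is solved
  numerically (Brent) so the expected case fraction equals the configured
  prevalence (default 0.014) exactly.
- **Sex skew**: the sex log odds-ratio is logit(0.822) − logit(0.493), the
  rare-outcome value that makes the case mix ~82.2% male. Age (+0.18/year)
  and race effects (Hispanic −0.19, Black −0.10, Asian −0.81, Other +0.45
  vs White) reproduce the reference cohort's composition skews.
- **Markers**: each modality block shares one latent factor, giving a known
  pairwise within-block correlation; `confounding_strength` adds the
  standardized demographic log-odds to every marker, so demographics
  confound markers and outcome jointly; planted effects add a mean shift of
  `size` (in pre-confounding noise SD units) to cases. Near-duplicate pairs
  overwrite one non-planted marker with 0.95 × its partner plus noise to
  exercise pruning.
- **Propensity** is the true model probability, clipped to [10⁻⁶, 1−10⁻⁶]
  (mirroring a design in which scores are supplied with the dataset rather
  than refit); for cohorts loaded from disk without a generator,
  `compute_propensity` fits a demographic-only logistic model.

Default blocks scale the reference marker panels to ~1/4 size (77 markers
across s-MRI, DTI, RSI, f-MRI Rest, Anthropometrics, Medical-History,
SDSC); default planted effects are modest (|d| 0.10–0.30) and concentrated
in SDSC, f-MRI and s-MRI with RSI null, emulating the qualitative modality
ordering seen in the target population. The distributional form of real
propensity scores is not public; the logistic form here is a modeling
choice.

**What the generator does not emulate**: missing data, acquisition sites and
site effects, longitudinal waves, non-Gaussian marker distributions,
heavy-tailed measurement error, and realistic cross-modality correlation
beyond the shared demographic factor. Passing tests therefore demonstrate
the pipeline's statistical behavior (calibration under the null, confound
removal, signal recovery, balance, no leakage, reproducibility) — not
real-data classification performance, which depends on effect sizes and
correlation structure the generator only stylizes.

## Problem sizes and defaults

Library defaults are the reference configuration (K=5, k=10, N=10, P=0.90,
threshold 0.5, λ=1); `repetitions` defaults to 50, with 300 available to
mirror the study-scale protocol. The test suite and the acceptance script
run at desk scale as the package's own choice of test conditions: cohorts of
800–5,000 participants, R = 1–50, and 20 master seeds for the recovery
study; `scripts/acceptance.py` uses n = 4,000 and R = 20 for the ablation
grid.

## Known limitations

- Specificity on matched validation sets describes the matched control
  subsample, not the control population; it is reported as-is, consistent
  with the matched-evaluation design.
- λ is not tuned (no nested CV by design); the default favors stability in
  the p ≫ n matched regime.
- The permutation-null calibration uses a fresh label permutation per
  repetition; with ~28 cases a single frozen permutation carries sampling
  noise of ±0.07 AUC, which would dominate the diagnostic.
- Matching assumes the supplied propensity is a faithful one-dimensional
  summary of the demographics; a misspecified score leaves residual
  imbalance that the SMD report will reveal but the pipeline will not fix.
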