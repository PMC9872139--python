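# Methods

`snvsig` builds survival-prognostic signatures from highly sparse binary
genotype matrices (rare somatic mutations coded 0/1 per gene per patient).
The pipeline has four stages; each is usable on its own.

## 1. Univariable Cox screening

Every marker `x_j ∈ {0,1}^n` is fitted in its own Cox proportional-hazards
model by Newton iteration on the partial likelihood with the **Efron**
correction for tied event times. Markers with Wald `p < α` (default
`α = 0.05`) are kept. This is a deliberately rough pre-filter: no
multiple-testing correction is applied, because the goal is to reduce
dimension for the auto-encoder, not to make inferential claims.

Numerical choices: Newton steps are damped (clipped to ±2 per iteration);
a fit whose coefficient escapes |β| > 15, or whose information vanishes, is
flagged non-converged (monotone likelihood, typical for markers whose few
carriers all die early) and is never retained. Markers with fewer than 2
carriers are excluded before fitting — with one carrier the coefficient is
determined by a single subject and the Wald test is meaningless.

## 2. Auto-encoder feature compression

A single-hidden-layer auto-encoder maps inputs `x ∈ [0,1]^p` through
`y = ReLU(Wx + b)` (hidden dimension `d`, default 100) and back through
`z = h(W'y + b')`. The decoder `h` is sigmoid paired with mean
cross-entropy (MCE) loss — the pairing appropriate when entries are bit
probabilities — or ReLU paired with mean squared error. Losses are averaged
over all `n·p` entries (the convention of mainstream deep-learning
frameworks, which is what makes reported loss magnitudes comparable across
matrix shapes). Continuous inputs are min-max normalized to `[0,1]` first;
0/1 matrices pass through unchanged.

Training is plain NumPy: Glorot-uniform initial weights and zero biases
from the config seed, Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-7), mini-batches
re-shuffled each epoch from a seeded generator, the final incomplete batch
kept. Defaults follow the regime the pipeline targets: learning rate 0.005,
batch size 32, 200 epochs for genotype matrices. Gradients are exact
analytic expressions, verified against central finite differences to 1e-5
relative error in the test-suite. Sigmoid outputs are clipped to
`[1e-7, 1-1e-7]` inside the MCE only. Weights are untied by default; tied
weights (`W' = Wᵀ`) are supported.

*Binary accuracy* is the fraction of entries whose 0.5-thresholded
reconstruction exactly equals the input entry; inputs that are not exactly
0 or 1 can never match, so on continuous data the metric measures the
exact-zero content reconstructed on the correct side of the threshold.
Under this single definition, two reconstruction orderings hold and are
tested as statistical properties over ≥5 seeds:

* *sparser is easier* — matched continuous image sets with 80% vs 50%
  zeros: the sparser set ends with higher binary accuracy;
* *sigmoid/MCE beats ReLU/MSE on sparse binary matrices* — the ReLU/MSE
  decoder plateaus just below perfect reconstruction (dead units on rare
  carriers) while sigmoid/MCE reaches accuracy 1.0 under the same budget.
  On continuous sparse images the two pairings converge to the same
  thresholded accuracy, so the ordering is asserted where it is real:
  binary inputs, the pipeline's actual domain.

## 3. LASSO feature selection

**Linear LASSO.** With standardized predictors and centered response the
objective is `Σᵢ(yᵢ − Σⱼ xᵢⱼβⱼ)² + λΣⱼ|βⱼ|`, solved by cyclic coordinate
descent with soft-thresholding (stationarity tolerance 1e-7 on max |Δβ|).
Along a decreasing λ path, candidates are pre-screened by the sequential
strong rule `|2xⱼᵀr(β_prev)| ≥ 2λ_k − λ_{k−1}`; because the rule can
(rarely) discard an active predictor, the KKT conditions are re-checked
over all predictors after convergence and violators are re-solved, so
screened solutions are exact. The violation counter is exposed.

**LASSO-Cox.** The penalized objective is `−(1/n)·logPL(β) + λ‖β‖₁` with
the **Breslow** tie approximation, maximised by iteratively reweighted
least squares: each outer step builds the diagonal quadratic expansion of
the partial likelihood in the linear predictor and solves the weighted
LASSO by coordinate descent (numba-compiled inner sweeps). Predictors are
standardized internally by population SD and coefficients are reported on
the original scale. This matches R `glmnet` conventions exactly; the
test-suite pins coefficients against frozen `glmnet 4.1-10` reference
solutions at matched λ, including the identical `λ_max`.

Ties asymmetry, deliberate: Breslow inside penalized fits (cheap and
standard for coordinate-descent Cox), Efron in the unpenalized screening
and evaluation fits.

λ grid: 100 points log-spaced from `λ_max` down to `0.01·λ_max`
(`0.05·λ_max` when p > n). At any grid point at or above the training
data's own `λ_max` the null model is returned by construction, so a flat
cross-validation curve resolves to the empty model rather than to numerical
dust. λ is tuned by 10-fold cross-validated partial-likelihood deviance in
the leave-fold-out difference form `−2[logPL_all(β^{(−k)}) −
logPL_train(β^{(−k)})]`, which stays defined for tiny held-out risk sets.
Folds are stratified on event status and re-randomized (capped retries) if
a training split lacks events. Default selection rule is the CV minimum
(ties to the largest λ); the one-standard-error rule is exposed and is what
recovers the "nothing is selected from pure noise" behaviour exactly.

## 4. Signature evaluation

The selected features enter a multivariable Cox fit (lifelines); the risk
score is the linear predictor at mean-centered covariates, hence mean 0.
Evaluation reports:

* **Harrell's C** — usable pairs are those where the earlier time is an
  observed event (tied event times are not comparable; an event tied with a
  censoring time is usable); score ties count ½. The standard error comes
  from the per-subject influence decomposition of the ratio U-statistic.
  The implementation is checked against an O(n²) brute-force pair counter
  and against scikit-survival.
* **R²** — Cox–Snell `1 − exp(2(l₀−l₁)/n)` rescaled by its attainable
  maximum (Nagelkerke); both raw and rescaled values are reported, since
  the cited R fitting functions print the rescaled one. The null partial
  likelihood uses the same Efron convention as the fit.
* **Cross-validated C and R²** — k-fold (default 5), folds stratified on
  event status; backward stepwise-AIC pruning (`AIC = −2logPL + 2k`) is
  applied *inside each training fold* to avoid leaking held-out
  information. Dispersion across folds is reported as SD, with the SE of
  the mean alongside.
* **Optimal cutoff** — maximally selected standardized log-rank statistic
  over midpoints between distinct order statistics, each group constrained
  to hold ≥ `minprop` (default 0.1) of the samples; ties break to the lower
  cutpoint. The internal z-statistic squared is checked against the
  lifelines log-rank χ².
* **Kaplan–Meier / log-rank** — lifelines estimators behind the module
  surface.
* **Time-dependent AUC** — cumulative-case/dynamic-control AUC with IPCW
  from the Kaplan–Meier censoring distribution (scikit-survival), CIs by
  seeded bootstrap (200 resamples). Default time grid: eight points up to
  the 90th percentile of follow-up; explicit grids (e.g. 2/5/8 years in
  days) are configurable. Times outside the observed range are dropped with
  a warning.
* **Breslow baseline / calibration** — `H₀(t)` steps by `d_k / Σ_{risk}
  exp(lp)` at each event time (reduces to Nelson–Aalen at `lp = 0`);
  predicted `S(t|x) = exp(−H₀(t))^{exp(lp)}` is compared per risk group and
  time against the Kaplan–Meier estimate, with the signed deviation
  (positive = survival overestimated).

## Pipeline orchestration

One global seed fans out to per-stage seeds via a stable hash of the stage
name (all below 2³¹), so stages can be rerun independently yet
reproducibly. Both arms — `ae` (screen → auto-encoder → LASSO-Cox →
evaluation) and `direct` (LASSO-Cox straight on the screened binary
markers) — consume the identical screened matrix for a given seed. An empty
screening result or an empty LASSO selection ends the run gracefully with
status `no-signal`.

## Synthetic data

`GenotypeSimSpec` draws i.i.d. Bernoulli carrier indicators (optionally
with per-predictor zero probabilities, or Gaussian-copula block correlation
that preserves the marginals) and survival from a proportional-hazards
model with exponential or Weibull baseline: `S(t|x) = S₀(t)^{exp(xᵀβ)}`,
inverted per subject. Censoring is an independent exponential whose scale
is calibrated by bisection on the realised censored fraction. The reference
scenario (`scenario_sparse_cox`) is n = 200, p = 400, 99% zeros, five true
effects with |log HR| = 1.5 and mixed signs, exponential baseline, 30%
censoring — strong rare-variant effects and typical cohort censoring;
chosen once and used unchanged by the tests and the acceptance script.

`ImageSimSpec` produces sparse continuous matrices: a `zero_prob` fraction
of exact zeros, nonzero intensities Beta(2, 2) (smooth, bounded, no pile-up
at exactly 1). `corrupt_threshold(X, τ)` zeroes entries strictly below τ —
idempotent, with zero fraction non-decreasing in τ.

What the generators do *not* emulate, hence what passing tests cannot
show: linkage disequilibrium or any realistic haplotype/correlation
structure among genes; informative censoring; the bimodal intensity
histogram of real handwritten-digit images (real digit pixels pile up near
0 and 1, Beta(2,2) does not); cohort-level covariates. Results on real
cohorts additionally wobble under auto-encoder retraining, since the
extracted features depend on the initialisation seed.

## Problem sizes and runtime choices

The test-suite and acceptance script run the reference scenario at its full
size (200 × 400, hidden dim 100, 200 epochs, 10-fold CV on both arms);
property simulations use 60–500 subjects and hundreds of replicates where a
distributional claim is tested (e.g. type-I error of screening over 600
null replicates). These sizes make the whole battery complete in a few
minutes on one CPU while keeping every statistical assertion at a scale
where its standard error is small relative to the asserted band.

## Known limitations

* Apparent (training-data) C-index and R² of a model refit on
  LASSO-selected features are optimistic; the cross-validated variants are
  the honest numbers, and both are reported.
* The direct arm's behaviour on extremely sparse predictors is fragile by
  construction — with ~2 carriers per predictor the CV curve near the null
  model is nearly flat and the selected-set size varies strongly across
  seeds and fold assignments.
* No competing risks, stratification, time-varying effects, or external
  validation machinery.
* The maxstat cutoff p-value is not corrected for the maximal selection
  (only the cutpoint location is used downstream).
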