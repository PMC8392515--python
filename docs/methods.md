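# Methods

## Model

The model is a linear-Gaussian SEM over eight structural variables — four
latent constructs (`ses`, `lifestyle`, `healthy_food`, `unhealthy_food`),
two observed exogenous controls (`parent_bmi`, `parent_body_fat`) and two
observed outcomes (`bmi`, `body_fat`) — with fifteen directed paths forming
a DAG: `ses` is exogenous; `lifestyle`, `healthy_food` and `unhealthy_food`
mediate; each outcome is regressed on the four latents plus its own parental
control. The measurement model is reflective: 17 indicators load on their
construct with uncorrelated normal uniquenesses. Writing `s = B s + ζ`
(`Cov ζ = Ψ` diagonal) and `y = Λ s + ε` (`Cov ε = Θ` diagonal, zero for
directly observed structural variables), the implied covariance is

    Σ(θ) = Λ (I−B)⁻¹ Ψ (I−B)⁻ᵀ Λ' + Θ.

Assumptions: indicators are treated as continuous after per-column
z-standardization (the Likert origin of the survey items is ignored by all
estimators); rows are i.i.d.; no missing data (the fit functions reject
incomplete input); exogenous variables are mutually uncorrelated.

Identification and scale: every latent has unit variance and its first
loading is constrained positive, so all reported loadings and path
coefficients are fully standardized. The fixed coordinate order is
(socioeconomic 1–6, lifestyle 1–4, healthy 1–3, unhealthy 1–4,
`parent_bmi`, `parent_body_fat`, `bmi`, `body_fat`).

## Synthetic-data generator

`generate_study` emulates the survey layout this model was designed for:
`n_total` defaults to 881 completed questionnaires, split into boy/girl
groups (default fraction 0.5 — the source study does not report group
sizes; sizes are `round(n·f)` and the remainder). Per group, the generating
truth (`default_true_params`) uses the published standardized loadings for
all 17 indicators and the published per-group standardized path
coefficients; residual variances are the unique values that give every
variable unit total variance (walking the DAG in topological order and
setting `ψ = 1 − b'Σ_pp b`; any coefficient set whose systematic variance
reaches 1 is rejected). Rows are i.i.d. draws from `N(0, Σ(θ_true))` via a
Cholesky factor, bit-reproducible from the seed.

What the generator does *not* emulate: ordinal (Likert-binned) responses —
a quantile-based discretizer is provided but off by default since every
estimator treats indicators as continuous; non-normal tails; missing or
careless responses; cluster structure from school-based sampling; and any
dependence between the controls and socioeconomic status. Passing tests
therefore demonstrate correctness of the estimators under the model's own
assumptions, not robustness to the ways real survey data violate them.

## Reliability and validity stage

Loadings entering the elimination rule come from a single-factor
maximum-likelihood factor analysis per construct (scikit-learn
`FactorAnalysis`) on the z-scored indicator block, standardized as
`w/sqrt(w² + ψ)` and sign-anchored so the block's loading sum is positive.
The thresholds are alpha > 0.7, AVE > 0.5 and loading ≥ 0.7; an indicator
loading *strictly below* 0.7 is dropped (a loading of exactly 0.7 is
retained), and constructs are re-summarized on the survivors. The filter is
idempotent, and a construct left without indicators is flagged invalid
rather than silently removed. The pipeline applies one extra guard when
acting on the filter's verdicts: a construct always keeps at least its two
strongest indicators, because a single-indicator latent with a free loading
and free uniqueness is not identified in the ML/Gibbs parameterizations.

## Gibbs sampler

Full conditionals cycle over:

1. **Latent scores.** Given parameters, each row's latent vector is normal
   with precision `Σ_η⁻¹ + Λ'Θ⁻¹Λ + Γ'Θ_z⁻¹Γ` (identical across rows, so
   the draw is vectorized); the outcome equations contribute through their
   latent coefficients Γ after subtracting the control terms.
2. **Coefficients.** Every loading, latent-to-latent path and outcome
   regression has a conjugate normal update. Prior means: the eight
   latent→outcome paths take the active regime's hyperprior means; all
   other coefficients (loadings, mediation paths, control paths) take 0.5,
   the study's "0.5 to all unknown coefficients" convention. Prior variance
   defaults to 1.0 (the "small variance" convention) with per-path
   overrides available; regime II halves and regime III doubles exactly the
   eight hyperprior means.
3. **Residual variances.** Conjugate inverse-gamma with the noninformative
   (0.01, 0.01) shape/scale.

Scale and sign identification are imposed inside the chain: after every
latent-score draw the four score columns are re-centered and rescaled to
unit variance, and after the coefficient draws any latent whose first
loading came out negative is reflected (scores, loadings and all touching
coefficients flip sign). The chain therefore samples standardized
coefficients directly; the per-sweep rescaling is a pragmatic
identification device (akin to parameter expansion), and its agreement with
standardized ML — max |Bayes − ML| ≈ 0.002 at n = 5000 — is the check that
it targets the intended posterior.

Defaults: 2 chains × 10 000 iterations with 5 000 burn-in and thin 1; the
pipeline and tests use shorter chains (≈1 000–3 000 iterations) because the
sampler mixes quickly on this model (split-R̂ < 1.05 throughout — the
classic split-chain Gelman–Rubin factor, cross-checked against
`arviz.rhat(method="split")`). The point estimate is the posterior mean;
the reported uncertainty is the posterior SD with the population (ddof = 0)
convention, and intervals are central 95% quantiles. Degenerate inputs
(zero-variance columns, non-finite draws) abort with the offending
variable or parameter named.

## Maximum likelihood

`fit_ml` minimizes `F = log|Σ(θ)| + tr(SΣ⁻¹) − log|S| − p` on the
correlation matrix of the observed columns. Free parameters: 17 loadings,
15 paths, and log-parameterized variances (17 uniquenesses, 5 disturbances,
2 control variances; exogenous latent variance fixed at 1) — 56 in the full
model, giving df = 231 − 56 = 175. The gradient is analytic (trace-form
derivatives of Σ through Λ, B, Ψ, Θ), optimization is multi-start L-BFGS-B
(a principal-axis/proxy-regression start plus jittered restarts; restarts
agree to 1e−6 in F), and `chisq = (n−1)·F_min`. Output is standardized
through the implied variances; standard errors are
`acov(θ) = 2/(n−1) · H⁻¹` with H the finite-difference Hessian of the
analytic gradient, pushed through the standardization map by a numerical
delta method. The type-I calibration of the downstream z-test (empirical
per-path rejection rates 0.04–0.06 at n = 441 per group) is the end-to-end
validation of these SEs.

## PLS path modeling

Classical PLS with Mode-A outer weights and the centroid inner scheme,
tolerance 1e−6 on the normalized weight change, at most 300 iterations;
controls and outcomes are single-indicator composites. Path coefficients
are OLS regressions on the standardized composite scores following the
structural DAG. Because composites carry measurement error and exclude the
outcome columns, PLS paths are systematically attenuated relative to ML —
about −0.12 on the strongest socioeconomic path at n = 5000 — which is the
expected Mode-A behavior, not an estimation defect; it also caps PLS
predictive R² below the ML/Bayes value on the same data.

## Predictions and metrics

For ML/Bayes fits, predictions apply the estimated structural equations to
regression-method factor scores `E[s|y] = V Λ'Σ⁻¹ y` computed from the full
observed vector (chosen because it minimizes mean-squared score error and
reproduces the observed outcomes exactly in the noise-free limit); PLS uses
its native composite scores. Metrics: R² is the squared Pearson correlation
of observed and predicted (the printed formula's missing squares are read
as intent); RMSE is the standard root-mean-squared error (the printed
radical is malformed); the comparison table's "MSE" formula is literally a
mean absolute error and is implemented verbatim under the name
`mse_printed`, with the conventional MSE also exposed. MAPE requires all
observed values nonzero and is otherwise refused.

Fit indices use the independence (diagonal) model as baseline
(`χ²_b = (n−1)(log|diag S| − log|S|)`, df = p(p−1)/2) and the standard
closed forms for NFI/IFI/RFI/TLI/CFI plus the ML trace-form GFI. CFI ≥ NFI
holds whenever the baseline's χ²/df ratio is at least the model's — the
property test uses that (correct) precondition.

## Moderation

Per-path critical ratios between independent group fits, with each group's
own SE (posterior SD for Bayes, delta-method asymptotic SE for ML) and no
pooling; two-sided normal p-values, significance at |z| > 1.96, rows in the
published table order. p-values are clamped to the smallest positive float
so the (0, 1] contract survives underflow at extreme z.

## Problem sizes used in the test suite

Parameter recovery runs 50 replicates at n = 2000 (alternating girl/boy
truth, ±0.10 band on every path); prior-regime robustness at n = 2000
(< 0.05 shift); Bayes-vs-ML agreement at n = 5000 (< 0.03); moderation
type-I calibration with 1000 replicate pairs at n = 441 per group
(rate 0.05 ± 0.02 per path); Monte-Carlo covariance checks at 10⁵–10⁶
rows. These sizes make the whole suite run in a few minutes while keeping
each check's sampling error well inside its assertion band.

## Known limitations

- The sampler's per-sweep score standardization is an approximation to an
  exactly-identified posterior; it is validated by ML agreement rather than
  by a formal invariance argument.
- No ordinal/probit measurement model, no missing-data augmentation, no
  measurement-invariance testing across groups, and no bootstrap SEs for
  PLS (moderation inference is restricted to Bayes/ML fits).
- Reported group-level results inherit the generator's idealizations; in
  particular the R² values of the predictive comparison reflect
  regression-method scores conditioned on the full observed vector and are
  not comparable to out-of-sample predictive accuracy.
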