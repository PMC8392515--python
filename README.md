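# obesem

Multi-group structural equation modeling (SEM) of adolescent obesity:
Gibbs-sampler Bayesian estimation alongside maximum-likelihood (ML) and PLS
path modeling, exercised end to end on synthetic survey data with known
ground truth.

## The problem

Adolescent obesity studies commonly model body mass index (BMI) and body fat
as joint outcomes of household socioeconomic status, lifestyle and eating
behavior. The model implemented here has four latent constructs measured by
17 survey indicators —

| construct | indicators |
| --- | --- |
| household socioeconomic (`ses`) | parents' age, education and income (6) |
| `lifestyle` | sleep, physical activity, screen time, pocket money (4) |
| `healthy_food` | fruits, vegetables, whole grains (3) |
| `unhealthy_food` | snacks, fast food, soft drinks, sweets (4) |

— plus two observed outcomes (`bmi`, `body_fat`) and two parental controls
(`parent_bmi`, `parent_body_fat`). Socioeconomic status acts on the outcomes
directly and through three mediators (lifestyle and the two food-intake
constructs), giving fifteen directed paths; gender moderates every path and
is handled by fitting the boy and girl models separately and comparing
coefficients with the critical-ratio test
`z = (b_boy − b_girl) / sqrt(se_boy² + se_girl²)` at |z| > 1.96.

All coefficients are fully standardized: each latent has unit variance with
its first loading constrained positive, and indicators are z-scored. In
matrix form the structural system is `s = B s + ζ`, `Cov(ζ) = Ψ`, with
observations `y = Λ s + ε`, so the implied covariance is
`Σ = Λ (I−B)⁻¹ Ψ (I−B)⁻ᵀ Λ' + Θ`.

Because the original survey data are not public, the package ships a
first-class synthetic-data generator whose defaults reproduce the study
conditions: 881 respondents split into boy/girl groups, the published
standardized loadings, and the published per-group path coefficients as
ground truth (residual variances solved so every variable has unit
variance). Everything downstream — the reliability filter (Cronbach's alpha
> 0.7, AVE > 0.5, loading ≥ 0.7), the Gibbs sampler with its Type I/II/III
hyperprior regimes, ML with analytic gradients, PLS (Mode-A outer, centroid
inner), fit indices (GFI/NFI/IFI/RFI/TLI/CFI), predictive metrics
(R², RMSE, MAPE) and the moderation table — runs against that known truth.

## Worked example

```python
import obesem as ob

study = ob.generate_study(n_total=881, boy_fraction=0.5, seed=0)
spec = study.spec.drop_indicators(["age_father", "age_mother", "income_mother"])
prior = ob.make_prior("II", ob.default_prior("girl"))
mcmc = ob.McmcConfig(n_iterations=3000, burn_in=1000, n_chains=2, seed=0)
fit = ob.fit_bayes(study.group_data("girl"), spec, prior, mcmc)
print(ob.posterior_summary(fit).loc[
    ["ses->healthy_food", "ses->lifestyle", "unhealthy_food->bmi"]].round(3))
```

prints

```
                     estimate     se  ci_low  ci_high  rhat
parameter
ses->healthy_food       0.553  0.049   0.458    0.650   1.0
ses->lifestyle          0.072  0.055  -0.037    0.180   1.0
unhealthy_food->bmi     0.774  0.038   0.702    0.849   1.0
```

The 441 girls in this draw were generated with true coefficients 0.61, 0.05
and 0.71 on those three paths: each posterior mean lands within about one
posterior SD of its generating value, the 95% credible intervals cover the
truth, and split-R̂ = 1.0 says the two chains mixed. Socioeconomic status
shows its strong positive effect on healthy food intake while its path to
lifestyle is indistinguishable from zero — the same qualitative pattern the
girl model is built from.

The same analysis runs from the shell:

```
obesem simulate --n-total 881 --seed 0 study.csv
obesem fit study.csv --group girl --regime II
obesem moderate study.csv          # 15-row boy-vs-girl critical-ratio table
obesem run-all --seed 0            # full pipeline bundle (CSV + manifest)
```

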