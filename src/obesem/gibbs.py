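"""Bayesian estimation of the SEM by Gibbs sampling.

The sampler cycles over the full conditional distributions of

(a) the per-respondent latent scores given loadings, paths and variances
    (multivariate normal, identical precision across respondents),
(b) every loading and regression coefficient given the latent scores
    (conjugate normal), and
(c) every residual variance (conjugate inverse-gamma).

Identification: after each latent-score draw the score columns are
re-centered and rescaled to unit variance, and after the coefficient draws
each latent is reflected if its first loading is negative.  The chain
therefore samples fully standardized coefficients directly, matching the
standardized output convention of the rest of the package.

Priors are normal on coefficients (the eight latent->outcome means come from
the prior regime, everything else defaults to mean 0.5 with the common
"small" variance) and inverse-gamma on residual variances (noninformative
(0.01, 0.01) by default).  The posterior point estimate is the mean of the
retained draws; the reported uncertainty is the posterior standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model_spec import (
    ModelSpec,
    ParameterSet,
    PriorConfig,
    default_prior,
)

__all__ = [
    "McmcConfig",
    "BayesFit",
    "fit_bayes",
    "posterior_summary",
    "prior_sensitivity",
    "split_rhat",
]


@dataclass(frozen=True)
class McmcConfig:
    n_iterations: int = 10_000
    burn_in: int = 5_000
    thin: int = 1
    n_chains: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.n_iterations:
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")

    @property
    def n_draws_per_chain(self) -> int:
        return (self.n_iterations - self.burn_in) // self.thin


def split_rhat(chains: np.ndarray) -> float:
    """Classic split-R-hat: each chain is halved, then the Gelman-Rubin
    potential scale reduction factor is computed over the half-chains."""
    chains = np.atleast_2d(np.asarray(chains, dtype=float))
    n = chains.shape[1] // 2
    if n < 2:
        return np.nan
    halves = np.concatenate([chains[:, :n], chains[:, n : 2 * n]], axis=0)
    w = halves.var(axis=1, ddof=1).mean()
    if w == 0:
        return 1.0
    b = n * halves.mean(axis=1).var(ddof=1)
    var_hat = (n - 1) / n * w + b / n
    return float(np.sqrt(var_hat / w))


@dataclass
class BayesFit:
    """Posterior draws and summaries from one Gibbs run.

    ``draws`` maps parameter labels (indicator names for loadings, path
    labels for coefficients, ``var:<name>`` for residual variances) to arrays
    of shape (n_chains, n_draws)."""

    draws: dict[str, np.ndarray]
    spec: ModelSpec
    prior: PriorConfig
    mcmc: McmcConfig
    estimates: dict[str, float] = field(init=False)
    se: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        self.estimates = {k: float(np.mean(v)) for k, v in self.draws.items()}
        # population-SD convention (ddof=0), documented in posterior_summary
        self.se = {k: float(np.std(v)) for k, v in self.draws.items()}

    @property
    def structural_estimates(self) -> dict[str, float]:
        return {p: self.estimates[p] for p in self.spec.path_labels}

    @property
    def structural_se(self) -> dict[str, float]:
        return {p: self.se[p] for p in self.spec.path_labels}

    @property
    def params(self) -> ParameterSet:
        """Posterior-mean parameters as a ParameterSet."""
        loadings = {i: self.estimates[i] for i in self.spec.indicator_names}
        resid = {
            name: self.estimates[f"var:{name}"]
            for name in (*self.spec.indicator_names, *self.spec.endogenous)
        }
        for name in self.spec.exogenous:
            resid[name] = 1.0  # standardized scale
        return ParameterSet(loadings, self.structural_estimates, resid)

    def diagnostics(self) -> pd.DataFrame:
        rows = [
            {"parameter": k, "rhat": split_rhat(v), "n_draws": v.size}
            for k, v in self.draws.items()
        ]
        return pd.DataFrame(rows).set_index("parameter")

    def draws_table(self) -> pd.DataFrame:
        """Chains stacked into a posterior-draws table, one column per
        parameter, for external diagnostics."""
        return pd.DataFrame({k: v.reshape(-1) for k, v in self.draws.items()})


def _inv_gamma(rng: np.random.Generator, shape: float, scale: float) -> float:
    return scale / rng.gamma(shape)


def _gibbs_chain(
    Y: np.ndarray,
    spec: ModelSpec,
    prior: PriorConfig,
    mcmc: McmcConfig,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    n = Y.shape[0]
    obs = list(spec.observed_names)
    col = {c: j for j, c in enumerate(obs)}
    lat_names = spec.latent_names
    m = len(lat_names)
    lidx = {l: i for i, l in enumerate(lat_names)}

    # indicator bookkeeping
    ind_names = list(spec.indicator_names)
    ind_lat = np.array([lidx[spec.latent_of(i)] for i in ind_names])
    first_ind = {l.name: ind_names.index(l.indicators[0]) for l in spec.latents}
    X = Y[:, [col[i] for i in ind_names]]

    # latent-latent regressions (endogenous latents only), topological order
    lat_regs = []  # (target_idx, parent_idxs, prior_means, prior_vars)
    for name in spec.topological_order():
        if name in lidx and spec.parents(name):
            parents = spec.parents(name)
            if any(p not in lidx for p in parents):
                raise ValueError(f"latent {name!r} has a non-latent parent")
            labels = [f"{p}->{name}" for p in parents]
            lat_regs.append(
                (
                    lidx[name],
                    np.array([lidx[p] for p in parents]),
                    np.array([prior.mean_for(lb) for lb in labels]),
                    np.array([prior.variance_for(lb) for lb in labels]),
                    labels,
                )
            )

    # outcome regressions: latent parents + control parents
    out_regs = []
    for out in spec.observed_outcomes:
        parents = spec.parents(out)
        lat_par = [p for p in parents if p in lidx]
        ctl_par = [p for p in parents if p not in lidx]
        labels = [f"{p}->{out}" for p in (*lat_par, *ctl_par)]
        out_regs.append(
            (
                Y[:, col[out]],
                np.array([lidx[p] for p in lat_par]),
                Y[:, [col[p] for p in ctl_par]],
                np.array([prior.mean_for(lb) for lb in labels]),
                np.array([prior.variance_for(lb) for lb in labels]),
                labels,
            )
        )

    a0, b0 = prior.variance_prior
    v_lam = prior.prior_variance
    mu_lam = prior.loading_mean

    # state
    lam = np.full(len(ind_names), 0.7)
    theta_x = np.full(len(ind_names), 0.5)
    lat_coefs = [np.zeros(len(r[1])) for r in lat_regs]
    psi = np.ones(m)  # disturbance variance per latent (exogenous: total var 1)
    out_coefs = [np.zeros(len(r[3])) for r in out_regs]
    theta_z = np.ones(len(out_regs))

    n_rec = mcmc.n_draws_per_chain
    labels_all = (
        ind_names
        + [lb for r in lat_regs for lb in r[4]]
        + [lb for r in out_regs for lb in r[5]]
        + [f"var:{i}" for i in ind_names]
        + [f"var:{l}" for l in lat_names if spec.parents(l)]
        + [f"var:{o}" for o in spec.observed_outcomes]
    )
    store = {k: np.empty(n_rec) for k in labels_all}
    rec = 0

    I_m = np.eye(m)
    for sweep in range(mcmc.n_iterations):
        # --- (a) latent scores -------------------------------------------------
        Bll = np.zeros((m, m))
        for (t, pidx, _, _, _), c in zip(lat_regs, lat_coefs):
            Bll[t, pidx] = c
        A = np.linalg.solve(I_m - Bll, I_m)
        sigma_eta = (A * psi) @ A.T
        prec = np.linalg.inv(sigma_eta)
        G_x = np.zeros((len(ind_names), m))
        G_x[np.arange(len(ind_names)), ind_lat] = lam
        prec += (G_x / theta_x[:, None]).T @ G_x
        R = (X / theta_x) @ G_x
        for (z, lat_par, C, _, _, _), c, tz in zip(out_regs, out_coefs, theta_z):
            g = np.zeros(m)
            g[lat_par] = c[: len(lat_par)]
            resid_fixed = z - C @ c[len(lat_par):]
            prec += np.outer(g, g) / tz
            R += np.outer(resid_fixed, g) / tz
        cov = np.linalg.inv(prec)
        cov = (cov + cov.T) / 2.0
        eta = R @ cov + rng.standard_normal((n, m)) @ np.linalg.cholesky(cov).T
        # standardize each latent column (scale identification)
        eta -= eta.mean(axis=0)
        sd = eta.std(axis=0)
        if np.any(sd == 0):
            raise RuntimeError("degenerate latent scores (zero variance)")
        eta /= sd

        # --- (b) loadings + (c) measurement residuals --------------------------
        for j in range(len(ind_names)):
            e = eta[:, ind_lat[j]]
            xj = X[:, j]
            p_j = n / theta_x[j] + 1.0 / v_lam
            mean_j = (e @ xj / theta_x[j] + mu_lam / v_lam) / p_j
            lam[j] = mean_j + rng.standard_normal() / np.sqrt(p_j)
            r = xj - lam[j] * e
            theta_x[j] = _inv_gamma(rng, a0 + n / 2.0, b0 + 0.5 * (r @ r))

        # --- structural regressions among latents ------------------------------
        for k_, (t, pidx, m0, v0, _) in enumerate(lat_regs):
            Xp = eta[:, pidx]
            y = eta[:, t]
            prec_b = Xp.T @ Xp / psi[t] + np.diag(1.0 / v0)
            cov_b = np.linalg.inv(prec_b)
            mean_b = cov_b @ (Xp.T @ y / psi[t] + m0 / v0)
            coef = mean_b + np.linalg.cholesky((cov_b + cov_b.T) / 2) @ rng.standard_normal(len(m0))
            lat_coefs[k_] = coef
            r = y - Xp @ coef
            psi[t] = _inv_gamma(rng, a0 + n / 2.0, b0 + 0.5 * (r @ r))

        # --- outcome regressions ----------------------------------------------
        for k_, (z, lat_par, C, m0, v0, _) in enumerate(out_regs):
            Xp = np.concatenate([eta[:, lat_par], C], axis=1)
            prec_b = Xp.T @ Xp / theta_z[k_] + np.diag(1.0 / v0)
            cov_b = np.linalg.inv(prec_b)
            mean_b = cov_b @ (Xp.T @ z / theta_z[k_] + m0 / v0)
            coef = mean_b + np.linalg.cholesky((cov_b + cov_b.T) / 2) @ rng.standard_normal(len(m0))
            out_coefs[k_] = coef
            r = z - Xp @ coef
            theta_z[k_] = _inv_gamma(rng, a0 + n / 2.0, b0 + 0.5 * (r @ r))

        # --- sign constraint: first loading positive ---------------------------
        signs = np.ones(m)
        for lname, j0 in first_ind.items():
            if lam[j0] < 0:
                signs[lidx[lname]] = -1.0
        if np.any(signs < 0):
            lam *= signs[ind_lat]
            eta *= signs
            for k_, (t, pidx, *_rest) in enumerate(lat_regs):
                lat_coefs[k_] = lat_coefs[k_] * signs[t] * signs[pidx]
            for k_, (_, lat_par, *_rest) in enumerate(out_regs):
                out_coefs[k_][: len(lat_par)] *= signs[lat_par]

        # --- record ------------------------------------------------------------
        if sweep >= mcmc.burn_in and (sweep - mcmc.burn_in) % mcmc.thin == 0 and rec < n_rec:
            for j, name in enumerate(ind_names):
                store[name][rec] = lam[j]
                store[f"var:{name}"][rec] = theta_x[j]
            for (t, _, _, _, labels), coef in zip(lat_regs, lat_coefs):
                for lb, c in zip(labels, coef):
                    store[lb][rec] = c
                store[f"var:{lat_names[t]}"][rec] = psi[t]
            for k_, (reg, coef) in enumerate(zip(out_regs, out_coefs)):
                for lb, c in zip(reg[5], coef):
                    store[lb][rec] = c
                store[f"var:{spec.observed_outcomes[k_]}"][rec] = theta_z[k_]
            rec += 1

    for k, v in store.items():
        if not np.all(np.isfinite(v)):
            raise RuntimeError(f"non-finite posterior draw for parameter {k!r}")
    return store


def fit_bayes(
    data: pd.DataFrame,
    spec: ModelSpec,
    prior: PriorConfig | None = None,
    mcmc: McmcConfig = McmcConfig(),
) -> BayesFit:
    """Gibbs-sampler fit of the SEM on one group's data.

    The data are z-standardized per column before sampling; same seed gives
    identical chains."""
    prior = prior or default_prior("girl")
    cols = list(spec.observed_names)
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise KeyError(f"data is missing columns: {missing}")
    raw = data[cols].to_numpy(dtype=float)
    if np.isnan(raw).any():
        raise ValueError("data contains missing values; the sampler requires completeness")
    sd = raw.std(axis=0, ddof=1)
    for c, s in zip(cols, sd):
        if s == 0 or not np.isfinite(s):
            raise ValueError(f"column {c!r} has zero variance; cannot standardize")
    Y = (raw - raw.mean(axis=0)) / sd

    ss = np.random.SeedSequence(mcmc.seed)
    chains: dict[str, list[np.ndarray]] = {}
    for child in ss.spawn(mcmc.n_chains):
        draws = _gibbs_chain(Y, spec, prior, mcmc, np.random.default_rng(child))
        for k, v in draws.items():
            chains.setdefault(k, []).append(v)
    return BayesFit(
        draws={k: np.stack(v) for k, v in chains.items()},
        spec=spec,
        prior=prior,
        mcmc=mcmc,
    )


def posterior_summary(fit: BayesFit) -> pd.DataFrame:
    """One row per free parameter: posterior mean, posterior SD (population
    convention, ddof=0), central 95% credible interval and split-R-hat."""
    rows = []
    for name, draws in fit.draws.items():
        flat = draws.reshape(-1)
        if flat.size < 2:
            raise ValueError(f"parameter {name!r} has fewer than 2 retained draws")
        lo, hi = np.percentile(flat, [2.5, 97.5])
        rows.append(
            {
                "parameter": name,
                "estimate": float(flat.mean()),
                "se": float(flat.std()),
                "ci_low": float(lo),
                "ci_high": float(hi),
                "rhat": split_rhat(draws),
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


@dataclass
class PriorSensitivityResult:
    """Per-regime estimates on identical data, plus per-path spread."""

    table: pd.DataFrame  # index (path, regime), columns estimate/se
    discrepancy: pd.Series  # per path: max |estimate difference| across regimes
    fits: dict[str, BayesFit]

    @property
    def max_discrepancy(self) -> float:
        return float(self.discrepancy.max())


def prior_sensitivity(
    data: pd.DataFrame,
    spec: ModelSpec,
    priors: Mapping[str, PriorConfig],
    mcmc: McmcConfig = McmcConfig(),
) -> PriorSensitivityResult:
    """Fit the same data once per prior regime (same seed) and tabulate the
    structural estimates side by side, mirroring the prior-sensitivity
    comparison of the study."""
    if len(priors) < 2:
        raise ValueError("prior_sensitivity needs at least 2 prior regimes")
    fits = {regime: fit_bayes(data, spec, prior, mcmc) for regime, prior in priors.items()}
    rows = []
    for regime, fit in fits.items():
        for path, est in fit.structural_estimates.items():
            rows.append(
                {
                    "path": path,
                    "regime": regime,
                    "estimate": est,
                    "se": fit.structural_se[path],
                }
            )
    table = pd.DataFrame(rows).set_index(["path", "regime"])
    est = table["estimate"].unstack("regime")
    discrepancy = (est.max(axis=1) - est.min(axis=1)).rename("max_abs_discrepancy")
    return PriorSensitivityResult(table=table, discrepancy=discrepancy, fits=fits)
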