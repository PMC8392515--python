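"""Maximum-likelihood and PLS estimation of the same SEM topology.

``fit_ml`` minimizes the normal-theory discrepancy

    F(theta) = log|Sigma(theta)| + tr(S Sigma(theta)^-1) - log|S| - p

over the free parameters (loadings, path coefficients, log residual
variances) with an analytic gradient and multi-start L-BFGS-B, working on the
correlation matrix of the z-standardized data.  Estimates are reported fully
standardized; standard errors come from the inverse curvature of the
discrepancy at the optimum, propagated to the standardized scale by the
delta method.

``fit_pls`` is classical PLS path modeling: Mode-A outer weights, centroid
inner scheme, iterated to weight convergence, then OLS path coefficients on
the standardized composite scores following the structural DAG.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .model_spec import ModelSpec, ParameterSet

__all__ = ["MLFit", "PLSFit", "fit_ml", "fit_ml_cov", "fit_pls", "predict_outcomes"]


# ---------------------------------------------------------------------------
# parameter packing
# ---------------------------------------------------------------------------


class _MLProblem:
    """Index plumbing between the flat optimizer vector and SEM matrices.

    Free parameters: one loading per indicator, one coefficient per path,
    log residual variance per indicator, log disturbance variance per
    endogenous structural variable, log total variance per exogenous observed
    variable.  Exogenous latent variances are fixed at 1."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        self.obs = list(spec.observed_names)
        self.struct = list(spec.structural_names)
        self.sidx = {n: i for i, n in enumerate(self.struct)}
        self.p = len(self.obs)
        self.k = len(self.struct)
        self.ind_names = list(spec.indicator_names)
        self.ind_rows = np.arange(len(self.ind_names))
        self.ind_cols = np.array([self.sidx[spec.latent_of(i)] for i in self.ind_names])
        self.path_ts = np.array(
            [(self.sidx[p.target], self.sidx[p.source]) for p in spec.paths]
        )
        self.endo = [n for n in self.struct if spec.parents(n)]
        self.exo_obs = [
            n for n in spec.exogenous if n not in spec.latent_names
        ]
        self.exo_lat = [n for n in spec.exogenous if n in spec.latent_names]
        self.var_names = self.endo + self.exo_obs  # free psi entries
        self.var_idx = np.array([self.sidx[n] for n in self.var_names])
        self.n_lam = len(self.ind_names)
        self.n_path = len(spec.paths)
        self.n_free = self.n_lam + self.n_path + self.n_lam + len(self.var_names)
        # fixed unit entries of G for directly observed structural variables
        self.direct = [
            (self.obs.index(n), self.sidx[n])
            for n in (*spec.controls, *spec.observed_outcomes)
        ]

    def unpack(self, x: np.ndarray):
        nl, npth = self.n_lam, self.n_path
        lam = x[:nl]
        b = x[nl : nl + npth]
        theta = np.exp(x[nl + npth : nl + npth + nl])
        psi_free = np.exp(x[nl + npth + nl :])
        G = np.zeros((self.p, self.k))
        G[self.ind_rows, self.ind_cols] = lam
        for r, c in self.direct:
            G[r, c] = 1.0
        B = np.zeros((self.k, self.k))
        B[self.path_ts[:, 0], self.path_ts[:, 1]] = b
        psi = np.ones(self.k)
        psi[self.var_idx] = psi_free
        theta_full = np.zeros(self.p)
        theta_full[: self.n_lam] = theta
        return G, B, psi, theta_full

    def fml_grad(self, x: np.ndarray, S: np.ndarray, logdet_S: float):
        G, B, psi, theta = self.unpack(x)
        A = np.linalg.solve(np.eye(self.k) - B, np.eye(self.k))
        V = (A * psi) @ A.T
        sigma = G @ V @ G.T + np.diag(theta)
        try:
            cho = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError:
            return 1e10, np.zeros_like(x)
        logdet = 2.0 * np.sum(np.log(np.diag(cho)))
        sigma_inv = np.linalg.inv(sigma)
        SinvS = sigma_inv @ S
        F = logdet + np.trace(SinvS) - logdet_S - self.p
        M = sigma_inv - SinvS @ sigma_inv  # Sigma^-1 (Sigma - S) Sigma^-1
        M = (M + M.T) / 2.0
        grad = np.empty_like(x)
        T = M @ G @ V
        grad[: self.n_lam] = 2.0 * T[self.ind_rows, self.ind_cols]
        W = G.T @ M @ G
        U = V @ W @ A
        grad[self.n_lam : self.n_lam + self.n_path] = 2.0 * U[
            self.path_ts[:, 1], self.path_ts[:, 0]
        ]
        grad[self.n_lam + self.n_path : 2 * self.n_lam + self.n_path] = (
            np.diag(M)[: self.n_lam] * theta[: self.n_lam]
        )
        D = A.T @ W @ A
        grad[2 * self.n_lam + self.n_path :] = np.diag(D)[self.var_idx] * psi[self.var_idx]
        return float(F), grad

    # -- output conversion ------------------------------------------------------

    def standardized(self, x: np.ndarray) -> np.ndarray:
        """Standardized (loadings, paths) vector for the delta method."""
        G, B, psi, theta = self.unpack(x)
        A = np.linalg.solve(np.eye(self.k) - B, np.eye(self.k))
        V = (A * psi) @ A.T
        sd_s = np.sqrt(np.diag(V))
        sd_y = np.sqrt(np.diag(G @ V @ G.T) + theta)
        lam_std = (
            x[: self.n_lam] * sd_s[self.ind_cols] / sd_y[self.ind_rows]
        )
        b = x[self.n_lam : self.n_lam + self.n_path]
        b_std = b * sd_s[self.path_ts[:, 1]] / sd_s[self.path_ts[:, 0]]
        return np.concatenate([lam_std, b_std])

    def to_parameter_set(self, x: np.ndarray) -> ParameterSet:
        G, B, psi, theta = self.unpack(x)
        A = np.linalg.solve(np.eye(self.k) - B, np.eye(self.k))
        V = (A * psi) @ A.T
        var_s = np.diag(V)
        var_y = np.diag(G @ V @ G.T) + theta
        std = self.standardized(x)
        loadings = dict(zip(self.ind_names, std[: self.n_lam]))
        structural = dict(zip(self.spec.path_labels, std[self.n_lam :]))
        resid = {
            name: float(theta[j] / var_y[j])
            for j, name in enumerate(self.ind_names)
        }
        for name in self.struct:
            i = self.sidx[name]
            resid[name] = float(psi[i] / var_s[i])
        return ParameterSet(loadings, structural, resid)

    # -- starting values --------------------------------------------------------

    def start_from_cov(self, S: np.ndarray) -> np.ndarray:
        """Consistent-ish start: per-block principal-axis loadings, then
        proxy-score regressions for the paths."""
        obs_idx = {n: j for j, n in enumerate(self.obs)}
        lam0 = np.empty(self.n_lam)
        proxy = np.zeros((self.k, self.p))  # weights defining proxy scores
        for l in self.spec.latents:
            J = [obs_idx[i] for i in l.indicators]
            sub = S[np.ix_(J, J)]
            ev, evec = np.linalg.eigh(sub)
            v = evec[:, -1]
            if v.sum() < 0:
                v = -v
            lam_b = np.clip(v * np.sqrt(max(ev[-1], 1e-3)), 0.05, 0.98)
            for j, lam_j in zip(J, lam_b):
                lam0[j] = lam_j
            w = v / np.sqrt(max(float(v @ sub @ v), 1e-8))
            proxy[self.sidx[l.name], J] = w
        for n in (*self.spec.controls, *self.spec.observed_outcomes):
            proxy[self.sidx[n], obs_idx[n]] = 1.0
        phi = proxy @ S @ proxy.T  # proxy-score covariance among structural vars
        phi = (phi + phi.T) / 2.0
        d = np.sqrt(np.clip(np.diag(phi), 1e-8, None))
        phi = phi / np.outer(d, d)
        b0 = np.empty(self.n_path)
        psi0 = {n: 1.0 for n in self.var_names}
        for v in self.endo:
            pidx = [self.sidx[p] for p in self.spec.parents(v)]
            t = self.sidx[v]
            coef = np.linalg.solve(
                phi[np.ix_(pidx, pidx)] + 1e-6 * np.eye(len(pidx)), phi[pidx, t]
            )
            psi0[v] = float(np.clip(1.0 - coef @ phi[pidx, t], 0.05, 1.0))
            for j, p in enumerate(self.spec.parents(v)):
                b0[self.spec.path_labels.index(f"{p}->{v}")] = coef[j]
        for n in self.exo_obs:
            psi0[n] = float(S[obs_idx[n], obs_idx[n]])
        theta0 = np.clip(1.0 - lam0**2, 0.05, 1.0)
        return np.concatenate(
            [
                lam0,
                b0,
                np.log(theta0),
                np.log([psi0[n] for n in self.var_names]),
            ]
        )


@dataclass
class MLFit:
    """Standardized ML estimates with asymptotic (delta-method) SEs."""

    estimates: ParameterSet
    loading_se: dict[str, float]
    structural_se_: dict[str, float]
    discrepancy: float
    chisq: float
    df: int
    n: int
    converged: bool
    spec: ModelSpec
    raw_params: np.ndarray
    start_discrepancies: tuple[float, ...] = ()

    @property
    def structural_estimates(self) -> dict[str, float]:
        return dict(self.estimates.structural)

    @property
    def structural_se(self) -> dict[str, float]:
        return dict(self.structural_se_)

    @property
    def se(self) -> dict[str, float]:
        return {**self.loading_se, **self.structural_se_}


def fit_ml_cov(
    S: np.ndarray,
    n: int,
    spec: ModelSpec,
    n_starts: int = 2,
    seed: int = 0,
    compute_se: bool = True,
) -> MLFit:
    """ML fit from a moment (covariance/correlation) matrix directly."""
    S = np.asarray(S, dtype=float)
    prob = _MLProblem(spec)
    if S.shape != (prob.p, prob.p):
        raise ValueError(f"moment matrix must be {prob.p}x{prob.p}")
    eig = np.linalg.eigvalsh(S)
    if eig[0] <= 0:
        raise ValueError(
            f"sample covariance is not positive definite (min eigenvalue {eig[0]:.3e})"
        )
    logdet_S = float(np.linalg.slogdet(S)[1])
    rng = np.random.default_rng(seed)
    x_start = prob.start_from_cov(S)
    best = None
    found: list[float] = []
    for s in range(max(1, n_starts)):
        x0 = x_start.copy()
        if s > 0:
            x0[: prob.n_lam + prob.n_path] += rng.normal(0, 0.05, prob.n_lam + prob.n_path)
            x0[prob.n_lam + prob.n_path :] += rng.normal(
                0, 0.1, prob.n_free - prob.n_lam - prob.n_path
            )
        res = optimize.minimize(
            prob.fml_grad,
            x0,
            args=(S, logdet_S),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 1000, "ftol": 1e-14, "gtol": 1e-9},
        )
        found.append(float(res.fun))
        if best is None or res.fun < best.fun:
            best = res
    x_hat = best.x
    F = float(best.fun)
    params = prob.to_parameter_set(x_hat)
    df = prob.p * (prob.p + 1) // 2 - prob.n_free
    loading_se: dict[str, float] = {}
    structural_se: dict[str, float] = {}
    if compute_se:
        acov_std = _standardized_acov(prob, x_hat, S, logdet_S, n)
        se_std = np.sqrt(np.clip(np.diag(acov_std), 0, None))
        loading_se = dict(zip(prob.ind_names, se_std[: prob.n_lam]))
        structural_se = dict(zip(spec.path_labels, se_std[prob.n_lam :]))
    return MLFit(
        estimates=params,
        loading_se=loading_se,
        structural_se_=structural_se,
        discrepancy=F,
        chisq=max(0.0, (n - 1) * F),
        df=df,
        n=n,
        converged=bool(best.success),
        spec=spec,
        raw_params=x_hat,
        start_discrepancies=tuple(found),
    )


def _standardized_acov(
    prob: _MLProblem, x: np.ndarray, S: np.ndarray, logdet_S: float, n: int
) -> np.ndarray:
    """Asymptotic covariance of the standardized (loading, path) estimates:
    acov(theta) = 2/(n-1) H^-1 with H the discrepancy Hessian, then the delta
    method through the standardization map."""
    h = 1e-5
    m = len(x)
    H = np.empty((m, m))
    g0 = prob.fml_grad(x, S, logdet_S)[1]
    for i in range(m):
        xp = x.copy()
        xp[i] += h
        H[i] = (prob.fml_grad(xp, S, logdet_S)[1] - g0) / h
    H = (H + H.T) / 2.0
    acov = 2.0 / max(n - 1, 1) * np.linalg.pinv(H)
    f0 = prob.standardized(x)
    J = np.empty((len(f0), m))
    for i in range(m):
        xp = x.copy()
        xp[i] += h
        J[:, i] = (prob.standardized(xp) - f0) / h
    return J @ acov @ J.T


def fit_ml(
    data: pd.DataFrame,
    spec: ModelSpec,
    n_starts: int = 2,
    seed: int = 0,
    compute_se: bool = True,
) -> MLFit:
    """ML fit on the correlation matrix of the observed columns (the model is
    estimated on z-standardized variables throughout)."""
    cols = list(spec.observed_names)
    raw = data[cols].to_numpy(dtype=float)
    if np.isnan(raw).any():
        raise ValueError("data contains missing values")
    S = np.corrcoef(raw, rowvar=False)
    return fit_ml_cov(S, len(raw), spec, n_starts=n_starts, seed=seed, compute_se=compute_se)


# ---------------------------------------------------------------------------
# PLS path modeling
# ---------------------------------------------------------------------------


@dataclass
class PLSFit:
    outer_weights: dict[str, float]
    loadings: dict[str, float]
    path_coefficients: dict[str, float]
    factor_scores: pd.DataFrame
    converged: bool
    iterations: int
    last_change: float
    spec: ModelSpec

    @property
    def structural_estimates(self) -> dict[str, float]:
        return dict(self.path_coefficients)


def fit_pls(
    data: pd.DataFrame,
    spec: ModelSpec,
    tol: float = 1e-6,
    max_iter: int = 300,
) -> PLSFit:
    """Classical PLS path modeling (Mode-A outer estimation, centroid inner
    scheme).  Directly observed structural variables (controls, outcomes) are
    single-indicator composites equal to their standardized column."""
    cols = list(spec.observed_names)
    raw = data[cols].to_numpy(dtype=float)
    if np.isnan(raw).any():
        raise ValueError("data contains missing values")
    n = len(raw)
    Z = (raw - raw.mean(axis=0)) / raw.std(axis=0, ddof=1)
    obs_idx = {c: j for j, c in enumerate(cols)}
    struct = list(spec.structural_names)
    blocks = {l.name: [obs_idx[i] for i in l.indicators] for l in spec.latents}
    for nm in (*spec.controls, *spec.observed_outcomes):
        blocks[nm] = [obs_idx[nm]]
    # undirected adjacency from the structural paths
    adj: dict[str, set[str]] = {nm: set() for nm in struct}
    for p in spec.paths:
        adj[p.source].add(p.target)
        adj[p.target].add(p.source)

    weights = {nm: np.ones(len(J)) / np.sqrt(len(J)) for nm, J in blocks.items()}
    multi = [nm for nm, J in blocks.items() if len(J) > 1]

    def scores_of(w):
        sc = {}
        for nm, J in blocks.items():
            s = Z[:, J] @ w[nm]
            sc[nm] = (s - s.mean()) / s.std(ddof=1)
        return sc

    converged = False
    change = np.inf
    it = 0
    scores = scores_of(weights)
    for it in range(1, max_iter + 1):
        inner = {}
        for nm in struct:
            e = np.zeros(n)
            for nb in adj[nm]:
                r = float(scores[nm] @ scores[nb]) / (n - 1)
                e += np.sign(r if r != 0 else 1.0) * scores[nb]
            if not adj[nm]:
                e = scores[nm]
            inner[nm] = e
        new_w = {}
        change = 0.0
        for nm in multi:
            J = blocks[nm]
            w = Z[:, J].T @ inner[nm] / (n - 1)  # Mode A: covariances with inner proxy
            w = w / np.linalg.norm(w)
            old = weights[nm] / np.linalg.norm(weights[nm])
            if w @ old < 0:
                w = -w
            change = max(change, float(np.max(np.abs(w - old))))
            new_w[nm] = w
        weights.update(new_w)
        scores = scores_of(weights)
        if change < tol:
            converged = True
            break

    # sign convention: score correlates positively with its first indicator
    for l in spec.latents:
        j0 = obs_idx[l.indicators[0]]
        if float(scores[l.name] @ Z[:, j0]) < 0:
            scores[l.name] = -scores[l.name]
            weights[l.name] = -weights[l.name]

    loadings = {}
    outer = {}
    for l in spec.latents:
        for i, j in zip(l.indicators, blocks[l.name]):
            loadings[i] = float(scores[l.name] @ Z[:, j]) / (n - 1)
            outer[i] = float(weights[l.name][l.indicators.index(i)])
    paths: dict[str, float] = {}
    for v in struct:
        parents = spec.parents(v)
        if not parents:
            continue
        Xp = np.column_stack([scores[p] for p in parents])
        coef, *_ = np.linalg.lstsq(Xp, scores[v], rcond=None)
        for p, c in zip(parents, coef):
            paths[f"{p}->{v}"] = float(c)
    score_frame = pd.DataFrame({nm: scores[nm] for nm in struct})
    return PLSFit(
        outer_weights=outer,
        loadings=loadings,
        path_coefficients={p: paths[p] for p in spec.path_labels},
        factor_scores=score_frame,
        converged=converged,
        iterations=it,
        last_change=float(change),
        spec=spec,
    )


# ---------------------------------------------------------------------------
# predictions
# ---------------------------------------------------------------------------


def predict_outcomes(fit, data: pd.DataFrame, spec: ModelSpec | None = None) -> pd.DataFrame:
    """Per-row predicted outcomes (on the data's own scale).

    For ML/Bayes fits (anything exposing standardized ``ParameterSet``
    estimates) the latent scores are regression-method scores computed from
    the full observed vector, and predictions apply the structural equations
    to those scores plus the control terms.  For PLS fits the native
    composite scores are used."""
    from .model_spec import implied_covariance, structural_matrices

    if spec is None:
        spec = fit.spec
    cols = list(spec.observed_names)
    missing = [c for c in data.columns if c not in (*cols, spec.group_variable)]
    if missing:
        raise ValueError(f"data has out-of-spec columns: {missing}")
    raw = data[cols].to_numpy(dtype=float)
    mean = raw.mean(axis=0)
    sd = raw.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Z = (raw - mean) / sd
    out_names = list(spec.observed_outcomes)
    out_cols = [cols.index(o) for o in out_names]

    if isinstance(fit, PLSFit):
        scores = {nm: fit.factor_scores[nm].to_numpy() for nm in spec.latent_names}
        # PLS scores belong to the fitting data; recompute for new data
        if len(fit.factor_scores) != len(raw):
            raise ValueError("PLS predictions require the fitting dataset")
        coefs = fit.path_coefficients
    else:
        params = fit if isinstance(fit, ParameterSet) else (
            fit.estimates if isinstance(fit, MLFit) else fit.params
        )
        sigma = implied_covariance(spec, params).to_numpy()
        _, psi, G, _ = structural_matrices(spec, params)
        B, _, _, _ = structural_matrices(spec, params)
        k = B.shape[0]
        A = np.linalg.solve(np.eye(k) - B, np.eye(k))
        V = (A * psi) @ A.T
        # regression-method scores for every structural variable
        shat = Z @ np.linalg.solve(sigma, G @ V)
        scores = {nm: shat[:, i] for i, nm in enumerate(spec.structural_names)}
        coefs = params.structural

    preds = {}
    for o, j in zip(out_names, out_cols):
        yhat = np.zeros(len(raw))
        for p in spec.parents(o):
            src = scores[p] if p in spec.latent_names else Z[:, cols.index(p)]
            yhat = yhat + coefs[f"{p}->{o}"] * src
        preds[o] = yhat * sd[j] + mean[j]
    return pd.DataFrame(preds, index=data.index)
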