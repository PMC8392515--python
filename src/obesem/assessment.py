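"""Model fit indices and the three-estimator predictive comparison.

Incremental indices compare the fitted model's chi-square against the
independence (diagonal) baseline:

    NFI = (X2b - X2m) / X2b
    IFI = (X2b - X2m) / (X2b - dfm)
    RFI = (X2b/dfb - X2m/dfm) / (X2b/dfb)
    TLI = (X2b/dfb - X2m/dfm) / (X2b/dfb - 1)
    CFI = 1 - max(X2m - dfm, 0) / max(X2b - dfb, X2m - dfm, 0)

GFI uses the ML trace form on (sample, implied) covariance matrices.

The predictive comparison mirrors the published metric set: R^2 (squared
Pearson correlation), RMSE, MAPE, and the table's "MSE" — whose printed
formula is a mean absolute error, implemented verbatim as ``mse_printed``
with the conventional mean squared error also exposed as ``mse``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .classical import fit_ml, fit_pls, predict_outcomes
from .gibbs import McmcConfig, fit_bayes
from .model_spec import ModelSpec, PriorConfig

__all__ = [
    "FitIndexReport",
    "PredictiveMetrics",
    "fit_indices",
    "baseline_chisq",
    "predictive_metrics",
    "compare_estimators",
]


@dataclass(frozen=True)
class FitIndexReport:
    gfi: float
    nfi: float
    ifi: float
    rfi: float
    tli: float
    cfi: float
    chisq_model: float
    df_model: int
    chisq_baseline: float
    df_baseline: int
    n: int

    def to_dict(self) -> dict[str, float]:
        return {
            k: getattr(self, k) for k in ("gfi", "nfi", "ifi", "rfi", "tli", "cfi")
        }


def baseline_chisq(S: np.ndarray, n: int) -> tuple[float, int]:
    """Chi-square and df of the independence (diagonal covariance) baseline."""
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    f_b = float(np.sum(np.log(np.diag(S))) - np.linalg.slogdet(S)[1])
    return max(0.0, (n - 1) * f_b), p * (p - 1) // 2


def fit_indices(
    chisq_model: float,
    df_model: int,
    chisq_baseline: float,
    df_baseline: int,
    sample_cov: np.ndarray,
    implied_cov: np.ndarray,
    n: int,
) -> FitIndexReport:
    """Standard incremental/absolute fit indices from model and baseline
    chi-squares plus the ML trace form GFI."""
    if chisq_model < 0 or chisq_baseline < 0:
        raise ValueError("chi-squares must be >= 0")
    if df_baseline <= 0:
        raise ValueError("baseline df must be > 0")
    if chisq_baseline == 0:
        raise ValueError("baseline chi-square is 0; incremental indices are undefined")
    x2m, x2b = float(chisq_model), float(chisq_baseline)
    nfi = (x2b - x2m) / x2b
    ifi = (x2b - x2m) / (x2b - df_model)
    ratio_b = x2b / df_baseline
    ratio_m = x2m / df_model if df_model > 0 else 0.0
    rfi = (ratio_b - ratio_m) / ratio_b
    tli = (ratio_b - ratio_m) / (ratio_b - 1.0)
    num = max(x2m - df_model, 0.0)
    den = max(x2b - df_baseline, x2m - df_model, 0.0)
    cfi = 1.0 - (num / den if den > 0 else 0.0)
    S = np.asarray(sample_cov, dtype=float)
    sig = np.asarray(implied_cov, dtype=float)
    R = np.linalg.solve(sig, S)
    I = np.eye(S.shape[0])
    gfi = 1.0 - np.trace((R - I) @ (R - I)) / np.trace(R @ R)
    return FitIndexReport(
        gfi=float(gfi),
        nfi=float(nfi),
        ifi=float(ifi),
        rfi=float(rfi),
        tli=float(tli),
        cfi=float(cfi),
        chisq_model=x2m,
        df_model=df_model,
        chisq_baseline=x2b,
        df_baseline=df_baseline,
        n=n,
    )


@dataclass(frozen=True)
class PredictiveMetrics:
    r2: float
    rmse: float
    mape: float | None
    mse_printed: float  # the table's printed formula: mean absolute error
    mse: float  # conventional mean squared error
    n: int

    def to_dict(self) -> dict[str, float]:
        return {
            "r2": self.r2,
            "rmse": self.rmse,
            "mape": self.mape,
            "mse_printed": self.mse_printed,
            "mse": self.mse,
        }


def predictive_metrics(
    observed: np.ndarray | pd.Series,
    predicted: np.ndarray | pd.Series,
    mape: bool = True,
) -> PredictiveMetrics:
    """Accuracy of per-row predictions against observations."""
    y = np.asarray(observed, dtype=float).ravel()
    yhat = np.asarray(predicted, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise ValueError("observed and predicted must have equal length")
    if y.size < 2:
        raise ValueError("need at least 2 observations")
    err = yhat - y
    rmse = float(np.sqrt(np.mean(err**2)))
    mse_conv = float(np.mean(err**2))
    mae = float(np.mean(np.abs(err)))
    if np.std(y) == 0 or np.std(yhat) == 0:
        r2 = np.nan  # constant series: correlation undefined
    else:
        r2 = float(np.corrcoef(y, yhat)[0, 1] ** 2)
    mape_val: float | None = None
    if mape:
        if np.any(y == 0):
            raise ValueError("MAPE requires all observed values to be nonzero")
        mape_val = float(np.mean(np.abs(err / y)))
    return PredictiveMetrics(
        r2=r2, rmse=rmse, mape=mape_val, mse_printed=mae, mse=mse_conv, n=y.size
    )


def compare_estimators(
    data: pd.DataFrame,
    spec: ModelSpec,
    prior: PriorConfig | None = None,
    mcmc: McmcConfig = McmcConfig(),
    ml_seed: int = 0,
) -> pd.DataFrame:
    """Fit ML, PLS and the Gibbs-sampler Bayes estimator on identical data
    and tabulate the predictive metrics on the stacked outcome predictions.

    Any estimator failure marks its row failed; the others are still
    reported."""
    outcomes = list(spec.observed_outcomes)
    obs = data[outcomes].to_numpy(dtype=float).ravel(order="F")
    rows = []
    fits = {}
    for name, fitter in (
        ("ML", lambda: fit_ml(data, spec, seed=ml_seed, compute_se=False)),
        ("PLS", lambda: fit_pls(data, spec)),
        ("Bayesian", lambda: fit_bayes(data, spec, prior, mcmc)),
    ):
        row: dict[str, object] = {"estimator": name, "failed": False}
        try:
            fit = fitter()
            fits[name] = fit
            pred = predict_outcomes(fit, data, spec)
            m = predictive_metrics(obs, pred[outcomes].to_numpy().ravel(order="F"))
            row.update(
                {
                    "R2": m.r2,
                    "RMSE": m.rmse,
                    "MAPE": m.mape,
                    "MSE_printed": m.mse_printed,
                }
            )
        except Exception as exc:  # pragma: no cover - failure path
            row.update({"failed": True, "error": str(exc)})
        rows.append(row)
    table = pd.DataFrame(rows).set_index("estimator")
    table.attrs["fits"] = fits
    return table
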