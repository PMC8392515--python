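"""Reliability and validity stage: Cronbach's alpha, AVE and the
loading-threshold elimination rule.

The study's convergent-validity rules are applied per construct: Cronbach's
alpha above 0.7, average variance extracted (AVE) above 0.5, and a
standardized loading of at least 0.7 per indicator — indicators strictly
below the loading threshold are eliminated before the structural analysis.
Loadings entering the filter come from a single-factor fit per construct on
the z-standardized indicator block.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import FactorAnalysis

from .model_spec import ModelSpec

__all__ = [
    "ReliabilityReport",
    "cronbach_alpha",
    "cronbach_alpha_from_cov",
    "average_variance_extracted",
    "construct_loadings",
    "reliability_filter",
]


def cronbach_alpha_from_cov(cov: np.ndarray) -> float:
    """Alpha from an item covariance matrix: k/(k-1) (1 - sum(var_i)/var(sum))."""
    cov = np.asarray(cov, dtype=float)
    k = cov.shape[0]
    if k < 2:
        raise ValueError("Cronbach's alpha needs at least 2 items")
    item_var = np.diag(cov)
    if np.any(item_var <= 0):
        raise ValueError("all items must have positive variance")
    total_var = float(cov.sum())
    return k / (k - 1) * (1.0 - float(item_var.sum()) / total_var)


def cronbach_alpha(items: pd.DataFrame | np.ndarray) -> float:
    """Internal-consistency reliability of an n x k item table."""
    X = np.asarray(items, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("item table must be n x k with k >= 2")
    return cronbach_alpha_from_cov(np.cov(X, rowvar=False, ddof=1))


def average_variance_extracted(loadings: Sequence[float]) -> float:
    """Mean squared standardized loading of a construct."""
    lam = np.asarray(list(loadings), dtype=float)
    if lam.size == 0:
        raise ValueError("loadings must be non-empty")
    return float(np.mean(lam**2))


def construct_loadings(data: pd.DataFrame, spec: ModelSpec) -> dict[str, dict[str, float]]:
    """Standardized loadings from a single-factor ML fit per construct.

    Each indicator block is z-standardized and fit with a one-factor model;
    the standardized loading is w_j / sqrt(w_j^2 + psi_j).  Signs are anchored
    so each block's loading sum is positive."""
    out: dict[str, dict[str, float]] = {}
    for latent in spec.latents:
        X = data[list(latent.indicators)].to_numpy(dtype=float)
        Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        fa = FactorAnalysis(n_components=1, random_state=0)
        fa.fit(Z)
        w = fa.components_[0]
        if w.sum() < 0:
            w = -w
        lam = w / np.sqrt(w**2 + fa.noise_variance_)
        out[latent.name] = dict(zip(latent.indicators, lam))
    return out


@dataclass
class ConstructSummary:
    name: str
    loadings: dict[str, float]  # all computed loadings, retained + dropped
    retained: tuple[str, ...]
    dropped: tuple[str, ...]
    ave: float  # on retained indicators
    alpha: float | None  # on retained indicators, None without item data
    valid: bool

    def passes(self, alpha_threshold: float, ave_threshold: float) -> dict[str, bool]:
        return {
            "ave_ok": self.ave > ave_threshold,
            "alpha_ok": (self.alpha is None) or (self.alpha > alpha_threshold),
        }


@dataclass
class ReliabilityReport:
    constructs: dict[str, ConstructSummary]
    loading_threshold: float
    alpha_threshold: float
    ave_threshold: float

    @property
    def dropped(self) -> dict[str, str]:
        """Indicator -> reason, across all constructs."""
        return {
            i: f"loading {c.loadings[i]:.2f} < {self.loading_threshold}"
            for c in self.constructs.values()
            for i in c.dropped
        }

    @property
    def retained_loadings(self) -> dict[str, dict[str, float]]:
        return {
            name: {i: c.loadings[i] for i in c.retained}
            for name, c in self.constructs.items()
        }

    def to_frame(self) -> pd.DataFrame:
        """Long-format table mirroring the published reliability layout."""
        rows = []
        for c in self.constructs.values():
            flags = c.passes(self.alpha_threshold, self.ave_threshold)
            for i, lam in c.loadings.items():
                rows.append(
                    {
                        "construct": c.name,
                        "indicator": i,
                        "loading": lam,
                        "retained": i in c.retained,
                        "ave": c.ave,
                        "alpha": c.alpha,
                        "ave_ok": flags["ave_ok"],
                        "alpha_ok": flags["alpha_ok"],
                    }
                )
        return pd.DataFrame(rows)


def reliability_filter(
    loadings: Mapping[str, Mapping[str, float]],
    item_data: pd.DataFrame | None = None,
    loading_threshold: float = 0.7,
    alpha_threshold: float = 0.7,
    ave_threshold: float = 0.5,
) -> ReliabilityReport:
    """Apply the elimination rule: indicators with loading strictly below the
    threshold are dropped (a loading exactly at the threshold is retained),
    and each construct is re-summarized (AVE, alpha) on its retained
    indicators.  A construct left with no retained indicator is flagged
    invalid."""
    constructs: dict[str, ConstructSummary] = {}
    for name, lam_map in loadings.items():
        lam_map = dict(lam_map)
        retained = tuple(i for i, l in lam_map.items() if l >= loading_threshold)
        dropped = tuple(i for i in lam_map if i not in retained)
        valid = bool(retained)
        ave = average_variance_extracted([lam_map[i] for i in retained]) if valid else np.nan
        alpha = None
        if item_data is not None and len(retained) >= 2:
            alpha = cronbach_alpha(item_data[list(retained)])
        constructs[name] = ConstructSummary(
            name=name,
            loadings=lam_map,
            retained=retained,
            dropped=dropped,
            ave=ave,
            alpha=alpha,
            valid=valid,
        )
    return ReliabilityReport(
        constructs=constructs,
        loading_threshold=loading_threshold,
        alpha_threshold=alpha_threshold,
        ave_threshold=ave_threshold,
    )
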