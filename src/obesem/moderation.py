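"""Multi-group gender-moderation analysis.

The same SEM is fit separately per group and each structural path's
coefficients are compared with the critical-ratio test

    z = (b_boy - b_girl) / sqrt(se_boy^2 + se_girl^2),

two-sided normal p-value, significance at |z| > 1.96.  Standard errors come
from each group's own fit (posterior SD for the Bayes estimator, asymptotic
SE for ML) without pooling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model_spec import DISPLAY_NAMES, ModelSpec

__all__ = ["ModerationRow", "z_difference", "multigroup_table", "Z_CRITICAL"]

Z_CRITICAL = 1.96


class FitResult(Protocol):
    structural_estimates: dict[str, float]
    structural_se: dict[str, float]


def z_difference(b1: float, se1: float, b2: float, se2: float) -> tuple[float, float]:
    """Critical ratio and two-sided normal p-value for a coefficient
    difference between two independent groups."""
    if se1 < 0 or se2 < 0:
        raise ValueError("standard errors must be >= 0")
    denom = np.hypot(se1, se2)
    if denom == 0:
        raise ValueError("both standard errors are zero; z is undefined")
    z = (b1 - b2) / denom
    # clamp against floating-point underflow so p stays in (0, 1]
    p = max(2.0 * stats.norm.sf(abs(z)), np.finfo(float).tiny)
    return float(z), float(p)


@dataclass(frozen=True)
class ModerationRow:
    path: str
    coef_boy: float
    coef_girl: float
    se_boy: float
    se_girl: float
    z: float
    p: float

    @property
    def significant(self) -> bool:
        return abs(self.z) > Z_CRITICAL


def _display_path(label: str) -> str:
    src, tgt = label.split("->")
    return f"{DISPLAY_NAMES.get(src, src)} -> {DISPLAY_NAMES.get(tgt, tgt)}"


def multigroup_table(
    fit_boy: FitResult, fit_girl: FitResult, spec: ModelSpec
) -> list[ModerationRow]:
    """One critical-ratio row per structural/control path (15 for the default
    obesity model), ordered as in the published multi-group table."""
    rows = []
    boy_est, girl_est = fit_boy.structural_estimates, fit_girl.structural_estimates
    boy_se, girl_se = fit_boy.structural_se, fit_girl.structural_se
    for label in spec.path_labels:
        for name, est in (("boy", boy_est), ("girl", girl_est)):
            if label not in est:
                raise KeyError(f"path {label!r} missing from the {name} fit")
        z, p = z_difference(boy_est[label], boy_se[label], girl_est[label], girl_se[label])
        rows.append(
            ModerationRow(
                path=label,
                coef_boy=boy_est[label],
                coef_girl=girl_est[label],
                se_boy=boy_se[label],
                se_girl=girl_se[label],
                z=z,
                p=p,
            )
        )
    return rows


def moderation_frame(rows: Sequence[ModerationRow]) -> pd.DataFrame:
    """Export table with display path names and a significance flag."""
    return pd.DataFrame(
        [
            {
                "path": _display_path(r.path),
                "coef_boy": r.coef_boy,
                "coef_girl": r.coef_girl,
                "z": r.z,
                "p": r.p,
                "significant": r.significant,
            }
            for r in rows
        ]
    )
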