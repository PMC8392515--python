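"""Synthetic two-group survey generator with known ground truth.

The generator emulates the layout of the Tehran adolescent survey (881
completed questionnaires, boy/girl groups): 17 Likert-derived indicators, two
obesity outcomes (BMI, body fat) and two parental controls.  The generating
parameters are the study's published values — the per-group standardized path
coefficients of the multi-group table and the published factor loadings —
with residual variances solved so that every variable has unit total variance.
Data are drawn from the implied multivariate normal distribution; an optional
post-hoc Likert discretization is provided but off by default since all
estimators treat the indicators as continuous.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .model_spec import (
    ModelSpec,
    ParameterSet,
    build_obesity_model,
    implied_covariance,
)

__all__ = [
    "SyntheticDataset",
    "TABLE_LOADINGS",
    "GIRL_STRUCTURAL",
    "BOY_STRUCTURAL",
    "default_true_params",
    "generate_group_dataset",
    "generate_study",
    "discretize_likert",
]

#: published standardized loadings, all 17 indicators
TABLE_LOADINGS: Mapping[str, float] = {
    "age_father": 0.48,
    "age_mother": 0.32,
    "edu_father": 0.79,
    "edu_mother": 0.71,
    "income_mother": 0.46,
    "income_father": 0.79,
    "sleep": 0.81,
    "physical_activity": 0.83,
    "screen_time": 0.79,
    "pocket_money": 0.87,
    "fruits": 0.73,
    "vegetables": 0.71,
    "whole_grains": 0.76,
    "snacks": 0.88,
    "fast_food": 0.87,
    "soft_drink": 0.95,
    "sweets": 0.93,
}

#: published girl-model standardized path coefficients
GIRL_STRUCTURAL: Mapping[str, float] = {
    "ses->healthy_food": 0.61,
    "ses->unhealthy_food": 0.31,
    "ses->lifestyle": 0.05,
    "ses->bmi": 0.10,
    "ses->body_fat": 0.09,
    "lifestyle->healthy_food": 0.25,
    "lifestyle->unhealthy_food": 0.33,
    "lifestyle->bmi": -0.20,
    "lifestyle->body_fat": -0.21,
    "healthy_food->bmi": -0.21,
    "healthy_food->body_fat": 0.22,
    "unhealthy_food->bmi": 0.71,
    "unhealthy_food->body_fat": 0.76,
    "parent_bmi->bmi": 0.22,
    "parent_body_fat->body_fat": 0.18,
}

#: published boy-model standardized path coefficients
BOY_STRUCTURAL: Mapping[str, float] = {
    "ses->healthy_food": 0.41,
    "ses->unhealthy_food": 0.08,
    "ses->lifestyle": 0.31,
    "ses->bmi": -0.19,
    "ses->body_fat": 0.22,
    "lifestyle->healthy_food": 0.06,
    "lifestyle->unhealthy_food": 0.37,
    "lifestyle->bmi": -0.09,
    "lifestyle->body_fat": -0.29,
    "healthy_food->bmi": 0.09,
    "healthy_food->body_fat": 0.34,
    "unhealthy_food->bmi": 0.53,
    "unhealthy_food->body_fat": 0.65,
    "parent_bmi->bmi": 0.19,
    "parent_body_fat->body_fat": 0.23,
}


def _unit_variance_residuals(
    spec: ModelSpec, structural: Mapping[str, float]
) -> dict[str, float]:
    """Disturbance variances making every structural variable unit-variance.

    Walks the DAG in topological order; for each endogenous variable the
    systematic variance b' Sigma_pp b is computed from the covariance of its
    parents and the residual is 1 minus that.  Rejects parameter combinations
    whose systematic variance reaches 1."""
    names = spec.structural_names
    idx = {n: i for i, n in enumerate(names)}
    k = len(names)
    sigma = np.zeros((k, k))
    resid: dict[str, float] = {}
    for v in spec.topological_order():
        i = idx[v]
        parents = spec.parents(v)
        if not parents:
            sigma[i, i] = 1.0
            resid[v] = 1.0  # exogenous: total variance
            continue
        p_idx = [idx[p] for p in parents]
        b = np.array([structural[f"{p}->{v}"] for p in parents])
        var_sys = float(b @ sigma[np.ix_(p_idx, p_idx)] @ b)
        psi = 1.0 - var_sys
        if psi <= 0:
            raise ValueError(
                f"unit-variance constraint violated for {v!r}: systematic "
                f"variance {var_sys:.4f} >= 1; the path coefficients are too large"
            )
        row = b @ sigma[p_idx, :]
        sigma[i, :] = row
        sigma[:, i] = row
        sigma[i, i] = 1.0
        resid[v] = psi
    return resid


def default_true_params(group: str, spec: ModelSpec | None = None) -> ParameterSet:
    """Ground-truth parameters for one gender group: published loadings and
    per-group path coefficients, residual variances from the unit-variance
    standardization convention."""
    spec = spec or build_obesity_model()
    structural = {"girl": GIRL_STRUCTURAL, "boy": BOY_STRUCTURAL}.get(group)
    if structural is None:
        raise ValueError(f"unknown group {group!r}; expected 'boy' or 'girl'")
    loadings = {i: TABLE_LOADINGS[i] for i in spec.indicator_names}
    resid = {i: 1.0 - lam**2 for i, lam in loadings.items()}
    resid.update(_unit_variance_residuals(spec, structural))
    structural = {p: structural[p] for p in spec.path_labels}
    return ParameterSet(loadings=loadings, structural=structural, residual_variances=resid)


@dataclass
class SyntheticDataset:
    """Generated survey table plus the truth that produced it."""

    data: pd.DataFrame  # observed columns + group column
    truth: dict[str, ParameterSet]  # group label -> generating parameters
    seed: int
    spec: ModelSpec

    @property
    def n(self) -> int:
        return len(self.data)

    def group_sizes(self) -> dict[str, int]:
        return self.data[self.spec.group_variable].value_counts().to_dict()

    def group_data(self, group: str) -> pd.DataFrame:
        gcol = self.spec.group_variable
        sub = self.data[self.data[gcol] == group]
        if sub.empty:
            raise KeyError(f"no rows for group {group!r}")
        return sub[list(self.spec.observed_names)].reset_index(drop=True)

    # -- text round trip --------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        """Write the table as CSV with a sidecar ``<path>.truth.json``."""
        path = Path(path)
        self.data.to_csv(path, index=False)
        sidecar = {
            "seed": self.seed,
            "spec": self.spec.to_dict(),
            "truth": {
                g: {
                    "loadings": p.loadings,
                    "structural": p.structural,
                    "residual_variances": p.residual_variances,
                }
                for g, p in self.truth.items()
            },
        }
        path.with_suffix(path.suffix + ".truth.json").write_text(
            json.dumps(sidecar, indent=1)
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "SyntheticDataset":
        path = Path(path)
        data = pd.read_csv(path)
        meta = json.loads(path.with_suffix(path.suffix + ".truth.json").read_text())
        truth = {
            g: ParameterSet(d["loadings"], d["structural"], d["residual_variances"])
            for g, d in meta["truth"].items()
        }
        return cls(data=data, truth=truth, seed=meta["seed"], spec=ModelSpec.from_dict(meta["spec"]))


def generate_group_dataset(
    spec: ModelSpec,
    params: ParameterSet,
    n: int,
    seed: int | np.random.Generator,
    group: str = "girl",
) -> SyntheticDataset:
    """Independent draws from the linear-Gaussian model implied by the
    parameters.  Identical (spec, params, n, seed) gives bit-identical output."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sigma = implied_covariance(spec, params).to_numpy()
    chol = np.linalg.cholesky(sigma)
    draws = rng.standard_normal((n, sigma.shape[0])) @ chol.T
    data = pd.DataFrame(draws, columns=list(spec.observed_names))
    data[spec.group_variable] = group
    seed_val = seed if isinstance(seed, (int, np.integer)) else -1
    return SyntheticDataset(data=data, truth={group: params}, seed=int(seed_val), spec=spec)


def generate_study(
    n_total: int = 881,
    boy_fraction: float = 0.5,
    seed: int = 0,
    spec: ModelSpec | None = None,
) -> SyntheticDataset:
    """Two-group study: boys and girls drawn from their own ground truth.

    The default 881 mirrors the completed-questionnaire count of the survey;
    the boy fraction defaults to an even split since group sizes were not
    published.  Group sizes are round(n_total * boy_fraction) and the rest."""
    if not 0 < boy_fraction < 1:
        raise ValueError("boy_fraction must be strictly between 0 and 1")
    spec = spec or build_obesity_model()
    n_boy = round(n_total * boy_fraction)
    n_girl = n_total - n_boy
    if n_boy < 1 or n_girl < 1:
        raise ValueError("both groups need at least one row")
    ss = np.random.SeedSequence(seed)
    rng_boy, rng_girl = (np.random.default_rng(s) for s in ss.spawn(2))
    truth = {g: default_true_params(g, spec) for g in ("boy", "girl")}
    boys = generate_group_dataset(spec, truth["boy"], n_boy, rng_boy, group="boy")
    girls = generate_group_dataset(spec, truth["girl"], n_girl, rng_girl, group="girl")
    data = pd.concat([boys.data, girls.data], ignore_index=True)
    return SyntheticDataset(data=data, truth=truth, seed=seed, spec=spec)


def discretize_likert(
    data: pd.DataFrame, columns: list[str], n_levels: int = 5
) -> pd.DataFrame:
    """Optional post-hoc discretization of continuous indicators into ordered
    Likert bins at equally spaced quantile cut points (1..n_levels)."""
    out = data.copy()
    qs = np.linspace(0, 1, n_levels + 1)[1:-1]
    for c in columns:
        cuts = np.quantile(data[c], qs)
        out[c] = np.digitize(data[c], cuts) + 1
    return out
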