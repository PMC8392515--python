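"""Declarative SEM topology for the adolescent-obesity model.

The model combines a measurement part (four latent constructs, each measured
by Likert-type indicators treated as continuous after z-standardization) and
a structural part (a directed acyclic graph of regressions among the latents,
two observed outcomes and two observed parental controls):

* ``ses`` — household socioeconomic status, 6 indicators,
* ``lifestyle`` — 4 indicators,
* ``healthy_food`` / ``unhealthy_food`` — food-intake constructs, 3 + 4 indicators,
* outcomes ``bmi`` and ``body_fat``, controls ``parent_bmi`` and ``parent_body_fat``.

Identification convention: every latent variable has unit variance and its
first loading is constrained positive, so all reported coefficients are fully
standardized.  The fixed coordinate order used everywhere is: the 17
indicators (socioeconomic 1-6, lifestyle 1-4, healthy 1-3, unhealthy 1-4),
then ``parent_bmi``, ``parent_body_fat``, ``bmi``, ``body_fat``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "LatentDef",
    "PathDef",
    "ModelSpec",
    "PriorConfig",
    "ParameterSet",
    "build_obesity_model",
    "default_prior",
    "make_prior",
    "implied_covariance",
    "structural_matrices",
    "BETA_PATHS",
    "DISPLAY_NAMES",
]

#: display names used in exported tables
DISPLAY_NAMES = {
    "ses": "Household Socioeconomic",
    "lifestyle": "Lifestyle",
    "healthy_food": "Healthy Food Intake",
    "unhealthy_food": "Unhealthy Food Intake",
    "bmi": "BMI",
    "body_fat": "Body Fat",
    "parent_bmi": "Parent's BMI",
    "parent_body_fat": "Parent's Body Fat",
}


def path_label(source: str, target: str) -> str:
    return f"{source}->{target}"


@dataclass(frozen=True)
class LatentDef:
    """One latent construct and its reflective indicators."""

    name: str
    indicators: tuple[str, ...]
    #: per-indicator free/fixed flags; True means the loading is free.
    loadings_pattern: tuple[bool, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "indicators", tuple(self.indicators))
        if not self.indicators:
            raise ValueError(f"latent {self.name!r} needs at least one indicator")
        pattern = tuple(self.loadings_pattern) or (True,) * len(self.indicators)
        if len(pattern) != len(self.indicators):
            raise ValueError(f"loadings_pattern length mismatch for {self.name!r}")
        object.__setattr__(self, "loadings_pattern", pattern)


@dataclass(frozen=True)
class PathDef:
    """A directed regression path of the structural model."""

    source: str
    target: str
    role: str = "structural"  # "structural" or "control"

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValueError(f"self-loop {self.source!r} not allowed")
        if self.role not in ("structural", "control"):
            raise ValueError(f"unknown path role {self.role!r}")

    @property
    def label(self) -> str:
        return path_label(self.source, self.target)


@dataclass(frozen=True)
class ModelSpec:
    """Full latent/indicator/path topology of one multi-group SEM."""

    latents: tuple[LatentDef, ...]
    observed_outcomes: tuple[str, ...]
    controls: tuple[str, ...]
    paths: tuple[PathDef, ...]
    group_variable: str = "gender"

    def __post_init__(self) -> None:
        object.__setattr__(self, "latents", tuple(self.latents))
        object.__setattr__(self, "observed_outcomes", tuple(self.observed_outcomes))
        object.__setattr__(self, "controls", tuple(self.controls))
        object.__setattr__(self, "paths", tuple(self.paths))
        inds = self.indicator_names
        if len(set(inds)) != len(inds):
            raise ValueError("indicator labels must be unique across the model")
        declared = set(self.structural_names)
        for p in self.paths:
            for end in (p.source, p.target):
                if end not in declared:
                    raise ValueError(f"path endpoint {end!r} is not a declared variable")
        self.topological_order()  # raises on cycles

    # -- coordinate bookkeeping -------------------------------------------------

    @property
    def latent_names(self) -> tuple[str, ...]:
        return tuple(l.name for l in self.latents)

    @property
    def indicator_names(self) -> tuple[str, ...]:
        return tuple(i for l in self.latents for i in l.indicators)

    @property
    def structural_names(self) -> tuple[str, ...]:
        """Variables of the structural system: latents, controls, outcomes."""
        return (*self.latent_names, *self.controls, *self.observed_outcomes)

    @property
    def observed_names(self) -> tuple[str, ...]:
        """All observed columns in the fixed coordinate order."""
        return (*self.indicator_names, *self.controls, *self.observed_outcomes)

    @property
    def path_labels(self) -> tuple[str, ...]:
        return tuple(p.label for p in self.paths)

    def latent_of(self, indicator: str) -> str:
        for l in self.latents:
            if indicator in l.indicators:
                return l.name
        raise KeyError(indicator)

    def parents(self, name: str) -> tuple[str, ...]:
        """Parents of a structural variable, in structural-name order."""
        srcs = {p.source for p in self.paths if p.target == name}
        return tuple(v for v in self.structural_names if v in srcs)

    def topological_order(self) -> tuple[str, ...]:
        names = self.structural_names
        pending = {n: set(self.parents(n)) for n in names}
        order: list[str] = []
        while pending:
            ready = [n for n in names if n in pending and not pending[n]]
            if not ready:
                raise ValueError("structural graph contains a cycle")
            for n in ready:
                order.append(n)
                del pending[n]
                for deps in pending.values():
                    deps.discard(n)
        return tuple(order)

    @property
    def exogenous(self) -> tuple[str, ...]:
        return tuple(n for n in self.structural_names if not self.parents(n))

    @property
    def endogenous(self) -> tuple[str, ...]:
        return tuple(n for n in self.structural_names if self.parents(n))

    def drop_indicators(self, names: Iterable[str]) -> "ModelSpec":
        """Return a new spec with the given indicators removed (e.g. after the
        reliability filter).  A construct may not lose all its indicators."""
        drop = set(names)
        unknown = drop - set(self.indicator_names)
        if unknown:
            raise KeyError(f"unknown indicators: {sorted(unknown)}")
        new_latents = []
        for l in self.latents:
            kept = tuple(i for i in l.indicators if i not in drop)
            if not kept:
                raise ValueError(f"construct {l.name!r} would lose all indicators")
            new_latents.append(LatentDef(l.name, kept))
        return replace(self, latents=tuple(new_latents))

    # -- serialization ----------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "latents": [
                {"name": l.name, "indicators": list(l.indicators)} for l in self.latents
            ],
            "observed_outcomes": list(self.observed_outcomes),
            "controls": list(self.controls),
            "paths": [
                {"source": p.source, "target": p.target, "role": p.role}
                for p in self.paths
            ],
            "group_variable": self.group_variable,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelSpec":
        return cls(
            latents=tuple(
                LatentDef(x["name"], tuple(x["indicators"])) for x in d["latents"]
            ),
            observed_outcomes=tuple(d["observed_outcomes"]),
            controls=tuple(d["controls"]),
            paths=tuple(
                PathDef(x["source"], x["target"], x.get("role", "structural"))
                for x in d["paths"]
            ),
            group_variable=d.get("group_variable", "gender"),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# default obesity topology
# ---------------------------------------------------------------------------

_SES_INDICATORS = (
    "age_father",
    "age_mother",
    "edu_father",
    "edu_mother",
    "income_mother",
    "income_father",
)
_LIFESTYLE_INDICATORS = ("sleep", "physical_activity", "screen_time", "pocket_money")
_HEALTHY_INDICATORS = ("fruits", "vegetables", "whole_grains")
_UNHEALTHY_INDICATORS = ("snacks", "fast_food", "soft_drink", "sweets")

#: the eight latent->outcome hyperprior paths, in beta1..beta8 order
BETA_PATHS = (
    "ses->bmi",
    "ses->body_fat",
    "lifestyle->bmi",
    "lifestyle->body_fat",
    "healthy_food->bmi",
    "healthy_food->body_fat",
    "unhealthy_food->bmi",
    "unhealthy_food->body_fat",
)

#: report row order for the 15-path multi-group table
TABLE_PATH_ORDER = (
    "ses->healthy_food",
    "ses->unhealthy_food",
    "ses->lifestyle",
    "ses->bmi",
    "ses->body_fat",
    "lifestyle->healthy_food",
    "lifestyle->unhealthy_food",
    "lifestyle->bmi",
    "lifestyle->body_fat",
    "healthy_food->bmi",
    "healthy_food->body_fat",
    "unhealthy_food->bmi",
    "unhealthy_food->body_fat",
    "parent_bmi->bmi",
    "parent_body_fat->body_fat",
)


def build_obesity_model() -> ModelSpec:
    """The fixed adolescent-obesity topology: one exogenous latent (household
    socioeconomic status), three mediators (lifestyle, healthy and unhealthy
    food intake), outcomes BMI and body fat, and two parental control paths —
    fifteen directed paths in total."""
    latents = (
        LatentDef("ses", _SES_INDICATORS),
        LatentDef("lifestyle", _LIFESTYLE_INDICATORS),
        LatentDef("healthy_food", _HEALTHY_INDICATORS),
        LatentDef("unhealthy_food", _UNHEALTHY_INDICATORS),
    )
    paths = []
    for lbl in TABLE_PATH_ORDER:
        src, tgt = lbl.split("->")
        role = "control" if src.startswith("parent_") else "structural"
        paths.append(PathDef(src, tgt, role))
    return ModelSpec(
        latents=latents,
        observed_outcomes=("bmi", "body_fat"),
        controls=("parent_bmi", "parent_body_fat"),
        paths=tuple(paths),
    )


def default_model_path() -> Path:
    return Path(str(resources.files("obesem").joinpath("obesity_model.yaml")))


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PriorConfig:
    """Normal priors on coefficients, inverse-gamma on residual variances.

    ``path_means`` holds the eight latent->outcome hyperprior means
    (beta1..beta8).  Coefficients without an explicit entry (loadings,
    latent->latent paths, control paths) take ``loading_mean`` as their prior
    mean.  ``prior_variance`` is the common coefficient prior variance (the
    "small variance" convention); ``path_variances`` can override it per path.
    ``variance_prior`` is the (shape, scale) of the noninformative
    inverse-gamma prior on residual variances."""

    path_means: Mapping[str, float]
    loading_mean: float = 0.5
    prior_variance: float = 1.0
    variance_prior: tuple[float, float] = (0.01, 0.01)
    path_variances: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "path_means", dict(self.path_means))
        object.__setattr__(self, "path_variances", dict(self.path_variances))
        if self.prior_variance <= 0:
            raise ValueError("prior_variance must be > 0")
        a, b = self.variance_prior
        if a <= 0 or b <= 0:
            raise ValueError("variance_prior shape and scale must be > 0")

    def mean_for(self, label: str) -> float:
        return float(self.path_means.get(label, self.loading_mean))

    def variance_for(self, label: str) -> float:
        return float(self.path_variances.get(label, self.prior_variance))


_TYPE_I_MEANS = {
    "girl": (0.4, 0.7, 0.3, 0.5, 0.7, 0.7, 0.6, 0.7),
    "boy": (0.5, 0.4, 0.6, 0.6, 0.7, 0.7, 0.5, 0.6),
}


def default_prior(group: str) -> PriorConfig:
    """Type I prior for one gender group: the base beta1..beta8 means."""
    if group not in _TYPE_I_MEANS:
        raise ValueError(f"unknown group {group!r}; expected 'boy' or 'girl'")
    return PriorConfig(path_means=dict(zip(BETA_PATHS, _TYPE_I_MEANS[group])))


def make_prior(regime: str, base: PriorConfig) -> PriorConfig:
    """Derive a prior regime from the base (Type I) configuration.

    Regime I returns the base unchanged, II halves every path mean, III
    doubles every path mean; the 0.5 loading mean is regime-invariant."""
    if not base.path_means:
        raise ValueError("base prior has no path means populated")
    scale = {"I": 1.0, "II": 0.5, "III": 2.0}.get(regime)
    if scale is None:
        raise ValueError(f"unknown prior regime {regime!r}; expected 'I', 'II' or 'III'")
    return replace(base, path_means={k: v * scale for k, v in base.path_means.items()})


# ---------------------------------------------------------------------------
# parameters and the model-implied covariance
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParameterSet:
    """Numeric values for one group's model.

    ``residual_variances`` covers every observed indicator, every endogenous
    structural variable (disturbance variance) and every exogenous structural
    variable (its total variance; 1.0 for standardized latents)."""

    loadings: Mapping[str, float]
    structural: Mapping[str, float]
    residual_variances: Mapping[str, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "loadings", dict(self.loadings))
        object.__setattr__(self, "structural", dict(self.structural))
        object.__setattr__(self, "residual_variances", dict(self.residual_variances))
        bad = {k: v for k, v in self.residual_variances.items() if v <= 0}
        if bad:
            raise ValueError(f"non-positive residual variances: {bad}")

    def latent_covariances(self, spec: ModelSpec) -> np.ndarray:
        """Model-implied covariance among the latent variables."""
        V = _structural_covariance(spec, self)
        k = len(spec.latent_names)
        return V[:k, :k]


def structural_matrices(
    spec: ModelSpec, params: ParameterSet
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(B, psi, G, theta): path matrix, structural residual variances,
    observed-on-structural loading matrix, measurement residual variances."""
    names = spec.structural_names
    idx = {n: i for i, n in enumerate(names)}
    k = len(names)
    B = np.zeros((k, k))
    for p in spec.paths:
        try:
            B[idx[p.target], idx[p.source]] = params.structural[p.label]
        except KeyError:
            raise KeyError(f"parameter set is missing path {p.label!r}") from None
    psi = np.empty(k)
    for n in names:
        try:
            psi[idx[n]] = params.residual_variances[n]
        except KeyError:
            raise KeyError(f"parameter set is missing a variance for {n!r}") from None
    obs = spec.observed_names
    G = np.zeros((len(obs), k))
    theta = np.zeros(len(obs))
    for j, name in enumerate(obs):
        if name in idx and name not in spec.indicator_names:
            G[j, idx[name]] = 1.0  # directly observed structural variable
        else:
            G[j, idx[spec.latent_of(name)]] = params.loadings[name]
            theta[j] = params.residual_variances[name]
    return B, psi, G, theta


def _structural_covariance(spec: ModelSpec, params: ParameterSet) -> np.ndarray:
    B, psi, _, _ = structural_matrices(spec, params)
    k = B.shape[0]
    A = np.linalg.solve(np.eye(k) - B, np.eye(k))
    V = (A * psi) @ A.T
    return (V + V.T) / 2.0


def implied_covariance(spec: ModelSpec, params: ParameterSet) -> pd.DataFrame:
    """Reduced-form covariance matrix of all observed variables.

    For the linear system s = B s + zeta with Cov(zeta) = diag(psi) and
    observations y = G s + eps, the implied covariance is
    Sigma = G (I-B)^-1 diag(psi) (I-B)^-T G' + diag(theta)."""
    B, psi, G, theta = structural_matrices(spec, params)
    k = B.shape[0]
    A = np.linalg.solve(np.eye(k) - B, np.eye(k))
    V = (A * psi) @ A.T
    sigma = G @ ((V + V.T) / 2.0) @ G.T + np.diag(theta)
    sigma = (sigma + sigma.T) / 2.0
    eig = np.linalg.eigvalsh(sigma)
    if eig[0] <= 1e-12 * max(eig[-1], 1.0):
        raise ValueError(
            "implied covariance is not positive definite "
            f"(min eigenvalue {eig[0]:.3e}); check residual variances"
        )
    obs = list(spec.observed_names)
    return pd.DataFrame(sigma, index=obs, columns=obs)
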