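"""End-to-end study orchestration and sampling-design arithmetic.

``run_full_study`` executes the whole analysis on a synthetic study:
generation, reliability filtering, per-group Gibbs fits under the requested
prior regimes, prior-sensitivity comparison, ML and PLS fits, fit indices,
the three-estimator predictive comparison and the gender-moderation table.
Every numeric artifact is reproducible bit-for-bit from the config.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assessment import baseline_chisq, compare_estimators, fit_indices
from .classical import fit_ml
from .gibbs import McmcConfig, fit_bayes, prior_sensitivity
from .measurement import construct_loadings, reliability_filter
from .model_spec import (
    ModelSpec,
    PriorConfig,
    build_obesity_model,
    default_prior,
    implied_covariance,
    make_prior,
)
from .moderation import moderation_frame, multigroup_table
from .synthetic import generate_study

__all__ = ["StudyConfig", "min_sample_size", "response_rate", "run_full_study"]

log = logging.getLogger("obesem")


def min_sample_size(n_parameters: int, ratio: int = 20) -> int:
    """N:q sample-size rule of thumb: participants per estimated parameter."""
    if n_parameters < 1 or ratio < 1:
        raise ValueError("n_parameters and ratio must be >= 1")
    return int(n_parameters) * int(ratio)


def response_rate(completed: int, distributed: int) -> float:
    """Completed questionnaires as a percentage, to one decimal."""
    if distributed <= 0:
        raise ValueError("distributed must be > 0")
    if not 0 <= completed <= distributed:
        raise ValueError("completed must be between 0 and distributed")
    return round(100.0 * completed / distributed, 1)


@dataclass
class StudyConfig:
    n_total: int = 881
    boy_fraction: float = 0.5
    seed: int = 0
    prior_regimes: tuple[str, ...] = ("I", "II", "III")
    mcmc: McmcConfig = field(default_factory=lambda: McmcConfig(
        n_iterations=4000, burn_in=1500, thin=1, n_chains=2
    ))
    loading_threshold: float = 0.7
    alpha_threshold: float = 0.7
    ave_threshold: float = 0.5
    groups: tuple[str, ...] = ("boy", "girl")
    output_dir: str = "obesem_results"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mcmc"] = asdict(self.mcmc)
        return d

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class StudyBundle:
    config: StudyConfig
    output_dir: Path
    artifacts: dict[str, Path]
    manifest: dict

    def table(self, name: str) -> pd.DataFrame:
        return pd.read_csv(self.artifacts[name])


def _round_numeric(df: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    out = df.copy()
    for c in out.select_dtypes(include=[np.number]).columns:
        out[c] = out[c].round(decimals)
    return out


def run_full_study(config: StudyConfig) -> StudyBundle:
    """Run every stage in order and write the report bundle.

    Stage failures never abort the run silently: each failure is recorded in
    the manifest and later stages that do not depend on it still execute."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = build_obesity_model()
    artifacts: dict[str, Path] = {}
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": config.config_hash,
        "seed": config.seed,
        "versions": {"obesem": __version__, "numpy": np.__version__, "pandas": pd.__version__},
        "stages": {},
        "failures": {},
    }
    t_all = time.perf_counter()

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                result = fn()
                manifest["stages"][name] = {
                    "status": "ok",
                    "seconds": round(time.perf_counter() - t0, 3),
                }
                return result
            except Exception as exc:
                log.exception("stage %s failed", name)
                manifest["stages"][name] = {
                    "status": "failed",
                    "seconds": round(time.perf_counter() - t0, 3),
                }
                manifest["failures"][name] = str(exc)
                return None
        return deco

    def save(name: str, df: pd.DataFrame, decimals: int = 2) -> None:
        path = out / f"{name}.csv"
        _round_numeric(df, decimals).to_csv(path, index=False)
        artifacts[name] = path

    # 1. synthetic study -------------------------------------------------------
    @stage("simulate")
    def dataset():
        ds = generate_study(config.n_total, config.boy_fraction, config.seed)
        ds.to_csv(out / "study_data.csv")
        artifacts["study_data"] = out / "study_data.csv"
        return ds

    if dataset is None:
        manifest["elapsed_seconds"] = round(time.perf_counter() - t_all, 3)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        return StudyBundle(config, out, artifacts, manifest)

    pooled = dataset.data[list(spec.observed_names)]

    # 2. reliability filter ----------------------------------------------------
    @stage("reliability")
    def report():
        loadings = construct_loadings(pooled, spec)
        rep = reliability_filter(
            loadings,
            item_data=pooled,
            loading_threshold=config.loading_threshold,
            alpha_threshold=config.alpha_threshold,
            ave_threshold=config.ave_threshold,
        )
        save("reliability_table", rep.to_frame())
        return rep

    # Apply the elimination rule, but keep every construct identified: a
    # latent needs at least two indicators, so the weakest flagged indicators
    # are dropped only while two survivors remain.
    fit_spec = spec
    if report is not None and report.dropped:
        dropped: list[str] = []
        for c in report.constructs.values():
            flagged = sorted(c.dropped, key=lambda i: c.loadings[i])
            n_keep = len(c.loadings) - len(flagged)
            while flagged and n_keep < 2:
                flagged.pop()  # retain the strongest flagged indicator
                n_keep += 1
            dropped.extend(flagged)
        if dropped:
            fit_spec = spec.drop_indicators(dropped)
        manifest["dropped_indicators"] = sorted(dropped)

    have_both = all(g in dataset.group_sizes() for g in config.groups) and len(config.groups) == 2

    # 3. per-group Bayes fits under all regimes + sensitivity ------------------
    group_fits: dict[str, object] = {}
    sensitivity_tables = []
    for group in config.groups:
        if group not in dataset.group_sizes():
            manifest["failures"][f"bayes_{group}"] = f"no rows for group {group!r}"
            continue

        @stage(f"bayes_{group}")
        def res(group=group):
            gdata = dataset.group_data(group)
            priors = {
                reg: make_prior(reg, default_prior(group)) for reg in config.prior_regimes
            }
            mcmc = McmcConfig(
                n_iterations=config.mcmc.n_iterations,
                burn_in=config.mcmc.burn_in,
                thin=config.mcmc.thin,
                n_chains=config.mcmc.n_chains,
                seed=config.mcmc.seed + sum(ord(c) for c in group),
            )
            if len(priors) >= 2:
                sens = prior_sensitivity(gdata, fit_spec, priors, mcmc)
                fits = sens.fits
            else:
                reg = next(iter(priors))
                sens = None
                fits = {reg: fit_bayes(gdata, fit_spec, priors[reg], mcmc)}
            # the study's rule: keep the regime with the smallest mean SE
            mean_se = {
                reg: float(np.mean(list(f.structural_se.values())))
                for reg, f in fits.items()
            }
            chosen = min(mean_se, key=mean_se.get)
            manifest.setdefault("chosen_regime", {})[group] = chosen
            return sens, fits[chosen]

        if res is not None:
            sens, chosen_fit = res
            group_fits[group] = chosen_fit
            if sens is not None:
                t = sens.table.reset_index()
                t.insert(0, "group", group)
                sensitivity_tables.append(t)

    if sensitivity_tables:
        save("prior_sensitivity_table", pd.concat(sensitivity_tables, ignore_index=True), 3)

    # 4. estimator comparison + fit indices (pooled sample) --------------------
    pooled_fit = pooled[list(fit_spec.observed_names)]

    @stage("compare_estimators")
    def comparison():
        cmp_mcmc = McmcConfig(
            n_iterations=config.mcmc.n_iterations,
            burn_in=config.mcmc.burn_in,
            thin=config.mcmc.thin,
            n_chains=1,
            seed=config.mcmc.seed,
        )
        generic_prior = PriorConfig(path_means={})
        table = compare_estimators(pooled_fit, fit_spec, generic_prior, cmp_mcmc)
        save("estimator_comparison", table.reset_index(), 3)
        return table

    @stage("fit_indices")
    def indices():
        mlfit = fit_ml(pooled_fit, fit_spec, seed=config.seed, compute_se=False)
        S = np.corrcoef(pooled_fit.to_numpy(), rowvar=False)
        x2b, dfb = baseline_chisq(S, mlfit.n)
        implied = implied_covariance(fit_spec, mlfit.estimates).to_numpy()
        rep = fit_indices(mlfit.chisq, mlfit.df, x2b, dfb, S, implied, mlfit.n)
        save("fit_indices", pd.DataFrame([rep.to_dict()]), 3)
        return rep

    # 5. moderation ------------------------------------------------------------
    if have_both and all(g in group_fits for g in ("boy", "girl")):

        @stage("moderation")
        def rows():
            r = multigroup_table(group_fits["boy"], group_fits["girl"], fit_spec)
            frame = moderation_frame(r)
            save("moderation_table", frame, 3)
            manifest["n_significant_paths"] = int(frame["significant"].sum())
            return r
    else:
        manifest["stages"]["moderation"] = {"status": "skipped"}
        manifest["failures"]["moderation"] = (
            "moderation requires both a boy and a girl group fit"
        )

    manifest["elapsed_seconds"] = round(time.perf_counter() - t_all, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    artifacts["manifest"] = out / "manifest.json"
    return StudyBundle(config, out, artifacts, manifest)
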