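import numpy as np
import pandas as pd
import pytest

import obesem as ob
from obesem.model_spec import LatentDef, ModelSpec, PathDef


class TestML:
    def test_population_moments_give_perfect_fit(self, filtered_spec):
        """Fitting the implied covariance itself recovers the generating
        parameters with discrepancy ~ 0."""
        truth = ob.default_true_params("girl", filtered_spec)
        sigma = ob.implied_covariance(filtered_spec, truth).to_numpy()
        fit = ob.fit_ml_cov(sigma, n=10_000, spec=filtered_spec, compute_se=False)
        assert fit.discrepancy < 1e-8
        for p in filtered_spec.path_labels:
            assert fit.structural_estimates[p] == pytest.approx(truth.structural[p], abs=1e-3)
        for i in filtered_spec.indicator_names:
            assert fit.estimates.loadings[i] == pytest.approx(truth.loadings[i], abs=1e-3)

    def test_multi_start_agreement(self, filtered_spec, girl_data_2000):
        data, _ = girl_data_2000
        fit = ob.fit_ml(data, filtered_spec, n_starts=3, seed=42, compute_se=False)
        best = min(fit.start_discrepancies)
        assert all(f - best < 1e-6 for f in fit.start_discrepancies)

    def test_recovery_at_n5000(self, filtered_spec):
        """Most replicates recover every structural path within 0.05 at
        n=5000 (the worst path's sampling SD is ~0.02, so the all-path event
        holds in roughly 9 of 10 replicates)."""
        truth = ob.default_true_params("girl", filtered_spec)
        ss = np.random.SeedSequence(55).spawn(20)
        worsts = []
        for s in ss:
            d = ob.generate_group_dataset(
                filtered_spec, truth, 5000, np.random.default_rng(s)
            ).group_data("girl")
            fit = ob.fit_ml(d, filtered_spec, n_starts=1, compute_se=False)
            worsts.append(
                max(
                    abs(fit.structural_estimates[p] - truth.structural[p])
                    for p in filtered_spec.path_labels
                )
            )
        assert sum(w <= 0.05 for w in worsts) >= 17
        assert np.median(worsts) < 0.04

    def test_scale_equivariance(self, filtered_spec, girl_data_2000):
        """Multiplying one indicator by a constant leaves the standardized
        output unchanged."""
        data, _ = girl_data_2000
        d = data.head(800)
        scaled = d.copy()
        scaled["snacks"] = scaled["snacks"] * 13.7
        a = ob.fit_ml(d, filtered_spec, compute_se=False)
        b = ob.fit_ml(scaled, filtered_spec, compute_se=False)
        for p in filtered_spec.path_labels:
            assert a.structural_estimates[p] == pytest.approx(b.structural_estimates[p], abs=1e-7)

    def test_degrees_of_freedom_contract(self, spec, filtered_spec, girl_data_2000):
        data, _ = girl_data_2000
        fit = ob.fit_ml(data, filtered_spec, compute_se=False)
        p = len(filtered_spec.observed_names)
        assert fit.df == p * (p + 1) // 2 - 50
        assert fit.df > 0
        assert fit.discrepancy >= 0

    def test_non_pd_moment_matrix_rejected(self, filtered_spec):
        S = np.zeros((18, 18))
        with pytest.raises(ValueError, match="positive definite"):
            ob.fit_ml_cov(S, 100, filtered_spec)

    def test_se_magnitude_tracks_sampling_spread(self, filtered_spec):
        """Delta-method SEs match the Monte-Carlo spread of the estimator
        within a factor consistent with 25 replicates."""
        truth = ob.default_true_params("girl", filtered_spec)
        path = "unhealthy_food->bmi"
        ests, ses = [], []
        ss = np.random.SeedSequence(77).spawn(25)
        for s in ss:
            d = ob.generate_group_dataset(
                filtered_spec, truth, 600, np.random.default_rng(s)
            ).group_data("girl")
            f = ob.fit_ml(d, filtered_spec, n_starts=1)
            ests.append(f.structural_estimates[path])
            ses.append(f.structural_se[path])
        mc_sd = np.std(ests, ddof=1)
        assert np.mean(ses) == pytest.approx(mc_sd, rel=0.5)


def _single_indicator_spec():
    return ModelSpec(
        latents=(LatentDef("a", ("x1",)), LatentDef("b", ("x2",))),
        observed_outcomes=("y",),
        controls=(),
        paths=(PathDef("a", "b"), PathDef("a", "y"), PathDef("b", "y")),
    )


class TestPLS:
    def test_single_indicator_degenerates_to_ols(self):
        """With one indicator per latent the composites equal the
        standardized columns and paths equal standardized OLS coefficients."""
        spec = _single_indicator_spec()
        rng = np.random.default_rng(3)
        x1 = rng.standard_normal(500)
        x2 = 0.5 * x1 + rng.standard_normal(500)
        y = 0.3 * x1 - 0.4 * x2 + rng.standard_normal(500)
        data = pd.DataFrame({"x1": x1, "x2": x2, "y": y})
        fit = ob.fit_pls(data, spec)
        z = (data - data.mean()) / data.std(ddof=1)
        np.testing.assert_allclose(fit.factor_scores["a"], z["x1"], atol=1e-10)
        X = np.column_stack([z["x1"], z["x2"]])
        beta = np.linalg.lstsq(X, z["y"], rcond=None)[0]
        assert fit.path_coefficients["a->y"] == pytest.approx(beta[0], abs=1e-8)
        assert fit.path_coefficients["b->y"] == pytest.approx(beta[1], abs=1e-8)

    def test_row_permutation_invariance(self, filtered_spec, girl_data_2000):
        data, _ = girl_data_2000
        d = data.head(600)
        rng = np.random.default_rng(0)
        perm = d.iloc[rng.permutation(len(d))].reset_index(drop=True)
        a = ob.fit_pls(d, filtered_spec)
        b = ob.fit_pls(perm, filtered_spec)
        for p in filtered_spec.path_labels:
            assert a.path_coefficients[p] == pytest.approx(b.path_coefficients[p], abs=1e-9)

    def test_scores_standardized_and_converged(self, filtered_spec, girl_data_2000):
        data, _ = girl_data_2000
        fit = ob.fit_pls(data, filtered_spec)
        assert fit.converged
        means = fit.factor_scores.mean()
        sds = fit.factor_scores.std(ddof=1)
        np.testing.assert_allclose(means, 0.0, atol=1e-10)
        np.testing.assert_allclose(sds, 1.0, atol=1e-10)

    def test_agreement_band_with_ml(self, filtered_spec):
        """PLS composite paths track ML within the attenuation band measured
        in simulation (Mode-A composites shrink the strongest latent paths;
        the band is 0.15 at n=5000)."""
        truth = ob.default_true_params("girl", filtered_spec)
        d = ob.generate_group_dataset(filtered_spec, truth, 5000, seed=19).group_data("girl")
        ml = ob.fit_ml(d, filtered_spec, compute_se=False)
        pls = ob.fit_pls(d, filtered_spec)
        for p in filtered_spec.path_labels:
            assert pls.path_coefficients[p] == pytest.approx(
                ml.structural_estimates[p], abs=0.15
            )


class TestPredictions:
    def test_shape_contract_and_alignment(self, filtered_spec, girl_data_2000):
        data, _ = girl_data_2000
        d = data.head(300)
        fit = ob.fit_ml(d, filtered_spec, compute_se=False)
        pred = ob.predict_outcomes(fit, d, filtered_spec)
        assert pred.shape == (300, 2)
        assert list(pred.columns) == ["bmi", "body_fat"]
        assert list(pred.index) == list(d.index)

    def test_zero_paths_predict_outcome_means(self, filtered_spec, girl_data_2000):
        data, _ = girl_data_2000
        d = data.head(400)
        truth = ob.default_true_params("girl", filtered_spec)
        null = ob.ParameterSet(
            truth.loadings,
            {p: 0.0 for p in filtered_spec.path_labels},
            truth.residual_variances,
        )
        pred = ob.predict_outcomes(null, d, filtered_spec)
        assert pred["bmi"].to_numpy() == pytest.approx(d["bmi"].mean())
        assert pred["body_fat"].to_numpy() == pytest.approx(d["body_fat"].mean())

    def test_noise_free_limit_reproduces_outcomes(self, filtered_spec):
        """With vanishing outcome disturbance the regression-method scores
        reproduce the observed outcomes."""
        truth = ob.default_true_params("girl", filtered_spec)
        rv = dict(truth.residual_variances)
        rv["bmi"] = rv["body_fat"] = 1e-8
        noiseless = ob.ParameterSet(truth.loadings, truth.structural, rv)
        d = ob.generate_group_dataset(filtered_spec, noiseless, 400, seed=13).group_data("girl")
        pred = ob.predict_outcomes(noiseless, d, filtered_spec)
        err = np.abs(pred.to_numpy() - d[["bmi", "body_fat"]].to_numpy())
        assert err.max() < 1e-6

    def test_out_of_spec_columns_rejected(self, filtered_spec, girl_data_2000):
        data, _ = girl_data_2000
        d = data.head(50).copy()
        fit = ob.fit_ml(data.head(300), filtered_spec, compute_se=False)
        d["extra"] = 1.0
        with pytest.raises(ValueError, match="out-of-spec"):
            ob.predict_outcomes(fit, d, filtered_spec)

    def test_bayes_and_ml_predictions_agree(self, filtered_spec, girl_data_2000, fast_mcmc):
        data, _ = girl_data_2000
        d = data.head(1000)
        ml = ob.fit_ml(d, filtered_spec, compute_se=False)
        bayes = ob.fit_bayes(d, filtered_spec, ob.default_prior("girl"), fast_mcmc)
        pa = ob.predict_outcomes(ml, d, filtered_spec).to_numpy()
        pb = ob.predict_outcomes(bayes, d, filtered_spec).to_numpy()
        assert np.max(np.abs(pa - pb)) < 0.1
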