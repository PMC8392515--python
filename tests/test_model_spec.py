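import numpy as np
import pytest

import obesem as ob
from obesem.model_spec import BETA_PATHS, LatentDef, PathDef, ModelSpec


class TestTopology:
    def test_default_model_shape(self, spec):
        assert len(spec.paths) == 15
        assert len(spec.indicator_names) == 17
        assert [len(l.indicators) for l in spec.latents] == [6, 4, 3, 4]
        assert spec.observed_outcomes == ("bmi", "body_fat")
        assert spec.controls == ("parent_bmi", "parent_body_fat")

    def test_structural_graph_is_acyclic(self, spec):
        order = spec.topological_order()
        pos = {n: i for i, n in enumerate(order)}
        for p in spec.paths:
            assert pos[p.source] < pos[p.target]

    def test_coordinate_convention(self, spec):
        obs = spec.observed_names
        assert obs[:6] == spec.latents[0].indicators
        assert obs[-4:] == ("parent_bmi", "parent_body_fat", "bmi", "body_fat")

    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            ModelSpec(
                latents=(LatentDef("a", ("x1",)), LatentDef("b", ("x2",))),
                observed_outcomes=(),
                controls=(),
                paths=(PathDef("a", "b"), PathDef("b", "a")),
            )

    def test_self_loop_and_unknown_endpoint_rejected(self):
        with pytest.raises(ValueError, match="self-loop"):
            PathDef("a", "a")
        with pytest.raises(ValueError, match="not a declared"):
            ModelSpec(
                latents=(LatentDef("a", ("x1",)),),
                observed_outcomes=("y",),
                controls=(),
                paths=(PathDef("a", "nope"),),
            )

    def test_drop_indicators(self, spec):
        smaller = spec.drop_indicators(["age_father", "age_mother", "income_mother"])
        assert len(smaller.indicator_names) == 14
        assert smaller.latents[0].indicators == ("edu_father", "edu_mother", "income_father")
        with pytest.raises(ValueError, match="lose all"):
            spec.drop_indicators(spec.latents[2].indicators)

    def test_yaml_round_trip(self, spec, tmp_path):
        path = tmp_path / "model.yaml"
        spec.to_yaml(path)
        assert ob.ModelSpec.from_yaml(path) == spec

    def test_shipped_default_config_matches_builder(self, spec):
        from obesem.model_spec import default_model_path

        assert ob.ModelSpec.from_yaml(default_model_path()) == spec


class TestPriors:
    def test_regimes_scale_the_eight_hyperpriors(self):
        base = ob.default_prior("girl")
        assert base.path_means["ses->bmi"] == pytest.approx(0.4)
        two = ob.make_prior("II", base)
        three = ob.make_prior("III", base)
        assert two.path_means["ses->bmi"] == pytest.approx(0.2)
        assert three.path_means["ses->bmi"] == pytest.approx(0.8)
        assert ob.make_prior("I", base) == base
        assert len(base.path_means) == 8
        assert set(base.path_means) == set(BETA_PATHS)

    def test_loading_mean_is_half_and_regime_invariant(self):
        base = ob.default_prior("boy")
        assert base.loading_mean == 0.5
        assert ob.make_prior("III", base).loading_mean == 0.5

    def test_unknown_regime_rejected(self):
        with pytest.raises(ValueError, match="regime"):
            ob.make_prior("IV", ob.default_prior("girl"))

    def test_invalid_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            ob.PriorConfig(path_means={}, prior_variance=0.0)
        with pytest.raises(ValueError):
            ob.PriorConfig(path_means={}, variance_prior=(0.0, 1.0))


class TestImpliedCovariance:
    def test_symmetric_and_positive_definite(self, spec, girl_truth):
        sigma = ob.implied_covariance(spec, girl_truth).to_numpy()
        assert np.array_equal(sigma, sigma.T)
        assert np.linalg.eigvalsh(sigma)[0] > 0

    def test_zero_paths_give_block_diagonal(self, spec, girl_truth):
        params = ob.ParameterSet(
            loadings={i: 1.0 for i in spec.indicator_names},
            structural={p: 0.0 for p in spec.path_labels},
            residual_variances={
                **{i: 1.0 for i in spec.indicator_names},
                **{n: 1.0 for n in spec.structural_names},
            },
        )
        sigma = ob.implied_covariance(spec, params)
        # within-construct covariance equals the (unit) latent variance
        assert sigma.loc["edu_father", "edu_mother"] == pytest.approx(1.0)
        # across constructs and with outcomes: exactly zero
        assert sigma.loc["edu_father", "sleep"] == 0.0
        assert sigma.loc["snacks", "bmi"] == 0.0
        assert sigma.loc["bmi", "body_fat"] == 0.0

    def test_invariant_to_path_declaration_order(self, spec, girl_truth):
        shuffled = ModelSpec(
            latents=spec.latents,
            observed_outcomes=spec.observed_outcomes,
            controls=spec.controls,
            paths=tuple(reversed(spec.paths)),
        )
        a = ob.implied_covariance(spec, girl_truth).to_numpy()
        b = ob.implied_covariance(shuffled, girl_truth).to_numpy()
        np.testing.assert_allclose(a, b, atol=0)

    def test_nested_parameter_sets_identical(self, spec, boy_truth):
        """Fixing an absent path at 0 must not change the covariance."""
        base = ModelSpec(
            latents=spec.latents,
            observed_outcomes=spec.observed_outcomes,
            controls=spec.controls,
            paths=tuple(p for p in spec.paths if p.label != "ses->bmi"),
        )
        params_base = ob.ParameterSet(
            boy_truth.loadings,
            {k: v for k, v in boy_truth.structural.items() if k != "ses->bmi"},
            boy_truth.residual_variances,
        )
        params_zero = ob.ParameterSet(
            boy_truth.loadings,
            {**params_base.structural, "ses->bmi": 0.0},
            boy_truth.residual_variances,
        )
        a = ob.implied_covariance(base, params_base).to_numpy()
        b = ob.implied_covariance(spec, params_zero).to_numpy()
        np.testing.assert_allclose(a, b, atol=1e-14)

    def test_negative_residual_variance_rejected(self, spec, girl_truth):
        with pytest.raises(ValueError, match="non-positive"):
            ob.ParameterSet(
                girl_truth.loadings,
                girl_truth.structural,
                {**girl_truth.residual_variances, "bmi": -0.1},
            )

    def test_matches_monte_carlo_covariance(self, spec, girl_truth):
        """Law-of-large-numbers oracle: the sample covariance of 10^6
        generated rows reproduces the implied covariance elementwise."""
        sigma = ob.implied_covariance(spec, girl_truth).to_numpy()
        ds = ob.generate_group_dataset(spec, girl_truth, 1_000_000, seed=4)
        emp = np.cov(ds.group_data("girl").to_numpy(), rowvar=False)
        assert np.max(np.abs(emp - sigma)) < 0.02

    def test_latent_covariances_spd(self, spec, girl_truth):
        phi = girl_truth.latent_covariances(spec)
        assert phi.shape == (4, 4)
        assert np.linalg.eigvalsh(phi)[0] > 0
        np.testing.assert_allclose(np.diag(phi), 1.0, atol=1e-12)
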