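import numpy as np
import pytest

import obesem as ob

#: indicators the published reliability table eliminates (loading < 0.7)
WEAK_SES_INDICATORS = ("age_father", "age_mother", "income_mother")


@pytest.fixture(scope="session")
def spec() -> ob.ModelSpec:
    return ob.build_obesity_model()


@pytest.fixture(scope="session")
def filtered_spec(spec) -> ob.ModelSpec:
    """Topology after the reliability filter, as used for structural fits."""
    return spec.drop_indicators(WEAK_SES_INDICATORS)


@pytest.fixture(scope="session")
def girl_truth(spec) -> ob.ParameterSet:
    return ob.default_true_params("girl", spec)


@pytest.fixture(scope="session")
def boy_truth(spec) -> ob.ParameterSet:
    return ob.default_true_params("boy", spec)


@pytest.fixture(scope="session")
def girl_data_2000(filtered_spec):
    """One seeded n=2000 draw from the girl truth on the filtered topology."""
    truth = ob.default_true_params("girl", filtered_spec)
    ds = ob.generate_group_dataset(filtered_spec, truth, 2000, seed=101)
    return ds.group_data("girl"), truth


@pytest.fixture(scope="session")
def fast_mcmc() -> ob.McmcConfig:
    return ob.McmcConfig(n_iterations=1000, burn_in=400, n_chains=1, seed=0)
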