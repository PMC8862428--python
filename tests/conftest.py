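import pytest

import actikin as ak


@pytest.fixture(scope="session")
def detergent_params():
    return ak.REFERENCE_PARAMS["detergent"]


@pytest.fixture(scope="session")
def nanodisc_params():
    return ak.REFERENCE_PARAMS["nanodiscs"]


@pytest.fixture(scope="session")
def proteoliposome_params():
    return ak.REFERENCE_PARAMS["proteoliposomes"]


@pytest.fixture(scope="session")
def noise_free():
    return ak.NoiseSpec(cv=0.0, additive_floor=0.0)


@pytest.fixture(scope="session")
def noise_free_detergent_obs(detergent_params, noise_free):
    """Noise-free synthetic dataset on the standard detergent design."""
    return ak.simulate_dataset(
        detergent_params,
        ak.standard_context("detergent"),
        ak.standard_design("detergent"),
        noise_free,
        seed=0,
    )
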