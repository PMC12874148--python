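import numpy as np
import pytest

from racpol import load_preset


@pytest.fixture(scope="session")
def wp():
    return load_preset("wp")


@pytest.fixture(scope="session")
def wpi():
    return load_preset("wpi")


@pytest.fixture(scope="session")
def wpi_pip3():
    return load_preset("wpi_pip3")


@pytest.fixture(scope="session")
def wp_spatial():
    return load_preset("wp_spatial")


@pytest.fixture(scope="session")
def wpi_double_pulse_traces():
    """Small noiseless homogeneous WPI population under the 120 s
    double-pulse; shared across fitting tests."""
    from racpol import PopulationSpec, generate_population

    spec = PopulationSpec(n_cells=3, base_params=load_preset("wpi"),
                          heterogeneity_cv=0.0, noise_sd=0.0, seed=11)
    return generate_population(spec, protocol="double_pulse_120")
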