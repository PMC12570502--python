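import numpy as np
import pytest

from rnapkin import ElongationComplex, ExperimentDesign, NoiseModel, extend_with_subset, tk_scaffold
from rnapkin.tables import chain_params, scheme1_params


@pytest.fixture(scope="session")
def scaffold():
    return tk_scaffold()


@pytest.fixture(scope="session")
def ec10(scaffold):
    """The 10-mer elongation complex: primer + the single radiolabeled CMP."""
    return extend_with_subset(ElongationComplex.assemble(scaffold), {"CTP"})


@pytest.fixture(scope="session")
def table1_params():
    return scheme1_params()


@pytest.fixture(scope="session")
def chain_params_65c_1000():
    return chain_params(1000.0, temperature="65C")


@pytest.fixture(scope="session")
def chain_params_25c_1000():
    return chain_params(1000.0, temperature="25C")


@pytest.fixture
def small_design():
    """A light sampling design for fast unit tests (not the study design)."""
    return ExperimentDesign(
        time_grid=np.geomspace(5e-3, 10.0, 15),
        concentrations_uM=(10.0, 250.0),
        replicates=3,
    )


@pytest.fixture
def quiet_noise():
    return NoiseModel(fraction_sd=0.0, amplitude_range=(1.0, 1.0), seed=0)
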