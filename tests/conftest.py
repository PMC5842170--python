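import numpy as np
import pytest

from sewerch4.datasets import METHANE_RATES, STUDY_SHEAR_STRESSES, archaea_table
from sewerch4.simulate import ExperimentConfig, NoiseConfig, gen_experiment


@pytest.fixture(scope="session")
def printed_rates():
    """The seven published (shear stress, daily methane rate) pairs."""
    return np.array(STUDY_SHEAR_STRESSES), np.array(METHANE_RATES)


@pytest.fixture(scope="session")
def archaea_ref():
    return archaea_table()


@pytest.fixture(scope="session")
def zero_noise_config():
    return ExperimentConfig(noise=NoiseConfig.zero())


@pytest.fixture(scope="session")
def experiment_dir(tmp_path_factory):
    """One default noisy experiment bundle (seed 1) on disk."""
    out = tmp_path_factory.mktemp("bundle") / "exp"
    gen_experiment(ExperimentConfig(seed=1), out)
    return out
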