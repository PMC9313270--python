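import numpy as np
import pytest

from peakfluo import ampsim, triplicate_panel


@pytest.fixture(scope="session")
def noise_free_cfg() -> ampsim.SimConfig:
    return ampsim.SimConfig(noise_sd_well=0.0, noise_sd_process=0.0)


@pytest.fixture(scope="session")
def default_cfg() -> ampsim.SimConfig:
    return ampsim.SimConfig()


@pytest.fixture(scope="session")
def tuned_noise_free_cfg() -> ampsim.SimConfig:
    return ampsim.quantification_tuned_config(noise_sd_well=0.0, noise_sd_process=0.0)


@pytest.fixture(scope="session")
def panel():
    """0 / 0.1 / 1 / 10 ng/mL in triplicate plus unknowns at 0.3 and 3."""
    return triplicate_panel(unknowns=(0.3, 3.0))


@pytest.fixture(scope="session")
def standards_panel():
    return triplicate_panel()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
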