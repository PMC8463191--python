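import numpy as np
import pytest

import thalcor


@pytest.fixture(scope="session")
def default_params() -> thalcor.ModelParameters:
    return thalcor.ModelParameters()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def short_config() -> thalcor.SimulationConfig:
    """A 16 s run leaving a 6 s analysis window — enough for 0.2 Hz
    spectral resolution while keeping unit tests fast."""
    return thalcor.SimulationConfig(duration=16.0, transient=10.0,
                                    n_repeats=1, seed=11)
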