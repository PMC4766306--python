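import numpy as np
import pytest

from cypscreen.synthetic import ScreenScenario, generate_screen_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """The full five-assembly scenario with the planted orthogroup."""
    return generate_screen_dataset(ScreenScenario(seed=1))


@pytest.fixture(scope="session")
def small_scenario():
    return ScreenScenario(
        n_assemblies=3,
        n_p450_decoys=10,
        n_background=8,
        n_correlated_non_p450=1,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_scenario):
    """A three-assembly scenario kept small for fast per-stage tests."""
    return generate_screen_dataset(small_scenario)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
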