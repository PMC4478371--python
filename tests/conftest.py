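import numpy as np
import pytest

from ceamodel import bundled_scenario_path, load_scenario, make_melanoma_like_scenario


@pytest.fixture(scope="session")
def fixture_scenario():
    """The packaged base-case scenario (economics + illustrative curves)."""
    return load_scenario(bundled_scenario_path())


@pytest.fixture(scope="session")
def melanoma_scenario():
    return make_melanoma_like_scenario(seed=123)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
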