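import numpy as np
import pytest

from melanosub.sensitivities import standard_sensitivities
from melanosub.stimulus import (
    build_synthetic_primaries,
    generate_candidates,
    solve_metamer_pair,
)


@pytest.fixture(scope="session")
def sens():
    return standard_sensitivities()


@pytest.fixture(scope="session")
def primaries():
    """The default synthetic two-projector rig (published chromaticities)."""
    return build_synthetic_primaries(seed=0)


@pytest.fixture(scope="session")
def metamer_pair(primaries):
    return solve_metamer_pair(primaries)


@pytest.fixture(scope="session")
def candidate_set(primaries):
    return generate_candidates(primaries, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
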