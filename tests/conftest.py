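import numpy as np
import pytest

from puckerpath.synthetic import (
    build_surrogate_pmf_1d,
    build_surrogate_pucker_landscape,
    build_surrogate_reaction_landscape,
)


@pytest.fixture(scope="session")
def reaction_landscape():
    return build_surrogate_reaction_landscape()


@pytest.fixture(scope="session")
def pucker_landscape():
    return build_surrogate_pucker_landscape()


@pytest.fixture(scope="session")
def pmf1d():
    return build_surrogate_pmf_1d(17.7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
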