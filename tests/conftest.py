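import numpy as np
import pytest

from ardra import FixtureSpec, make_aefb_like, make_cohort


@pytest.fixture(scope="session")
def default_fixture():
    """The standard synthetic full-length 16S-like sequence plus truth."""
    return make_aefb_like(FixtureSpec(seed=0))


@pytest.fixture(scope="session")
def cohort():
    """Standard cohort: 10 marker-bearing targets, 10 outgroup, divergence 5."""
    return make_cohort(FixtureSpec(seed=7), n_target=10, n_outgroup=10, divergence=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_dna(rng, n, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=n))
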