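import numpy as np
import pytest

from glucangel.builder import build_hydrogel, standard_composition
from glucangel.synthetic import gen_crossing_fixture, gen_toy_hydrogel


@pytest.fixture(scope="session")
def full_hydrogel_100_0():
    """Full-scale pure-cellulose sample: 12 fibers + 96 single chains."""
    return build_hydrogel(standard_composition("100:0", seed=7))


@pytest.fixture(scope="session")
def toy_hydrogel():
    """Quarter-scale 100:0 sample with a 3-frame pseudo-dynamics trajectory."""
    built, frames, report = gen_toy_hydrogel(scale=0.25, seed=11, n_frames=3)
    return built, frames, report


@pytest.fixture(scope="session")
def crossing_fixture():
    """Five chains planted to cross one nanofiber at 3.0 A."""
    return gen_crossing_fixture(n_chains=5, n_fibers=1, seed=4)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
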