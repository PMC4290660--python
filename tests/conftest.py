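import numpy as np
import pytest

from decoyrank import synthgen
from decoyrank.synthgen import NoiseSchedule, ToySpec


@pytest.fixture(scope="session")
def helix12():
    return synthgen.make_toy(ToySpec(topology="helix", n_residues=12))


@pytest.fixture(scope="session")
def helix20():
    return synthgen.make_toy(ToySpec(topology="helix", n_residues=20))


@pytest.fixture(scope="session")
def hairpin16():
    return synthgen.make_toy(ToySpec(topology="hairpin", n_residues=16))


@pytest.fixture(scope="session")
def hlh60():
    return synthgen.make_toy(ToySpec(topology="helix-loop-helix", n_residues=60))


@pytest.fixture(scope="session")
def small_pool(hlh60):
    """40-decoy pool over a sigma ladder, with ground-truth provenance."""
    return synthgen.perturb(
        hlh60, NoiseSchedule(sigmas=(0.5, 1.0, 2.0, 4.0), decoys_per_sigma=10, seed=11)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
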