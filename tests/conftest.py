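import numpy as np
import pytest

from helixmech.curation import UNIQUE_DIMERS
from helixmech.potentials import HarmonicStepPotential, PotentialSet


def make_uniform_set(
    mean=(0.0, 0.0, 36.0, 0.0, 0.0, 3.4),
    sds=(4.0, 4.0, 4.0, 0.4, 0.5, 0.3),
) -> PotentialSet:
    """Homogeneous isotropic dimer set: every class shares one diagonal
    potential, so reflections are identities and closed-form elastic-rod
    results apply."""
    mean = np.asarray(mean, dtype=float)
    cov = np.diag(np.square(sds))
    pots = {d: HarmonicStepPotential(d, mean.copy(), cov.copy()) for d in UNIQUE_DIMERS}
    return PotentialSet("dimer", pots)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20220759)


@pytest.fixture(scope="session")
def uniform_set():
    return make_uniform_set()


@pytest.fixture(scope="session")
def bdna_dimer_set():
    from helixmech.synth import bdna_potential_set

    return bdna_potential_set("dimer")


@pytest.fixture(scope="session")
def bdna_tetramer_set():
    from helixmech.synth import bdna_potential_set

    return bdna_potential_set("tetramer")


@pytest.fixture(scope="session")
def small_ensemble():
    """Sampled dimer-level ensemble, 400 draws per class, 5% contamination."""
    from helixmech.synth import default_spec, sample_ensemble

    return sample_ensemble(default_spec("dimer", n_per_class=400, seed=11))


def random_spd(rng, dim=6, scale=1.0):
    A = rng.normal(size=(dim, dim))
    return scale * (A @ A.T + dim * np.eye(dim))
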