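import numpy as np
import pytest

from coopscape.synth import SyntheticDesign
from coopscape.theory import ResourceDistribution, TraitModel


@pytest.fixture(scope="session")
def design():
    """Default study design (three media, 12 replicates, calibrated noise)."""
    return SyntheticDesign()


@pytest.fixture(scope="session")
def design_noiseless():
    return SyntheticDesign(sigma_density=0.0, sigma_absorbance=0.0)


@pytest.fixture()
def two_point():
    """The paired-microcosm distribution: R in {0.5, 1.5} equally likely."""
    return ResourceDistribution.two_point(0.5, 1.5)


@pytest.fixture()
def linear_model():
    return TraitModel(r=1.0, a=1.0)


def random_atom_distribution(rng, n_atoms=None, mean=None):
    """Random atomic resource distribution, optionally recentred on a mean."""
    k = int(n_atoms or rng.integers(2, 6))
    rs = rng.uniform(0.2, 3.0, size=k)
    ws = rng.dirichlet(np.ones(k))
    if mean is not None:
        rs = rs * (mean / float(np.dot(rs, ws)))
    return ResourceDistribution.from_atoms(zip(rs, ws))
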