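import numpy as np
import pytest

from lagnet import GeneNetworkModel
from lagnet.io import ExpressionProfile
from lagnet.pairwise import PairStats, associativity_measure
from lagnet.simulate import generate, random_planted_network


def make_profile(n_genes=6, n_points=14, seed=0, dt=0.5):
    """Small random periodic-ish profile for metric-level tests."""
    rng = np.random.default_rng(seed)
    t = np.arange(n_points)
    values = np.vstack(
        [
            np.sin(2 * np.pi * t / rng.uniform(6, 13) + rng.uniform(0, 2 * np.pi))
            + rng.normal(0, 0.3, n_points)
            for _ in range(n_genes)
        ]
    )
    genes = tuple(f"G{i:02d}" for i in range(n_genes))
    return ExpressionProfile(genes, np.arange(n_points) * dt, values)


def random_pair_stats(n_genes, rng, weights=(1.0, 1.0)):
    """A synthetic PairStats collection with uniform random metrics."""
    from itertools import combinations

    genes = [f"g{i:03d}" for i in range(n_genes)]
    out = []
    for a, b in combinations(genes, 2):
        mi = float(rng.uniform(0, 2))
        r = float(rng.uniform(-1, 1))
        p = float(rng.uniform(0, 1))
        am, alpha = associativity_measure(mi, r, *weights)
        out.append(PairStats(a, b, mi, r, p, am, alpha))
    return out


@pytest.fixture
def profile6():
    return make_profile()


@pytest.fixture(scope="session")
def frozen_regime():
    """The default synthetic study regime with its ground truth."""
    planted = random_planted_network()
    profile, truth = generate(planted)
    return planted, profile, truth


@pytest.fixture(scope="session")
def frozen_fit(frozen_regime):
    """Full pipeline fit on the frozen regime, shared across tests."""
    _, profile, _ = frozen_regime
    return GeneNetworkModel(profile).fit()
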