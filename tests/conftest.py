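import numpy as np
import pytest

from cgindiv.core import ParticleState, PopulationState, TraitSpec
from cgindiv.synthdata import (
    FixtureConfig,
    cluster_partition,
    make_aligned_population,
    make_quartet_population,
    make_scrambled_population,
)

DIRECTION = TraitSpec("direction", "angular_degrees", "degrees")


def simple_population(directions, positions=None, t=0):
    """Hand-built population with one angular 'direction' trait."""
    if positions is None:
        positions = [(float(i), 0.0) for i in range(len(directions))]
    particles = [
        ParticleState(id=i, position=np.asarray(p, dtype=float),
                      traits={"direction": float(d)})
        for i, (p, d) in enumerate(zip(positions, directions))
    ]
    return PopulationState(t=t, particles=particles, trait_specs=[DIRECTION])


@pytest.fixture
def fixture_config():
    return FixtureConfig(seed=1)


@pytest.fixture
def aligned_pop(fixture_config):
    return make_aligned_population(fixture_config)


@pytest.fixture
def scrambled_pop(fixture_config):
    return make_scrambled_population(fixture_config)


@pytest.fixture
def clusters_partition(fixture_config):
    return cluster_partition(fixture_config)


@pytest.fixture
def quartet_scenario():
    return make_quartet_population(3, seed=1)
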