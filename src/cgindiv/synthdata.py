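"""Seeded generators for all toy populations and environments used in tests.

Every generator is a pure function of its configuration and seed; identical
seeds give bit-identical outputs.  The flagship fixture is a population of
12 cells in 4 well-separated spatial clusters of 3, in two paired variants
sharing the same geometry under a common seed:

* **aligned** — within each cluster, member headings lie within +/- 20
  degrees of a cluster mean; the designated cluster carries exactly
  240, 220 and 200 degrees (mean 220, maximal deviation 20).
* **scrambled** — same positions, headings uniform on [0, 360); the
  designated cluster carries exactly 350, 240 and 80 degrees (arithmetic
  mean ~223, maximal deviation from it 143).

The paired design isolates the effect of heading coherence on the
coarse-graining prediction error: the aligned variant compresses well, the
scrambled one does not.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .coarse_grain import Partition
from .core import (
    Environment,
    LightSource,
    ParticleState,
    PopulationState,
    ResourcePatch,
    TraitSpec,
)
from .errors import ValidationError

#: Printed heading triplet of the designated (coherent) cluster.
ALIGNED_TRIPLET = (240.0, 220.0, 200.0)
#: Printed heading triplet of the designated cluster, scrambled variant.
SCRAMBLED_TRIPLET = (350.0, 240.0, 80.0)

#: Maximal within-cluster deviation from the cluster mean, aligned mode.
ALIGNED_SPREAD_DEG = 20.0

DIRECTION = TraitSpec("direction", "angular_degrees", "degrees")


@dataclass(frozen=True)
class FixtureConfig:
    """Configuration of the clustered-population generators.

    ``separation`` is the centre-to-centre distance between clusters; it
    defaults to 5x ``cluster_spread`` so clusters are unambiguous to a
    proximity graph.  The seed is mandatory.
    """

    seed: int
    n_clusters: int = 4
    cluster_size: int = 3
    cluster_spread: float = 2.0
    separation: Optional[float] = None
    speed: float = 1.0
    direction_mode: str = "aligned"  # {"aligned", "scrambled"}

    def __post_init__(self) -> None:
        if self.n_clusters < 1 or self.cluster_size < 1:
            raise ValidationError("cluster counts must be positive")
        if self.cluster_spread <= 0:
            raise ValidationError("cluster_spread must be > 0")
        if self.separation is not None and self.separation < 5 * self.cluster_spread:
            raise ValidationError(
                "separation must be >= 5x cluster_spread to keep clusters distinct"
            )
        if self.direction_mode not in ("aligned", "scrambled"):
            raise ValidationError(
                f"direction_mode must be 'aligned' or 'scrambled', got "
                f"{self.direction_mode!r}"
            )
        if self.speed <= 0:
            raise ValidationError("speed must be > 0")

    @property
    def sep(self) -> float:
        return (
            self.separation
            if self.separation is not None
            else 5.0 * self.cluster_spread
        )


def _cluster_geometry(config: FixtureConfig) -> np.ndarray:
    """Positions (n_clusters*cluster_size, 2), a pure function of the seed.

    Cluster centres sit on a row-major grid with ``sep`` spacing; members
    are scattered uniformly in a disc of radius ``cluster_spread / 2``
    around their centre, so intra-cluster distances never exceed
    ``cluster_spread`` while inter-cluster distances stay >= 4x that.
    """
    geom_rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[0])
    cols = int(np.ceil(np.sqrt(config.n_clusters)))
    positions = []
    for c in range(config.n_clusters):
        center = np.array([(c % cols) * config.sep, (c // cols) * config.sep])
        for _ in range(config.cluster_size):
            r = (config.cluster_spread / 2.0) * np.sqrt(geom_rng.uniform())
            phi = geom_rng.uniform(0, 2 * np.pi)
            positions.append(center + r * np.array([np.cos(phi), np.sin(phi)]))
    return np.array(positions)


def _direction_rng(config: FixtureConfig) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])


def _build(config: FixtureConfig, directions: np.ndarray) -> PopulationState:
    positions = _cluster_geometry(config)
    particles = [
        ParticleState(
            id=i,
            position=positions[i],
            traits={"direction": float(directions[i])},
        )
        for i in range(len(positions))
    ]
    return PopulationState(t=0, particles=particles, trait_specs=[DIRECTION])


def make_aligned_population(config: FixtureConfig) -> PopulationState:
    """Clustered population with coherent within-cluster headings.

    Cluster 0 (the designated cluster) carries exactly the
    :data:`ALIGNED_TRIPLET` headings when it has 3 members; other clusters
    draw a uniform mean heading and scatter members within +/- 20 degrees
    of it.
    """
    rng = _direction_rng(config)
    n = config.n_clusters * config.cluster_size
    directions = np.empty(n)
    for c in range(config.n_clusters):
        lo = c * config.cluster_size
        if c == 0 and config.cluster_size == len(ALIGNED_TRIPLET):
            directions[lo : lo + config.cluster_size] = ALIGNED_TRIPLET
            continue
        # keep the cluster mean away from the 0/360 cut so the coherent
        # headings never wrap (plain-degree aggregation stays meaningful)
        mean = rng.uniform(ALIGNED_SPREAD_DEG, 360.0 - ALIGNED_SPREAD_DEG)
        directions[lo : lo + config.cluster_size] = mean + rng.uniform(
            -ALIGNED_SPREAD_DEG, ALIGNED_SPREAD_DEG, config.cluster_size
        )
    return _build(config, directions)


def make_scrambled_population(config: FixtureConfig) -> PopulationState:
    """Paired variant of :func:`make_aligned_population`: identical geometry
    under the same seed, but incoherent headings.

    Cluster 0 carries exactly the :data:`SCRAMBLED_TRIPLET`; all other
    headings are uniform on [0, 360).
    """
    rng = _direction_rng(config)
    n = config.n_clusters * config.cluster_size
    directions = rng.uniform(0.0, 360.0, n)
    if config.cluster_size == len(SCRAMBLED_TRIPLET):
        directions[: config.cluster_size] = SCRAMBLED_TRIPLET
    return _build(config, directions)


def make_clustered_population(config: FixtureConfig) -> PopulationState:
    """Dispatch on ``config.direction_mode``."""
    if config.direction_mode == "aligned":
        return make_aligned_population(config)
    return make_scrambled_population(config)


def cluster_partition(config: FixtureConfig) -> Partition:
    """The intended coarse-graining of the clustered fixtures: one block per
    spatial cluster."""
    return Partition(
        {
            c * config.cluster_size + i: c
            for c in range(config.n_clusters)
            for i in range(config.cluster_size)
        }
    )


# ---------------------------------------------------------------------------
# Environments


def make_corner_resources(
    extent: float, amount: float = 1.0, diffusion: float = 25.0
) -> Environment:
    """Four equal resource patches at the corners of the square [0, extent]^2."""
    if extent <= 0:
        raise ValidationError("extent must be > 0")
    corners = [(0.0, 0.0), (0.0, extent), (extent, 0.0), (extent, extent)]
    return Environment(
        resource_patches=tuple(
            ResourcePatch(c, amount, diffusion) for c in corners
        ),
        state_label="corner_resources",
    )


def make_central_light(extent: float, intensity: float = 1.0, decay: float = 25.0) -> Environment:
    """One light source at the centre of the square [0, extent]^2."""
    if extent <= 0:
        raise ValidationError("extent must be > 0")
    return Environment(
        light_sources=(LightSource((extent / 2.0, extent / 2.0), intensity, decay),),
        state_label="central_light",
    )


# ---------------------------------------------------------------------------
# Interaction-threshold scenario


def make_quartet_population(
    n_quartets: int, seed: int, radius: float = 1.0
) -> tuple[PopulationState, Partition, Partition]:
    """Quartets of mutually interacting particles, plus two rival partitions.

    Each quartet sits at the corners of a small square so all four members
    are pairwise within *radius* (every member has exactly 3 partners);
    quartets are separated by 10x the radius.  Returns the population, the
    matched quartet partition and the deliberately mismatched pair partition
    (consecutive pairs within each quartet).
    """
    if n_quartets < 1:
        raise ValidationError("n_quartets must be >= 1")
    rng = np.random.default_rng(seed)
    side = radius / 2.0  # square diagonal = radius / sqrt(2) < radius
    offsets = np.array(
        [[0.0, 0.0], [side, 0.0], [0.0, side], [side, side]]
    )
    particles = []
    quartet_assignment = {}
    pair_assignment = {}
    for q in range(n_quartets):
        center = np.array([10.0 * radius * q, 0.0])
        for j in range(4):
            pid = 4 * q + j
            particles.append(
                ParticleState(
                    id=pid,
                    position=center + offsets[j],
                    traits={"direction": float(rng.uniform(0, 360))},
                )
            )
            quartet_assignment[pid] = q
            pair_assignment[pid] = 2 * q + (j // 2)
    pop = PopulationState(t=0, particles=particles, trait_specs=[DIRECTION])
    return pop, Partition(quartet_assignment), Partition(pair_assignment)
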