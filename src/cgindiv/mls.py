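"""Birth-death population process with two-level fitness accounting.

Generations are discrete, synchronous and non-overlapping at both levels: in
one generation step every particle with at least ``min_partners``
interaction partners within ``interaction_radius`` produces
``offspring_count`` offspring at its own position (traits inherited), and
every parent dies.  Because generations are synchronous, each offspring
particle belongs to exactly one offspring collective, and each offspring
collective traces back to exactly one parent collective — the mapping rule
that makes collective-level bookkeeping well defined.  Asynchronous life
cycles break that mapping and are rejected.

Two collective fitness measures are computed from the same events:

* **MLS1** — particles produced, aggregated (mean or sum) over the members
  of a collective; tied to particle fitness by construction.
* **MLS2** — offspring *collectives* produced; depends on how offspring are
  grouped, not on how many there are, so collectives with equal MLS1
  fitness can differ in MLS2 fitness and vice versa.

Offspring grouping convention: the offspring of one parent block, taken in
parent-id order, are chunked into ``ceil(n_offspring / block_size)``
offspring collectives.  The convention is deterministic and replaceable via
``offspring_grouper``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np

from .coarse_grain import Partition
from .core import ParticleState, PopulationState
from .errors import ConfigurationError, DomainError, MappingRuleError

PartnerScope = str  # {"block", "global"}


@dataclass(frozen=True)
class ReproductionRule:
    """Threshold reproduction: interact with enough neighbours or leave none.

    Parameters
    ----------
    interaction_radius : float
        Two particles interact when their distance is <= this radius.
    min_partners : int
        Minimum number of interaction partners required to reproduce.
    offspring_count : int
        Offspring per reproducing particle.
    partner_scope : {"block", "global"}
        Count partners within the particle's own block only (default) or
        across the whole population.
    jitter : float
        Std-dev of isotropic Gaussian placement noise for offspring; 0
        (default) places offspring exactly at the parent position.  A seeded
        generator is mandatory when jitter > 0.
    generations : str
        Only "synchronous" is supported.
    """

    interaction_radius: float
    min_partners: int = 3
    offspring_count: int = 1
    partner_scope: PartnerScope = "block"
    jitter: float = 0.0
    generations: str = "synchronous"

    def __post_init__(self) -> None:
        if self.interaction_radius <= 0:
            raise ConfigurationError("interaction_radius must be > 0")
        if self.min_partners < 0 or self.offspring_count < 0:
            raise ConfigurationError("counts must be non-negative")
        if self.partner_scope not in ("block", "global"):
            raise ConfigurationError(
                f"partner_scope must be 'block' or 'global', got "
                f"{self.partner_scope!r}"
            )
        if self.jitter < 0:
            raise ConfigurationError("jitter must be >= 0")
        if self.generations != "synchronous":
            raise MappingRuleError(
                "asynchronous particle/collective generations break the "
                "offspring mapping rule and are not supported"
            )


@dataclass
class FitnessRecord:
    """Fitness bookkeeping for one generation step."""

    particle_fitness: dict[int, int]
    mls1_fitness: dict[int, float]
    mls2_fitness: dict[int, int]


def _partner_counts(
    pop: PopulationState, part: Partition, rule: ReproductionRule
) -> dict[int, int]:
    alive = pop.alive_particles()
    counts = {p.id: 0 for p in alive}
    for i, a in enumerate(alive):
        for b in alive[i + 1 :]:
            if (
                rule.partner_scope == "block"
                and part.block_of(a.id) != part.block_of(b.id)
            ):
                continue
            if np.linalg.norm(a.position - b.position) <= rule.interaction_radius:
                counts[a.id] += 1
                counts[b.id] += 1
    return counts


def step_generation(
    pop: PopulationState,
    part: Partition,
    rule: ReproductionRule,
    rng: Optional[np.random.Generator] = None,
) -> tuple[PopulationState, dict[int, list[int]]]:
    """One synchronous generation: reproduce-or-perish, parents replaced.

    Returns the offspring population (time index advanced by one) and the
    parentage map ``parent_id -> [offspring ids]`` covering every alive
    parent (empty list for non-reproducers).
    """
    part.validate_covers(pop)
    if rule.jitter > 0 and rng is None:
        raise ConfigurationError(
            "offspring placement jitter requires a seeded random generator"
        )
    counts = _partner_counts(pop, part, rule)
    alive = sorted(pop.alive_particles(), key=lambda p: p.id)
    next_id = max((p.id for p in pop.particles), default=-1) + 1
    offspring: list[ParticleState] = []
    parentage: dict[int, list[int]] = {p.id: [] for p in alive}
    for parent in alive:
        if counts[parent.id] < rule.min_partners:
            continue
        for _ in range(rule.offspring_count):
            position = parent.position.copy()
            if rule.jitter > 0:
                position = position + rng.normal(0.0, rule.jitter, size=2)
            offspring.append(
                ParticleState(
                    id=next_id,
                    position=position,
                    traits=dict(parent.traits),
                    alive=True,
                    parent_id=parent.id,
                )
            )
            parentage[parent.id].append(next_id)
            next_id += 1
    new_pop = PopulationState(
        t=pop.t + 1, particles=offspring, trait_specs=list(pop.trait_specs)
    )
    return new_pop, parentage


def particle_fitness(parentage: Mapping[int, Sequence[int]]) -> dict[int, int]:
    """Offspring particle count per parent."""
    return {pid: len(kids) for pid, kids in parentage.items()}


def mls1_fitness(
    part: Partition,
    fitnesses: Mapping[int, int],
    mapping: str = "mean",
) -> dict[int, float]:
    """Aggregate particle fitness per collective (particles-produced measure)."""
    if mapping not in ("mean", "sum"):
        raise DomainError(f"mapping must be 'mean' or 'sum', got {mapping!r}")
    out: dict[int, float] = {}
    for cid, members in part.blocks().items():
        missing = [m for m in members if m not in fitnesses]
        if missing:
            raise DomainError(
                f"no fitness recorded for member(s) {missing} of collective {cid}"
            )
        vals = [fitnesses[m] for m in members]
        out[cid] = float(np.mean(vals)) if mapping == "mean" else float(np.sum(vals))
    return out


def group_offspring_by_parent_block(
    part_parent: Partition, parentage: Mapping[int, Sequence[int]]
) -> Partition:
    """Default offspring-collective formation.

    The offspring of each parent block, in parent-id order, are chunked into
    ``ceil(n_offspring / block_size)`` groups of at most ``block_size``.
    Offspring collective ids are assigned sequentially from 0 in parent
    collective-id order.
    """
    assignment: dict[int, int] = {}
    next_cid = 0
    for cid, members in sorted(part_parent.blocks().items()):
        kids = [k for m in members for k in parentage.get(m, [])]
        if not kids:
            continue
        size = len(members)
        n_groups = math.ceil(len(kids) / size)
        for g in range(n_groups):
            for k in kids[g * size : (g + 1) * size]:
                assignment[k] = next_cid
            next_cid += 1
    return Partition(assignment)


OffspringGrouper = Callable[[Partition, Mapping[int, Sequence[int]]], Partition]


def mls2_fitness(
    part_parent: Partition,
    part_offspring: Partition,
    parentage: Mapping[int, Sequence[int]],
) -> dict[int, int]:
    """Offspring collectives produced per parent collective.

    Every offspring collective must trace (through its members' parents) to
    exactly one parent collective; otherwise the synchronous mapping rule is
    violated and :class:`~cgindiv.errors.MappingRuleError` is raised.  The
    result is independent of offspring particle counts: only the grouping
    matters.
    """
    child_to_parent = {
        k: pid for pid, kids in parentage.items() for k in kids
    }
    out = {cid: 0 for cid in part_parent.blocks()}
    for off_cid, members in sorted(part_offspring.blocks().items()):
        parent_cids = set()
        for m in members:
            if m not in child_to_parent:
                raise MappingRuleError(
                    f"offspring {m} has no recorded parent"
                )
            parent_cids.add(part_parent.block_of(child_to_parent[m]))
        if len(parent_cids) != 1:
            raise MappingRuleError(
                f"offspring collective {off_cid} traces to parent "
                f"collectives {sorted(parent_cids)}; the synchronous mapping "
                "rule requires exactly one"
            )
        out[parent_cids.pop()] += 1
    return out


def record_generation(
    pop: PopulationState,
    part: Partition,
    rule: ReproductionRule,
    mls1_mapping: str = "mean",
    rng: Optional[np.random.Generator] = None,
    grouper: OffspringGrouper = group_offspring_by_parent_block,
) -> tuple[PopulationState, Partition, FitnessRecord]:
    """One generation with full two-level fitness bookkeeping."""
    new_pop, parentage = step_generation(pop, part, rule, rng=rng)
    fitness = particle_fitness(parentage)
    part_offspring = grouper(part, parentage)
    record = FitnessRecord(
        particle_fitness=fitness,
        mls1_fitness=mls1_fitness(part, fitness, mls1_mapping),
        mls2_fitness=mls2_fitness(part, part_offspring, parentage),
    )
    return new_pop, part_offspring, record


# ---------------------------------------------------------------------------
# Partition quality for predicting collective reproduction


@dataclass
class ReproductionDelta:
    """Prediction error of collective-level reproduction for one partition."""

    partition: Partition
    delta: float
    per_generation: list[dict[int, tuple[int, int]]] = field(default_factory=list)


def coarse_graining_reproduction_delta(
    pop: PopulationState,
    rule: ReproductionRule,
    candidates: Sequence[Partition],
    steps: int = 1,
    grouper: OffspringGrouper = group_offspring_by_parent_block,
) -> list[ReproductionDelta]:
    """How well each candidate partition predicts collective reproduction.

    The truthful pathway simulates the particle-level process under the
    physical interaction structure (partners counted globally within the
    radius), then coarse-grains the offspring and counts offspring
    collectives per parent collective (MLS2).  The projected pathway uses
    only the collective-level summary: a collective is predicted to produce
    ``offspring_count`` offspring collectives iff its member count exceeds
    ``min_partners``, else none.  The per-partition delta is the maximal
    absolute difference between the two counts, over collectives and over
    the *steps* simulated generations.

    A partition whose blocks mirror the interaction neighbourhoods predicts
    reproduction exactly (delta 0); a partition that cuts across them sees
    some collectives reproduce and others not, for no reason visible at the
    collective level (delta > 0).
    """
    if not candidates:
        raise DomainError("need at least one candidate partition")
    truthful_rule = ReproductionRule(
        interaction_radius=rule.interaction_radius,
        min_partners=rule.min_partners,
        offspring_count=rule.offspring_count,
        partner_scope="global",
        jitter=rule.jitter,
    )
    results = []
    for candidate in candidates:
        current = pop
        part = candidate
        per_gen: list[dict[int, tuple[int, int]]] = []
        worst = 0.0
        for _ in range(steps):
            if not current.alive_particles():
                break
            new_pop, parentage = step_generation(current, part, truthful_rule)
            part_offspring = grouper(part, parentage)
            truthful = mls2_fitness(part, part_offspring, parentage)
            comparison = {}
            for cid, members in part.blocks().items():
                projected = (
                    rule.offspring_count
                    if len(members) > rule.min_partners
                    else 0
                )
                comparison[cid] = (truthful[cid], projected)
                worst = max(worst, abs(truthful[cid] - projected))
            per_gen.append(comparison)
            current = new_pop
            part = part_offspring
        results.append(
            ReproductionDelta(partition=candidate, delta=worst, per_generation=per_gen)
        )
    return results
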