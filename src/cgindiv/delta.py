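"""The coarse-graining prediction-error statistic and the individuality decision.

Two pathways predict the coarse-grained state of a system at a later time:

* **truthful** (C_T): evolve every particle, then coarse-grain the result;
* **projected** (C_P): coarse-grain first, then evolve each collective as a
  single entity carrying its aggregated traits.

Their difference, ``delta_C = C_T - C_P``, measures the information lost by
compressing the description before predicting.  A coarse-graining is judged
acceptable against a tolerance ``theta`` — accept iff the summary error is
strictly below ``theta`` — and the best candidate partition is the one with
the minimal acceptable error (``delta_C*``).  Per-collective deltas are
reported signed; the population-level summary used for the decision is the
maximal absolute per-collective error.

Because ecology alone can mimic coordination (particles independently
climbing the same resource gradient move as one), the statistic can be
conditioned on a set of weighted environment states and reduced either by
the Euclidean norm across all per-environment per-trait elements or by
their maximum; the max reduction implements "below theta in every
environment state" literally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .coarse_grain import CollectiveState, Partition, apply_partition
from .core import Environment, PopulationState
from .dynamics import UpdateRule, evolve
from .errors import DomainError, ValidationError
from .budget import OpsLedger

POSITION_TRAIT = "position"


@dataclass(frozen=True)
class Threshold:
    """Tolerable prediction error theta (> 0), optionally per trait."""

    theta: float
    per_trait: Optional[Mapping[str, float]] = None

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ValidationError(f"theta must be > 0, got {self.theta}")
        if self.per_trait:
            for name, value in self.per_trait.items():
                if value <= 0:
                    raise ValidationError(
                        f"theta for trait {name!r} must be > 0, got {value}"
                    )

    def for_trait(self, trait: str) -> float:
        if self.per_trait and trait in self.per_trait:
            return self.per_trait[trait]
        return self.theta


@dataclass(eq=False)
class CollectiveDelta:
    """Signed prediction error for one collective and one trait."""

    collective_id: int
    truthful: Union[float, np.ndarray]
    projected: Union[float, np.ndarray]
    delta: Union[float, np.ndarray]  # always truthful - projected
    truthful_dispersion: float

    @property
    def magnitude(self) -> float:
        return float(np.linalg.norm(np.atleast_1d(self.delta)))


@dataclass(eq=False)
class PredictionComparison:
    """Truthful vs. projected prediction for one trait under one partition."""

    trait: str
    per_collective: list[CollectiveDelta]
    population_delta: float  # max absolute per-collective error, >= 0
    steps: int
    partition: Partition

    def to_dict(self) -> dict:
        return {
            "trait": self.trait,
            "steps": self.steps,
            "population_delta": self.population_delta,
            "per_collective": [
                {
                    "collective_id": d.collective_id,
                    "truthful": np.atleast_1d(d.truthful).tolist(),
                    "projected": np.atleast_1d(d.projected).tolist(),
                    "delta": np.atleast_1d(d.delta).tolist(),
                    "truthful_dispersion": d.truthful_dispersion,
                }
                for d in self.per_collective
            ],
        }


# ---------------------------------------------------------------------------
# The two pathways


def truthful_prediction(
    pop: PopulationState,
    rule: UpdateRule,
    env: Optional[Environment],
    steps: int,
    part: Partition,
    ledger: Optional[OpsLedger] = None,
) -> list[CollectiveState]:
    """Evolve at the particle level for *steps*, then coarse-grain."""
    part.validate_covers(pop)
    final = evolve(pop, rule, env, steps, ledger=ledger)[-1]
    return apply_partition(final, part)


def projected_prediction(
    pop: PopulationState,
    rule: UpdateRule,
    env: Optional[Environment],
    steps: int,
    part: Partition,
    ledger: Optional[OpsLedger] = None,
) -> list[CollectiveState]:
    """Coarse-grain first, then evolve each collective as a single entity."""
    part.validate_covers(pop)
    collectives = apply_partition(pop, part)
    return evolve(collectives, rule, env, steps, ledger=ledger)[-1]


# ---------------------------------------------------------------------------
# delta_C


def _trait_value(c: CollectiveState, trait: str, kind: str):
    if kind == "positional":
        return c.centroid.copy()
    return c.agg_traits[trait]


def _trait_kind(pop: PopulationState, trait: str) -> str:
    if trait == POSITION_TRAIT and trait not in pop.trait_names:
        return "positional"
    return pop.trait_kind(trait)


def delta_C(
    pop: PopulationState,
    rule: UpdateRule,
    env: Optional[Environment],
    steps: int,
    part: Partition,
    trait: str = POSITION_TRAIT,
) -> PredictionComparison:
    """Per-collective signed prediction error ``C_T - C_P`` for one trait.

    For positional traits the truthful centroid is compared with the
    projected point prediction, and the dispersion of the truthful members
    (how far the 'entity' actually spread in space) is reported alongside.
    The summary ``population_delta`` is the maximal absolute per-collective
    error (Euclidean norm for positional deltas).
    """
    kind = _trait_kind(pop, trait)
    truthful = truthful_prediction(pop, rule, env, steps, part)
    projected = projected_prediction(pop, rule, env, steps, part)
    t_by_id = {c.collective_id: c for c in truthful}
    p_by_id = {c.collective_id: c for c in projected}
    if set(t_by_id) != set(p_by_id):
        raise DomainError(
            "collective membership changed during prediction; birth-death "
            "dynamics are handled by the mls module"
        )
    per = []
    for cid in sorted(t_by_id):
        ct = _trait_value(t_by_id[cid], trait, kind)
        cp = _trait_value(p_by_id[cid], trait, kind)
        per.append(
            CollectiveDelta(
                collective_id=cid,
                truthful=ct,
                projected=cp,
                delta=ct - cp,
                truthful_dispersion=t_by_id[cid].dispersion,
            )
        )
    population_delta = max(d.magnitude for d in per) if per else 0.0
    return PredictionComparison(
        trait=trait,
        per_collective=per,
        population_delta=population_delta,
        steps=steps,
        partition=part,
    )


def delta_vector(
    pop: PopulationState,
    rules: Union[UpdateRule, Mapping[str, UpdateRule]],
    env: Optional[Environment],
    steps: int,
    part: Partition,
    traits: Sequence[str],
) -> list[PredictionComparison]:
    """One :func:`delta_C` per trait under the *same* partition.

    Functional integration demands that the coarse-graining defining
    individuals works for many traits at once; this evaluates a candidate
    partition trait by trait, each trait optionally driven by its own
    update rule.
    """
    if not traits:
        raise DomainError("delta_vector requires at least one trait")
    out = []
    for trait in traits:
        rule = rules[trait] if isinstance(rules, Mapping) else rules
        out.append(delta_C(pop, rule, env, steps, part, trait))
    return out


def acceptable(comp: PredictionComparison, th: Threshold) -> bool:
    """Strict decision rule: accept iff error < theta; theta itself rejects."""
    return comp.population_delta < th.for_trait(comp.trait)


# ---------------------------------------------------------------------------
# Candidate search


@dataclass
class BestPartitionResult:
    """Outcome of a candidate-partition search.

    ``accepted`` is False when no candidate stays below theta (the
    no-acceptable-partition verdict); then ``partition`` and ``comparison``
    are None.  ``evaluated`` keeps every (partition, comparison) pair for
    reporting.
    """

    partition: Optional[Partition]
    comparison: Optional[PredictionComparison]
    accepted: bool
    evaluated: list[tuple[Partition, PredictionComparison]] = field(
        default_factory=list
    )


def _tie_break_steps(steps: int) -> list[int]:
    return sorted({max(1, steps // 2), max(1, steps), max(1, 2 * steps)})


def best_partition(
    pop: PopulationState,
    rule: UpdateRule,
    env: Optional[Environment],
    steps: int,
    candidates: Sequence[Partition],
    th: Threshold,
    trait: str = POSITION_TRAIT,
) -> BestPartitionResult:
    """The acceptable candidate with minimal summary error (``delta_C*``).

    Ties (equal minimal error) are re-evaluated at shorter and longer step
    counts (``{steps/2, steps, 2*steps}``, integer, >= 1), then broken by
    fewest blocks, then by lexicographic block structure.  Candidates are
    taken as given: the trivially-zero singleton partition is never
    injected.
    """
    if not candidates:
        raise DomainError("best_partition requires at least one candidate")
    evaluated = [
        (part, delta_C(pop, rule, env, steps, part, trait)) for part in candidates
    ]
    passing = [(p, c) for p, c in evaluated if acceptable(c, th)]
    if not passing:
        return BestPartitionResult(None, None, False, evaluated)
    best_value = min(c.population_delta for _, c in passing)
    tol = 1e-12 * max(1.0, abs(best_value))
    tied = [(p, c) for p, c in passing if c.population_delta - best_value <= tol]
    if len(tied) > 1:
        def tie_key(item):
            part, comp = item
            profile = tuple(
                delta_C(pop, rule, env, k, part, trait).population_delta
                for k in _tie_break_steps(steps)
            )
            structure = tuple(sorted(tuple(m) for m in part.blocks().values()))
            return (profile, part.n_blocks, structure)

        tied.sort(key=tie_key)
    winner, comp = tied[0]
    return BestPartitionResult(winner, comp, True, evaluated)


# ---------------------------------------------------------------------------
# Environment conditioning


@dataclass
class ConditionedDelta:
    """delta_C conditioned on a distribution over environment states."""

    per_env: dict[str, list[PredictionComparison]]
    weights: dict[str, float]
    elements: np.ndarray  # per-env per-trait population deltas, flattened
    reduction: str  # "euclidean" | "max"
    reduced: float

    def acceptable(self, th: Threshold) -> bool:
        """Accept iff the reduced error stays below theta.

        Under the ``max`` reduction this is exactly 'below theta in all the
        states of the environment'.
        """
        return self.reduced < th.theta


def conditioned_delta(
    pop: PopulationState,
    rules: Union[UpdateRule, Mapping[str, UpdateRule]],
    envs: Sequence[tuple[Environment, float]],
    steps: int,
    part: Partition,
    traits: Sequence[str],
    reduction: str = "max",
) -> ConditionedDelta:
    """Evaluate :func:`delta_vector` in each weighted environment state.

    *envs* pairs each :class:`~cgindiv.core.Environment` with its occupancy
    probability (weights must be >= 0 with positive sum; zero-weight states
    are dropped from the support).  The per-environment per-trait summary
    errors are reduced to one scalar either as the Euclidean norm across all
    elements ("euclidean") or as their maximum ("max").
    """
    if not envs:
        raise DomainError("conditioned_delta requires at least one environment")
    weights = [w for _, w in envs]
    if any(w < 0 for w in weights):
        raise DomainError("environment weights must be >= 0")
    if sum(weights) <= 0:
        raise DomainError("environment weights must have a positive sum")
    if reduction not in ("euclidean", "max"):
        raise DomainError(f"unknown reduction {reduction!r}")
    per_env: dict[str, list[PredictionComparison]] = {}
    wmap: dict[str, float] = {}
    elements = []
    for env, w in envs:
        if w == 0:
            continue
        comps = delta_vector(pop, rules, env, steps, part, traits)
        per_env[env.state_label] = comps
        wmap[env.state_label] = w
        elements.extend(c.population_delta for c in comps)
    arr = np.asarray(elements, dtype=float)
    reduced = float(np.linalg.norm(arr)) if reduction == "euclidean" else float(
        arr.max()
    )
    return ConditionedDelta(
        per_env=per_env,
        weights=wmap,
        elements=arr,
        reduction=reduction,
        reduced=reduced,
    )
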