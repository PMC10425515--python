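"""Operation accounting and prediction horizons under a computational budget.

The unit of cost is one operation per entity per timestep: evolving N
entities for k steps costs ``N * k`` operations (times any per-step cost a
rule declares).  Given a fixed operation budget, the prediction horizon is
the largest number of whole timesteps affordable — so coarse-graining n
particles into b < n collectives lengthens the horizon by the compression
factor n/b.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import DomainError


@dataclass(frozen=True)
class OpsBudget:
    """A computational budget in operations, with a per-entity step cost."""

    budget: int
    ops_per_entity_per_step: int = 1

    def __post_init__(self) -> None:
        if self.budget < 0:
            raise DomainError(f"budget must be >= 0, got {self.budget}")
        if self.ops_per_entity_per_step < 1:
            raise DomainError(
                "ops_per_entity_per_step must be >= 1, got "
                f"{self.ops_per_entity_per_step}"
            )


def horizon(budget: OpsBudget, n_entities: int) -> int:
    """Largest number of whole timesteps affordable for *n_entities*.

    ``floor(budget / (n_entities * ops_per_entity_per_step))``; antitone in
    the number of entities, monotone in the budget.
    """
    if n_entities < 1:
        raise DomainError(f"n_entities must be >= 1, got {n_entities}")
    return budget.budget // (n_entities * budget.ops_per_entity_per_step)


def cost(n_entities: int, ops_per_entity_per_step: int, steps: int) -> int:
    """Total operation cost of evolving *n_entities* for *steps* timesteps."""
    if n_entities < 0 or ops_per_entity_per_step < 0 or steps < 0:
        raise DomainError("cost arguments must be non-negative")
    return n_entities * ops_per_entity_per_step * steps


@dataclass
class OpsLedger:
    """Running tally of simulation operations.

    The dynamics engine records one entry per timestep; the total is the sum
    of ``n_entities * ops_per_entity`` over entries.
    """

    entries: list[tuple[int, int]] = field(default_factory=list)

    def record(self, n_entities: int, ops_per_entity: int = 1) -> None:
        if n_entities < 0 or ops_per_entity < 0:
            raise DomainError("ledger entries must be non-negative")
        self.entries.append((n_entities, ops_per_entity))

    @property
    def total(self) -> int:
        return sum(n * c for n, c in self.entries)

    def reset(self) -> None:
        self.entries.clear()
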