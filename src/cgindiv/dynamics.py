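"""Deterministic one-step update rules, applied identically at both levels.

Three rules are registered:

``ballistic``
    Move at constant speed along the current heading; heading unchanged.
``chemotaxis``
    Re-orient along the gradient of the summed resource field (each patch
    contributes ``amount * exp(-d / diffusion)``), then move ballistically.
    ``sign=+1`` attracts (up-gradient), ``sign=-1`` repels.
``phototaxis``
    Same, on the light field; the default sign is -1 (negative phototaxis:
    flee the light).

The same rule steps a fine-grained particle (position + direction trait) or
a coarse-grained collective (centroid + aggregated direction): that a
collective is evolved as a single entity with its averaged heading is
precisely what makes the projected pathway cheap — and lossy.  All rules are
deterministic; at an exact field extremum (zero gradient) the heading is
left unchanged.

There are no particle-particle interactions and no spatial boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .budget import OpsLedger
from .coarse_grain import CollectiveState
from .core import Environment, PopulationState, normalize_angle
from .errors import ConfigurationError

REGISTERED_RULES = ("ballistic", "chemotaxis", "phototaxis")

_GRAD_EPS = 1e-12


@dataclass(frozen=True)
class UpdateRule:
    """A named update rule with its parameters.

    Parameters
    ----------
    name : {"ballistic", "chemotaxis", "phototaxis"}
    speed : float
        Displacement per timestep, length units (> 0).
    sign : int
        +1 to move up-gradient (attraction), -1 down-gradient (repulsion).
        Defaults to +1; phototaxis conventionally uses -1.
    direction_trait : str
        Name of the angular trait holding the heading, degrees.
    ops_per_step : int
        Declared cost of stepping one entity once (ledger unit).
    """

    name: str
    speed: float = 1.0
    sign: int = 1
    direction_trait: str = "direction"
    ops_per_step: int = 1

    def __post_init__(self) -> None:
        if self.name not in REGISTERED_RULES:
            raise ConfigurationError(
                f"unknown rule {self.name!r}; registered rules: {REGISTERED_RULES}"
            )
        if self.speed <= 0:
            raise ConfigurationError(f"speed must be > 0, got {self.speed}")
        if self.sign not in (1, -1):
            raise ConfigurationError(f"sign must be +1 or -1, got {self.sign}")
        if self.ops_per_step < 1:
            raise ConfigurationError("ops_per_step must be >= 1")


# ---------------------------------------------------------------------------
# Fields and gradients


def resource_field(env: Environment, point: np.ndarray) -> float:
    """Summed resource concentration at *point*."""
    total = 0.0
    for p in env.resource_patches:
        d = float(np.linalg.norm(point - np.asarray(p.location)))
        total += p.amount * np.exp(-d / p.diffusion)
    return total


def light_field(env: Environment, point: np.ndarray) -> float:
    """Summed light intensity at *point*."""
    total = 0.0
    for s in env.light_sources:
        d = float(np.linalg.norm(point - np.asarray(s.location)))
        total += s.intensity * np.exp(-d / s.decay)
    return total


def _exp_gradient(
    sources: Sequence[tuple[tuple[float, float], float, float]],
    point: np.ndarray,
) -> np.ndarray:
    """Analytic gradient of a sum of isotropic exponential kernels.

    Each source is (location, weight, length scale); the kernel is
    ``w * exp(-d / lam)`` so the gradient contribution points toward the
    source with magnitude ``w * exp(-d / lam) / lam``.  A source exactly at
    *point* contributes nothing (the kernel has a cusp there).
    """
    grad = np.zeros(2)
    for loc, w, lam in sources:
        delta = np.asarray(loc, dtype=float) - point
        d = float(np.linalg.norm(delta))
        if d < _GRAD_EPS:
            continue
        grad += (w * np.exp(-d / lam) / lam) * (delta / d)
    return grad


def resource_gradient(env: Environment, point: np.ndarray) -> np.ndarray:
    return _exp_gradient(
        [(p.location, p.amount, p.diffusion) for p in env.resource_patches],
        np.asarray(point, dtype=float),
    )


def light_gradient(env: Environment, point: np.ndarray) -> np.ndarray:
    return _exp_gradient(
        [(s.location, s.intensity, s.decay) for s in env.light_sources],
        np.asarray(point, dtype=float),
    )


# ---------------------------------------------------------------------------
# Single-entity steps


def step_ballistic(
    position: np.ndarray, direction_deg: float, speed: float
) -> np.ndarray:
    """New position after one ballistic step; heading is unchanged."""
    theta = np.deg2rad(direction_deg)
    return np.asarray(position, dtype=float) + speed * np.array(
        [np.cos(theta), np.sin(theta)]
    )


def _taxis_direction(
    grad: np.ndarray, current_direction: float, sign: int
) -> float:
    if np.linalg.norm(grad) < _GRAD_EPS:
        return current_direction  # degenerate: keep heading
    g = sign * grad
    return normalize_angle(float(np.rad2deg(np.arctan2(g[1], g[0]))))


def step_chemotaxis(
    position: np.ndarray,
    direction_deg: float,
    env: Environment,
    rule: UpdateRule,
) -> tuple[np.ndarray, float]:
    """Re-orient along the resource gradient (times ``rule.sign``), then move."""
    if not env.resource_patches:
        raise ConfigurationError("chemotaxis requires at least one resource patch")
    position = np.asarray(position, dtype=float)
    new_dir = _taxis_direction(
        resource_gradient(env, position), direction_deg, rule.sign
    )
    return step_ballistic(position, new_dir, rule.speed), new_dir


def step_phototaxis(
    position: np.ndarray,
    direction_deg: float,
    env: Environment,
    rule: UpdateRule,
) -> tuple[np.ndarray, float]:
    """Re-orient along (sign * light gradient), then move.

    With the conventional ``sign=-1`` the entity heads directly away from
    the intensity-weighted light gradient.
    """
    if not env.light_sources:
        raise ConfigurationError("phototaxis requires at least one light source")
    position = np.asarray(position, dtype=float)
    new_dir = _taxis_direction(
        light_gradient(env, position), direction_deg, rule.sign
    )
    return step_ballistic(position, new_dir, rule.speed), new_dir


def _step_entity(
    position: np.ndarray,
    direction_deg: float,
    rule: UpdateRule,
    env: Optional[Environment],
) -> tuple[np.ndarray, float]:
    if rule.name == "ballistic":
        return step_ballistic(position, direction_deg, rule.speed), direction_deg
    if env is None:
        raise ConfigurationError(f"rule {rule.name!r} requires an environment")
    if rule.name == "chemotaxis":
        return step_chemotaxis(position, direction_deg, env, rule)
    if rule.name == "phototaxis":
        return step_phototaxis(position, direction_deg, env, rule)
    raise ConfigurationError(f"unknown rule {rule.name!r}")


# ---------------------------------------------------------------------------
# Trajectories

State = Union[PopulationState, list]


def _step_population(
    pop: PopulationState, rule: UpdateRule, env: Optional[Environment]
) -> PopulationState:
    new = pop.copy()
    new.t = pop.t + 1
    for p in new.particles:
        if not p.alive:
            continue
        pos, direction = _step_entity(
            p.position, p.traits[rule.direction_trait], rule, env
        )
        p.position = pos
        p.traits[rule.direction_trait] = direction
    return new


def _step_collectives(
    collectives: Sequence[CollectiveState],
    rule: UpdateRule,
    env: Optional[Environment],
) -> list[CollectiveState]:
    out = []
    for c in collectives:
        new = c.copy()
        pos, direction = _step_entity(
            c.centroid, c.agg_traits[rule.direction_trait], rule, env
        )
        new.centroid = pos
        new.agg_traits[rule.direction_trait] = direction
        out.append(new)
    return out


def evolve(
    state: State,
    rule: UpdateRule,
    env: Optional[Environment] = None,
    steps: int = 1,
    ledger: Optional[OpsLedger] = None,
) -> list[State]:
    """Evolve a population or a list of collectives for *steps* timesteps.

    Returns the trajectory ``[state_0, state_1, ..., state_steps]`` (length
    ``steps + 1``; ``steps=0`` returns just the input).  When a *ledger* is
    supplied, one entry of ``n_entities * rule.ops_per_step`` operations is
    recorded per timestep.
    """
    if steps < 0:
        raise ConfigurationError(f"steps must be >= 0, got {steps}")
    trajectory: list[State] = [state]
    current = state
    for _ in range(steps):
        if isinstance(current, PopulationState):
            n = len(current.alive_particles())
            current = _step_population(current, rule, env)
        else:
            n = len(current)
            current = _step_collectives(current, rule, env)
        if ledger is not None:
            ledger.record(n, rule.ops_per_step)
        trajectory.append(current)
    return trajectory
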