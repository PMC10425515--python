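"""Domain types for particle populations, traits and environments, plus CSV I/O.

The fine-grained description of a system is a :class:`PopulationState`: an
ordered list of particles, each with a planar position and a set of named
real-valued traits.  Trait semantics (linear quantity, angular direction in
degrees, or positional) are declared once per population via
:class:`TraitSpec`; angular traits are normalised into ``[0, 360)`` on
construction.  Environments are collections of isotropic resource patches
and light sources on the same plane.

Populations round-trip losslessly through a plain CSV with columns
``id,x,y,<trait...>,alive,parent_id``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

TraitKind = Literal["linear", "angular_degrees", "positional"]

_TRAIT_KINDS = ("linear", "angular_degrees", "positional")


@dataclass(frozen=True)
class TraitSpec:
    """Declaration of one per-particle trait.

    Parameters
    ----------
    name : str
        Unique trait name within a population.
    kind : {"linear", "angular_degrees", "positional"}
        Aggregation/comparison semantics.  ``angular_degrees`` values are
        always reported in ``[0, 360)``.
    units : str
        Free-text units, for reports only.
    """

    name: str
    kind: TraitKind = "linear"
    units: str = ""

    def __post_init__(self) -> None:
        if self.kind not in _TRAIT_KINDS:
            raise ValidationError(
                f"unknown trait kind {self.kind!r}; expected one of {_TRAIT_KINDS}"
            )


def normalize_angle(value: float) -> float:
    """Map an angle in degrees into ``[0, 360)``."""
    return float(np.mod(value, 360.0))


@dataclass(eq=False)
class ParticleState:
    """One particle: integer id, planar position, named traits."""

    id: int
    position: np.ndarray
    traits: dict[str, float]
    alive: bool = True
    parent_id: Optional[int] = None

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (2,):
            raise ValidationError(
                f"particle {self.id}: position must be a 2-vector, got shape {pos.shape}"
            )
        self.position = pos
        self.traits = {k: float(v) for k, v in self.traits.items()}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ParticleState):
            return NotImplemented
        return (
            self.id == other.id
            and np.array_equal(self.position, other.position)
            and self.traits == other.traits
            and self.alive == other.alive
            and self.parent_id == other.parent_id
        )

    def copy(self) -> "ParticleState":
        return ParticleState(
            id=self.id,
            position=self.position.copy(),
            traits=dict(self.traits),
            alive=self.alive,
            parent_id=self.parent_id,
        )


@dataclass(eq=False)
class PopulationState:
    """Fine-grained description of a population at one integer time index.

    Invariants enforced on construction: ``t >= 0``; particle ids unique;
    every declared trait present on every particle; angular traits
    normalised into ``[0, 360)``; trait names unique.
    """

    t: int
    particles: list[ParticleState]
    trait_specs: list[TraitSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValidationError(f"time index must be >= 0, got {self.t}")
        names = [s.name for s in self.trait_specs]
        if len(set(names)) != len(names):
            raise ValidationError(f"duplicate trait names in {names}")
        ids = [p.id for p in self.particles]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate particle id(s): {dup}")
        angular = {s.name for s in self.trait_specs if s.kind == "angular_degrees"}
        for p in self.particles:
            missing = [n for n in names if n not in p.traits]
            if missing:
                raise ValidationError(
                    f"particle {p.id} is missing trait(s) {missing}"
                )
            for name in angular:
                p.traits[name] = normalize_angle(p.traits[name])

    # -- convenience accessors -------------------------------------------
    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PopulationState):
            return NotImplemented
        return (
            self.t == other.t
            and self.trait_specs == other.trait_specs
            and self.particles == other.particles
        )

    def __len__(self) -> int:
        return len(self.particles)

    @property
    def ids(self) -> list[int]:
        return [p.id for p in self.particles]

    @property
    def trait_names(self) -> list[str]:
        return [s.name for s in self.trait_specs]

    def trait_kind(self, name: str) -> TraitKind:
        for s in self.trait_specs:
            if s.name == name:
                return s.kind
        raise KeyError(name)

    def get(self, particle_id: int) -> ParticleState:
        for p in self.particles:
            if p.id == particle_id:
                return p
        raise KeyError(particle_id)

    def alive_particles(self) -> list[ParticleState]:
        return [p for p in self.particles if p.alive]

    def positions(self) -> np.ndarray:
        return np.array([p.position for p in self.particles], dtype=float)

    def trait_values(self, name: str) -> np.ndarray:
        return np.array([p.traits[name] for p in self.particles], dtype=float)

    def copy(self) -> "PopulationState":
        return PopulationState(
            t=self.t,
            particles=[p.copy() for p in self.particles],
            trait_specs=list(self.trait_specs),
        )


@dataclass(frozen=True)
class ResourcePatch:
    """Point resource patch with an isotropic exponential diffusion field."""

    location: tuple[float, float]
    amount: float
    diffusion: float

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise ValidationError(f"patch amount must be >= 0, got {self.amount}")
        if self.diffusion <= 0:
            raise ValidationError(
                f"patch diffusion length must be > 0, got {self.diffusion}"
            )


@dataclass(frozen=True)
class LightSource:
    """Point light source; intensity decays exponentially with distance."""

    location: tuple[float, float]
    intensity: float
    decay: float = 10.0

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValidationError(
                f"light intensity must be >= 0, got {self.intensity}"
            )
        if self.decay <= 0:
            raise ValidationError(f"light decay length must be > 0, got {self.decay}")


@dataclass(frozen=True)
class Environment:
    """Discrete environment state: resource patches plus light sources."""

    resource_patches: tuple[ResourcePatch, ...] = ()
    light_sources: tuple[LightSource, ...] = ()
    state_label: str = "default"

    @classmethod
    def from_dict(cls, d: dict) -> "Environment":
        patches = tuple(
            ResourcePatch(tuple(p["location"]), p["amount"], p["diffusion"])
            for p in d.get("resource_patches", [])
        )
        lights = tuple(
            LightSource(
                tuple(s["location"]), s["intensity"], s.get("decay", 10.0)
            )
            for s in d.get("light_sources", [])
        )
        return cls(patches, lights, d.get("state_label", "default"))

    def to_dict(self) -> dict:
        return {
            "resource_patches": [
                {
                    "location": list(p.location),
                    "amount": p.amount,
                    "diffusion": p.diffusion,
                }
                for p in self.resource_patches
            ],
            "light_sources": [
                {
                    "location": list(s.location),
                    "intensity": s.intensity,
                    "decay": s.decay,
                }
                for s in self.light_sources
            ],
            "state_label": self.state_label,
        }


# ---------------------------------------------------------------------------
# Tabular I/O


def write_population(pop: PopulationState, path) -> None:
    """Write a population to CSV (columns ``id,x,y,<trait...>,alive,parent_id``).

    ``read_population(write_population(p))`` is the identity, row order
    preserved.
    """
    trait_names = pop.trait_names
    rows = []
    for p in pop.particles:
        row: dict[str, object] = {
            "id": p.id,
            "x": p.position[0],
            "y": p.position[1],
        }
        for name in trait_names:
            row[name] = p.traits[name]
        row["alive"] = int(p.alive)
        row["parent_id"] = "" if p.parent_id is None else p.parent_id
        rows.append(row)
    columns = ["id", "x", "y", *trait_names, "alive", "parent_id"]
    df = pd.DataFrame(rows, columns=columns)
    # %.17g preserves every float bit-for-bit through the text round-trip
    df.to_csv(path, index=False, float_format="%.17g")


def read_population(
    path, trait_specs: Sequence[TraitSpec], t: int = 0
) -> PopulationState:
    """Read a population CSV written by :func:`write_population`.

    Raises
    ------
    FormatError
        If a required column (``id``, ``x``, ``y`` or a declared trait) is
        absent, naming the missing column.
    ValidationError
        If ids are duplicated or any other invariant fails.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    required = ["id", "x", "y"] + [s.name for s in trait_specs]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {path}")
    particles = []
    for _, row in df.iterrows():
        alive = bool(int(row["alive"])) if "alive" in df.columns else True
        parent: Optional[int] = None
        if "parent_id" in df.columns and pd.notna(row["parent_id"]) and row[
            "parent_id"
        ] != "":
            parent = int(row["parent_id"])
        particles.append(
            ParticleState(
                id=int(row["id"]),
                position=np.array([row["x"], row["y"]], dtype=float),
                traits={s.name: float(row[s.name]) for s in trait_specs},
                alive=alive,
                parent_id=parent,
            )
        )
    return PopulationState(t=t, particles=particles, trait_specs=list(trait_specs))
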