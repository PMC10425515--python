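"""Partitions into collectives, trait aggregation and elementary coarse-graining.

A coarse-graining is a :class:`Partition`: a disjoint, covering assignment of
particle ids to collective ids.  Applying a partition lumps each block into a
single :class:`CollectiveState` whose traits are aggregates (by default the
arithmetic mean) of the members' traits, whose position is the member
centroid, and whose dispersion is the maximal member distance from that
centroid.

Also provided are the elementary coarse-graining operators on raw values and
grids — rounding, block averaging and decimation — and the system/environment
bipartition enumeration (``2**n - 2`` labelled two-block partitions of n
items).

Angular traits aggregate by plain arithmetic mean of degrees by default; a
circular (resultant-vector) mean is available as an alternative method.  The
arithmetic default is deliberate: the error of a coarse-grained direction is
measured as a plain absolute difference in degrees, without wrap-around, so
the aggregate and the error scale agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np

from .core import PopulationState, TraitKind, normalize_angle
from .errors import CoverageError, DomainError, ResourceError

AggregationMethod = str  # {"arithmetic_mean", "circular_mean", "sum"}

#: Guard on bipartition enumeration: 2**20 partitions is already ~1e6.
MAX_BIPARTITION_IDS = 20


@dataclass(frozen=True)
class Partition:
    """Assignment of particle ids to collective ids.

    The assignment is stored as an immutable sorted tuple of
    ``(particle_id, collective_id)`` pairs so partitions are hashable and
    comparable; :attr:`assignment` exposes it as a dict.
    """

    items: tuple[tuple[int, int], ...]

    def __init__(self, assignment: Mapping[int, int] | Iterable[tuple[int, int]]):
        if isinstance(assignment, Mapping):
            pairs = tuple(sorted((int(k), int(v)) for k, v in assignment.items()))
        else:
            pairs = tuple(sorted((int(k), int(v)) for k, v in assignment))
        object.__setattr__(self, "items", pairs)

    @property
    def assignment(self) -> dict[int, int]:
        return dict(self.items)

    def blocks(self) -> dict[int, list[int]]:
        """Collective id -> sorted member particle ids."""
        out: dict[int, list[int]] = {}
        for pid, cid in self.items:
            out.setdefault(cid, []).append(pid)
        for members in out.values():
            members.sort()
        return out

    @property
    def n_blocks(self) -> int:
        return len({cid for _, cid in self.items})

    @property
    def particle_ids(self) -> list[int]:
        return [pid for pid, _ in self.items]

    def block_of(self, particle_id: int) -> int:
        return self.assignment[particle_id]

    @classmethod
    def singleton(cls, ids: Iterable[int]) -> "Partition":
        """The identity coarse-graining: every particle its own collective."""
        return cls({int(i): int(i) for i in ids})

    def same_blocks(self, other: "Partition") -> bool:
        """Equality up to relabelling of collective ids."""
        mine = sorted(tuple(m) for m in self.blocks().values())
        theirs = sorted(tuple(m) for m in other.blocks().values())
        return mine == theirs

    def validate_covers(self, pop: PopulationState) -> None:
        """Raise :class:`CoverageError` unless this partition covers exactly
        the alive particles of *pop*."""
        alive = {p.id for p in pop.alive_particles()}
        assigned = set(self.particle_ids)
        missing = sorted(alive - assigned)
        extra = sorted(assigned - alive)
        if missing:
            raise CoverageError(f"partition misses alive particle(s) {missing}")
        if extra:
            raise CoverageError(
                f"partition assigns unknown/dead particle(s) {extra}"
            )


@dataclass(eq=False)
class CollectiveState:
    """Coarse-grained entity: aggregated traits, centroid and dispersion."""

    collective_id: int
    member_ids: frozenset[int]
    agg_traits: dict[str, float]
    centroid: np.ndarray
    dispersion: float = 0.0

    def __post_init__(self) -> None:
        if not self.member_ids:
            raise DomainError("a collective must have at least one member")
        self.centroid = np.asarray(self.centroid, dtype=float)
        if self.dispersion < 0:
            raise DomainError("dispersion must be >= 0")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CollectiveState):
            return NotImplemented
        return (
            self.collective_id == other.collective_id
            and self.member_ids == other.member_ids
            and self.agg_traits == other.agg_traits
            and np.array_equal(self.centroid, other.centroid)
            and self.dispersion == other.dispersion
        )

    def copy(self) -> "CollectiveState":
        return CollectiveState(
            collective_id=self.collective_id,
            member_ids=self.member_ids,
            agg_traits=dict(self.agg_traits),
            centroid=self.centroid.copy(),
            dispersion=self.dispersion,
        )


def write_partition(part: Partition, path) -> None:
    """Serialise a partition as CSV with columns ``particle_id,collective_id``."""
    import pandas as pd

    pd.DataFrame(part.items, columns=["particle_id", "collective_id"]).to_csv(
        path, index=False
    )


def read_partition(path) -> Partition:
    """Read a partition CSV written by :func:`write_partition`."""
    import pandas as pd

    from .errors import FormatError

    df = pd.read_csv(path)
    for col in ("particle_id", "collective_id"):
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {path}")
    return Partition(
        dict(zip(df["particle_id"].astype(int), df["collective_id"].astype(int)))
    )


# ---------------------------------------------------------------------------
# Aggregation and error


def aggregate(
    values: Sequence[float],
    kind: TraitKind = "linear",
    method: AggregationMethod = "arithmetic_mean",
) -> float:
    """Aggregate member trait values into one collective-level value.

    A singleton input is returned unchanged (the identity of coarse-graining
    at block size one).  Angular results are normalised into ``[0, 360)``.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise DomainError("cannot aggregate an empty list of values")
    if method == "arithmetic_mean":
        out = float(vals.mean())
    elif method == "sum":
        out = float(vals.sum())
    elif method == "circular_mean":
        rad = np.deg2rad(vals)
        out = float(np.rad2deg(np.arctan2(np.sin(rad).mean(), np.cos(rad).mean())))
    else:
        raise DomainError(f"unknown aggregation method {method!r}")
    if kind == "angular_degrees":
        out = normalize_angle(out)
    return out


def max_abs_error(
    values: Sequence[float],
    center: float,
    kind: TraitKind = "angular_degrees",
    wrap: bool = False,
) -> float:
    """Maximal absolute deviation of *values* from *center*.

    By default this is the plain (non-wrapped) absolute difference, matching
    the arithmetic-mean aggregation of directions.  With ``wrap=True`` and an
    angular kind, differences are taken on the circle (never exceeding 180).
    """
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise DomainError("cannot compute the error of an empty list")
    diff = np.abs(vals - center)
    if wrap and kind == "angular_degrees":
        diff = np.minimum(diff % 360.0, 360.0 - diff % 360.0)
    return float(diff.max())


def default_method_for(kind: TraitKind) -> AggregationMethod:
    return "arithmetic_mean"


def apply_partition(
    pop: PopulationState,
    part: Partition,
    methods: Optional[Mapping[str, AggregationMethod]] = None,
) -> list[CollectiveState]:
    """Coarse-grain *pop* under *part*: one :class:`CollectiveState` per block.

    Aggregated traits are computed by :func:`aggregate` (arithmetic mean
    unless overridden per trait in *methods*); the centroid is the mean
    member position; dispersion is the maximal member distance from the
    centroid.
    """
    part.validate_covers(pop)
    methods = dict(methods or {})
    collectives = []
    for cid, members in sorted(part.blocks().items()):
        ps = [pop.get(pid) for pid in members]
        positions = np.array([p.position for p in ps])
        centroid = positions.mean(axis=0)
        dispersion = float(np.linalg.norm(positions - centroid, axis=1).max())
        agg = {}
        for spec in pop.trait_specs:
            method = methods.get(spec.name, default_method_for(spec.kind))
            agg[spec.name] = aggregate(
                [p.traits[spec.name] for p in ps], spec.kind, method
            )
        collectives.append(
            CollectiveState(
                collective_id=cid,
                member_ids=frozenset(members),
                agg_traits=agg,
                centroid=centroid,
                dispersion=dispersion,
            )
        )
    return collectives


# ---------------------------------------------------------------------------
# Bipartition enumeration (system vs. environment)


def count_bipartitions(n: int) -> int:
    """Number of ways to split n micro-variables into two labelled non-empty
    macro-variables: ``2**n - 2``."""
    if n < 1:
        raise DomainError(f"n must be >= 1, got {n}")
    return 2**n - 2


def enumerate_bipartitions(ids: Sequence[int]) -> list[Partition]:
    """All labelled two-block ('system' = 0 / 'environment' = 1) partitions.

    Length equals :func:`count_bipartitions`.  Guarded at
    ``len(ids) <= MAX_BIPARTITION_IDS`` to prevent exponential blow-up.
    """
    ids = list(ids)
    n = len(ids)
    if n < 1:
        raise DomainError("ids must be non-empty")
    if n > MAX_BIPARTITION_IDS:
        raise ResourceError(
            f"refusing to enumerate 2**{n}-2 bipartitions "
            f"(guard is {MAX_BIPARTITION_IDS} ids)"
        )
    out = []
    for size in range(1, n):
        for system in combinations(ids, size):
            sys_set = set(system)
            assignment = {i: (0 if i in sys_set else 1) for i in ids}
            out.append(Partition(assignment))
    return out


# ---------------------------------------------------------------------------
# Proximity-pruned candidate partitions


def proximity_partitions(
    pop: PopulationState, block_size: int, radius: float
) -> list[Partition]:
    """Candidate partitions pruned by spatial proximity.

    Builds the undirected graph with an edge whenever two alive particles
    are within *radius*, then groups each connected component into connected
    blocks of *block_size* by greedy nearest-neighbour growth (seeding from
    the lowest remaining id; ties broken by lowest id).  Partitions whose
    blocks would contain mutually distant particles never arise because
    blocks only grow along graph edges.

    Returns a list with one partition when a grouping of the requested size
    exists, and an empty list otherwise.
    """
    if block_size < 1:
        raise DomainError(f"block_size must be >= 1, got {block_size}")
    if radius <= 0:
        raise DomainError(f"radius must be > 0, got {radius}")
    alive = pop.alive_particles()
    g = nx.Graph()
    g.add_nodes_from(p.id for p in alive)
    pos = {p.id: p.position for p in alive}
    for a, b in combinations(alive, 2):
        if np.linalg.norm(a.position - b.position) <= radius:
            g.add_edge(a.id, b.id)

    assignment: dict[int, int] = {}
    next_cid = 0
    for comp in sorted(nx.connected_components(g), key=min):
        comp = set(comp)
        if block_size == 1:
            for pid in sorted(comp):
                assignment[pid] = next_cid
                next_cid += 1
            continue
        if len(comp) % block_size != 0:
            return []
        remaining = set(comp)
        while remaining:
            seed = min(remaining)
            block = [seed]
            remaining.remove(seed)
            while len(block) < block_size:
                frontier = [
                    pid
                    for pid in remaining
                    if any(g.has_edge(pid, b) for b in block)
                ]
                if not frontier:
                    return []  # component cannot be cut into connected blocks
                frontier.sort(
                    key=lambda pid: (
                        min(np.linalg.norm(pos[pid] - pos[b]) for b in block),
                        pid,
                    )
                )
                nxt = frontier[0]
                block.append(nxt)
                remaining.remove(nxt)
            for pid in block:
                assignment[pid] = next_cid
            next_cid += 1
    return [Partition(assignment)] if assignment else []


# ---------------------------------------------------------------------------
# Elementary value/grid operators


def round_values(values: Sequence[float], ndigits: int = 0) -> list[float]:
    """Element-wise rounding, half away from zero (platform independent)."""
    scale = 10.0**ndigits
    out = []
    for v in values:
        scaled = v * scale
        rounded = np.floor(np.abs(scaled) + 0.5) * np.sign(scaled)
        out.append(float(rounded / scale))
    return out


def block_average(grid, factor: int):
    """Average *factor* x *factor* blocks of a 2-D grid.

    The output has dimensions ``input / factor``; with factor 2 the grid
    shrinks four-fold in area.
    """
    arr = np.asarray(grid, dtype=float)
    if arr.ndim != 2:
        raise DomainError(f"grid must be 2-D, got {arr.ndim}-D")
    if factor < 1:
        raise DomainError(f"factor must be >= 1, got {factor}")
    r, c = arr.shape
    if r % factor or c % factor:
        raise DomainError(
            f"grid shape {arr.shape} not divisible by factor {factor}"
        )
    return arr.reshape(r // factor, factor, c // factor, factor).mean(axis=(1, 3))


def decimate(grid, stride: int):
    """Keep grid cells at indices divisible by *stride* along both axes."""
    arr = np.asarray(grid, dtype=float)
    if arr.ndim != 2:
        raise DomainError(f"grid must be 2-D, got {arr.ndim}-D")
    if stride < 1:
        raise DomainError(f"stride must be >= 1, got {stride}")
    return arr[::stride, ::stride]
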