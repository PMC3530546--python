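"""Unified particle representation shared by the MD/DPDE and SPH domains.

A single :class:`ParticleSystem` holds both atomistic (MD/DPDE) particles and
continuum (SPH) integration nodes.  Every particle carries, besides the usual
position/velocity/mass, an internal-energy reservoir ``u`` with heat capacity
``C`` (so that the internal temperature is ``T_int = u / C``), a domain tag,
and an SPH smoothing length ``h``.  The two temperature notions of the coupled
scheme live here:

* kinetic temperature — equipartition over particle momenta,
  ``T_kin = sum(m v^2) / (dof * k_B)``;
* internal temperature — continuum state variable ``T_int = u / C``.

Neighbor search is delegated to :func:`scipy.spatial.cKDTree` with periodic
wrapping on the periodic axes; correctness is defined by equivalence with a
brute-force all-pairs enumeration (see the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "DomainTag",
    "UnitSystem",
    "SimulationBox",
    "ParticleSystem",
    "NeighborList",
    "build_lattice",
    "minimum_image_displacement",
    "build_neighbor_list",
    "internal_temperature",
    "kinetic_temperature",
]


class DomainTag(IntEnum):
    """Domain membership of a particle."""

    MD = 0
    SPH = 1


@dataclass
class UnitSystem:
    """Unit scales.  In reduced (Lennard-Jones) mode ``k_B`` is exactly 1."""

    kB: float = 1.0
    epsilon_unit: float = 1.0
    sigma_unit: float = 1.0
    mass_unit: float = 1.0
    reduced: bool = True

    def __post_init__(self) -> None:
        if self.reduced and self.kB != 1.0:
            raise ValueError("reduced-unit mode fixes k_B = 1 exactly")


@dataclass
class SimulationBox:
    """Orthorhombic box centered about the origin.

    ``periodic[a]`` selects minimum-image wrapping on axis ``a``; a
    non-periodic axis may carry mirror walls (handled by the integrator).
    """

    extent: np.ndarray  # (3,)
    periodic: np.ndarray  # (3,) bool

    def __post_init__(self) -> None:
        self.extent = np.asarray(self.extent, dtype=float)
        self.periodic = np.asarray(self.periodic, dtype=bool)
        if self.extent.shape != (3,) or np.any(self.extent <= 0):
            raise ValueError("box extent must be three positive lengths")

    @property
    def lo(self) -> np.ndarray:
        return -self.extent / 2.0

    @property
    def hi(self) -> np.ndarray:
        return self.extent / 2.0

    def wrap(self, positions: np.ndarray) -> np.ndarray:
        """Wrap positions into the primary cell along periodic axes."""
        pos = np.array(positions, dtype=float)
        for a in range(3):
            if self.periodic[a]:
                L = self.extent[a]
                pos[:, a] -= L * np.round(pos[:, a] / L)
        return pos


@dataclass
class ParticleSystem:
    """State of all particles (MD and SPH) plus the box and unit system."""

    box: SimulationBox
    position: np.ndarray  # (N, 3)
    velocity: np.ndarray  # (N, 3)
    mass: np.ndarray  # (N,)
    internal_energy: np.ndarray  # (N,)
    heat_capacity: np.ndarray  # (N,)
    tag: np.ndarray  # (N,) int8, DomainTag values
    smoothing_length: np.ndarray  # (N,)
    units: UnitSystem = field(default_factory=UnitSystem)
    dof_per_particle: int = 3
    density: np.ndarray | None = None
    pressure: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.position)
        self.position = np.ascontiguousarray(self.position, dtype=float)
        self.velocity = np.ascontiguousarray(self.velocity, dtype=float)
        for name in ("mass", "internal_energy", "heat_capacity", "smoothing_length"):
            setattr(self, name, np.ascontiguousarray(getattr(self, name), dtype=float))
        self.tag = np.ascontiguousarray(self.tag, dtype=np.int8)
        shapes_ok = (
            self.position.shape == (n, 3)
            and self.velocity.shape == (n, 3)
            and all(
                getattr(self, name).shape == (n,)
                for name in ("mass", "internal_energy", "heat_capacity", "smoothing_length", "tag")
            )
        )
        if not shapes_ok:
            raise ValueError("inconsistent array shapes in ParticleSystem")
        if np.any(self.mass <= 0):
            raise ValueError("all masses must be positive")
        if np.any(self.heat_capacity <= 0):
            raise ValueError("all heat capacities must be positive")
        if np.any(self.smoothing_length <= 0):
            raise ValueError("all smoothing lengths must be positive")
        if np.any(self.internal_energy < 0):
            raise ValueError("internal energies must be non-negative")
        if self.density is None:
            self.density = np.zeros(n)
        if self.pressure is None:
            self.pressure = np.zeros(n)

    @property
    def n_particles(self) -> int:
        return len(self.position)

    @property
    def md_mask(self) -> np.ndarray:
        return self.tag == DomainTag.MD

    @property
    def sph_mask(self) -> np.ndarray:
        return self.tag == DomainTag.SPH

    @property
    def internal_temperature(self) -> np.ndarray:
        return self.internal_energy / self.heat_capacity

    def kinetic_energy(self) -> float:
        return 0.5 * float(np.sum(self.mass * np.einsum("ij,ij->i", self.velocity, self.velocity)))

    def total_internal_energy(self) -> float:
        return float(np.sum(self.internal_energy))

    def copy(self) -> "ParticleSystem":
        return ParticleSystem(
            box=SimulationBox(self.box.extent.copy(), self.box.periodic.copy()),
            position=self.position.copy(),
            velocity=self.velocity.copy(),
            mass=self.mass.copy(),
            internal_energy=self.internal_energy.copy(),
            heat_capacity=self.heat_capacity.copy(),
            tag=self.tag.copy(),
            smoothing_length=self.smoothing_length.copy(),
            units=self.units,
            dof_per_particle=self.dof_per_particle,
            density=None if self.density is None else self.density.copy(),
            pressure=None if self.pressure is None else self.pressure.copy(),
        )


def build_lattice(
    nx: int,
    ny: int,
    nz: int,
    spacing: float,
    md_core_extent: int = 0,
    *,
    mass: float = 1.0,
    heat_capacity: float = 100.0,
    internal_energy: float = 100.0,
    smoothing_length: float | None = None,
    periodic=(True, True, True),
    md_slab: tuple[int, int, int] | None = None,
    units: UnitSystem | None = None,
) -> ParticleSystem:
    """Build a simple cubic lattice centered about (0, 0, 0).

    The central ``md_core_extent``^3 sites are tagged MD and the rest SPH.
    Alternatively ``md_slab=(axis, lo, hi)`` tags the lattice layers with
    index ``lo <= i < hi`` along ``axis`` as MD (shock-bar geometry).
    Velocities are zero; ``m``, ``C``, ``u`` are uniform.
    """
    if spacing <= 0:
        raise ValueError("lattice spacing must be positive")
    if min(nx, ny, nz) < 1:
        raise ValueError("lattice extents must be positive")
    if md_core_extent > min(nx, ny, nz):
        raise ValueError("MD core larger than the lattice")
    dims = np.array([nx, ny, nz])
    idx = np.stack(
        np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"), axis=-1
    ).reshape(-1, 3)
    pos = (idx - (dims - 1) / 2.0) * spacing
    n = len(pos)

    tags = np.full(n, DomainTag.SPH, dtype=np.int8)
    if md_slab is not None:
        axis, lo, hi = md_slab
        if not (0 <= lo < hi <= dims[axis]):
            raise ValueError("MD slab indices out of range")
        tags[(idx[:, axis] >= lo) & (idx[:, axis] < hi)] = DomainTag.MD
    elif md_core_extent > 0:
        core_lo = (dims - md_core_extent) // 2
        in_core = np.all((idx >= core_lo) & (idx < core_lo + md_core_extent), axis=1)
        tags[in_core] = DomainTag.MD

    h = 2.5 * spacing if smoothing_length is None else smoothing_length
    box = SimulationBox(extent=dims * spacing, periodic=np.asarray(periodic))
    return ParticleSystem(
        box=box,
        position=pos,
        velocity=np.zeros((n, 3)),
        mass=np.full(n, mass),
        internal_energy=np.full(n, internal_energy),
        heat_capacity=np.full(n, heat_capacity),
        tag=tags,
        smoothing_length=np.full(n, h),
        units=units or UnitSystem(),
    )


def minimum_image_displacement(r_i, r_j, box: SimulationBox) -> np.ndarray:
    """Shortest image of ``r_i - r_j`` along periodic axes; raw otherwise."""
    d = np.asarray(r_i, dtype=float) - np.asarray(r_j, dtype=float)
    for a in range(3):
        if box.periodic[a]:
            L = box.extent[a]
            d[..., a] -= L * np.round(d[..., a] / L)
    return d


@dataclass
class NeighborList:
    """Symmetric pair list (i < j) within ``cutoff + skin``.

    Pairs are stored in canonical (sorted-by-(i, j)) order so that stochastic
    sweeps consuming one random variate per pair are reproducible.  The list
    is valid until some particle has moved more than ``skin / 2`` since the
    build (checked by :meth:`needs_rebuild`).
    """

    i: np.ndarray
    j: np.ndarray
    cutoff: float
    skin: float
    built_positions: np.ndarray

    @property
    def n_pairs(self) -> int:
        return len(self.i)

    def needs_rebuild(self, positions: np.ndarray) -> bool:
        if len(positions) != len(self.built_positions):
            return True
        disp = positions - self.built_positions
        # pair membership is invariant under uniform translation (minimum
        # image), so only displacement relative to the mean matters
        disp = disp - disp.mean(axis=0)
        return bool(np.max(np.einsum("ij,ij->i", disp, disp), initial=0.0) > (self.skin / 2.0) ** 2)


def build_neighbor_list(system: ParticleSystem, cutoff: float, skin: float = 0.3) -> NeighborList:
    """Enumerate all pairs with minimum-image distance <= cutoff + skin."""
    if cutoff <= 0 or skin < 0:
        raise ValueError("cutoff must be positive and skin non-negative")
    box = system.box
    reach = cutoff + skin
    for a in range(3):
        if box.periodic[a] and reach >= box.extent[a] / 2.0:
            raise ValueError(
                f"cutoff + skin = {reach} exceeds half the periodic extent on axis {a}"
            )
    pos = system.position
    # cKDTree with boxsize handles the periodic axes; non-periodic axes get a
    # boxsize far larger than the data so no wrapping occurs there.
    shifted = np.empty_like(pos)
    boxsize = np.empty(3)
    for a in range(3):
        if box.periodic[a]:
            L = box.extent[a]
            shifted[:, a] = np.mod(pos[:, a] + L / 2.0, L)
            boxsize[a] = L
        else:
            span = pos[:, a].max() - pos[:, a].min() if len(pos) else 1.0
            shifted[:, a] = pos[:, a] - (pos[:, a].min() if len(pos) else 0.0) + reach
            boxsize[a] = span + 4.0 * reach + 1.0
    if len(pos) < 2:
        empty = np.empty(0, dtype=np.int64)
        return NeighborList(empty, empty, cutoff, skin, pos.copy())
    tree = cKDTree(shifted, boxsize=boxsize)
    pairs = tree.query_pairs(reach, output_type="ndarray")
    if len(pairs):
        lo = np.minimum(pairs[:, 0], pairs[:, 1])
        hi = np.maximum(pairs[:, 0], pairs[:, 1])
        order = np.lexsort((hi, lo))
        i_idx, j_idx = lo[order], hi[order]
    else:
        i_idx = j_idx = np.empty(0, dtype=np.int64)
    return NeighborList(
        np.ascontiguousarray(i_idx), np.ascontiguousarray(j_idx), cutoff, skin, pos.copy()
    )


def internal_temperature(u, C):
    """Continuum temperature of the internal reservoir, ``T = u / C``."""
    u = np.asarray(u, dtype=float)
    C = np.asarray(C, dtype=float)
    if np.any(C <= 0):
        raise ValueError("heat capacity must be positive")
    if np.any(u < 0):
        raise ValueError("internal energy must be non-negative")
    return u / C


def kinetic_temperature(velocities, masses, dof_per_particle: int = 3, kB: float = 1.0) -> float:
    """Equipartition kinetic temperature of an ensemble.

    ``T = sum_i m_i |v_i|^2 / (N_dof * k_B)`` with ``N_dof = N * dof``.
    """
    v = np.atleast_2d(np.asarray(velocities, dtype=float))
    m = np.atleast_1d(np.asarray(masses, dtype=float))
    if v.size == 0:
        raise ValueError("kinetic temperature of an empty selection is undefined")
    if m.size == 1:
        m = np.full(len(v), m[0])
    mv2 = float(np.sum(m * np.einsum("ij,ij->i", v, v)))
    return mv2 / (dof_per_particle * len(v) * kB)
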