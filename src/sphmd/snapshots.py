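"""Trajectory/state snapshots: LAMMPS-style dump text and XYZ export.

The dump carries every field needed to restore the state exactly
(id, type, position, velocity, internal energy, heat capacity, density,
pressure, mass, smoothing length), written with 17 significant digits so the
text round trip is bit-exact for IEEE doubles.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .particle_state import ParticleSystem, SimulationBox, UnitSystem

__all__ = ["write_snapshot", "read_snapshot", "write_xyz"]

_COLUMNS = "id type x y z vx vy vz u C rho P mass h"
_FMT = "%.17g"


def write_snapshot(system: ParticleSystem, path, timestep: int = 0) -> None:
    """Write a LAMMPS-style text dump of the full particle state."""
    path = Path(path)
    n = system.n_particles
    flags = " ".join("pp" if p else "ff" for p in system.box.periodic)
    lines = [
        "ITEM: TIMESTEP",
        str(int(timestep)),
        "ITEM: NUMBER OF ATOMS",
        str(n),
        f"ITEM: BOX BOUNDS {flags}",
    ]
    for a in range(3):
        lines.append(f"{system.box.lo[a]:.17g} {system.box.hi[a]:.17g}")
    lines.append(f"ITEM: ATOMS {_COLUMNS}")
    rho = system.density if system.density is not None else np.zeros(n)
    P = system.pressure if system.pressure is not None else np.zeros(n)
    for i in range(n):
        vals = [
            i + 1,
            int(system.tag[i]) + 1,
            *system.position[i],
            *system.velocity[i],
            system.internal_energy[i],
            system.heat_capacity[i],
            rho[i],
            P[i],
            system.mass[i],
            system.smoothing_length[i],
        ]
        lines.append(" ".join(str(v) if isinstance(v, int) else _FMT % v for v in vals))
    path.write_text("\n".join(lines) + "\n")


def read_snapshot(path) -> tuple[ParticleSystem, int]:
    """Read a dump written by :func:`write_snapshot`; returns (system, timestep)."""
    lines = Path(path).read_text().splitlines()
    try:
        assert lines[0].startswith("ITEM: TIMESTEP")
        timestep = int(lines[1])
        assert lines[2].startswith("ITEM: NUMBER OF ATOMS")
        n = int(lines[3])
        assert lines[4].startswith("ITEM: BOX BOUNDS")
        flags = lines[4].split()[3:6]
        periodic = [f == "pp" for f in flags]
        bounds = [tuple(map(float, lines[5 + a].split())) for a in range(3)]
        header = lines[8]
        assert header.startswith("ITEM: ATOMS")
    except (AssertionError, IndexError, ValueError) as exc:
        raise ValueError(f"malformed snapshot file {path}") from exc
    cols = header.split()[2:]
    if cols != _COLUMNS.split():
        raise ValueError(f"unexpected dump columns {cols}; expected {_COLUMNS.split()}")
    extent = np.array([hi - lo for lo, hi in bounds])
    body = lines[9 : 9 + n]
    if len(body) != n or (len(lines) > 9 + n and lines[9 + n].strip()):
        raise ValueError("snapshot body length does not match the declared atom count")
    ncol = len(cols)
    data = np.empty((n, ncol))
    for k, ln in enumerate(body):
        parts = ln.split()
        if len(parts) != ncol:
            raise ValueError(f"column mismatch on atom line {k + 1}: "
                             f"got {len(parts)} fields, expected {ncol}")
        data[k] = [float(p) for p in parts]
    order = np.argsort(data[:, 0].astype(int))
    data = data[order]
    if n == 0:
        data = data.reshape(0, ncol)
    system = ParticleSystem(
        box=SimulationBox(extent=extent, periodic=np.array(periodic)),
        position=data[:, 2:5],
        velocity=data[:, 5:8],
        mass=data[:, 12],
        internal_energy=data[:, 8],
        heat_capacity=data[:, 9],
        tag=(data[:, 1] - 1).astype(np.int8),
        smoothing_length=data[:, 13],
        units=UnitSystem(),
        density=data[:, 10],
        pressure=data[:, 11],
    )
    return system, timestep


def write_xyz(system: ParticleSystem, path, comment: str = "") -> None:
    """Minimal XYZ export for viewers (element = MD/SPH tag)."""
    path = Path(path)
    names = {0: "M", 1: "S"}
    lines = [str(system.n_particles), comment]
    for i in range(system.n_particles):
        x, y, z = system.position[i]
        lines.append(f"{names[int(system.tag[i])]} {x:.8f} {y:.8f} {z:.8f}")
    path.write_text("\n".join(lines) + "\n")
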