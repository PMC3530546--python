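"""DPDE local thermostat: pairwise dissipative + stochastic forces on MD particles.

Dissipative Particle Dynamics at constant Energy (DPDE) gives every particle
an internal energy reservoir ``u`` with heat capacity ``C``.  Pairs of MD
particles exchange kinetic and internal energy through a central thermal
force

    F_ij = [ -gamma_ij omega(r)^2 (e . v_ij) + sigma omega(r) xi_ij / sqrt(dt) ] e,

with the friction tied to the noise amplitude by the fluctuation-dissipation
relation at the pair's local internal temperatures,

    gamma_ij = sigma^2 (1/T_i + 1/T_j) / (4 k_B),

i.e. ``sigma^2 / (2 k_B Theta_ij)`` with ``Theta_ij`` the harmonic mean of the
two internal temperatures (the average local temperature of the interacting
pair).  The matching internal-energy update is derived by imposing total
energy conservation on the stochastic dynamics, which requires Ito calculus:
the quadratic variation of the noise impulse contributes a deterministic
drift, so for each pair

    d(u_i + u_j) = [ gamma_ij w^2 (e.v)^2 - (sigma^2 w^2 / 2)(1/m_i + 1/m_j) ] dt
                   - sigma w (e.v) xi sqrt(dt),

split evenly between the two particles.  The discrete update closes the pair
energy budget up to an O(dt) zero-mean term (the fluctuation of xi^2 about
its Ito mean), so total-energy drift decreases with the time step.

At stationarity the thermostat equilibrates the kinetic temperature of the
MD particles with their local internal temperature, which is the property the
atomistic/continuum coupling relies on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._kernels import dpde_pass, two_particle_dpde
from .particle_state import DomainTag, NeighborList, ParticleSystem

__all__ = [
    "DPDEParams",
    "PairThermalUpdate",
    "dpd_weight",
    "pair_thermal_force",
    "apply_thermostat_sweep",
    "two_particle_equilibrium_check",
]


@dataclass(frozen=True)
class DPDEParams:
    """Thermostat parameters.

    sigma_dpde : fluctuation amplitude (controls the interaction strength)
    r_dpde     : range of the weight function omega(r)
    weight_form: 'lucy_normalized' (default; omega(0) = 1, same family as the
                 SPH kernel) or 'linear_dpd' (standard DPD 1 - r/rc ramp)
    """

    sigma_dpde: float = 10.0
    r_dpde: float = 2.5
    weight_form: str = "lucy_normalized"

    def __post_init__(self):
        if self.sigma_dpde < 0 or self.r_dpde <= 0:
            raise ValueError("require sigma_dpde >= 0 and r_dpde > 0")
        if self.weight_form not in ("lucy_normalized", "linear_dpd"):
            raise ValueError(f"unknown weight_form {self.weight_form!r}")


@dataclass
class PairThermalUpdate:
    """Result of one pair interaction: force on i (on j: exact negative)."""

    force_i: np.ndarray
    du_i: float
    du_j: float
    ke_change: float  # analytic (Ito) kinetic-energy change of the pair


def dpd_weight(r: float, params: DPDEParams) -> float:
    """omega(r): compactly supported weight, omega(0) = 1."""
    q = r / params.r_dpde
    if q >= 1.0:
        return 0.0
    if params.weight_form == "linear_dpd":
        return 1.0 - q
    return (1.0 + 3.0 * q) * (1.0 - q) ** 3


class NonPositiveTemperatureError(RuntimeError):
    def __init__(self, particle):
        self.particle = particle
        super().__init__(f"non-positive internal temperature on particle {particle}")


def pair_thermal_force(
    v_ij, r_ij, T_i: float, T_j: float, params: DPDEParams, xi: float, dt: float,
    m_i: float = 1.0, m_j: float = 1.0, kB: float = 1.0, pair=(0, 1),
) -> PairThermalUpdate:
    """Reference (pure Python) DPDE pair update.

    ``v_ij = v_i - v_j``, ``r_ij = r_i - r_j``; ``xi`` is the symmetric
    standard Gaussian draw of the pair.  Returns the force on particle i and
    the internal-energy increments of both particles for one step ``dt``.
    """
    if T_i <= 0:
        raise NonPositiveTemperatureError(pair[0])
    if T_j <= 0:
        raise NonPositiveTemperatureError(pair[1])
    r_ij = np.asarray(r_ij, dtype=float)
    v_ij = np.asarray(v_ij, dtype=float)
    r = float(np.linalg.norm(r_ij))
    w = dpd_weight(r, params) if r > 0 else 0.0
    if w == 0.0:
        return PairThermalUpdate(np.zeros(3), 0.0, 0.0, 0.0)
    e = r_ij / r
    evr = float(e @ v_ij)
    sigma = params.sigma_dpde
    gamma = sigma * sigma * (1.0 / T_i + 1.0 / T_j) / (4.0 * kB)
    force = (-gamma * w * w * evr + sigma * w * xi / math.sqrt(dt)) * e
    minv = 1.0 / m_i + 1.0 / m_j
    # -E_xi[dKE]: drag work + stochastic cross term + Ito drift of the noise
    # impulse, plus the O(dt^2) drag-impulse work so the closure is exact in
    # expectation per step
    gw2 = gamma * w * w
    dpair = (
        gw2 * evr * evr * dt
        - 0.5 * sigma * sigma * w * w * minv * dt
        - sigma * w * evr * xi * math.sqrt(dt)
        - 0.5 * gw2 * gw2 * evr * evr * minv * dt * dt
    )
    return PairThermalUpdate(force, 0.5 * dpair, 0.5 * dpair, -dpair)


def apply_thermostat_sweep(
    system: ParticleSystem,
    neighbors: NeighborList,
    params: DPDEParams,
    rng: np.random.Generator,
    dt: float,
    rvec: np.ndarray | None = None,
    dist: np.ndarray | None = None,
):
    """One thermostat sweep over all MD-MD pairs (one Gaussian draw per pair).

    Velocity and internal-energy increments are applied in place (parallel
    update; total momentum change is exactly zero by pair antisymmetry).
    Returns a diagnostics dict with the sweep's net kinetic->internal energy
    flux and the number of active pairs.
    """
    if params.weight_form != "lucy_normalized":
        return _sweep_python(system, neighbors, params, rng, dt)
    from ._kernels import pair_geometry

    ip, jp = neighbors.i, neighbors.j
    if rvec is None or dist is None:
        rvec = np.empty((len(ip), 3))
        dist = np.empty(len(ip))
        pair_geometry(system.position, ip, jp, system.box.extent,
                      system.box.periodic, rvec, dist)
    md = system.tag == DomainTag.MD
    if not np.any(md):
        raise ValueError("thermostat sweep requires a non-empty MD subset")
    sel = np.flatnonzero(md[ip] & md[jp])
    xi = rng.standard_normal(len(sel))
    dvel = np.zeros_like(system.velocity)
    du = np.zeros(system.n_particles)
    flux, n_active, err = dpde_pass(
        sel, ip, jp, rvec, dist, system.velocity, system.mass,
        system.internal_energy, system.heat_capacity,
        params.sigma_dpde, params.r_dpde, system.units.kB, dt, xi, dvel, du,
    )
    if err >= 0:
        i, j = int(ip[err]), int(jp[err])
        bad = i if system.internal_energy[i] <= 0 else j
        raise NonPositiveTemperatureError(bad)
    system.velocity += dvel
    system.internal_energy += du
    clamped = system.internal_energy < 0
    n_clamped = int(np.count_nonzero(clamped))
    system.internal_energy[clamped] = 0.0
    return {"flux": float(flux), "n_active_pairs": int(n_active), "n_clamped": n_clamped}


def _sweep_python(system, neighbors, params, rng, dt):
    """Fallback sweep for non-default weight forms (reference path)."""
    from .particle_state import minimum_image_displacement

    md = system.tag == DomainTag.MD
    sel = np.flatnonzero(md[neighbors.i] & md[neighbors.j])
    xi = rng.standard_normal(len(sel))
    dvel = np.zeros_like(system.velocity)
    du = np.zeros(system.n_particles)
    flux = 0.0
    n_active = 0
    T = system.internal_temperature
    for n, k in enumerate(sel):
        i, j = int(neighbors.i[k]), int(neighbors.j[k])
        r_ij = minimum_image_displacement(system.position[i], system.position[j], system.box)
        if np.linalg.norm(r_ij) >= params.r_dpde:
            continue
        upd = pair_thermal_force(
            system.velocity[i] - system.velocity[j], r_ij, T[i], T[j], params,
            xi[n], dt, system.mass[i], system.mass[j], system.units.kB, (i, j),
        )
        imp = upd.force_i * dt
        dvel[i] += imp / system.mass[i]
        dvel[j] -= imp / system.mass[j]
        du[i] += upd.du_i
        du[j] += upd.du_j
        flux += upd.du_i + upd.du_j
        n_active += 1
    system.velocity += dvel
    system.internal_energy += du
    clamped = system.internal_energy < 0
    system.internal_energy[clamped] = 0.0
    return {"flux": float(flux), "n_active_pairs": n_active,
            "n_clamped": int(np.count_nonzero(clamped))}


def two_particle_equilibrium_check(
    params: DPDEParams,
    *,
    T0: float = 1.0,
    heat_capacity: float = 100.0,
    mass: float = 1.0,
    dt: float = 5e-6,
    n_steps: int = 20_000_000,
    seed: int = 0,
    box_extent: float = 2.0,
    n_blocks: int = 20,
    kB: float = 1.0,
):
    """Long thermostat-only run of two MD particles; stationary statistics.

    Starts from internal temperature ``T0`` (u = C T0) and a relative
    velocity drawn so the relative-motion kinetic temperature is ``T0``
    (equal and opposite velocities; the pair force conserves the
    center-of-mass momentum exactly, so only the relative degrees of
    freedom thermalize and the kinetic temperature is measured on them).
    Returns a dict with the time-averaged kinetic and internal
    temperatures, their standard errors (from block averages, so
    autocorrelation on scales shorter than a block is absorbed), the
    relative total-energy drift of the run and the RMS per-step energy
    closure error of the Ito update (which is O(dt) and zero-mean; the
    drift decreases with the configured dt).
    """
    if n_steps // n_blocks < 100:
        raise ValueError("insufficient samples per block for stationary statistics")
    rng = np.random.default_rng(seed)
    pos = np.array([[-0.4, 0.0, 0.0], [0.4, 0.0, 0.0]])
    direction = rng.standard_normal(3)
    direction /= np.linalg.norm(direction)
    # mu |v_rel|^2 = 3 kB T0 with mu = m/2, v_rel = 2 v  ->  v = sqrt(1.5 kB T0 / m)
    speed = math.sqrt(1.5 * kB * T0 / mass)
    vel = np.vstack([speed * direction, -speed * direction])
    m = np.full(2, float(mass))
    u = np.full(2, heat_capacity * T0)
    C = np.full(2, float(heat_capacity))
    extent = np.full(3, float(box_extent))
    xi = rng.standard_normal(n_steps)
    block_size = n_steps // n_blocks
    bt = np.zeros(n_blocks)
    bi = np.zeros(n_blocks)
    be = np.zeros(n_blocks)
    rms_step = two_particle_dpde(
        pos, vel, m, u, C, extent, params.sigma_dpde, params.r_dpde, kB, dt,
        xi[: block_size * n_blocks], block_size, bt, bi, be,
    )
    e0 = mass * speed**2 + 2 * heat_capacity * T0  # KE = 2 * (m v^2 / 2)
    tkin = float(np.mean(bt))
    tint = float(np.mean(bi))
    se_kin = float(np.std(bt, ddof=1) / math.sqrt(n_blocks))
    se_int = float(np.std(bi, ddof=1) / math.sqrt(n_blocks))
    drift = float(np.max(np.abs(be - e0)) / abs(e0))
    return {
        "T_kin": tkin,
        "T_int": tint,
        "se_T_kin": se_kin,
        "se_T_int": se_int,
        "difference": tkin - tint,
        "se_difference": math.hypot(se_kin, se_int),
        "energy_drift_rel": drift,
        "rms_step_energy_error": float(rms_step),
        "E0": float(e0),
    }
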