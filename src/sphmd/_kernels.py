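"""Numba-compiled inner loops shared by the SPH, LJ, DPDE and conduction channels.

All kernels are serial (no prange) so that runs are bit-reproducible for a
given seed.  Pair channels follow one sign convention throughout:
``rvec = r_i - r_j`` and a positive scalar force pushes ``i`` along ``+rvec``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

LUCY_NORM_3D = 105.0 / (16.0 * np.pi)


@njit(cache=False)
def _lucy_w(r, h):
    if r >= h:
        return 0.0
    q = r / h
    return LUCY_NORM_3D / (h * h * h) * (1.0 + 3.0 * q) * (1.0 - q) ** 3


@njit(cache=False)
def _lucy_dwdr(r, h):
    if r >= h:
        return 0.0
    q = r / h
    return LUCY_NORM_3D / (h * h * h * h) * (-12.0 * q) * (1.0 - q) ** 2


@njit(cache=False)
def pair_geometry(pos, ip, jp, extent, periodic, rvec, dist):
    """Minimum-image separation vectors r_i - r_j and distances for all pairs."""
    for k in range(ip.size):
        i = ip[k]
        j = jp[k]
        r2 = 0.0
        for a in range(3):
            d = pos[i, a] - pos[j, a]
            if periodic[a]:
                L = extent[a]
                d -= L * np.round(d / L)
            rvec[k, a] = d
            r2 += d * d
        dist[k] = np.sqrt(r2)


@njit(cache=False)
def density_pass(ip, jp, dist, h, m, rho):
    """SPH density summation; ``rho`` pre-filled with the self term."""
    for k in range(ip.size):
        i = ip[k]
        j = jp[k]
        r = dist[k]
        if r < h[i]:
            rho[i] += m[j] * _lucy_w(r, h[i])
        if r < h[j]:
            rho[j] += m[i] * _lucy_w(r, h[j])


@njit(cache=False)
def shepard_pass(ip, jp, dist, h, m, rho_raw, denom):
    """Partition-of-unity denominator sum_j (m_j / rho_j) W_ij.

    Dividing the raw kernel density by this sum restores the partition of
    unity where the kernel support is irregularly sampled — most importantly
    near free surfaces and walls, where the bare summation under-counts the
    missing half-space.  In a homogeneous interior the factor is ~1 and the
    estimate is unchanged.  ``denom`` is pre-filled with the self term
    (m_i / rho_i) W(0, h_i).
    """
    for k in range(ip.size):
        i = ip[k]
        j = jp[k]
        r = dist[k]
        if r < h[i]:
            denom[i] += m[j] / rho_raw[j] * _lucy_w(r, h[i])
        if r < h[j]:
            denom[j] += m[i] / rho_raw[i] * _lucy_w(r, h[j])


@njit(cache=False)
def force_pass(
    ip, jp, rvec, dist, vel, m, rho, P, u, C, h, tag,
    eps, sig, rcut, shift, nu, alpha_diff, mon_alpha, c_mon,
    lam_md, kB, enable_lj, enable_sph, enable_cond, cross_visc,
    forces, du_sph_rate, du_cond_rate,
):
    """Fused LJ + SPH(pressure + viscosity) + conduction pair sweep.

    Channel weights per pair: MD-MD pairs take the MD (LJ) channel only,
    SPH-SPH pairs the SPH channel only, cross pairs the lambda-weighted sum.
    When ``cross_visc`` is False the SPH channel on cross pairs carries the
    pressure term only: the artificial viscosity is a continuum-domain
    dissipation mechanism (nodal velocity -> internal energy) and applying
    it to atomistic thermal motion over-damps the interface.  Heat
    conduction acts across all pairs.  Returns (weighted LJ potential
    energy, LJ virial sum r.F, overlap pair index or -1).
    """
    pe = 0.0
    virial = 0.0
    err = -1
    for k in range(ip.size):
        i = ip[k]
        j = jp[k]
        r = dist[k]
        ti = tag[i]
        tj = tag[j]
        if ti == 0 and tj == 0:
            wmd = 1.0
            wsph = 0.0
        elif ti == 1 and tj == 1:
            wmd = 0.0
            wsph = 1.0
        else:
            wmd = lam_md
            wsph = 1.0 - lam_md
        fx = 0.0
        fy = 0.0
        fz = 0.0
        if enable_lj and wmd > 0.0 and r < rcut:
            if r < 1e-12:
                err = k
                continue
            sr6 = (sig / r) ** 6
            e_pair = 4.0 * eps * (sr6 * sr6 - sr6) - shift
            fmag = 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / r
            pe += wmd * e_pair
            virial += wmd * fmag * r
            fscal = wmd * fmag / r
            fx += fscal * rvec[k, 0]
            fy += fscal * rvec[k, 1]
            fz += fscal * rvec[k, 2]
        hi = h[i]
        hj = h[j]
        hmax = hi if hi > hj else hj
        if (enable_sph or enable_cond) and 0.0 < r < hmax:
            hbar = 0.5 * (hi + hj)
            dwbar = 0.5 * (_lucy_dwdr(r, hi) + _lucy_dwdr(r, hj))
            if enable_sph and wsph > 0.0:
                vx = vel[i, 0] - vel[j, 0]
                vy = vel[i, 1] - vel[j, 1]
                vz = vel[i, 2] - vel[j, 2]
                vdotr = vx * rvec[k, 0] + vy * rvec[k, 1] + vz * rvec[k, 2]
                rhobar = 0.5 * (rho[i] + rho[j])
                denom = r * r + 0.01 * hbar * hbar
                pi_visc = 0.0
                if cross_visc or wsph == 1.0:
                    # linear artificial viscosity in kinematic form; ``nu``
                    # arrives pre-multiplied by the calibrated prefactor
                    pi_visc = -nu * vdotr / (denom * rhobar)
                    if mon_alpha > 0.0 and vdotr < 0.0:
                        mu = hbar * vdotr / denom
                        pi_visc += (-mon_alpha * c_mon * mu + 2.0 * mon_alpha * mu * mu) / rhobar
                pfac = P[i] / (rho[i] * rho[i]) + P[j] / (rho[j] * rho[j]) + pi_visc
                common = wsph * m[i] * m[j] * pfac * dwbar
                fscal = -common / r
                fx += fscal * rvec[k, 0]
                fy += fscal * rvec[k, 1]
                fz += fscal * rvec[k, 2]
                du = 0.5 * common * vdotr / r
                du_sph_rate[i] += du
                du_sph_rate[j] += du
            if enable_cond and alpha_diff > 0.0:
                Ti = u[i] / C[i]
                Tj = u[j] / C[j]
                ki = alpha_diff * rho[i] * C[i] / m[i]
                kj = alpha_diff * rho[j] * C[j] / m[j]
                khar = 4.0 * ki * kj / (ki + kj)
                Fij = -(r * dwbar) / (r * r + 0.01 * hbar * hbar)
                q = m[i] * m[j] / (rho[i] * rho[j]) * khar * (Tj - Ti) * Fij
                du_cond_rate[i] += q
                du_cond_rate[j] -= q
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
    return pe, virial, err


@njit(cache=False)
def dpde_pass(
    pair_sel, ip, jp, rvec, dist, vel, m, u, C,
    sigma, rdpde, kB, dt, xi, dvel, du_inc,
):
    """DPDE thermostat sweep over the selected (MD-MD) pairs.

    Thermal force per pair: dissipative drag with friction fixed by the
    fluctuation-dissipation relation at the pair's local internal
    temperatures, gamma_ij = sigma^2 (1/T_i + 1/T_j) / (4 k_B), plus noise
    sigma * omega(r) * xi / sqrt(dt); weight omega is the Lucy profile
    normalized to omega(0) = 1 with range rdpde (noise weight omega,
    dissipative weight omega^2).  Internal-energy increments follow the
    Ito-corrected energy balance, split evenly over the pair.  Velocity and
    energy increments are accumulated (parallel update).  Returns (net
    kinetic->internal flux, active pair count, index of a pair with
    non-positive internal temperature or -1).
    """
    flux = 0.0
    n_active = 0
    err = -1
    sqdt = np.sqrt(dt)
    for n in range(pair_sel.size):
        k = pair_sel[n]
        r = dist[k]
        if r <= 0.0 or r >= rdpde:
            continue
        i = ip[k]
        j = jp[k]
        Ti = u[i] / C[i]
        Tj = u[j] / C[j]
        if Ti <= 0.0 or Tj <= 0.0:
            err = k
            break
        q = r / rdpde
        w = (1.0 + 3.0 * q) * (1.0 - q) ** 3
        gamma = sigma * sigma * (1.0 / Ti + 1.0 / Tj) / (4.0 * kB)
        ex = rvec[k, 0] / r
        ey = rvec[k, 1] / r
        ez = rvec[k, 2] / r
        evr = (
            ex * (vel[i, 0] - vel[j, 0])
            + ey * (vel[i, 1] - vel[j, 1])
            + ez * (vel[i, 2] - vel[j, 2])
        )
        x = xi[n]
        imp = (-gamma * w * w * evr + sigma * w * x / sqdt) * dt
        dvel[i, 0] += imp * ex / m[i]
        dvel[i, 1] += imp * ey / m[i]
        dvel[i, 2] += imp * ez / m[i]
        dvel[j, 0] -= imp * ex / m[j]
        dvel[j, 1] -= imp * ey / m[j]
        dvel[j, 2] -= imp * ez / m[j]
        minv = 1.0 / m[i] + 1.0 / m[j]
        # -E_xi[dKE]: drag work + stochastic cross term + Ito drift of the
        # noise impulse, plus the O(dt^2) drag-impulse work so the closure
        # is exact in expectation per step
        gw2 = gamma * w * w
        dpair = (
            gw2 * evr * evr * dt
            - 0.5 * sigma * sigma * w * w * minv * dt
            - sigma * w * evr * x * sqdt
            - 0.5 * gw2 * gw2 * evr * evr * minv * dt * dt
        )
        du_inc[i] += 0.5 * dpair
        du_inc[j] += 0.5 * dpair
        flux += dpair
        n_active += 1
    return flux, n_active, err


@njit(cache=False)
def two_particle_dpde(
    pos, vel, m, u, C, extent, sigma, rdpde, kB, dt, xi, block_size,
    block_tkin, block_tint, block_etot,
):
    """Thermostat-only dynamics of two MD particles in a periodic cell.

    Ballistic drift plus one DPDE pair update per step; per-block time
    averages of the relative-motion kinetic temperature, internal
    temperature and total energy are written into the provided arrays.  The
    pair force cannot change the center-of-mass momentum, so only the
    relative degrees of freedom thermalize and the kinetic temperature is
    taken as ``mu |v_rel|^2 / (3 kB)`` with ``mu`` the reduced mass.
    Returns the RMS per-step change of the total energy (the discrete
    closure error of the Ito update).
    """
    n_steps = xi.size
    sqdt = np.sqrt(dt)
    sum_sq_step = 0.0
    e_prev = 0.0
    for a in range(2):
        e_prev += 0.5 * m[a] * (vel[a, 0] ** 2 + vel[a, 1] ** 2 + vel[a, 2] ** 2)
        e_prev += u[a]
    for step in range(n_steps):
        for a in range(2):
            for b in range(3):
                pos[a, b] += vel[a, b] * dt
                L = extent[b]
                d = pos[a, b]
                pos[a, b] = d - L * np.round(d / L)
        r2 = 0.0
        rv = np.empty(3)
        for b in range(3):
            d = pos[0, b] - pos[1, b]
            L = extent[b]
            d -= L * np.round(d / L)
            rv[b] = d
            r2 += d * d
        r = np.sqrt(r2)
        if 0.0 < r < rdpde:
            q = r / rdpde
            w = (1.0 + 3.0 * q) * (1.0 - q) ** 3
            Ti = u[0] / C[0]
            Tj = u[1] / C[1]
            gamma = sigma * sigma * (1.0 / Ti + 1.0 / Tj) / (4.0 * kB)
            evr = 0.0
            for b in range(3):
                evr += rv[b] / r * (vel[0, b] - vel[1, b])
            x = xi[step]
            imp = (-gamma * w * w * evr + sigma * w * x / sqdt) * dt
            for b in range(3):
                e = rv[b] / r
                vel[0, b] += imp * e / m[0]
                vel[1, b] -= imp * e / m[1]
            minv = 1.0 / m[0] + 1.0 / m[1]
            dpair = (
                gamma * w * w * evr * evr * dt
                - 0.5 * sigma * sigma * w * w * minv * dt
                - sigma * w * evr * x * sqdt
            )
            u[0] += 0.5 * dpair
            u[1] += 0.5 * dpair
            if u[0] < 0.0:
                u[0] = 0.0
            if u[1] < 0.0:
                u[1] = 0.0
        ke = 0.0
        for a in range(2):
            ke += 0.5 * m[a] * (vel[a, 0] ** 2 + vel[a, 1] ** 2 + vel[a, 2] ** 2)
        etot = ke + u[0] + u[1]
        sum_sq_step += (etot - e_prev) ** 2
        e_prev = etot
        blk = step // block_size
        if blk < block_tkin.size:
            mu = m[0] * m[1] / (m[0] + m[1])
            vrel2 = 0.0
            for b in range(3):
                vrel2 += (vel[0, b] - vel[1, b]) ** 2
            block_tkin[blk] += mu * vrel2 / (3.0 * kB) / block_size
            block_tint[blk] += 0.5 * (u[0] / C[0] + u[1] / C[1]) / block_size
            block_etot[blk] += etot / block_size
    return np.sqrt(sum_sq_step / n_steps)
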