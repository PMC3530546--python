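"""Pair potential, SPH weighting kernel, and equations of state.

The atomistic domain interacts through the 12-6 Lennard-Jones potential, cut
and shifted so the pair energy vanishes at the cutoff.  The SPH domain uses
Lucy's quartic kernel

    W(r, h) = 105 / (16 pi h^3) * (1 + 3 r/h) (1 - r/h)^3,   r < h,

whose support radius is ``h`` itself, normalized to unit volume integral in
3D.  Continuum pressure comes from an :class:`EquationOfState`: either Tait's
weakly-compressible form or a tabulated LJ-fluid EOS built by calibrating
against virial pressures measured in short MD runs
(:func:`calibrate_lj_eos`), so that the SPH closure reproduces the pressures
the MD domain generates at the simulated state points.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import RectBivariateSpline, interp1d

__all__ = [
    "LJParams",
    "lj_energy_force",
    "lucy_kernel",
    "lucy_kernel_gradient",
    "TaitParams",
    "tait_pressure",
    "EquationOfState",
    "TaitEOS",
    "TabulatedLJEOS",
    "calibrate_lj_eos",
]

LUCY_NORM_3D = 105.0 / (16.0 * np.pi)


@dataclass(frozen=True)
class LJParams:
    """Cut-and-shifted 12-6 Lennard-Jones parameters (reduced units)."""

    epsilon: float = 1.0
    sigma_lj: float = 1.0
    r_cut: float = 2.5

    def __post_init__(self):
        if self.epsilon <= 0 or self.sigma_lj <= 0 or self.r_cut <= self.sigma_lj:
            raise ValueError("require epsilon, sigma > 0 and r_cut > sigma")

    @property
    def shift(self) -> float:
        """Unshifted pair energy at the cutoff (subtracted from u(r))."""
        sr6 = (self.sigma_lj / self.r_cut) ** 6
        return 4.0 * self.epsilon * (sr6 * sr6 - sr6)


class OverlapError(RuntimeError):
    """Raised when a pair distance collapses to zero."""

    def __init__(self, i=None, j=None):
        self.pair = (i, j)
        super().__init__(f"particle overlap (r = 0) for pair {i}, {j}")


def lj_energy_force(r: float, params: LJParams, i=None, j=None) -> tuple[float, float]:
    """Cut-and-shifted LJ pair energy and scalar force magnitude at distance r.

    The force is ``-d/dr`` of the (unshifted) 12-6 form for ``r < r_cut`` and
    exactly zero at and beyond the cutoff (right-continuous tie-break).
    Positive force means repulsion.
    """
    if r <= 0:
        raise OverlapError(i, j)
    if r >= params.r_cut:
        return 0.0, 0.0
    sr6 = (params.sigma_lj / r) ** 6
    energy = 4.0 * params.epsilon * (sr6 * sr6 - sr6) - params.shift
    force = 24.0 * params.epsilon * (2.0 * sr6 * sr6 - sr6) / r
    return energy, force


def lucy_kernel(r, h):
    """Lucy's quartic kernel in 3D, compact support of radius ``h``."""
    r = np.asarray(r, dtype=float)
    h = np.asarray(h, dtype=float)
    if np.any(h <= 0):
        raise ValueError("smoothing length must be positive")
    q = r / h
    w = LUCY_NORM_3D / h**3 * (1.0 + 3.0 * q) * (1.0 - q) ** 3
    return np.where(q < 1.0, w, 0.0)


def lucy_kernel_gradient(r_vec, h):
    """Gradient of the Lucy kernel w.r.t. the position of the first particle.

    ``dW/dr = -12 q (1-q)^2 * 105/(16 pi h^4)``; antisymmetric under particle
    exchange and zero at the origin and outside the support.
    """
    r_vec = np.asarray(r_vec, dtype=float)
    r = np.linalg.norm(r_vec, axis=-1)
    q = r / h
    dwdr = LUCY_NORM_3D / h**4 * (-12.0 * q * (1.0 - q) ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(r[..., None] > 0, r_vec / np.maximum(r, 1e-300)[..., None], 0.0)
    return np.where((q < 1.0) & (r > 0), dwdr, 0.0)[..., None] * unit


@dataclass(frozen=True)
class TaitParams:
    rho0: float = 1.0
    c0: float = 10.0
    gamma_exp: float = 7.0
    P_offset: float = 0.0

    def __post_init__(self):
        if self.rho0 <= 0 or self.c0 <= 0 or self.gamma_exp < 1:
            raise ValueError("require rho0 > 0, c0 > 0, gamma_exp >= 1")


def tait_pressure(rho, params: TaitParams):
    """Tait equation of state, ``P = rho0 c0^2/gamma [(rho/rho0)^gamma - 1]``.

    ``P(rho0) = P_offset`` and ``dP/drho`` at the reference density is
    ``c0^2`` (the reference sound speed squared); strictly increasing in rho.
    """
    rho = np.asarray(rho, dtype=float)
    if np.any(rho <= 0):
        raise ValueError("density must be positive")
    p = params.rho0 * params.c0**2 / params.gamma_exp
    return p * ((rho / params.rho0) ** params.gamma_exp - 1.0) + params.P_offset


class EquationOfState:
    """Maps (density, temperature) to pressure for continuum particles."""

    def pressure(self, rho, T):  # pragma: no cover - interface
        raise NotImplementedError


@dataclass
class TaitEOS(EquationOfState):
    params: TaitParams = field(default_factory=TaitParams)

    def pressure(self, rho, T):
        return tait_pressure(rho, self.params)


class TabulatedLJEOS(EquationOfState):
    """Interpolating LJ-fluid EOS P(rho, T) fit to measured MD pressures.

    Spline (in rho) x linear (in T) interpolation through the measured grid;
    exact at the calibration points.  Degenerate grids (a single isotherm or
    a single state point) fall back to lower-dimensional interpolation with
    constant extrapolation in the missing variable.
    """

    def __init__(self, rho_grid, T_grid, P_table, residuals=None, metadata=None):
        self.rho_grid = np.atleast_1d(np.asarray(rho_grid, dtype=float))
        self.T_grid = np.atleast_1d(np.asarray(T_grid, dtype=float))
        self.P_table = np.asarray(P_table, dtype=float).reshape(
            len(self.rho_grid), len(self.T_grid)
        )
        self.residuals = (
            np.zeros_like(self.P_table) if residuals is None else np.asarray(residuals, dtype=float)
        )
        self.metadata = dict(metadata or {})
        nr, nt = len(self.rho_grid), len(self.T_grid)
        if nr > 1 and nt > 1:
            kx = min(3, nr - 1)
            ky = min(3, nt - 1)
            self._spline = RectBivariateSpline(self.rho_grid, self.T_grid, self.P_table, kx=kx, ky=ky)
            self._mode = "2d"
        elif nr > 1:
            self._interp = interp1d(
                self.rho_grid, self.P_table[:, 0], kind=min(3, nr - 1), fill_value="extrapolate"
            )
            self._mode = "rho"
        elif nt > 1:
            self._interp = interp1d(
                self.T_grid, self.P_table[0, :], kind=min(3, nt - 1), fill_value="extrapolate"
            )
            self._mode = "T"
        else:
            self._mode = "const"

    def pressure(self, rho, T):
        rho = np.asarray(rho, dtype=float)
        T = np.broadcast_to(np.asarray(T, dtype=float), rho.shape).copy() if rho.shape else np.asarray(T, float)
        if self._mode == "2d":
            r = np.clip(rho, self.rho_grid[0], self.rho_grid[-1])
            t = np.clip(T, self.T_grid[0], self.T_grid[-1])
            return self._spline.ev(r, t)
        if self._mode == "rho":
            return np.asarray(self._interp(rho))
        if self._mode == "T":
            return np.asarray(self._interp(T))
        return np.full_like(rho, self.P_table[0, 0])

    # -- persistence ------------------------------------------------------
    def to_csv(self, path) -> None:
        """Persist as CSV (rho, T, P, fit_residual) + JSON metadata sidecar."""
        path = Path(path)
        rows = ["rho,T,P,fit_residual"]
        for a, rho in enumerate(self.rho_grid):
            for b, T in enumerate(self.T_grid):
                rows.append(f"{rho:.12g},{T:.12g},{self.P_table[a, b]:.12g},{self.residuals[a, b]:.12g}")
        path.write_text("\n".join(rows) + "\n")
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(self.metadata, indent=1))

    @classmethod
    def from_csv(cls, path) -> "TabulatedLJEOS":
        path = Path(path)
        data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        rho_grid = np.unique(data[:, 0])
        T_grid = np.unique(data[:, 1])
        P = np.full((len(rho_grid), len(T_grid)), np.nan)
        R = np.zeros_like(P)
        for rho, T, p, res in data:
            a = int(np.searchsorted(rho_grid, rho))
            b = int(np.searchsorted(T_grid, T))
            P[a, b], R[a, b] = p, res
        meta_path = path.with_suffix(path.suffix + ".json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        return cls(rho_grid, T_grid, P, residuals=R, metadata=meta)


def _default_md_engine(rho, T, lj: LJParams, seed, n_cells=6, equil_steps=2000, sample_steps=4000, dt=2e-3):
    """Measure the virial pressure of the LJ fluid at (rho, T) by a short MD run.

    NVT equilibration by velocity rescaling, then NVE sampling of the virial
    pressure ``P = (N k T_kin + W/3) / V``.  Returns (P_mean, P_block_std,
    fluid_ok) where ``fluid_ok`` is False when block-to-block pressure
    fluctuations diverge (two-phase / non-fluid state point).
    """
    # local import: integrator depends on this module
    from .integrator import run_nvt_pressure

    return run_nvt_pressure(
        rho=rho, T=T, lj=lj, seed=seed, n_cells=n_cells,
        equil_steps=equil_steps, sample_steps=sample_steps, dt=dt,
    )


def calibrate_lj_eos(state_points, md_engine=None, seed: int = 0, lj: LJParams | None = None,
                     **engine_kwargs) -> TabulatedLJEOS:
    """Build a tabulated LJ EOS from MD virial pressures at the state points.

    ``state_points`` is an iterable of (rho, T) pairs forming a (possibly
    degenerate) grid.  ``md_engine(rho, T, lj, seed, **kw)`` must return
    ``(P, P_err, fluid_ok)``; non-fluid points are flagged and excluded
    (their table entries are filled by interpolation along rho).
    """
    lj = lj or LJParams()
    engine = md_engine or _default_md_engine
    pts = [(float(r), float(T)) for r, T in state_points]
    rho_grid = np.unique([p[0] for p in pts])
    T_grid = np.unique([p[1] for p in pts])
    P = np.full((len(rho_grid), len(T_grid)), np.nan)
    R = np.zeros_like(P)
    excluded = []
    for k, (rho, T) in enumerate(pts):
        a = int(np.searchsorted(rho_grid, rho))
        b = int(np.searchsorted(T_grid, T))
        p, perr, ok = engine(rho, T, lj, seed + 1000 + k, **engine_kwargs)
        if ok:
            P[a, b] = p
            R[a, b] = perr
        else:
            excluded.append((rho, T))
    # fill any gaps (excluded or missing grid combinations) along rho
    for b in range(len(T_grid)):
        col = P[:, b]
        good = np.isfinite(col)
        if not np.any(good):
            raise ValueError(f"no fluid state points on isotherm T = {T_grid[b]}")
        if not np.all(good):
            P[~good, b] = np.interp(rho_grid[~good], rho_grid[good], col[good])
    meta = {
        "state_points": pts,
        "excluded": excluded,
        "seed": seed,
        "lj": {"epsilon": lj.epsilon, "sigma": lj.sigma_lj, "r_cut": lj.r_cut},
        "engine_kwargs": {k: v for k, v in engine_kwargs.items() if isinstance(v, (int, float, str))},
    }
    return TabulatedLJEOS(rho_grid, T_grid, P, residuals=R, metadata=meta)
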