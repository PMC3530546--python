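"""Measurement layer: temperature profiles, Maxwell-Boltzmann comparison,
equilibrium-temperature prediction, energy audit, and shock-front analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .particle_state import kinetic_temperature

__all__ = [
    "EnergyLedger",
    "FrontTrack",
    "temperature_profile",
    "equilibrium_temperature_estimate",
    "maxwell_boltzmann_check",
    "energy_audit",
    "locate_front",
    "fit_front_speed",
]


@dataclass
class EnergyLedger:
    """Per-step time series of the energy budget.

    ``total`` must equal kinetic + potential + internal at every record;
    ``damped_out`` is the cumulative energy removed by damping layers (it
    left the system by design and is added back by the audit).
    """

    records: list = field(default_factory=list)

    COLUMNS = ("step", "t", "KE", "PE", "U", "E_total", "damped_out", "clamp_count", "dpde_flux")

    def append(self, step, t, KE, PE, U, damped_out=0.0, clamp_count=0, dpde_flux=0.0):
        total = KE + PE + U
        self.records.append((step, t, KE, PE, U, total, damped_out, clamp_count, dpde_flux))

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.records, columns=self.COLUMNS)
        if len(df) and not df["t"].is_monotonic_increasing:
            raise ValueError("ledger time stamps must be monotone")
        return df

    def to_csv(self, path) -> None:
        self.frame().to_csv(path, index=False)


def temperature_profile(
    positions, velocities, masses, internal_energy, heat_capacity,
    axis: int, bin_width: float, extent=None, dof_per_particle: int = 3, kB: float = 1.0,
) -> pd.DataFrame:
    """Binned kinetic and internal temperature along one axis.

    Per-bin kinetic temperature is the equipartition estimate over the bin
    members; internal temperature is the mean of u/C.  Empty bins are
    flagged (``count`` 0, temperatures NaN).
    """
    x = np.asarray(positions)[:, axis]
    if x.size == 0:
        raise ValueError("empty selection")
    lo = -extent / 2.0 if extent is not None else x.min()
    hi = extent / 2.0 if extent is not None else x.max() + 1e-12
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width)))
    edges = lo + bin_width * np.arange(n_bins + 1)
    idx = np.clip(np.digitize(x, edges) - 1, 0, n_bins - 1)
    v = np.asarray(velocities)
    m = np.asarray(masses)
    Tint = np.asarray(internal_energy) / np.asarray(heat_capacity)
    rows = []
    for b in range(n_bins):
        sel = idx == b
        n = int(np.count_nonzero(sel))
        if n == 0:
            rows.append((0.5 * (edges[b] + edges[b + 1]), n, np.nan, np.nan, True))
            continue
        tk = kinetic_temperature(v[sel], m[sel], dof_per_particle, kB)
        rows.append((0.5 * (edges[b] + edges[b + 1]), n, tk, float(np.mean(Tint[sel])), False))
    return pd.DataFrame(rows, columns=["bin_center", "count", "T_kin", "T_int", "is_empty"])


def equilibrium_temperature_estimate(
    N: int, u0: float, C: float, KE0: float = 0.0, dof: int = 3, kB: float = 1.0
) -> float:
    """A-priori equilibrium temperature from the energy balance.

    Redistributes the initial internal energy (plus any initial kinetic
    energy) over the internal heat capacity and the translational degrees of
    freedom, neglecting the change in potential energy:

        N u0 + KE0 = N C T + (dof / 2) N kB T.
    """
    if C <= 0:
        raise ValueError("heat capacity must be positive")
    return (N * u0 + KE0) / (N * C + 0.5 * dof * N * kB)


def maxwell_boltzmann_check(
    velocity_components, m: float, T: float, kB: float = 1.0, bins: int | str = "fd"
):
    """Compare sampled velocity components against the MB (Gaussian) law.

    At temperature T each Cartesian velocity component of a particle of mass
    m is Gaussian with variance kB T / m.  Returns (histogram DataFrame with
    the theory curve, KS statistic, p-value).
    """
    v = np.asarray(velocity_components, dtype=float).ravel()
    if v.size < 1000:
        raise ValueError("need at least 1000 samples for a meaningful comparison")
    scale = np.sqrt(kB * T / m)
    ks = stats.kstest(v, "norm", args=(0.0, scale))
    counts, edges = np.histogram(v, bins=bins, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    theory = stats.norm.pdf(centers, 0.0, scale)
    hist = pd.DataFrame({"v": centers, "density": counts, "mb_theory": theory})
    return hist, float(ks.statistic), float(ks.pvalue)


def energy_audit(ledger, window=None) -> float:
    """Maximum relative drift of the (damping-corrected) total energy.

    ``max_t |E_total(t) + damped_out(t) - E_ref| / |E_ref|`` over the window
    (slice or boolean mask over records; default all records).
    """
    df = ledger.frame() if isinstance(ledger, EnergyLedger) else ledger
    if len(df) < 2:
        raise ValueError("energy audit needs at least two records")
    e = (df["E_total"] + df["damped_out"]).to_numpy()
    if window is not None:
        e = e[window]
    e0 = e[0]
    if e0 == 0:
        raise ValueError("reference total energy is zero")
    return float(np.max(np.abs(e - e0)) / abs(e0))


def locate_front(
    bin_centers, profile, upstream_rho=None, downstream_rho=None,
    min_contrast: float = 0.05, smooth: int = 3,
) -> float:
    """Position where the density crosses the upstream/downstream midpoint.

    Plateau levels default to the medians of the first and last quartile of
    bins (robust to bin noise near the front); the crossing is located by
    linear interpolation between the bracketing bins of the (optionally
    median-smoothed) profile.
    """
    x = np.asarray(bin_centers, dtype=float)
    rho = np.asarray(profile, dtype=float)
    good = np.isfinite(rho)
    x, rho = x[good], rho[good]
    if len(rho) < 4:
        raise ValueError("profile too short to locate a front")
    if smooth and smooth > 1 and len(rho) >= smooth:
        pad = smooth // 2
        padded = np.pad(rho, pad, mode="edge")
        rho_s = np.array([np.median(padded[k:k + smooth]) for k in range(len(rho))])
    else:
        rho_s = rho
    if upstream_rho is not None and downstream_rho is not None:
        lvl1, lvl2 = float(upstream_rho), float(downstream_rho)
    else:
        q = max(1, len(rho_s) // 4)
        lvl1 = float(np.median(rho_s[:q]))
        lvl2 = float(np.median(rho_s[-q:]))
    if abs(lvl2 - lvl1) < min_contrast * max(abs(lvl1), abs(lvl2), 1e-12):
        raise ValueError("density plateaus not distinguishable: contrast below threshold")
    mid = 0.5 * (lvl1 + lvl2)
    # scan for the crossing between the plateau levels
    sgn = np.sign(rho_s - mid)
    crossings = np.flatnonzero(sgn[:-1] * sgn[1:] < 0)
    on_mid = np.flatnonzero(sgn == 0)
    if len(on_mid) and (len(crossings) == 0 or on_mid[0] <= crossings[0]):
        return float(x[on_mid[0]])
    if len(crossings) == 0:
        raise ValueError("no midpoint crossing found in the profile")
    k = int(crossings[0])
    f = (mid - rho_s[k]) / (rho_s[k + 1] - rho_s[k])
    return float(x[k] + f * (x[k + 1] - x[k]))


@dataclass
class FrontTrack:
    """Shock-front position vs. time with linear-fit diagnostics."""

    t: np.ndarray
    x: np.ndarray
    segment: np.ndarray | None = None  # per-point labels, e.g. 'SPH'/'MD'

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"t": self.t, "x_front": self.x})
        if self.segment is not None:
            df["segment"] = self.segment
        return df


def _linfit(t, x):
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    if len(t) < 2 or np.ptp(t) == 0:
        raise ValueError("degenerate time values in front track")
    A = np.vstack([t, np.ones_like(t)]).T
    (slope, intercept), res, *_ = np.linalg.lstsq(A, x, rcond=None)
    pred = slope * t + intercept
    ss_res = float(np.sum((x - pred) ** 2))
    ss_tot = float(np.sum((x - np.mean(x)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    n = len(t)
    if n > 2 and np.var(t) > 0:
        se = np.sqrt(ss_res / (n - 2) / np.sum((t - np.mean(t)) ** 2))
    else:
        se = np.nan
    return float(slope), float(intercept), r2, float(se)


def fit_front_speed(track: FrontTrack, min_points: int = 5) -> dict:
    """Least-squares front speed (lab frame) plus per-segment slopes.

    Segments with fewer than ``min_points`` points are reported with NaN
    slope; R^2 accompanies every fitted slope.
    """
    if len(track.t) < min_points:
        raise ValueError(f"front track needs at least {min_points} points")
    slope, intercept, r2, se = _linfit(track.t, track.x)
    out = {"u_s_lab": slope, "intercept": intercept, "r2": r2, "stderr": se, "segments": {}}
    if track.segment is not None:
        for name in pd.unique(track.segment):
            sel = track.segment == name
            if np.count_nonzero(sel) >= min_points:
                s, b, r, e = _linfit(track.t[sel], track.x[sel])
                out["segments"][str(name)] = {"slope": s, "r2": r, "stderr": e,
                                              "n": int(np.count_nonzero(sel))}
            else:
                out["segments"][str(name)] = {"slope": float("nan"), "r2": float("nan"),
                                              "stderr": float("nan"),
                                              "n": int(np.count_nonzero(sel))}
    return out
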