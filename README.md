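# sphmd

Energy-conserving temperature coupling of a continuum domain (smoothed
particle hydrodynamics, SPH) and an atomistic domain (molecular dynamics
with the constant-energy dissipative-particle thermostat, DPDE), in one
particle-based simulator.

## The problem

Hybrid atomistic/continuum simulations must exchange both momentum and heat
across the domain interface, but the two descriptions define temperature
differently: in MD it is kinetic,

    T_kin = Σ m_i |v_i|² / (N_dof k_B),

while a continuum node carries an internal-energy state variable with
T_int = u_i / C_i.  Coupling them naively freezes the atomistic region: the
continuum's viscosity irreversibly converts nodal motion into internal
energy, and nothing converts it back.

`sphmd` closes the loop the way a local constant-energy thermostat does.
Every particle — atomistic or continuum — carries an internal reservoir
(u, C).  MD pairs interact through a pairwise thermal force

    F_ij = [ −γ_ij ω(r)² (e·v_ij) + σ ω(r) ξ_ij / √dt ] e,
    γ_ij = σ² (1/T_i + 1/T_j) / (4 k_B),

whose friction and noise satisfy the fluctuation–dissipation relation at
the pair's local internal temperatures; the matching internal-energy update
is derived with Itô calculus so kinetic + internal energy is conserved.
Continuum nodes follow the SPH discretization of the Navier–Stokes
equations (Lucy kernel density summation, symmetric pressure-gradient
forces with artificial viscosity in kinematic form, and the paired
internal-energy rate), closed by an equation of state — Tait, or a
tabulated Lennard-Jones EOS calibrated at run time against MD virial
pressures.  Heat conducts between *all* particles through the SPH form of
the Fourier law, and cross-domain pairs feel a λ-weighted mix of both force
channels.  At equilibrium the thermostat drives T_kin → T_int, so the two
temperature definitions agree by construction.

## Worked example

Run the scaled equilibrium verification (a 12³ Lennard-Jones lattice at
reduced density 0.8 whose central 6³ sites are atomistic, started at rest
with uniform internal energy u₀ = 400 ε and C = 400 k_B per particle):

```bash
sphmd equilibrium --seed 1 --out runs/equilibrium
```

which prints (seed 1):

```json
{
 "T_estimate": 0.9963,
 "T_plateau": 1.0212,
 "drift_ppm": 11.8,
 "mb_p_value": 0.013,
 "quiescence_ratio": 0.038,
 "clamp_count": 0,
 ...
}
```

Reading the numbers: the total energy (kinetic + potential + internal)
drifts by about 12 parts per million over 2×10⁴ steps; the kinetic
temperature measured at the center of the MD core settles at the value
predicted by redistributing the initial internal energy over the internal
heat capacity and the translational degrees of freedom
(T = u₀ / (C + 3k_B/2) ≈ 0.996; the center estimate carries a few percent
of statistical scatter at this system size); the MD velocity components
pass a Kolmogorov–Smirnov test against the Maxwell–Boltzmann law at that
temperature (p > 0.01); and the mean particle speed in the continuum
region stays below 4% of the MD thermal speed — the continuum is
quiescent, as the scheme requires.

The shock verification treats the bar as impacting a rigid wall:

```bash
sphmd shock --seed 1 --out runs/shock
```

reports the front track through SPH → MD → SPH and its piecewise fits; at
seed 1 the co-moving front speed is ≈11 (reduced units) with R² ≈ 0.999,
and the SPH- and MD-segment speeds agree to within a few percent.

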