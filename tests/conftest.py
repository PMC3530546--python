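"""Shared fixtures.

The expensive coupled runs (EOS calibration, equilibrium verification, shock
traversal) are session-scoped so the acceptance checks that share one run
(energy drift, equipartition, Maxwell-Boltzmann statistics, continuum
quiescence) reuse a single trajectory.
"""

import numpy as np
import pytest

from sphmd.config import default_equilibrium_config, default_shock_config
from sphmd.integrator import _make_eos, run_equilibrium_scenario, run_shock_scenario


@pytest.fixture(scope="session")
def lj_eos():
    """Tabulated LJ equation of state calibrated against short MD runs."""
    cfg = default_equilibrium_config(seed=1)
    return _make_eos(cfg, cfg.rng_seed)


@pytest.fixture(scope="session")
def equilibrium_run(lj_eos):
    """Scaled equilibrium verification run (12^3 lattice, 6^3 MD core)."""
    cfg = default_equilibrium_config(seed=1)
    return run_equilibrium_scenario(cfg, eos=lj_eos)


@pytest.fixture(scope="session")
def shock_run(lj_eos):
    """Scaled shock run (60x8x8 bar, 12-layer MD slab)."""
    cfg = default_shock_config(seed=1)
    return run_shock_scenario(cfg, eos=lj_eos)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
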