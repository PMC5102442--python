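"""Shared fixtures: the heavy rupture simulations are run once per session.

The canonical test vehicle is the 60 μm scaled membrane (study conditions
except diameter); the mass-scaling comparison uses a 40 μm mini membrane so
that the low-mass-scale runs (whose stable time step is ~100x smaller)
stay affordable.
"""

from __future__ import annotations

import numpy as np
import pytest

from perimem.driver import run_simulation
from perimem.fixtures import make_scaled_membrane

SWEEP_SEEDS = (101, 102, 103, 104, 105)
SWEEP_G = (0.0, 2.5, 7.5)
MASS_SCALES = (1e4, 1e6, 1e8)
MASS_SEEDS = (11, 12, 13)


@pytest.fixture(scope="session")
def g_sweep_runs():
    """Scaled-fixture trajectories for G ∈ {0, 2.5, 7.5} MPa × 5 seeds."""
    out = {}
    for G in SWEEP_G:
        for seed in SWEEP_SEEDS:
            cfg = make_scaled_membrane(diameter=60.0, n_pins=4, seed=seed,
                                       shear_G=G)
            cfg.snapshot_interval = 1e-3
            out[(G, seed)] = run_simulation(cfg)
    return out


@pytest.fixture(scope="session")
def fluid_runs(g_sweep_runs):
    """The G = 0 (fluid membrane) subset, keyed by seed."""
    return {seed: g_sweep_runs[(0.0, seed)] for seed in SWEEP_SEEDS}


@pytest.fixture(scope="session")
def pin_count_runs():
    """G = 0 runs with n ∈ {2, 8} pins (n = 4 comes from the sweep)."""
    out = {}
    for n in (2, 8):
        for seed in SWEEP_SEEDS:
            cfg = make_scaled_membrane(diameter=60.0, n_pins=n, seed=seed,
                                       shear_G=0.0)
            cfg.snapshot_interval = 1e-3
            out[(n, seed)] = run_simulation(cfg)
    return out


@pytest.fixture(scope="session")
def clustered_runs():
    """G = 0 runs with 6 pins confined to a small central disc."""
    out = {}
    for seed in (101, 102, 103):
        cfg = make_scaled_membrane(diameter=60.0, n_pins=6, seed=seed,
                                   shear_G=0.0, cluster=True)
        cfg.snapshot_interval = 1e-3
        out[seed] = run_simulation(cfg)
    return out


@pytest.fixture(scope="session")
def mass_scale_runs():
    """Mini-fixture trajectories across mass scales {1e4, 1e6, 1e8}."""
    out = {}
    for ms in MASS_SCALES:
        for seed in MASS_SEEDS:
            cfg = make_scaled_membrane(diameter=40.0, n_pins=3, seed=seed,
                                       shear_G=2.5, mass_scale=ms,
                                       target_expansion=1.08)
            out[(ms, seed)] = run_simulation(cfg)
    return out


@pytest.fixture(scope="session")
def quick_run():
    """One small, fast trajectory for generic driver/analysis checks."""
    cfg = make_scaled_membrane(diameter=40.0, n_pins=3, seed=7, shear_G=0.0,
                               target_expansion=1.08)
    cfg.snapshot_interval = 1e-3
    return run_simulation(cfg)


def final_dimension(traj, min_pixels=50):
    """Box-count D of the final rupture mask of a trajectory (NaN if empty)."""
    from perimem.analysis import box_count_dimension, rasterize_rupture
    snap = traj.snapshots[-1]
    mask = rasterize_rupture(snap.positions, snap.damage,
                             resolution=0.5, spacing_h=traj.membrane.spacing_h)
    if mask.pixels.sum() < min_pixels:
        return float("nan")
    return box_count_dimension(mask).dimension


def pore_count(traj, expansion, min_area=4.0):
    """Number of pores (≥ min_area μm²) at the snapshot nearest ``expansion``."""
    from perimem.analysis import detect_pores
    snap = traj.snapshot_at(expansion)
    pores = detect_pores(snap.positions, snap.damage, resolution=0.5,
                         spacing_h=traj.membrane.spacing_h)
    return sum(1 for p in pores if p.area >= min_area)
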