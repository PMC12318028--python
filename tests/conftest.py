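"""Shared ensembles for the analysis tests.

The heavier Monte Carlo ensembles are session-scoped so the whole suite
pays for equilibration once.  Problem sizes are desk-scale: a 200-atom
Lennard-Jones liquid and an 84-molecule ammonia-water box at the
experimental mixture composition (1 : 3.665 scaled down) and density.
"""

from __future__ import annotations

import numpy as np
import pytest

from solvnet.model import (
    PotentialSet,
    ammonia_template,
    build_box,
    lj_site_template,
    water_template,
)
from solvnet.simulate import MCState, MoveMix, TrajectorySpec, run_simulation


@pytest.fixture(scope="session")
def lj_liquid_frames():
    """A 200-particle Lennard-Jones liquid ensemble (10 frames)."""
    tpl = lj_site_template(label="LJ", epsilon=0.65, sigma=3.0)
    cfg = build_box([tpl], {"lj": 200}, number_density=0.02, seed=7)
    state = MCState(cfg, 120.0, PotentialSet(cutoff=9.0), seed=8)
    frames = run_simulation(
        state, TrajectorySpec(n_frames=10, frame_stride=10,
                              equilibration_sweeps=300))
    return frames


@pytest.fixture(scope="session")
def mixture_frames():
    """Ammonia-water ensemble at the study composition and density:
    66 water + 18 ammonia (1 : 3.667) at 0.92 g/cm^3, 273 K; 11 frames
    saved 50 sweeps apart after equilibration."""
    cfg = build_box([water_template(), ammonia_template()],
                    {"water": 66, "ammonia": 18},
                    mass_density=0.92, seed=21)
    state = MCState(cfg, 273.0, PotentialSet(cutoff=10.0), seed=22)
    frames = run_simulation(
        state, TrajectorySpec(n_frames=11, frame_stride=50,
                              equilibration_sweeps=1000))
    return frames


@pytest.fixture(scope="session")
def ideal_gas_mc_frames():
    """Non-interacting particles sampled by the Metropolis engine itself
    (every move accepted); large translation moves decorrelate frames."""
    tpl = lj_site_template(label="LJ", epsilon=0.0, sigma=0.0)
    cfg = build_box([tpl], {"lj": 150}, number_density=0.02, seed=31,
                    min_distance=0.0)
    state = MCState(cfg, 300.0, PotentialSet(cutoff=None), seed=32)
    moves = MoveMix(max_translation=cfg.box_length / 2.0)
    return run_simulation(
        state, TrajectorySpec(n_frames=25, frame_stride=2,
                              equilibration_sweeps=20), moves)
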