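"""Shared fixtures: synthetic systems reused across the suite.

Expensive computations (the sphere-in-solvent Q-clean curve at production
resolution, the Brownian ISF) are session-scoped so each is run once.
"""

from __future__ import annotations

import numpy as np
import pytest

import mdscatter as m
from mdscatter.correction import BoxSpec


@pytest.fixture(scope="session")
def toy_traj() -> m.Trajectory:
    return m.make_toy_system()


@pytest.fixture(scope="session")
def toy_table() -> m.SpeciesTable:
    return m.toy_species_table()


@pytest.fixture(scope="session")
def default_table() -> m.SpeciesTable:
    return m.SpeciesTable.default()


@pytest.fixture(scope="session")
def toy_qclean(toy_traj, toy_table):
    """Q-clean small-angle curve of the toy at production resolution
    (301 Q points 0..1, 100 orientations), plus the grid used."""
    b = toy_table.b_coh_array(toy_traj.labels)
    grid = m.make_qgrid(0.0, 1.0, 301, 100, seed=1)
    box = BoxSpec.create(20.0, (10.0, 10.0, 10.0), 6.646e-5)
    return m.diffractogram_qclean(toy_traj, grid, b, box), grid


@pytest.fixture(scope="session")
def brownian_traj() -> m.Trajectory:
    """Free-diffusion fixture at the parameter-recovery scale
    (500 particles x 2000 frames, D = 0.5 A^2/ps)."""
    return m.make_brownian_box(
        m.BrownianSpec(n_particles=500, n_frames=2000, diffusion=0.5,
                       dt=0.1, seed=42))


@pytest.fixture(scope="session")
def brownian_isf(brownian_traj):
    grid = m.make_qgrid(0.5, 1.0, 2, 10, seed=4)
    b_inc = np.ones(brownian_traj.n_atoms)
    return m.isf_incoherent(brownian_traj, grid, b_inc)


def first_local_min(q: np.ndarray, s: np.ndarray, q_lo: float = 0.5):
    """Position of the first local minimum of s(q) with q >= q_lo."""
    mask = q >= q_lo
    qq, ss = q[mask], s[mask]
    for j in range(1, len(ss) - 1):
        if ss[j] < ss[j - 1] and ss[j] < ss[j + 1]:
            return float(qq[j])
    return None
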