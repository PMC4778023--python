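"""Shared fixtures: the SD-I system is expensive, so it is built once."""

from __future__ import annotations

import numpy as np
import pytest

import drodot as dd


@pytest.fixture(scope="session")
def bg():
    return dd.OpticalBackground()


@pytest.fixture(scope="session")
def sd1(bg):
    """SD-I layout, standard grid, and sensing matrix."""
    layout = dd.make_layout("SD-I")
    grid = dd.standard_grid("SD-I")
    A = dd.build_sensing_matrix(layout, grid, bg)
    return layout, grid, A


@pytest.fixture(scope="session")
def sd1_matrix(sd1):
    return sd1[2]


@pytest.fixture(scope="session")
def fig1_truth(sd1):
    _, grid, _ = sd1
    return dd.voxelize_scene(dd.scene_library("fig1_disk"), grid)


@pytest.fixture(scope="session")
def sd1_grouping(sd1_matrix):
    """Greedy Pearson grouping of the raw SD-I matrix at tau = 0.96."""
    return dd.group_columns(sd1_matrix, 0.96)


@pytest.fixture(scope="session")
def sd1_dro_seed0(sd1_matrix, fig1_truth):
    """One full default DRO-DOT run on 2%-noise SD-I data (seed 0)."""
    ms = dd.simulate_measurements(sd1_matrix, fig1_truth, 0.02, seed=0)
    with np.errstate(all="ignore"):
        recon, report = dd.run_dro_dot(sd1_matrix, ms.y, ms.sigma2)
    return ms, recon, report
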