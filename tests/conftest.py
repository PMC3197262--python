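"""Shared fixtures: small phantoms simulated once per session.

The test phantom is a 7 mm tube with a 20 mm mesh stent on a 0.5 mm fine
grid (~40 x 40 x 88 voxels) — large enough for a reference segment on both
sides of the stent and small enough that a full simulation takes a
fraction of a second.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import stentmra as sm

TEST_GRID = 0.5  # mm fine grid used throughout the suite


def make_stent(
    material: sm.MaterialProps,
    diameter: float = 7.0,
    length: float = 20.0,
    design: str = "mesh",
    n_wires: int = 8,
    stent_id: int = 1,
) -> sm.StentSpec:
    return sm.StentSpec(
        id=stent_id,
        name=material.name,
        material=material,
        nominal_diameter=diameter,
        length=length,
        n_helical_wires=n_wires,
        design=design,
    )


def simulate(
    delta_chi: float = 0.0,
    shielding: float = 1.0,
    noise_sigma: float = 0.0,
    seed: int = 7,
    grid: float = TEST_GRID,
    design: str = "mesh",
) -> sm.PhantomImage:
    """One small-phantom simulation with the given artifact parameters."""
    mat = sm.MaterialProps("custom", delta_chi, shielding)
    stent = make_stent(mat, design=design)
    tube = sm.tube_for_stent(stent)
    acq = sm.AcquisitionParams(noise_sigma=noise_sigma, seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sub-voxel wall on the coarse test grid
        labels = sm.rasterize_phantom(tube, stent, grid_voxel=grid)
        return sm.simulate_image(labels, stent, tube, acq)


@pytest.fixture(scope="session")
def image_clean() -> sm.PhantomImage:
    """Artifact-free, noise-free phantom (delta_chi=0, shielding=1)."""
    return simulate()


@pytest.fixture(scope="session")
def image_noisy() -> sm.PhantomImage:
    """Artifact-free phantom with the default 2% Rician noise."""
    return simulate(noise_sigma=0.02)


@pytest.fixture(scope="session")
def chi_sweep_images() -> dict[float, sm.PhantomImage]:
    """Noise-free simulations across the material susceptibility range."""
    return {d: simulate(delta_chi=d) for d in (190e-6, 255e-6, 290e-6, 3e-3)}


@pytest.fixture(scope="session")
def table2():
    ms, df = sm.load_table2_measurements()
    return ms, df


@pytest.fixture(scope="session")
def table3():
    return sm.load_table3_scores()
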