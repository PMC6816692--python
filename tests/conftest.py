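"""Shared fixtures: a small oracle-friendly system and the chest-phantom
systems reused across the suite.

Everything is generated programmatically; the default pipeline has no
randomness, so fixtures are bit-reproducible.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from scatterpet.geometry import EnergyBinning, ImageGrid, ScannerGeometry
from scatterpet.phantoms import (
    chest_phantom,
    initial_guesses,
    simulate_measurements,
)
from scatterpet.systems import build_scatter_system, build_trues_system


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    """Zero-sensitivity / -inf warnings are expected in divergence and
    frozen-voxel scenarios exercised on purpose."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        yield


@pytest.fixture(scope="session")
def small_setup():
    """24-detector ring around a 4×4 grid with 4 energy bins: small enough
    for dense and scalar oracles, with enough angular sampling for rapidly
    identifiable activity reconstruction."""
    scanner = ScannerGeometry(n_detectors=24, ring_radius_cm=10.0)
    grid = ImageGrid(4, 4, 2.0)
    binning = EnergyBinning(4)
    scatter = build_scatter_system(scanner, grid, binning)
    trues = build_trues_system(scanner, grid)
    rng = np.random.default_rng(42)
    lam = 0.5 + rng.random(grid.n_voxels)
    rho = 0.02 + 0.08 * rng.random(grid.n_voxels)
    return {"scanner": scanner, "grid": grid, "binning": binning,
            "scatter": scatter, "trues": trues, "lam": lam, "rho": rho}


@pytest.fixture(scope="session")
def chest9():
    """Human-scale 9×9 chest phantom with its full 64-detector systems;
    other spatial scales are derived by exact length scaling."""
    ph = chest_phantom(resolution=9, scale=1.0)
    scatter = build_scatter_system(ph.scanner, ph.grid, EnergyBinning(10))
    trues = build_trues_system(ph.scanner, ph.grid)
    return {"phantom": ph, "scatter": scatter, "trues": trues}


def scaled_case(chest9, scale: float):
    """Phantom, systems, measurements, and initial guesses at a spatial
    scale derived from the human-scale build."""
    ph = chest_phantom(resolution=9, scale=scale)
    scatter = chest9["scatter"] if scale == 1.0 \
        else chest9["scatter"].scaled(scale)
    trues = chest9["trues"] if scale == 1.0 else chest9["trues"].scaled(scale)
    meas = simulate_measurements(ph, scatter, trues)
    lam0, rho0 = initial_guesses(ph)
    return ph, scatter, trues, meas, lam0, rho0
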