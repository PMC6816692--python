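"""Digital phantoms and noise-free measurement simulation.

The chest cross-section phantom is the package's normative evaluation
object: an elliptical soft-tissue body (μ = 0.096/cm) with two low-density
lung regions (μ = 0.03/cm), a denser spine region (μ = 0.13/cm), and an
activity distribution that is uniform over the body with a lesion of 4×
background activity inside one lung.  At the reference (human) scale the
18×18 grid has 2.5 cm voxels inside a 40 cm-radius detector ring; the rat
and rabbit scales shrink every length by 0.2 and 0.35.  By the unit
convention, ρ is stored numerically equal to μ at 511 keV (1/cm), so the
radiological products K ρ are dimensionless.

Measurements are noise-free expected counts: the default pipeline contains
no randomness at all.  A seeded Poisson sampler is available behind an
explicit flag for experimentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation

from .forward import forward_scatter, forward_trues
from .geometry import ImageGrid, ScannerGeometry
from .systems import ScatterSystem, TruesSystem

__all__ = [
    "Phantom",
    "Measurement",
    "chest_phantom",
    "flat_phantom",
    "initial_guesses",
    "simulate_measurements",
]

SOFT_TISSUE_MU = 0.096   # 1/cm at 511 keV, water-like
LUNG_MU = 0.03
SPINE_MU = 0.13
INITIAL_MU = 0.07
LESION_CONTRAST = 4.0

CHEST_VOXEL_CM = 2.5     # at 18×18 resolution, scale 1
CHEST_RING_CM = 40.0
SUPPORTED_SCALES = (0.2, 0.35, 1.0)


@dataclass
class Phantom:
    """Paired activity (λ, arbitrary units) and attenuation (μ = ρ, 1/cm)
    images with their grid and scanner metadata."""

    lam: np.ndarray
    mu: np.ndarray
    grid: ImageGrid
    scanner: ScannerGeometry
    label: str = ""

    @property
    def rho(self) -> np.ndarray:
        """Electron density in the μ-equivalent unit convention."""
        return self.mu

    def lam_image(self) -> np.ndarray:
        return self.lam.reshape(self.grid.ny, self.grid.nx)

    def mu_image(self) -> np.ndarray:
        return self.mu.reshape(self.grid.ny, self.grid.nx)


@dataclass
class Measurement:
    """Noise-free expected scatter (y, per SOR) and trues (z, per LOR)
    counts."""

    y: np.ndarray
    z: np.ndarray
    simulated: bool = True
    reduced: bool = False


def _chest_images_18() -> tuple[np.ndarray, np.ndarray]:
    """Membership-function definition of the 18×18 chest phantom, in voxel
    units with the grid center at (0, 0), x rightward, y upward."""
    n = 18
    col, row = np.meshgrid(np.arange(n), np.arange(n))
    x = col - (n - 1) / 2.0
    y = (n - 1) / 2.0 - row

    body = (x / 8.2) ** 2 + (y / 6.2) ** 2 <= 1.0
    lung_l = ((x + 3.4) / 2.1) ** 2 + ((y - 1.0) / 3.1) ** 2 <= 1.0
    lung_r = ((x - 3.4) / 2.1) ** 2 + ((y - 1.0) / 3.1) ** 2 <= 1.0
    spine = x ** 2 + (y + 4.3) ** 2 <= 1.4 ** 2
    lesion = (x + 3.4) ** 2 + (y - 1.0) ** 2 <= 1.2 ** 2

    mu = np.zeros((n, n))
    mu[body] = SOFT_TISSUE_MU
    mu[body & (lung_l | lung_r)] = LUNG_MU
    mu[body & spine] = SPINE_MU

    lam = np.zeros((n, n))
    lam[body] = 1.0
    lam[body & lesion] = LESION_CONTRAST
    return lam, mu


def chest_phantom(resolution: int = 18, scale: float = 1.0,
                  n_detectors: int = 64) -> Phantom:
    """Chest cross-section phantom at 18×18 or 9×9 voxels and one of the
    supported spatial scales (1 = human, 0.35 = rabbit, 0.2 = rat).

    The 9×9 version is the exact 2×2 block average of the 18×18 images (its
    voxels are twice as large, so the physical extent is unchanged).
    """
    if resolution not in (9, 18):
        raise ValueError("resolution must be 9 or 18")
    if not any(np.isclose(scale, s) for s in SUPPORTED_SCALES):
        raise ValueError(f"scale must be one of {SUPPORTED_SCALES}")
    lam18, mu18 = _chest_images_18()
    if resolution == 9:
        lam = lam18.reshape(9, 2, 9, 2).mean(axis=(1, 3))
        mu = mu18.reshape(9, 2, 9, 2).mean(axis=(1, 3))
        voxel = 2.0 * CHEST_VOXEL_CM * scale
    else:
        lam, mu = lam18, mu18
        voxel = CHEST_VOXEL_CM * scale
    grid = ImageGrid(resolution, resolution, voxel)
    scanner = ScannerGeometry(n_detectors=n_detectors,
                              ring_radius_cm=CHEST_RING_CM,
                              scale_factor=scale)
    label = f"chest-{resolution}x{resolution}-scale{scale:g}"
    return Phantom(lam=lam.ravel(), mu=mu.ravel(), grid=grid,
                   scanner=scanner, label=label)


def flat_phantom(n: int, lam_value: float = 1.0, mu_value: float = 0.1,
                 extent_cm: float = 45.0, n_detectors: int = 64,
                 ring_radius_cm: float = 40.0) -> Phantom:
    """Uniform n×n phantom covering the full field of view (λ = 1,
    μ = 0.1/cm by default), used for complexity and density studies.  The
    voxel size is adapted so the physical extent stays constant as n
    varies."""
    if n < 1:
        raise ValueError("n must be at least 1")
    grid = ImageGrid(n, n, extent_cm / n)
    scanner = ScannerGeometry(n_detectors=n_detectors,
                              ring_radius_cm=ring_radius_cm)
    return Phantom(lam=np.full(n * n, float(lam_value)),
                   mu=np.full(n * n, float(mu_value)),
                   grid=grid, scanner=scanner, label=f"flat-{n}x{n}")


def initial_guesses(phantom: Phantom,
                    total_activity: float | None = None
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Standard initial images: ρ filled with 0.07/cm inside a mask that
    generously bounds the true object (support dilated by one voxel), zero
    outside; λ homogeneous over the FOV, normalized to ``total_activity``
    (default: the phantom's true total)."""
    support = (phantom.mu > 0).reshape(phantom.grid.ny, phantom.grid.nx)
    mask = binary_dilation(support) if support.any() \
        else np.ones_like(support, dtype=bool)
    rho_init = np.where(mask.ravel(), INITIAL_MU, 0.0)
    total = float(np.sum(phantom.lam)) if total_activity is None \
        else float(total_activity)
    lam_init = np.full(phantom.grid.n_voxels, total / phantom.grid.n_voxels)
    return lam_init, rho_init


def simulate_measurements(phantom: Phantom, scatter: ScatterSystem,
                          trues: TruesSystem,
                          poisson_seed: int | None = None) -> Measurement:
    """Noise-free expected scatter and trues data for the phantom's true
    images, evaluated with the same forward model used for reconstruction.

    ``poisson_seed`` draws a Poisson realization of both vectors (opt-in;
    the default pipeline is deterministic and noise-free).
    """
    if scatter.grid.n_voxels != phantom.grid.n_voxels:
        raise ValueError("scatter system grid does not match the phantom")
    if trues.U.shape[1] != phantom.grid.n_voxels:
        raise ValueError("trues system grid does not match the phantom")
    y = forward_scatter(scatter, phantom.lam, phantom.rho)
    z = forward_trues(trues, phantom.lam, phantom.rho)
    if poisson_seed is not None:
        rng = np.random.default_rng(poisson_seed)
        y = rng.poisson(y).astype(float)
        z = rng.poisson(z).astype(float)
    return Measurement(y=y, z=z, simulated=True)
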