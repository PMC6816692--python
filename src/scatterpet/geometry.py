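"""Scanner, grid, and energy-bin geometry for 2-D scatter PET.

The scanner is a ring of equidistant detectors; images live on a square-voxel
grid centered on the scanner center.  Scattered coincidences are indexed by a
*surface of response* (SOR): the ordered detector pair (scattered detector
``d_s``, nonscattered detector ``d_n``) together with the energy bin of the
scattered photon.  In 2-D the SOR is the pair of circular arcs through both
detectors on which the detector baseline subtends the angle 180° − θ, where θ
is the Compton scattering angle associated with the measured photon energy
(inscribed-angle construction; the arc radius is R = b / (2 sin θ) for a
baseline of length b).

All lengths are in centimeters, energies in keV, angles in degrees at the
public surface (radians internally where noted).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

#: Annihilation photon energy.
E0_KEV = 511.0

#: Lowest possible energy of a single-scattered annihilation photon
#: (backscatter, θ = 180°): E0 / (1 + 2 E0 / m_e c²) = 511/3 keV.
MIN_SCATTER_ENERGY_KEV = E0_KEV / 3.0

#: Compton edge: the largest energy a 511 keV photon can transfer to an
#: electron in a single interaction, E0 − 511/3 ≈ 340.7 keV.
COMPTON_EDGE_KEV = E0_KEV - MIN_SCATTER_ENERGY_KEV


def scattering_angle_from_energy(energy_kev):
    """Compton scattering angle θ (degrees) of a 511 keV photon scattered
    to ``energy_kev``.

    Uses cos θ = 2 − 511/E, the Compton relation specialized to
    annihilation photons (E0 = m_e c²).

    Parameters
    ----------
    energy_kev : float or array_like
        Scattered photon energy in [511/3, 511] keV.

    Raises
    ------
    ValueError
        If any energy lies outside the single-scatter range.
    """
    e = np.asarray(energy_kev, dtype=float)
    if np.any(e < MIN_SCATTER_ENERGY_KEV - 1e-9) or np.any(e > E0_KEV + 1e-9):
        raise ValueError(
            f"no single-scatter solution for E outside "
            f"[{MIN_SCATTER_ENERGY_KEV:.3f}, {E0_KEV}] keV"
        )
    cos_theta = np.clip(2.0 - E0_KEV / e, -1.0, 1.0)
    theta = np.degrees(np.arccos(cos_theta))
    return float(theta) if np.isscalar(energy_kev) else theta


def energy_from_angle(theta_deg):
    """Energy (keV) of a 511 keV photon after Compton scattering by
    ``theta_deg`` degrees: E = 511 / (2 − cos θ).  Inverse of
    :func:`scattering_angle_from_energy`."""
    t = np.radians(np.asarray(theta_deg, dtype=float))
    e = E0_KEV / (2.0 - np.cos(t))
    return float(e) if np.isscalar(theta_deg) else e


@dataclass(frozen=True)
class ScannerGeometry:
    """Ring of equidistant detectors.

    ``ring_radius_cm`` is the radius of the unscaled system; the effective
    radius is ``ring_radius_cm * scale_factor``.  The scale factor is applied
    uniformly to the ring radius and (by the callers that build grids) to the
    voxel size, so that all size relations are preserved across spatial
    scales.
    """

    n_detectors: int = 64
    ring_radius_cm: float = 40.0
    scale_factor: float = 1.0

    def __post_init__(self):
        if self.n_detectors < 2:
            raise ValueError("need at least 2 detectors")
        if self.ring_radius_cm <= 0 or self.scale_factor <= 0:
            raise ValueError("ring radius and scale factor must be positive")

    @property
    def radius_cm(self) -> float:
        """Effective (scaled) ring radius."""
        return self.ring_radius_cm * self.scale_factor

    @property
    def detector_angles(self) -> np.ndarray:
        """Angular positions (radians), equally spaced on the ring."""
        return 2.0 * np.pi * np.arange(self.n_detectors) / self.n_detectors

    @property
    def detector_positions(self) -> np.ndarray:
        """(n_detectors, 2) Cartesian detector positions in cm."""
        a = self.detector_angles
        return self.radius_cm * np.stack([np.cos(a), np.sin(a)], axis=1)

    def pair_separation_deg(self, d1, d2) -> np.ndarray:
        """Angular separation (degrees) between detectors, on the circle."""
        step = 360.0 / self.n_detectors
        diff = np.abs(np.asarray(d1) - np.asarray(d2)) % self.n_detectors
        diff = np.minimum(diff, self.n_detectors - diff)
        return diff * step

    def with_scale(self, scale_factor: float) -> "ScannerGeometry":
        return ScannerGeometry(self.n_detectors, self.ring_radius_cm, scale_factor)


@dataclass(frozen=True)
class ImageGrid:
    """Square-voxel image grid centered on the scanner center.

    Voxels are addressed by 0-based (row, column); x increases with column
    (rightward), y decreases with row (row 0 is the top).  The flat voxel
    index is ``j = row * nx + col``.
    """

    nx: int
    ny: int
    voxel_cm: float

    def __post_init__(self):
        if self.nx < 1 or self.ny < 1:
            raise ValueError("grid must have at least one voxel per axis")
        if self.voxel_cm <= 0:
            raise ValueError("voxel size must be positive")

    @property
    def n_voxels(self) -> int:
        return self.nx * self.ny

    @property
    def x_edges(self) -> np.ndarray:
        half = self.nx * self.voxel_cm / 2.0
        return np.linspace(-half, half, self.nx + 1)

    @property
    def y_edges(self) -> np.ndarray:
        """Descending y edges; row r spans (y_edges[r+1], y_edges[r])."""
        half = self.ny * self.voxel_cm / 2.0
        return np.linspace(half, -half, self.ny + 1)

    @property
    def voxel_centers(self) -> np.ndarray:
        """(n_voxels, 2) centers in flat (row-major) order."""
        xc = (np.arange(self.nx) - (self.nx - 1) / 2.0) * self.voxel_cm
        yc = ((self.ny - 1) / 2.0 - np.arange(self.ny)) * self.voxel_cm
        xx, yy = np.meshgrid(xc, yc)
        return np.stack([xx.ravel(), yy.ravel()], axis=1)

    @property
    def half_extent(self) -> tuple[float, float]:
        return (self.nx * self.voxel_cm / 2.0, self.ny * self.voxel_cm / 2.0)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask for points strictly inside the grid bounding box."""
        hx, hy = self.half_extent
        p = np.atleast_2d(points)
        return (np.abs(p[:, 0]) < hx) & (np.abs(p[:, 1]) < hy)

    def point_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Flat voxel index of each point (caller guarantees containment)."""
        p = np.atleast_2d(points)
        hx, hy = self.half_extent
        col = np.clip(((p[:, 0] + hx) / self.voxel_cm).astype(int), 0, self.nx - 1)
        row = np.clip(((hy - p[:, 1]) / self.voxel_cm).astype(int), 0, self.ny - 1)
        return row * self.nx + col

    def fits_inside(self, radius_cm: float) -> bool:
        """True if all voxel centers lie strictly inside a ring of the
        given radius."""
        c = self.voxel_centers
        return bool(np.all(np.hypot(c[:, 0], c[:, 1]) < radius_cm))

    def with_voxel_cm(self, voxel_cm: float) -> "ImageGrid":
        return ImageGrid(self.nx, self.ny, voxel_cm)


@dataclass(frozen=True)
class EnergyBinning:
    """Equal-width energy binning of the scattered photon, descending from
    511 keV to 0.

    Bin ``k`` covers the half-open interval (edges[k+1], edges[k]].  The
    *effective* bins are those whose interval intersects the single-scatter
    range [511/3, 511) keV; only these can receive single-scattered
    coincidences and only these are enumerated when building systems.
    For the default 10 bins, 7 are effective.
    """

    n_bins: int = 10

    def __post_init__(self):
        if self.n_bins < 1:
            raise ValueError("need at least one energy bin")

    @property
    def bin_edges(self) -> np.ndarray:
        """Strictly decreasing edges, length n_bins + 1, from 511 to 0."""
        return E0_KEV * (1.0 - np.arange(self.n_bins + 1) / self.n_bins)

    @property
    def bin_width_kev(self) -> float:
        return E0_KEV / self.n_bins

    @property
    def effective_bins(self) -> np.ndarray:
        """Indices of bins reachable by single scatter."""
        uppers = self.bin_edges[:-1]
        return np.nonzero(uppers > MIN_SCATTER_ENERGY_KEV + 1e-12)[0]

    @property
    def n_effective(self) -> int:
        return len(self.effective_bins)

    def bin_center_kev(self, k: int) -> float:
        """Representative energy of bin k: the midpoint of the bin's
        intersection with the single-scatter range."""
        upper = self.bin_edges[k]
        lower = max(self.bin_edges[k + 1], MIN_SCATTER_ENERGY_KEV)
        if upper <= MIN_SCATTER_ENERGY_KEV:
            raise ValueError(f"bin {k} is not reachable by single scatter")
        return 0.5 * (min(upper, E0_KEV) + lower)

    def bin_angle_deg(self, k: int) -> float:
        """Scattering angle (degrees) at the representative bin energy."""
        return scattering_angle_from_energy(self.bin_center_kev(k))


# ---------------------------------------------------------------------------
# 2-D SOR loci
# ---------------------------------------------------------------------------

def _locus_arcs(p1: np.ndarray, p2: np.ndarray, theta_rad: float):
    """The two circular arcs on which the baseline p1–p2 subtends the
    inscribed angle 180° − θ.

    Returns a list of (center, start_angle, span_angle) triples; each arc is
    traced counterclockwise from ``start_angle`` over ``span_angle`` (which
    may be negative for clockwise tracing).  The arcs run from p1 to p2 and
    have radius R = b / (2 sin θ); their central angle is 2θ.
    """
    b = float(np.hypot(*(p2 - p1)))
    if b <= 0:
        raise ValueError("detector positions must be distinct")
    sin_t = math.sin(theta_rad)
    if sin_t <= 0:
        raise ValueError("theta must lie strictly between 0 and 180 degrees")
    radius = b / (2.0 * sin_t)
    mid = 0.5 * (p1 + p2)
    chord_dir = (p2 - p1) / b
    normal = np.array([-chord_dir[1], chord_dir[0]])
    h = math.sqrt(max(radius * radius - 0.25 * b * b, 0.0))
    phi = math.pi - theta_rad  # inscribed angle on the locus

    arcs = []
    for side in (+1.0, -1.0):
        center = mid + side * h * normal
        a1 = math.atan2(p1[1] - center[1], p1[0] - center[0])
        a2 = math.atan2(p2[1] - center[1], p2[0] - center[0])
        ccw = (a2 - a1) % (2.0 * math.pi)
        # candidate spans: ccw (positive) and cw (negative)
        best = None
        for span in (ccw, ccw - 2.0 * math.pi):
            mid_ang = a1 + 0.5 * span
            m = center + radius * np.array([math.cos(mid_ang), math.sin(mid_ang)])
            v1, v2 = p1 - m, p2 - m
            ang = math.atan2(abs(v1[0] * v2[1] - v1[1] * v2[0]), float(v1 @ v2))
            err = abs(ang - phi)
            if best is None or err < best[0]:
                best = (err, span, err)
        _, span, err = best
        if err > 1e-6:
            # both candidates equally good only in the θ = 90° degenerate
            # case where the two circles coincide; keep the side-specific arc
            pass
        arcs.append((center, a1, span))

    if h < 1e-12 * max(radius, 1.0):
        # θ = 90°: one circle, the two loci are the two semicircles.  Force
        # opposite directions so both halves are covered.
        (c0, a1_0, s0), (c1, a1_1, s1) = arcs
        arcs = [(c0, a1_0, math.pi), (c1, a1_1, -math.pi)]
    return radius, arcs


def sor_locus(d_s_pos, d_n_pos, theta_deg: float, n_samples: int = 64) -> np.ndarray:
    """Sample the 2-D SOR locus: the points from which the two detectors are
    seen under the angle 180° − θ.

    Returns an (2 * n_samples, 2) array: ``n_samples`` points on each of the
    two arcs, approximately uniform in arc length, ordered along each arc.
    For θ → 0 the locus degenerates to the chord between the detectors and
    the chord is sampled instead.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be at least 2")
    p1 = np.asarray(d_s_pos, dtype=float)
    p2 = np.asarray(d_n_pos, dtype=float)
    theta_rad = math.radians(theta_deg)
    if not 0.0 <= theta_deg < 180.0:
        raise ValueError("theta must lie in [0, 180) degrees")
    if theta_rad < 1e-9:
        t = np.linspace(0.0, 1.0, n_samples)[:, None]
        chord = p1 + t * (p2 - p1)
        return np.vstack([chord, chord[::-1]])
    pts, _ = _locus_samples(p1, p2, theta_rad, n_samples)
    return pts


def _locus_samples(p1, p2, theta_rad, n_per_arc):
    """Midpoint-rule samples of both arcs.

    Returns (points, weights): weights are fractions of the *total* locus arc
    length represented by each sample (they sum to 1 over both arcs).
    """
    radius, arcs = _locus_arcs(p1, p2, theta_rad)
    all_pts, all_w = [], []
    for center, a1, span in arcs:
        t = (np.arange(n_per_arc) + 0.5) / n_per_arc
        ang = a1 + span * t
        pts = center + radius * np.stack([np.cos(ang), np.sin(ang)], axis=1)
        all_pts.append(pts)
        all_w.append(np.full(n_per_arc, abs(span) / (2 * abs(span) * n_per_arc)))
    return np.vstack(all_pts), np.concatenate(all_w)


def subtended_angle_deg(points, p1, p2) -> np.ndarray:
    """Angle (degrees) under which the segment p1–p2 is seen from each
    point."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    v1 = np.asarray(p1, dtype=float) - pts
    v2 = np.asarray(p2, dtype=float) - pts
    cross = v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0]
    dot = np.sum(v1 * v2, axis=1)
    return np.degrees(np.arctan2(np.abs(cross), dot))


# ---------------------------------------------------------------------------
# Segment–voxel intersection (exact slab clipping)
# ---------------------------------------------------------------------------

def segment_voxel_lengths(grid: ImageGrid, p: np.ndarray, q: np.ndarray,
                          chunk: int = 8192):
    """Exact intersection lengths of line segments with every grid voxel.

    Clips each segment against the axis-aligned slab of every column and row
    (Liang–Barsky style) and combines the parametric intervals, which is
    exact for square voxels.

    Parameters
    ----------
    p, q : (M, 2) arrays
        Segment endpoints in cm.
    chunk : int
        Number of segments processed per vectorized batch.

    Returns
    -------
    seg_idx, vox_idx, lengths : 1-D arrays
        COO triplets of the strictly positive intersection lengths (cm).
    """
    p = np.atleast_2d(np.asarray(p, dtype=float))
    q = np.atleast_2d(np.asarray(q, dtype=float))
    xe = grid.x_edges
    ye = grid.y_edges[::-1]  # ascending
    out_seg, out_vox, out_len = [], [], []
    for lo in range(0, len(p), chunk):
        hi = min(lo + chunk, len(p))
        pp, qq = p[lo:hi], q[lo:hi]
        d = qq - pp
        seg_len = np.hypot(d[:, 0], d[:, 1])

        tx0, tx1 = _slab_intervals(pp[:, 0], d[:, 0], xe)        # (m, nx)
        ty0, ty1 = _slab_intervals(pp[:, 1], d[:, 1], ye)        # (m, ny)
        # voxel (row r, col c): ascending-y slab index is ny - 1 - r
        t0 = np.maximum(tx0[:, None, :], ty0[:, ::-1][:, :, None])
        t1 = np.minimum(tx1[:, None, :], ty1[:, ::-1][:, :, None])
        np.clip(t0, 0.0, 1.0, out=t0)
        np.clip(t1, 0.0, 1.0, out=t1)
        frac = t1 - t0
        lengths = frac * seg_len[:, None, None]
        s, r, c = np.nonzero(lengths > 1e-15)
        out_seg.append(s + lo)
        out_vox.append(r * grid.nx + c)
        out_len.append(lengths[s, r, c])
    return (np.concatenate(out_seg), np.concatenate(out_vox),
            np.concatenate(out_len))


def _slab_intervals(p0, d, edges):
    """Parametric [t_in, t_out] of segments within each slab of an ascending
    edge array; empty intervals are returned as t_in > t_out."""
    m, n = len(p0), len(edges) - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        t_edges = (edges[None, :] - p0[:, None]) / d[:, None]
    t0 = np.minimum(t_edges[:, :-1], t_edges[:, 1:])
    t1 = np.maximum(t_edges[:, :-1], t_edges[:, 1:])
    # degenerate (axis-parallel) segments: inside slab -> all t, else empty;
    # half-open slabs so a segment lying exactly on a shared edge is
    # assigned to one neighbor only
    par = np.abs(d) < 1e-300
    if np.any(par):
        inside = (p0[:, None] >= edges[None, :-1]) & (p0[:, None] < edges[None, 1:])
        t0 = np.where(par[:, None], np.where(inside, -np.inf, np.inf), t0)
        t1 = np.where(par[:, None], np.where(inside, np.inf, -np.inf), t1)
    return t0, t1
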