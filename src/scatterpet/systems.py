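"""Sparse system quantities for scatter and trues measurements.

The scatter system holds two rank-3 sparse quantities, flattened over their
(SOR, scattering-voxel) support:

* ``B`` with entries b[i][s][e] — sensitivity of SOR i to activity in voxel e
  via a scattering event in voxel s, disregarding attenuation.  In the
  default *geometric* weighting, b is the arc-length fraction of the SOR
  locus falling into s times the intersection length of the emission segment
  (scattering point → nonscattered detector) with e.
* ``K`` with entries k[i][s][t] — effective intersection length (cm) of the
  broken line of response d_n → x_s → d_s with the attenuating voxel t,
  averaged over the locus samples inside s.  The ratio of attenuation
  coefficients on the low-energy leg is a hook (``mu_ratio``) and defaults
  to 1 (energy-independent attenuation).

Both are stored as CSR matrices with one row per broken LOR (a retained
(SOR, s) pair); ``pair_sor`` and ``pair_voxel`` map rows back to the SOR and
scattering-voxel axes.  Attenuation is applied along the full broken LOR
regardless of the emission position (emission-independence of the effective
attenuation lengths), and k[i][s][t] is zero for scattering voxels s that are
geometrically incompatible with the SOR — conventions that make the support
of K over (i, s) identical to that of B.

The trues system is the usual unattenuated line-integral matrix U over lines
of response (unordered detector pairs).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace

import numpy as np
import scipy.sparse as sp

from .geometry import (
    E0_KEV,
    MIN_SCATTER_ENERGY_KEV,
    EnergyBinning,
    ImageGrid,
    ScannerGeometry,
    _locus_samples,
    scattering_angle_from_energy,
    segment_voxel_lengths,
)

__all__ = [
    "ScatterSystem",
    "TruesSystem",
    "build_scatter_system",
    "build_trues_system",
    "build_A_lambda",
    "geometric_density",
    "toy_scatter_system",
    "toy_trues_system",
]


@dataclass
class ScatterSystem:
    """Sparse scatter forward-model quantities on a fixed SOR enumeration.

    ``sor_ds``, ``sor_dn``, ``sor_bin`` give the (d_s, d_n, energy-bin)
    tuple of each retained SOR in the fixed, documented enumeration order:
    d_s-major, then d_n, then energy bin, with SORs whose locus has no
    in-grid scattering voxel dropped (``n_dropped`` counts them;
    ``n_candidates`` is the pre-drop enumeration size and is the SOR-axis
    logical dimension used for density bookkeeping).
    """

    scanner: ScannerGeometry
    grid: ImageGrid
    binning: EnergyBinning
    sor_ds: np.ndarray
    sor_dn: np.ndarray
    sor_bin: np.ndarray
    pair_sor: np.ndarray     # row -> SOR index, len n_pairs
    pair_voxel: np.ndarray   # row -> scattering voxel s, len n_pairs
    B: sp.csr_matrix         # (n_pairs, n_voxels), emission axis
    K: sp.csr_matrix         # (n_pairs, n_voxels), transmission axis
    n_candidates: int
    n_dropped: int
    weight_mode: str = "geometric"
    min_pair_separation_deg: float = 45.0

    @property
    def n_sors(self) -> int:
        return len(self.sor_ds)

    @property
    def n_pairs(self) -> int:
        return len(self.pair_sor)

    @property
    def n_voxels(self) -> int:
        return self.grid.n_voxels

    def scaled(self, factor: float) -> "ScatterSystem":
        """Same system with every length multiplied by ``factor``.

        B carries one intersection length (its arc weight is a dimensionless
        fraction), K is a length, so both scale linearly; the sparsity
        pattern is unchanged.  Equivalent to rebuilding at
        ``scale_factor * factor``.
        """
        return replace(
            self,
            scanner=self.scanner.with_scale(self.scanner.scale_factor * factor),
            grid=self.grid.with_voxel_cm(self.grid.voxel_cm * factor),
            B=(self.B * factor).tocsr(),
            K=(self.K * factor).tocsr(),
        )

    def sor_aggregator(self) -> sp.csr_matrix:
        """(n_sors, n_pairs) 0/1 matrix summing broken-LOR rows per SOR."""
        return sp.csr_matrix(
            (np.ones(self.n_pairs), (self.pair_sor, np.arange(self.n_pairs))),
            shape=(self.n_sors, self.n_pairs),
        )

    def density_K(self) -> float:
        """Geometrical density (%) of K relative to its logical dimensions
        (candidate SORs × voxels × voxels)."""
        dims = self.n_candidates * self.n_voxels * self.n_voxels
        return 100.0 * self.K.nnz / dims

    def density_A(self, lam: np.ndarray) -> float:
        """Geometrical density (%) of A_λ for the given activity image."""
        a = build_A_lambda(self, lam)
        dims = self.n_candidates * self.n_voxels
        return 100.0 * a.nnz / dims

    # -- serialization -----------------------------------------------------

    def save(self, path) -> None:
        """Save as an ``.npz`` archive of coordinate-format triplets plus
        JSON metadata."""
        bc, kc = self.B.tocoo(), self.K.tocoo()
        meta = {
            "version": 1,
            "scanner": [self.scanner.n_detectors, self.scanner.ring_radius_cm,
                        self.scanner.scale_factor],
            "grid": [self.grid.nx, self.grid.ny, self.grid.voxel_cm],
            "n_bins": self.binning.n_bins,
            "n_candidates": self.n_candidates,
            "n_dropped": self.n_dropped,
            "weight_mode": self.weight_mode,
            "min_pair_separation_deg": self.min_pair_separation_deg,
            "enumeration": "d_s-major, then d_n, then energy bin; "
                           "empty SORs dropped",
        }
        np.savez_compressed(
            path, meta=json.dumps(meta),
            sor_ds=self.sor_ds, sor_dn=self.sor_dn, sor_bin=self.sor_bin,
            pair_sor=self.pair_sor, pair_voxel=self.pair_voxel,
            b_row=bc.row, b_col=bc.col, b_val=bc.data,
            k_row=kc.row, k_col=kc.col, k_val=kc.data,
        )

    @classmethod
    def load(cls, path) -> "ScatterSystem":
        with np.load(path, allow_pickle=False) as f:
            meta = json.loads(str(f["meta"]))
            n_pairs = len(f["pair_sor"])
            n_vox = meta["grid"][0] * meta["grid"][1]
            B = sp.csr_matrix((f["b_val"], (f["b_row"], f["b_col"])),
                              shape=(n_pairs, n_vox))
            K = sp.csr_matrix((f["k_val"], (f["k_row"], f["k_col"])),
                              shape=(n_pairs, n_vox))
            return cls(
                scanner=ScannerGeometry(*[t(v) for t, v in
                                          zip((int, float, float), meta["scanner"])]),
                grid=ImageGrid(int(meta["grid"][0]), int(meta["grid"][1]),
                               float(meta["grid"][2])),
                binning=EnergyBinning(meta["n_bins"]),
                sor_ds=f["sor_ds"], sor_dn=f["sor_dn"], sor_bin=f["sor_bin"],
                pair_sor=f["pair_sor"], pair_voxel=f["pair_voxel"],
                B=B, K=K,
                n_candidates=meta["n_candidates"], n_dropped=meta["n_dropped"],
                weight_mode=meta["weight_mode"],
                min_pair_separation_deg=meta["min_pair_separation_deg"],
            )


@dataclass
class TruesSystem:
    """Unattenuated line-integral system over LORs (unordered detector
    pairs): u[l][j] is the intersection length (cm) of the chord with voxel
    j."""

    scanner: ScannerGeometry
    grid: ImageGrid
    lor_d1: np.ndarray
    lor_d2: np.ndarray
    U: sp.csr_matrix   # (n_lors, n_voxels)
    min_pair_separation_deg: float = 45.0

    @property
    def n_lors(self) -> int:
        return len(self.lor_d1)

    def scaled(self, factor: float) -> "TruesSystem":
        return replace(
            self,
            scanner=self.scanner.with_scale(self.scanner.scale_factor * factor),
            grid=self.grid.with_voxel_cm(self.grid.voxel_cm * factor),
            U=(self.U * factor).tocsr(),
        )


def _klein_nishina(theta_rad: float) -> float:
    """Klein–Nishina differential cross-section (unit classical-electron-
    radius units) for an incident 511 keV photon (E0 = m_e c²)."""
    ratio = 1.0 / (2.0 - math.cos(theta_rad))  # E' / E0
    return 0.5 * ratio ** 2 * (ratio + 1.0 / ratio - math.sin(theta_rad) ** 2)


def bin_sub_angles(binning: EnergyBinning, k: int, baseline: float,
                   voxel_cm: float, max_angles: int = 12):
    """Sub-angle quadrature of an energy bin's scattering-angle range.

    An energy bin collects single scatter over a whole interval of Compton
    angles, so its 2-D SOR is the annular band between the bin-edge arcs,
    not a single curve.  The band is sampled at the arcs of the midpoint
    energies of ``n`` equal sub-intervals of the bin's effective energy
    range, with ``n`` chosen so that adjacent arcs are at most one voxel
    apart at the chord midpoint (arc bulge (b/2)·tan(θ/2)), between 2 and
    ``max_angles``.

    Returns (energies_keV, angles_rad, weights); weights are uniform in
    energy and sum to 1.
    """
    e_hi = min(binning.bin_edges[k], E0_KEV)
    e_lo = max(binning.bin_edges[k + 1], MIN_SCATTER_ENERGY_KEV)
    if e_hi <= MIN_SCATTER_ENERGY_KEV:
        raise ValueError(f"bin {k} is not reachable by single scatter")
    th_small = math.radians(scattering_angle_from_energy(e_hi))
    th_large = math.radians(scattering_angle_from_energy(e_lo))
    bulge = lambda t: 0.5 * baseline * math.tan(min(t, math.pi - 1e-9) / 2)
    span = abs(bulge(th_large) - bulge(th_small))
    n = int(np.clip(math.ceil(span / voxel_cm) + 1, 2, max_angles))
    mids = e_hi - (np.arange(n) + 0.5) * (e_hi - e_lo) / n
    thetas = np.array([math.radians(scattering_angle_from_energy(e))
                       for e in mids])
    return mids, thetas, np.full(n, 1.0 / n)


def _ordered_pairs(scanner: ScannerGeometry, min_sep_deg: float):
    n = scanner.n_detectors
    ds, dn = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    ds, dn = ds.ravel(), dn.ravel()
    keep = (ds != dn) & (scanner.pair_separation_deg(ds, dn) >= min_sep_deg - 1e-9)
    return ds[keep], dn[keep]


def build_scatter_system(
    scanner: ScannerGeometry,
    grid: ImageGrid,
    binning: EnergyBinning,
    weight_mode: str = "geometric",
    min_pair_separation_deg: float = 45.0,
    arc_samples_per_voxel: float = 8.0,
    mu_ratio: float = 1.0,
    max_samples_per_arc: int = 2048,
    max_angles_per_bin: int = 12,
) -> ScatterSystem:
    """Construct the sparse scatter system for every SOR.

    SOR candidates are all ordered detector pairs (d_s, d_n) with angular
    separation at least ``min_pair_separation_deg``, crossed with the
    effective energy bins.  Each SOR's scattering support is the annular
    band swept by the locus arcs over the bin's scattering-angle range (see
    :func:`bin_sub_angles`); every sub-angle arc is sampled at
    ``arc_samples_per_voxel`` midpoints per voxel width.  Samples inside the
    grid are binned into scattering voxels s, and for each broken LOR
    d_n → x_s → d_s the intersection lengths with all voxels are accumulated
    into K (band-weighted average over the samples in s, the low-energy leg
    scaled by ``mu_ratio``) and, for the emission segment x_s → d_n, into B
    (band weight times length).  SORs whose band misses the grid entirely
    are dropped from the enumeration.

    In ``weight_mode="physics"`` the per-sub-angle Klein–Nishina
    cross-section, the polar-angle-to-energy Jacobian, and the sub-bin
    width additionally scale B; ``"geometric"`` keeps unit physical
    constants.
    """
    if weight_mode not in ("geometric", "physics"):
        raise ValueError("weight_mode must be 'geometric' or 'physics'")
    if not grid.fits_inside(scanner.radius_cm):
        raise ValueError("grid does not fit inside the detector ring")

    # build in voxel units (scale-free): all geometric decisions depend only
    # on the ring-radius-to-voxel ratio, so building at any scale factor is
    # exactly the unit-scale build with every length multiplied back
    unit = grid.voxel_cm
    out_scanner, out_grid = scanner, grid
    scanner = ScannerGeometry(scanner.n_detectors, scanner.radius_cm / unit)
    grid = ImageGrid(grid.nx, grid.ny, 1.0)

    pos = scanner.detector_positions
    ds_arr, dn_arr = _ordered_pairs(scanner, min_pair_separation_deg)
    eff_bins = binning.effective_bins
    n_pairs_geom = len(ds_arr)
    n_candidates = n_pairs_geom * len(eff_bins)
    if n_candidates == 0:
        raise ValueError("no SOR candidates for this geometry")

    # enumeration is d_s-major, then d_n, then energy bin; clipping is
    # batched per energy bin and rows are re-sorted into enumeration order
    # afterwards
    bin_pos = {int(kb): idx for idx, kb in enumerate(eff_bins)}
    nb = len(eff_bins)

    g_enum_parts, g_svox_parts = [], []
    b_rows, b_cols, b_vals = [], [], []
    k_rows, k_cols, k_vals = [], [], []
    group_offset = 0

    for kb in eff_bins:
        # sample the bin's annular band for every geometric pair
        pts_list, w_list, wb_list, pid_list = [], [], [], []
        for p_idx in range(n_pairs_geom):
            p1 = pos[ds_arr[p_idx]]
            p2 = pos[dn_arr[p_idx]]
            b = float(np.hypot(*(p2 - p1)))
            energies, thetas, e_weights = bin_sub_angles(
                binning, int(kb), b, grid.voxel_cm,
                max_angles=max_angles_per_bin)
            for theta, e_w in zip(thetas, e_weights):
                radius = b / (2.0 * math.sin(theta))
                arc_len = 2.0 * theta * radius  # per arc
                n_per_arc = int(np.clip(
                    math.ceil(arc_len / grid.voxel_cm
                              * arc_samples_per_voxel),
                    8, max_samples_per_arc))
                pts, w = _locus_samples(p1, p2, theta, n_per_arc)
                inside = grid.contains(pts)
                if not np.any(inside):
                    continue
                phys_w = 1.0
                if weight_mode == "physics":
                    jac = (2.0 - math.cos(theta)) ** 2 \
                        / (E0_KEV * math.sin(theta))
                    phys_w = _klein_nishina(theta) * jac \
                        * (binning.bin_width_kev * e_w)
                pts_list.append(pts[inside])
                w_list.append(e_w * w[inside])
                wb_list.append(phys_w * e_w * w[inside])
                pid_list.append(np.full(int(inside.sum()), p_idx,
                                        dtype=np.int64))
        if not pts_list:
            continue
        pts = np.vstack(pts_list)
        w = np.concatenate(w_list)
        wb = np.concatenate(wb_list)
        pid = np.concatenate(pid_list)
        svox = grid.point_to_voxel(pts)

        # group samples into broken LORs (pair, scattering voxel)
        group_key = pid * grid.n_voxels + svox
        uniq, g_idx = np.unique(group_key, return_inverse=True)
        n_groups = len(uniq)
        g_pair = uniq // grid.n_voxels
        g_svox = uniq % grid.n_voxels
        w_group = np.bincount(g_idx, weights=w, minlength=n_groups)

        det_s = pos[ds_arr[pid]]
        det_n = pos[dn_arr[pid]]

        # low-energy leg x_s -> d_s and high-energy leg x_s -> d_n
        seg_s = segment_voxel_lengths(grid, pts, det_s)
        seg_n = segment_voxel_lengths(grid, pts, det_n)

        # K: arc-weighted mean over samples of (leg_n + mu_ratio * leg_s)
        rows = np.concatenate([g_idx[seg_n[0]], g_idx[seg_s[0]]])
        cols = np.concatenate([seg_n[1], seg_s[1]])
        vals = np.concatenate([w[seg_n[0]] * seg_n[2],
                               mu_ratio * w[seg_s[0]] * seg_s[2]])
        K_bin = sp.csr_matrix((vals, (rows, cols)),
                              shape=(n_groups, grid.n_voxels))
        K_bin = sp.diags(1.0 / w_group) @ K_bin

        kc = K_bin.tocoo()
        k_rows.append(kc.row.astype(np.int64) + group_offset)
        k_cols.append(kc.col.astype(np.int64))
        k_vals.append(kc.data)

        # B: band weight times emission-segment length (x_s -> d_n)
        b_rows.append(g_idx[seg_n[0]].astype(np.int64) + group_offset)
        b_cols.append(seg_n[1].astype(np.int64))
        b_vals.append(wb[seg_n[0]] * seg_n[2])

        g_enum_parts.append(g_pair.astype(np.int64) * nb + bin_pos[int(kb)])
        g_svox_parts.append(g_svox.astype(np.int64))
        group_offset += n_groups

    if group_offset == 0:
        raise ValueError("no SOR locus intersects the image grid")

    g_enum = np.concatenate(g_enum_parts)
    g_svox = np.concatenate(g_svox_parts)
    n_groups_total = group_offset

    order = np.lexsort((g_svox, g_enum))
    rank = np.empty(n_groups_total, dtype=np.int64)
    rank[order] = np.arange(n_groups_total)

    uniq_enum, pair_sor = np.unique(g_enum[order], return_inverse=True)
    pair_voxel = g_svox[order]

    B = sp.csr_matrix(
        (np.concatenate(b_vals),
         (rank[np.concatenate(b_rows)], np.concatenate(b_cols))),
        shape=(n_groups_total, grid.n_voxels))
    K = sp.csr_matrix(
        (np.concatenate(k_vals),
         (rank[np.concatenate(k_rows)], np.concatenate(k_cols))),
        shape=(n_groups_total, grid.n_voxels))

    p_of_sor = uniq_enum // nb
    b_of_sor = np.asarray(eff_bins, dtype=np.int64)[uniq_enum % nb]

    B = (B * unit).tocsr()
    K = (K * unit).tocsr()

    system = ScatterSystem(
        scanner=out_scanner, grid=out_grid, binning=binning,
        sor_ds=ds_arr[p_of_sor].astype(np.int64),
        sor_dn=dn_arr[p_of_sor].astype(np.int64),
        sor_bin=b_of_sor,
        pair_sor=pair_sor.astype(np.int64),
        pair_voxel=pair_voxel,
        B=B, K=K,
        n_candidates=n_candidates,
        n_dropped=n_candidates - len(uniq_enum),
        weight_mode=weight_mode,
        min_pair_separation_deg=min_pair_separation_deg,
    )
    _ensure_self_attenuation(system)
    return system


def _ensure_self_attenuation(system: ScatterSystem) -> None:
    """A scattering voxel is always on the broken LOR through it; guarantee
    k[i][s][s] > 0 on the full support (guards against samples exactly on a
    voxel boundary)."""
    rows = np.arange(system.n_pairs)
    ind = sp.csr_matrix((np.ones(system.n_pairs), (rows, system.pair_voxel)),
                        shape=system.K.shape)
    diag = np.asarray(system.K.multiply(ind).sum(axis=1)).ravel()
    missing = np.nonzero(diag <= 0)[0]
    if len(missing):
        eps = 1e-9 * system.grid.voxel_cm
        add = sp.csr_matrix(
            (np.full(len(missing), eps),
             (missing, system.pair_voxel[missing])), shape=system.K.shape)
        system.K = (system.K + add).tocsr()


def build_A_lambda(system: ScatterSystem, lam: np.ndarray) -> sp.csr_matrix:
    """Contract B with an activity image: a[i][s] = Σ_e b[i][s][e] λ[e],
    returned as a sparse (n_sors, n_voxels) matrix over (SOR, scattering
    voxel).  The support never exceeds the (i, s) support of B."""
    lam = _check_image(lam, system.n_voxels, "lambda")
    vals = system.B @ lam
    A = sp.csr_matrix(
        (vals, (system.pair_sor, system.pair_voxel)),
        shape=(system.n_sors, system.n_voxels),
    )
    A.eliminate_zeros()
    return A


def a_pair_values(system: ScatterSystem, lam: np.ndarray) -> np.ndarray:
    """Per-broken-LOR values of A_λ, aligned with the system's pair rows."""
    lam = _check_image(lam, system.n_voxels, "lambda")
    return system.B @ lam


def build_trues_system(
    scanner: ScannerGeometry,
    grid: ImageGrid,
    min_pair_separation_deg: float = 45.0,
) -> TruesSystem:
    """Exact line-length LOR projector: u[l][j] is the chord–voxel
    intersection length, computed by exact slab clipping."""
    if not grid.fits_inside(scanner.radius_cm):
        raise ValueError("grid does not fit inside the detector ring")
    # scale-free build in voxel units, lengths multiplied back (see
    # build_scatter_system)
    unit = grid.voxel_cm
    norm_scanner = ScannerGeometry(scanner.n_detectors,
                                   scanner.radius_cm / unit)
    norm_grid = ImageGrid(grid.nx, grid.ny, 1.0)
    ds, dn = _ordered_pairs(norm_scanner, min_pair_separation_deg)
    keep = ds < dn
    d1, d2 = ds[keep], dn[keep]
    pos = norm_scanner.detector_positions
    seg, vox, lengths = segment_voxel_lengths(norm_grid, pos[d1], pos[d2])
    U = sp.csr_matrix((lengths * unit, (seg, vox)),
                      shape=(len(d1), grid.n_voxels))
    return TruesSystem(scanner=scanner, grid=grid, lor_d1=d1, lor_d2=d2, U=U,
                       min_pair_separation_deg=min_pair_separation_deg)


def geometric_density(quantity) -> float:
    """Percentage of structurally nonzero entries of a sparse (or dense)
    array relative to the product of its logical dimensions."""
    if sp.issparse(quantity):
        dims = quantity.shape[0] * quantity.shape[1]
        return 100.0 * quantity.nnz / dims
    arr = np.asarray(quantity)
    return 100.0 * np.count_nonzero(arr) / arr.size


def _check_image(x, n, name):
    x = np.asarray(x, dtype=float).ravel()
    if len(x) != n:
        raise ValueError(f"{name} has length {len(x)}, expected {n}")
    return x


# ---------------------------------------------------------------------------
# single-voxel toys
# ---------------------------------------------------------------------------

def toy_scatter_system(b: float = 1.0, k: float = 1.0,
                       voxel_cm: float = 1.0) -> ScatterSystem:
    """Single-voxel, single-SOR toy scatter system with b[0][0][0] = b and
    k[0][0][0] = k, used in closed-form analyses of the nonlinear scatter
    model."""
    scanner = ScannerGeometry(n_detectors=2, ring_radius_cm=voxel_cm)
    grid = ImageGrid(1, 1, voxel_cm)
    return ScatterSystem(
        scanner=scanner, grid=grid, binning=EnergyBinning(1),
        sor_ds=np.array([0]), sor_dn=np.array([1]), sor_bin=np.array([0]),
        pair_sor=np.array([0]), pair_voxel=np.array([0]),
        B=sp.csr_matrix(np.array([[b]])),
        K=sp.csr_matrix(np.array([[k]])),
        n_candidates=1, n_dropped=0,
    )


def toy_trues_system(u: float = 1.0, voxel_cm: float = 1.0) -> TruesSystem:
    """Single-voxel, single-LOR toy trues system with u[0][0] = u."""
    scanner = ScannerGeometry(n_detectors=2, ring_radius_cm=voxel_cm)
    grid = ImageGrid(1, 1, voxel_cm)
    return TruesSystem(scanner=scanner, grid=grid,
                       lor_d1=np.array([0]), lor_d2=np.array([1]),
                       U=sp.csr_matrix(np.array([[u]])))
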