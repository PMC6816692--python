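"""Emission-side building blocks: trues-MLEM/OSEM, trues-MLTR, and
scatter-MLEM.

These three updates, together with the scatter-to-attenuation algorithms,
are the components from which the joint activity–attenuation schedules are
assembled:

* trues-MLEM updates the activity λ from nonscattered data through the
  attenuated LOR projector Ũ = U ⊙ rows exp(−Uρ); the ordered-subsets
  (OSEM) variant restricts the rows per sub-update.
* trues-MLTR updates the attenuation ρ from nonscattered data with the
  relaxed additive transmission update
  ρ_new = ρ + η (1 − (Uᵀz) ⊘ (Uᵀz̄)), using unattenuated back-projections
  on both sides, followed by a clamp at zero.
* scatter-MLEM updates λ from scattered data: with ρ fixed the scatter
  model is linear in λ (ȳ = Ã_ρ λ with ã_i[e] = Σ_s ρ[s] b_i[s,e]
  exp(−Σ_t k_i[s,t] ρ[t])), so the regular MLEM update applies and the
  scatter likelihood at fixed ρ is nondecreasing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .forward import attenuation_factors, data_ratio
from .systems import ScatterSystem, TruesSystem, _check_image

__all__ = [
    "SubsetPartition",
    "partition_subsets",
    "trues_mlem_update",
    "trues_mltr_update",
    "scatter_mlem_update",
    "scatter_mlem_matrix_values",
]


@dataclass(frozen=True)
class SubsetPartition:
    """Interleaved partition of data rows into ordered subsets."""

    n_subsets: int
    assignment: np.ndarray

    def rows(self, subset: int) -> np.ndarray:
        return np.nonzero(self.assignment == subset)[0]

    def mask(self, subset: int) -> np.ndarray:
        return self.assignment == subset


def partition_subsets(n_rows: int, n_subsets: int,
                      angular_key: np.ndarray | None = None) -> SubsetPartition:
    """Partition rows into ``n_subsets`` interleaved subsets by angular key
    modulo n_subsets (balanced angular coverage per subset).

    With no key, plain row-index interleaving is used.
    """
    if n_subsets < 1:
        raise ValueError("n_subsets must be at least 1")
    if n_subsets > n_rows:
        raise ValueError("more subsets than rows")
    key = np.arange(n_rows) if angular_key is None \
        else np.asarray(angular_key, dtype=np.int64)
    if len(key) != n_rows:
        raise ValueError("angular_key length must equal n_rows")
    return SubsetPartition(n_subsets=n_subsets,
                           assignment=(key % n_subsets).astype(np.int64))


def trues_mlem_update(trues: TruesSystem, lam, rho, z,
                      rows: np.ndarray | None = None) -> np.ndarray:
    """One trues-MLEM (or, with ``rows``, OSEM sub-) update of λ:
    λ_new = λ ⊙ (Ũᵀ(z ⊘ z̄)) ⊘ (Ũᵀ1), with subset-restricted sensitivity
    in the OSEM variant."""
    lam = _check_image(lam, trues.U.shape[1], "lambda")
    rho = _check_image(rho, trues.U.shape[1], "rho")
    z = np.asarray(z, dtype=float).ravel()
    U = trues.U if rows is None else trues.U[rows]
    z_r = z if rows is None else z[rows]
    att = np.exp(-(U @ rho))
    zbar = (U @ lam) * att
    ratio = data_ratio(z_r, zbar)
    num = U.T @ (att * ratio)
    den = U.T @ att
    frozen = (den <= 0) & (lam > 0)
    if np.any(frozen):
        warnings.warn(f"{int(frozen.sum())} voxels have zero sensitivity; "
                      "frozen", RuntimeWarning)
    return np.where(den > 0, lam * num / np.where(den > 0, den, 1.0), lam)


def trues_mltr_update(trues: TruesSystem, rho, lam, z,
                      eta: float = 0.03) -> np.ndarray:
    """One relaxed trues-MLTR update of ρ:
    ρ_new = max(0, ρ + η (1 − (Uᵀz) ⊘ (Uᵀz̄))).

    Voxels whose back-projected expectation Uᵀz̄ vanishes are skipped (with
    a warning when they carry positive density).
    """
    lam = _check_image(lam, trues.U.shape[1], "lambda")
    rho = _check_image(rho, trues.U.shape[1], "rho")
    z = np.asarray(z, dtype=float).ravel()
    zbar = (trues.U @ lam) * np.exp(-(trues.U @ rho))
    num = trues.U.T @ z
    den = trues.U.T @ zbar
    ok = den > 0
    skipped = ~ok & (rho > 0)
    if np.any(skipped):
        warnings.warn(f"{int(skipped.sum())} voxels skipped: zero "
                      "back-projected expectation", RuntimeWarning)
    update = np.where(ok, eta * (1.0 - num / np.where(ok, den, 1.0)), 0.0)
    return np.maximum(rho + update, 0.0)


def scatter_mlem_matrix_values(system: ScatterSystem, rho) -> np.ndarray:
    """Per-broken-LOR weights ρ[s]·exp(−Σ_t k[i][s][t] ρ[t]) whose
    contraction with B over the pair rows yields Ã_ρ
    (ã_i[e] = Σ_s ρ[s] b_i[s,e] exp(−Σ_t k_i[s,t] ρ[t]))."""
    rho = _check_image(rho, system.n_voxels, "rho")
    return rho[system.pair_voxel] * attenuation_factors(system, rho)


def scatter_mlem_update(system: ScatterSystem, lam, rho, y) -> np.ndarray:
    """One scatter-MLEM update of λ at fixed ρ:
    λ_new = λ ⊙ (Ã_ρᵀ(y ⊘ ȳ)) ⊘ (Ã_ρᵀ1)."""
    lam = _check_image(lam, system.n_voxels, "lambda")
    y = np.asarray(y, dtype=float).ravel()
    w = scatter_mlem_matrix_values(system, rho)
    ybar = np.bincount(system.pair_sor, weights=w * (system.B @ lam),
                       minlength=system.n_sors)
    ratio = data_ratio(y, ybar)
    num = system.B.T @ (w * ratio[system.pair_sor])
    den = system.B.T @ w
    frozen = (den <= 0) & (lam > 0)
    if np.any(frozen):
        warnings.warn(f"{int(frozen.sum())} voxels have zero sensitivity; "
                      "frozen", RuntimeWarning)
    return np.where(den > 0, lam * num / np.where(den > 0, den, 1.0), lam)
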