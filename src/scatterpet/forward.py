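"""Scatter and trues forward models, Poisson log-likelihood, and gradients.

The nonlinear scatter model for SOR i is

    ybar_i = sum_s a_i[s] * exp(-sum_t k_i[s, t] rho[t]) * rho[s],

with a_i[s] = sum_e b_i[s, e] lambda[e].  The electron density rho enters
twice — as the scatterer density (linear factor) and in the attenuation
exponent — which makes the model nonlinear in rho.  Freezing the exponent at
an estimate rho_est yields the linearization ybar' = A~(rho_est) rho.

The trues (nonscattered) model is the attenuated line-integral model
zbar = (U lambda) * exp(-U rho).

All expected-count vectors are noise-free Poisson means; the log-likelihood
omits the data-factorial constant.
"""

from __future__ import annotations

import warnings

import numpy as np
import scipy.sparse as sp

from .systems import ScatterSystem, TruesSystem, _check_image, a_pair_values

__all__ = [
    "attenuation_factors",
    "attenuated_scatter_matrix",
    "forward_scatter",
    "forward_scatter_linearized",
    "forward_trues",
    "poisson_loglik",
    "scatter_loglik_gradient",
    "scatter_data_gradient",
]

#: Floor applied to expected counts inside update ratios only (never in
#: reported log-likelihoods); noise-free simulation makes exact 0/0 bins
#: common.
RATIO_FLOOR = 1e-15


def _rho_ok(rho, n):
    rho = _check_image(rho, n, "rho")
    if np.any(rho < 0):
        raise ValueError("rho must be nonnegative")
    return rho


def attenuation_factors(system: ScatterSystem, rho: np.ndarray,
                        rows=None) -> np.ndarray:
    """exp(−Σ_t k[i][s][t] ρ[t]) per broken-LOR row.

    The radiological paths K ρ are sparse matrix-vector products over the
    stored support, so the result has one entry per stored broken LOR and no
    dense (SOR × voxel) intermediate is ever formed; the elementwise
    combination with A_λ (``a ⊙ (expm1(−Kρ)) + a``) therefore preserves
    sparsity by construction.
    """
    rho = _rho_ok(rho, system.n_voxels)
    K = system.K if rows is None else system.K[rows]
    return np.expm1(-(K @ rho)) + 1.0


def attenuated_scatter_matrix(system: ScatterSystem, lam_or_a, rho,
                              as_matrix: bool = True):
    """Attenuated scatter system matrix Ã = A_λ ⊙ exp(−Kρ).

    ``lam_or_a`` is either an activity image (length n_voxels) or
    precomputed per-pair A_λ values (length n_pairs).  Returns a sparse
    (n_sors, n_voxels) matrix whose pattern is contained in that of A_λ,
    or the per-pair value vector if ``as_matrix`` is False.
    """
    a_vals = _as_pair_values(system, lam_or_a)
    att = attenuation_factors(system, rho)
    vals = a_vals * att
    if not as_matrix:
        return vals
    return sp.csr_matrix((vals, (system.pair_sor, system.pair_voxel)),
                         shape=(system.n_sors, system.n_voxels))


def _as_pair_values(system: ScatterSystem, lam_or_a) -> np.ndarray:
    x = np.asarray(lam_or_a, dtype=float).ravel()
    if len(x) == system.n_pairs and system.n_pairs != system.n_voxels:
        return x
    if len(x) == system.n_voxels:
        return a_pair_values(system, x)
    if len(x) == system.n_pairs:
        return x
    raise ValueError("expected an activity image or per-pair A_lambda values")


def forward_scatter(system: ScatterSystem, lam_or_a, rho) -> np.ndarray:
    """Expected scatter data ȳ of the nonlinear model, one entry per SOR."""
    rho = _rho_ok(rho, system.n_voxels)
    atil = attenuated_scatter_matrix(system, lam_or_a, rho, as_matrix=False)
    return np.bincount(system.pair_sor, weights=atil * rho[system.pair_voxel],
                       minlength=system.n_sors)


def forward_scatter_linearized(system: ScatterSystem, lam_or_a, rho_est,
                               rho) -> np.ndarray:
    """Linearized expected scatter data ȳ′ = Ã(ρ_est) ρ: linear in ρ and
    equal to the nonlinear model when ρ_est = ρ."""
    rho = _rho_ok(rho, system.n_voxels)
    atil = attenuated_scatter_matrix(system, lam_or_a, rho_est,
                                     as_matrix=False)
    return np.bincount(system.pair_sor, weights=atil * rho[system.pair_voxel],
                       minlength=system.n_sors)


def forward_trues(trues: TruesSystem, lam, rho) -> np.ndarray:
    """Expected trues data z̄ = (Uλ) ⊙ exp(−Uρ), one entry per LOR."""
    lam = _check_image(lam, trues.U.shape[1], "lambda")
    rho = _rho_ok(rho, trues.U.shape[1])
    return (trues.U @ lam) * np.exp(-(trues.U @ rho))


def poisson_loglik(data, expected) -> float:
    """Poisson log-likelihood Σ_i (y_i log ȳ_i − ȳ_i), without the
    log(y!) constant.

    Bins with y = ȳ = 0 contribute zero.  Bins with y > 0 but ȳ = 0 yield
    −inf (with a warning): the model assigns zero probability to observed
    counts.
    """
    y = np.asarray(data, dtype=float).ravel()
    ybar = np.asarray(expected, dtype=float).ravel()
    if y.shape != ybar.shape:
        raise ValueError("data and expected must have the same length")
    pos = y > 0
    if np.any(ybar[pos] == 0):
        warnings.warn("expected counts are zero where data is positive; "
                      "log-likelihood is -inf", RuntimeWarning)
        return float("-inf")
    ll = -float(np.sum(ybar))
    ll += float(np.sum(y[pos] * np.log(ybar[pos])))
    return ll


def data_ratio(y, ybar) -> np.ndarray:
    """y ⊘ ȳ with the 0/0 → 0 convention and an ε-floor on ȳ used only
    inside multiplicative/additive update ratios."""
    y = np.asarray(y, dtype=float)
    ybar = np.asarray(ybar, dtype=float)
    out = np.zeros_like(ybar)
    np.divide(y, np.maximum(ybar, RATIO_FLOOR), out=out,
              where=(y > 0) | (ybar > 0))
    return out


def scatter_data_gradient(system: ScatterSystem, lam_or_a, rho,
                          weights: np.ndarray) -> np.ndarray:
    """Weighted sum over SORs of the full data gradient:
    Σ_i w_i ∂ȳ_i/∂ρ_j, with

        ∂ȳ_i/∂ρ_j = ã_i[j] − Σ_s ρ[s] k_i[s, j] ã_i[s].

    The first (direct, scattering) term lives on the Ã support; the second
    (attenuation correction) term is assembled as ρᵀ acting over the
    scattering axis of K ⊙ (Ã ⊗ 1).
    """
    rho = _rho_ok(rho, system.n_voxels)
    atil = attenuated_scatter_matrix(system, lam_or_a, rho, as_matrix=False)
    w_pair = np.asarray(weights, dtype=float)[system.pair_sor]
    direct = np.bincount(system.pair_voxel, weights=atil * w_pair,
                         minlength=system.n_voxels)
    correction = system.K.T @ (rho[system.pair_voxel] * atil * w_pair)
    return direct - correction


def scatter_loglik_gradient(system: ScatterSystem, lam_or_a, rho, y,
                            mode: str = "full",
                            expected: np.ndarray | None = None) -> np.ndarray:
    """Gradient of the Poisson log-likelihood of the scatter data with
    respect to ρ.

    ``mode="full"`` differentiates the nonlinear model (double dependence of
    ȳ on ρ); ``mode="linearized"`` uses only the direct term
    ∂ȳ_i/∂ρ_j = ã_i[j], i.e. the gradient implied by the linearization.
    Both agree when K = 0.

    Raises if the model support is violated (ȳ_i = 0 with y_i > 0).
    """
    if mode not in ("full", "linearized"):
        raise ValueError("mode must be 'full' or 'linearized'")
    rho = _rho_ok(rho, system.n_voxels)
    y = np.asarray(y, dtype=float).ravel()
    ybar = forward_scatter(system, lam_or_a, rho) if expected is None \
        else np.asarray(expected, dtype=float)
    if np.any((ybar == 0) & (y > 0)):
        raise ValueError("model support violation: expected 0 where data > 0")
    coeff = data_ratio(y, ybar) - 1.0
    if mode == "full":
        return scatter_data_gradient(system, lam_or_a, rho, coeff)
    atil = attenuated_scatter_matrix(system, lam_or_a, rho, as_matrix=False)
    return np.bincount(system.pair_voxel,
                       weights=atil * coeff[system.pair_sor],
                       minlength=system.n_voxels)
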