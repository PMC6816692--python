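"""MLEM-OSL, MLGA, and the low-attenuation data-reduction criterion."""

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings, strategies as st

from scatterpet.forward import forward_scatter, poisson_loglik
from scatterpet.geometry import EnergyBinning, ImageGrid, ScannerGeometry
from scatterpet.s2a import (
    StepSizeSpec,
    low_attenuation_sor_mask,
    mlem_osl_update,
    mlga_update,
    reduce_scatter_data,
    run_s2a,
    tight_sor_critical_path_length,
)
from scatterpet.systems import ScatterSystem, toy_scatter_system

from conftest import scaled_case


def two_voxel_system():
    """Hand-checkable system: two SORs, voxel 0 scatters for SOR 0 only,
    voxel 1 for both."""
    scanner = ScannerGeometry(n_detectors=4, ring_radius_cm=5.0)
    grid = ImageGrid(2, 1, 1.0)
    return ScatterSystem(
        scanner=scanner, grid=grid, binning=EnergyBinning(1),
        sor_ds=np.array([0, 1]), sor_dn=np.array([2, 3]),
        sor_bin=np.array([0, 0]),
        pair_sor=np.array([0, 0, 1]), pair_voxel=np.array([0, 1, 1]),
        B=sp.csr_matrix(np.array([[0.7, 0.2],
                                  [0.1, 0.9],
                                  [0.0, 1.1]])),
        K=sp.csr_matrix(np.array([[0.8, 0.3],
                                  [0.2, 1.0],
                                  [0.0, 0.6]])),
        n_candidates=2, n_dropped=0,
    )


class TestFixedPoints:
    def test_mlem_osl_fixed_point_at_consistent_data(self, small_setup):
        s = small_setup["scatter"]
        lam, rho = small_setup["lam"], small_setup["rho"]
        y = forward_scatter(s, lam, rho)
        assert np.allclose(mlem_osl_update(s, lam, rho, y), rho, rtol=1e-12)

    @pytest.mark.parametrize("mode", ["mlem_like", "constant", "scaled"])
    def test_mlga_fixed_point_when_gradient_vanishes(self, small_setup, mode):
        s = small_setup["scatter"]
        lam, rho = small_setup["lam"], small_setup["rho"]
        y = forward_scatter(s, lam, rho)
        new = mlga_update(s, lam, rho, y, step=StepSizeSpec(mode, 0.5))
        assert np.allclose(new, rho, rtol=1e-10, atol=1e-14)


class TestSingleVoxelHighAttenuation:
    def test_mlem_osl_diverges_above_true_and_critical_density(self):
        # rho_n > rho_true > 1/k: MLEM-OSL moves away from the truth
        s = toy_scatter_system(b=1.0, k=1.0)
        lam = np.ones(1)
        y = forward_scatter(s, lam, np.array([2.0]))
        rho_n = np.array([2.5])
        rho_next = mlem_osl_update(s, lam, rho_n, y)
        assert rho_next[0] > rho_n[0]

    def test_mlga_moves_toward_likelihood_maximum(self):
        s = toy_scatter_system(b=1.0, k=1.0)
        lam = np.ones(1)
        y = forward_scatter(s, lam, np.array([2.0]))
        rho_n = np.array([2.5])
        rho_next = mlga_update(s, lam, rho_n, y, step=StepSizeSpec())
        # dense 1-D grid search of the likelihood on the high-attenuation
        # branch (rho > 1/k) where the iterate lives: maximum at rho = 2
        # (the low branch holds the second, equal-likelihood root)
        grid = np.linspace(1.01, 4.0, 3000)
        lls = [poisson_loglik(y, forward_scatter(s, lam, np.array([g])))
               for g in grid]
        best = grid[int(np.argmax(lls))]
        assert best == pytest.approx(2.0, abs=2e-3)
        assert abs(rho_next[0] - best) < abs(rho_n[0] - best)

    def test_full_gradient_sign_is_sign_of_one_minus_k_rho(self):
        # y -> 0 limit: gradient reduces to -dybar/drho... the *data*
        # gradient dybar/drho itself carries sign(1 - k rho)
        from scatterpet.forward import scatter_data_gradient
        s = toy_scatter_system(b=1.0, k=2.0)
        lam, w = np.ones(1), np.ones(1)
        for rho, sign in ((0.2, 1), (0.5, 0), (0.9, -1)):
            g = scatter_data_gradient(s, lam, np.array([rho]), w)[0]
            assert np.sign(round(g, 14)) == sign


def test_mlem_osl_matches_scalar_arithmetic_on_two_voxels():
    s = two_voxel_system()
    lam = np.array([1.0, 2.0])
    rho = np.array([0.4, 0.3])
    y = np.array([0.9, 0.5])
    B = np.asarray(s.B.todense())
    K = np.asarray(s.K.todense())
    a = B @ lam
    att = np.exp(-(K @ rho))
    atil = a * att                      # per broken LOR
    ybar = np.array([atil[0] * rho[0] + atil[1] * rho[1],
                     atil[2] * rho[1]])
    num0 = atil[0] * y[0] / ybar[0]
    num1 = atil[1] * y[0] / ybar[0] + atil[2] * y[1] / ybar[1]
    den0 = atil[0]
    den1 = atil[1] + atil[2]
    want = np.array([rho[0] * num0 / den0, rho[1] * num1 / den1])
    got = mlem_osl_update(s, lam, rho, y)
    assert np.allclose(got, want, rtol=1e-12)


def test_mlga_with_zero_K_and_unit_gamma_equals_mlem_osl(small_setup):
    from dataclasses import replace
    s = small_setup["scatter"]
    lam = small_setup["lam"]
    s0 = replace(s, K=sp.csr_matrix(s.K.shape))
    rho = small_setup["rho"]
    y = forward_scatter(s0, lam, rho) * 1.2
    got = mlga_update(s0, lam, rho, y, step=StepSizeSpec("mlem_like", 1.0))
    want = mlem_osl_update(s0, lam, rho, y)
    assert np.allclose(got, want, rtol=1e-12, atol=1e-15)


class TestNonnegativity:
    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_updates_preserve_nonnegativity(self, seed):
        rng = np.random.default_rng(seed)
        s = two_voxel_system()
        lam = rng.random(2) + 0.1
        rho = rng.random(2) * 3.0
        y = rng.random(2) * 2.0
        assert np.all(mlem_osl_update(s, lam, rho, y) >= 0)
        for mode in ("mlem_like", "constant", "scaled"):
            new = mlga_update(s, lam, rho, y,
                              step=StepSizeSpec(mode, rng.random() + 0.1))
            assert np.all(new >= 0)


class TestReduction:
    def test_zero_density_retains_everything(self, small_setup):
        s = small_setup["scatter"]
        mask = low_attenuation_sor_mask(s, np.zeros(s.n_voxels))
        assert mask.n_retained == s.n_sors

    def test_boundary_is_inclusive(self):
        s = toy_scatter_system(b=1.0, k=1.0)
        assert low_attenuation_sor_mask(s, np.array([1.0])).retained[0]
        assert not low_attenuation_sor_mask(s, np.array([1.5])).retained[0]

    def test_retained_fraction_shrinks_with_scale(self, chest9):
        fracs = []
        for scale in (0.2, 0.35, 1.0):
            ph, scatter, *_ = scaled_case(chest9, scale)
            fracs.append(
                low_attenuation_sor_mask(scatter, ph.rho).fraction_retained)
        assert fracs[0] >= fracs[1] >= fracs[2]
        assert fracs[0] > fracs[2]

    def test_all_true_mask_is_identity(self, small_setup):
        s = small_setup["scatter"]
        y = forward_scatter(s, small_setup["lam"], small_setup["rho"])
        mask = low_attenuation_sor_mask(s, np.zeros(s.n_voxels))
        y_red, s_red = reduce_scatter_data(s, y, mask)
        assert np.array_equal(y_red, y)
        assert abs(s_red.K - s.K).max() == 0
        assert np.array_equal(s_red.pair_sor, s.pair_sor)

    def test_reduced_loglik_is_sum_of_retained_terms(self, small_setup):
        s = small_setup["scatter"]
        lam, rho = small_setup["lam"], small_setup["rho"]
        y = forward_scatter(s, lam, rho * 2.5)
        mask = low_attenuation_sor_mask(s, rho * 8.0)
        assert 0 < mask.n_retained < s.n_sors
        y_red, s_red = reduce_scatter_data(s, y, mask)
        ybar = forward_scatter(s, lam, rho)
        ll_red = poisson_loglik(y_red, forward_scatter(s_red, lam, rho))
        per_term = np.where(y > 0, y * np.log(np.where(ybar > 0, ybar, 1.0)),
                            0.0) - ybar
        assert ll_red == pytest.approx(per_term[mask.retained].sum(),
                                       rel=1e-12)

    def test_empty_reduction_raises(self, small_setup):
        from scatterpet.s2a import ReductionMask
        s = small_setup["scatter"]
        y = np.zeros(s.n_sors)
        with pytest.raises(ValueError):
            reduce_scatter_data(s, y, ReductionMask(np.zeros(s.n_sors, bool)))


def test_tight_sor_critical_length_in_water_equivalent():
    assert tight_sor_critical_path_length(0.1) == pytest.approx(10.0,
                                                                abs=1e-9)
    with pytest.raises(ValueError):
        tight_sor_critical_path_length(0.0)


def test_run_s2a_divergence_guard_records_halt(chest9):
    ph, scatter, trues, meas, lam0, rho0 = scaled_case(chest9, 1.0)
    _, trace = run_s2a(scatter, ph.lam, meas.y, rho0, algorithm="mlem_osl",
                       n_iterations=50, rho_true=ph.rho)
    assert trace[-1]["diverged"]
    assert len(trace) < 50
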