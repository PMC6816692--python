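"""Forward models, Poisson log-likelihood, and gradients against
independent oracles."""

import numpy as np
import pytest

from scatterpet.forward import (
    attenuated_scatter_matrix,
    forward_scatter,
    forward_scatter_linearized,
    forward_trues,
    poisson_loglik,
    scatter_data_gradient,
    scatter_loglik_gradient,
)
from scatterpet.systems import (
    build_A_lambda,
    toy_scatter_system,
    toy_trues_system,
)


def dense_forward_scatter(system, lam, rho):
    """Triple-loop evaluation of the nonlinear scatter model."""
    B = np.asarray(system.B.todense())
    K = np.asarray(system.K.todense())
    ybar = np.zeros(system.n_sors)
    for row in range(system.n_pairs):
        i, s = system.pair_sor[row], system.pair_voxel[row]
        a = sum(B[row, e] * lam[e] for e in range(system.n_voxels))
        att = np.exp(-sum(K[row, t] * rho[t] for t in range(system.n_voxels)))
        ybar[i] += a * att * rho[s]
    return ybar


class TestAttenuatedScatterMatrix:
    def test_zero_rho_gives_A_lambda(self, small_setup):
        s = small_setup["scatter"]
        lam = small_setup["lam"]
        atil = attenuated_scatter_matrix(s, lam, np.zeros(s.n_voxels))
        assert abs(atil - build_A_lambda(s, lam)).max() == 0

    def test_single_entry_log_two(self):
        s = toy_scatter_system(b=2.0, k=1.0)
        atil = attenuated_scatter_matrix(s, np.ones(1), np.array([np.log(2)]))
        assert atil[0, 0] == pytest.approx(1.0, rel=1e-14)

    def test_matches_dense_exponential_oracle(self, small_setup):
        s = small_setup["scatter"]
        lam, rho = small_setup["lam"], small_setup["rho"]
        atil = np.asarray(
            attenuated_scatter_matrix(s, lam, rho).todense())
        A = np.zeros((s.n_sors, s.n_voxels))
        vals = np.asarray(s.B.todense()) @ lam
        att = np.exp(-np.asarray(s.K.todense()) @ rho)
        for row in range(s.n_pairs):
            A[s.pair_sor[row], s.pair_voxel[row]] = vals[row] * att[row]
        assert np.max(np.abs(atil - A)) < 1e-12

    def test_pattern_and_bounds(self, small_setup):
        s = small_setup["scatter"]
        lam, rho = small_setup["lam"], small_setup["rho"]
        atil = attenuated_scatter_matrix(s, lam, rho)
        alam = build_A_lambda(s, lam)
        assert (atil > alam).nnz == 0          # 0 <= Atil <= A elementwise
        assert atil.min() >= 0
        with pytest.raises(ValueError):
            attenuated_scatter_matrix(s, lam, -rho)


class TestForwardScatter:
    def test_single_voxel_low_attenuation_value(self):
        s = toy_scatter_system(b=1.0, k=1.0)
        ybar = forward_scatter(s, np.ones(1), np.array([0.2]))
        assert ybar[0] == pytest.approx(0.2 * np.exp(-0.2), rel=1e-14)
        assert round(float(ybar[0]), 2) == 0.16

    def test_no_scatterers_no_counts(self, small_setup):
        s = small_setup["scatter"]
        ybar = forward_scatter(s, small_setup["lam"], np.zeros(s.n_voxels))
        assert np.all(ybar == 0)

    def test_matches_triple_loop_oracle(self, small_setup):
        s = small_setup["scatter"]
        lam, rho = small_setup["lam"], small_setup["rho"]
        got = forward_scatter(s, lam, rho)
        want = dense_forward_scatter(s, lam, rho)
        assert np.max(np.abs(got - want)) < 1e-12

    def test_attenuation_only_removes_counts(self, small_setup):
        s = small_setup["scatter"]
        lam, rho = small_setup["lam"], small_setup["rho"]
        ybar = forward_scatter(s, lam, rho)
        unatten = np.asarray(
            (build_A_lambda(s, lam) @ rho)).ravel()
        assert np.all(ybar <= unatten + 1e-15)

    def test_monotone_decreasing_in_pure_attenuation_voxel(self, small_setup):
        # a voxel that only attenuates a given SOR (inside the SOR, not on
        # its hull) can only lower that SOR's expectation
        s = small_setup["scatter"]
        lam, rho = small_setup["lam"], small_setup["rho"]
        A = np.asarray(build_A_lambda(s, lam).todense())
        rows_by_sor = [np.nonzero(s.pair_sor == i)[0]
                       for i in range(s.n_sors)]
        found = 0
        for i in range(s.n_sors):
            rows = rows_by_sor[i]
            ksum = np.asarray(s.K[rows].sum(axis=0)).ravel()
            cand = np.nonzero((A[i] == 0) & (ksum > 0))[0]
            if len(cand) == 0:
                continue
            j = cand[0]
            base = forward_scatter(s, lam, rho)[i]
            bumped = rho.copy()
            bumped[j] += 0.5
            assert forward_scatter(s, lam, bumped)[i] < base
            found += 1
            if found >= 5:
                break
        assert found > 0


class TestLinearizedForward:
    def test_consistency_at_rho_est(self, small_setup):
        s = small_setup["scatter"]
        lam, rho = small_setup["lam"], small_setup["rho"]
        assert np.allclose(forward_scatter_linearized(s, lam, rho, rho),
                           forward_scatter(s, lam, rho), rtol=1e-14)

    def test_linear_in_rho(self, small_setup):
        s = small_setup["scatter"]
        lam, rho = small_setup["lam"], small_setup["rho"]
        y1 = forward_scatter_linearized(s, lam, rho, rho)
        y2 = forward_scatter_linearized(s, lam, rho, 2 * rho)
        assert np.allclose(y2, 2 * y1, rtol=1e-14)

    def test_high_attenuation_linearization_is_flatter(self):
        # 1-D toy: slope of the linearization is a e^{-k rho_est}
        s = toy_scatter_system(b=1.0, k=1.0)
        lam = np.ones(1)
        rho = np.array([1.0])
        slope0 = forward_scatter_linearized(s, lam, np.array([0.0]), rho)[0]
        slope2 = forward_scatter_linearized(s, lam, np.array([2.0]), rho)[0]
        assert slope0 == pytest.approx(1.0, rel=1e-14)
        assert slope2 == pytest.approx(np.exp(-2.0), rel=1e-14)


class TestForwardTrues:
    def test_no_attenuation_gives_plain_projection(self, small_setup):
        t = small_setup["trues"]
        lam = small_setup["lam"]
        zbar = forward_trues(t, lam, np.zeros(t.U.shape[1]))
        assert np.allclose(zbar, np.asarray(t.U @ lam).ravel())

    def test_single_voxel_closed_form(self):
        t = toy_trues_system(u=1.0)
        assert forward_trues(t, np.ones(1), np.array([2.0]))[0] == \
            pytest.approx(np.exp(-2.0), rel=1e-14)

    def test_matches_componentwise_oracle(self, small_setup):
        t = small_setup["trues"]
        lam, rho = small_setup["lam"], small_setup["rho"]
        U = np.asarray(t.U.todense())
        want = np.array([
            sum(U[l, j] * lam[j] for j in range(U.shape[1]))
            * np.exp(-sum(U[l, j] * rho[j] for j in range(U.shape[1])))
            for l in range(U.shape[0])])
        assert np.max(np.abs(forward_trues(t, lam, rho) - want)) < 1e-12

    def test_bounded_by_unattenuated(self, small_setup):
        t = small_setup["trues"]
        lam, rho = small_setup["lam"], small_setup["rho"]
        zbar = forward_trues(t, lam, rho)
        assert np.all(zbar >= 0)
        assert np.all(zbar <= np.asarray(t.U @ lam).ravel() + 1e-15)


class TestPoissonLoglik:
    def test_closed_form_values(self):
        assert poisson_loglik([1.0, 2.0], [1.0, 2.0]) == \
            pytest.approx(2 * np.log(2) - 3)
        ybar = np.array([0.3, 1.7, 0.0])
        assert poisson_loglik(np.zeros(3), ybar) == pytest.approx(-ybar.sum())

    def test_maximized_at_expected_equals_data(self):
        y = np.array([1.0, 2.0, 5.0])
        grid = np.linspace(0.2, 8.0, 300)
        # scan scalar multiples of y: argmax multiplier is 1
        lls = [poisson_loglik(y, m * y) for m in grid]
        assert grid[int(np.argmax(lls))] == pytest.approx(1.0, abs=0.02)

    def test_support_violation_is_minus_inf_with_warning(self):
        with pytest.warns(RuntimeWarning):
            assert poisson_loglik([1.0], [0.0]) == -np.inf


class TestGradients:
    def test_single_voxel_sign_change_at_unit_k_rho(self):
        s = toy_scatter_system(b=1.0, k=1.0)
        lam = np.ones(1)
        w = np.ones(1)
        d_lo = scatter_data_gradient(s, lam, np.array([0.9]), w)[0]
        d_hi = scatter_data_gradient(s, lam, np.array([1.1]), w)[0]
        d_at = scatter_data_gradient(s, lam, np.array([1.0]), w)[0]
        assert d_lo > 0 > d_hi
        assert d_at == pytest.approx(0.0, abs=1e-15)

    def test_full_equals_linearized_when_K_zero(self, small_setup):
        import scipy.sparse as sp
        from dataclasses import replace
        s = small_setup["scatter"]
        lam, rho = small_setup["lam"], small_setup["rho"]
        s0 = replace(s, K=sp.csr_matrix(s.K.shape))
        y = forward_scatter(s0, lam, rho)
        g_full = scatter_loglik_gradient(s0, lam, 0.9 * rho + 0.01, y,
                                         mode="full")
        g_lin = scatter_loglik_gradient(s0, lam, 0.9 * rho + 0.01, y,
                                        mode="linearized")
        assert np.allclose(g_full, g_lin, rtol=1e-12, atol=1e-15)

    def test_full_gradient_matches_finite_differences(self, small_setup):
        s = small_setup["scatter"]
        lam, rho = small_setup["lam"], small_setup["rho"]
        y = forward_scatter(s, lam, rho)
        rho0 = 0.9 * rho + 0.005
        g = scatter_loglik_gradient(s, lam, rho0, y, mode="full")
        eps = 1e-6
        for j in range(s.n_voxels):
            rp, rm = rho0.copy(), rho0.copy()
            rp[j] += eps
            rm[j] -= eps
            fd = (poisson_loglik(y, forward_scatter(s, lam, rp))
                  - poisson_loglik(y, forward_scatter(s, lam, rm))) / (2 * eps)
            assert g[j] == pytest.approx(fd, rel=1e-5, abs=1e-8)

    def test_full_is_linearized_plus_correction(self, small_setup):
        s = small_setup["scatter"]
        lam, rho = small_setup["lam"], small_setup["rho"]
        y = forward_scatter(s, lam, rho) * 1.1
        g_full = scatter_loglik_gradient(s, lam, rho, y, mode="full")
        g_lin = scatter_loglik_gradient(s, lam, rho, y, mode="linearized")
        # independent dense assembly of the correction term
        ybar = forward_scatter(s, lam, rho)
        coeff = y / ybar - 1.0
        K = np.asarray(s.K.todense())
        atil = np.asarray(s.B.todense()) @ lam \
            * np.exp(-K @ rho)
        corr = np.zeros(s.n_voxels)
        for row in range(s.n_pairs):
            i, sv = s.pair_sor[row], s.pair_voxel[row]
            corr += coeff[i] * rho[sv] * atil[row] * K[row]
        assert np.allclose(g_full, g_lin - corr, rtol=1e-10, atol=1e-12)

    def test_support_violation_raises(self):
        s = toy_scatter_system()
        with pytest.raises(ValueError):
            scatter_loglik_gradient(s, np.ones(1), np.zeros(1),
                                    np.array([1.0]))
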