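"""Solver correctness: subproblem oracles, descent, slice separation."""

import numpy as np
import pytest

from smshsl import (ReconConfig, build_complement, estimate_nullspace, ifft2c,
                    objective, reconstruct_slice, solve_U, solve_V, solve_x)
from smshsl.calibration import NullSpaceBasis
from smshsl.hankel_ops import block_hankel_lift
from smshsl.io_core import KSpaceVolume
from smshsl.quantify import leakage_fraction, nrmse
from smshsl.recon import FactorPair, _init_factors, rss_combine, reconstruct_group
from smshsl.simulation import caipi_demodulate


def toy_cfg(**kw):
    base = dict(kernel_r=2, rank_R=3, nullspace_cutoff=0.05, lambda_l=1e-3,
                alpha=0.5, outer_iters=10, cg_iters=200, cg_tol=1e-12, stop_tol=1e-8)
    base.update(kw)
    return ReconConfig(**base)


@pytest.fixture()
def toy(rng):
    """8×8×2 grid, Np=2, r=2 — small enough for dense oracles."""
    y = rng.standard_normal((8, 8, 2, 2)) + 1j * rng.standard_normal((8, 8, 2, 2))
    cols = 2 * 2 * 2
    q, _ = np.linalg.qr(rng.standard_normal((cols, cols))
                        + 1j * rng.standard_normal((cols, cols)))
    N = NullSpaceBasis(q[:, :5], 0.05, np.ones(cols), signal_basis=q[:, 5:])
    return y, N


class TestObjective:
    def test_zero_state_value(self, toy):
        y, N = toy
        cfg = toy_cfg()
        hy = block_hankel_lift(y, 2).matrix
        U = np.zeros((hy.shape[0], 3), complex)
        V = np.zeros((3, hy.shape[1]), complex)
        val = objective(np.zeros_like(y), U, V, y, N, cfg)
        assert val == pytest.approx(np.linalg.norm(hy @ N.basis) ** 2, rel=1e-10)

    def test_exact_solution_zeroes_terms(self, rng):
        """Consistent x, factors and exact null space: fidelity and coupling ~ 0."""
        x = rng.standard_normal((6, 6, 1, 1)) + 1j * rng.standard_normal((6, 6, 1, 1))
        hx = block_hankel_lift(x, 2).matrix
        u, s, vh = np.linalg.svd(hx, full_matrices=False)
        U, V = u * s, vh
        cols = hx.shape[1]
        q, _ = np.linalg.qr(rng.standard_normal((cols, cols)) + 0j)
        N = NullSpaceBasis(q[:, :1], 0.05, np.ones(cols))
        cfg = toy_cfg(lambda_l=1e-12)
        val = objective(x, U, V, x, N, cfg)
        assert val < 1e-12 * np.linalg.norm(hx) ** 2 + 1e-10

    def test_gauge_invariance(self, toy, rng):
        """(U, V) → (U·Q, Qᴴ·V) leaves the objective unchanged."""
        y, N = toy
        cfg = toy_cfg()
        hy = block_hankel_lift(y, 2).matrix
        fac = _init_factors(hy, 3, 0)
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)) + 1j * rng.standard_normal((3, 3)))
        v1 = objective(y, fac.U, fac.V, y, N, cfg)
        v2 = objective(y, fac.U @ q, q.conj().T @ fac.V, y, N, cfg)
        assert v1 == pytest.approx(v2, rel=1e-10)


class TestSolveX:
    def test_full_nullspace_returns_measurement(self, toy, rng):
        """N square unitary and α→0: the minimizer is y itself."""
        y, _ = toy
        cols = 8
        q, _ = np.linalg.qr(rng.standard_normal((cols, cols))
                            + 1j * rng.standard_normal((cols, cols)))
        N_full = NullSpaceBasis(q, 0.05, np.ones(cols))
        cfg = toy_cfg(alpha=1e-12)
        hy = block_hankel_lift(y, 2).matrix
        UV = np.zeros_like(hy)
        x = solve_x(y, UV, N_full, cfg)
        np.testing.assert_allclose(x, y, atol=1e-6)

    def test_matches_dense_normal_equations(self, toy, rng):
        """CG agrees with an explicit dense solve of the same quadratic."""
        y, N = toy
        cfg = toy_cfg()
        hy = block_hankel_lift(y, 2).matrix
        UV = rng.standard_normal(hy.shape) + 1j * rng.standard_normal(hy.shape)
        x = solve_x(y, UV, N, cfg)

        # densify the normal operator column by column and solve directly
        from smshsl.recon import _apply_B, _adjoint, _lift
        n = y.size
        A = np.zeros((n, n), complex)
        b_mat = (hy @ (N.basis @ N.basis.conj().T)) + 0.5 * cfg.alpha * UV
        for i in range(n):
            e = np.zeros(n, complex)
            e[i] = 1.0
            A[:, i] = _adjoint(_apply_B(_lift(e.reshape(y.shape), 2), N, 0.5 * cfg.alpha),
                               y.shape, 2).ravel()
        rhs = _adjoint(b_mat, y.shape, 2).ravel()
        x_dense = np.linalg.solve(A, rhs).reshape(y.shape)
        np.testing.assert_allclose(x, x_dense, atol=1e-8 * np.linalg.norm(x_dense))

    def test_never_increases_subproblem(self, toy, rng):
        y, N = toy
        cfg = toy_cfg(cg_iters=3)  # deliberately truncated
        hy = block_hankel_lift(y, 2).matrix
        UV = rng.standard_normal(hy.shape) + 1j * rng.standard_normal(hy.shape)

        def sub_val(x):
            hx = block_hankel_lift(x, 2).matrix
            return (np.linalg.norm((hy - hx) @ N.basis) ** 2
                    + 0.5 * cfg.alpha * np.linalg.norm(UV - hx) ** 2)

        x0 = rng.standard_normal(y.shape) + 1j * rng.standard_normal(y.shape)
        x1 = solve_x(y, UV, N, cfg, x0=x0)
        assert sub_val(x1) <= sub_val(x0) * (1 + 1e-12)


class TestFactorUpdates:
    def test_dense_ridge_oracle(self, rng):
        H = rng.standard_normal((20, 6)) + 1j * rng.standard_normal((20, 6))
        V = rng.standard_normal((3, 6)) + 1j * rng.standard_normal((3, 6))
        cfg = toy_cfg(lambda_l=0.37, alpha=1.3)
        U = solve_U(H, V, cfg)
        U_oracle = (cfg.alpha * H @ V.conj().T) @ np.linalg.inv(
            cfg.alpha * V @ V.conj().T + cfg.lambda_l * np.eye(3))
        np.testing.assert_allclose(U, U_oracle, atol=1e-10)
        Vn = solve_V(H, U, cfg)
        V_oracle = np.linalg.inv(cfg.alpha * U.conj().T @ U
                                 + cfg.lambda_l * np.eye(3)) @ (cfg.alpha * U.conj().T @ H)
        np.testing.assert_allclose(Vn, V_oracle, atol=1e-10)

    def test_projection_limits(self, rng):
        H = rng.standard_normal((12, 8)) + 1j * rng.standard_normal((12, 8))
        q, _ = np.linalg.qr(rng.standard_normal((8, 3)) + 1j * rng.standard_normal((8, 3)))
        V = q.conj().T  # orthonormal rows
        cfg = toy_cfg(lambda_l=1e-15, alpha=1.0)
        np.testing.assert_allclose(solve_U(H, V, cfg), H @ V.conj().T, atol=1e-9)
        # λℓ → ∞ ⇒ U → 0
        cfg_big = toy_cfg(lambda_l=1e15, alpha=1.0)
        assert np.linalg.norm(solve_U(H, V, cfg_big)) < 1e-12
        # U with orthonormal columns: V = Uᴴ H
        qu, _ = np.linalg.qr(rng.standard_normal((12, 3)) + 1j * rng.standard_normal((12, 3)))
        np.testing.assert_allclose(solve_V(H, qu, cfg), qu.conj().T @ H, atol=1e-9)

    def test_gauge_consistency(self, rng):
        """Updates from a unitarily rotated pair reach the same product U·V."""
        H = rng.standard_normal((20, 6)) + 1j * rng.standard_normal((20, 6))
        V = rng.standard_normal((3, 6)) + 1j * rng.standard_normal((3, 6))
        cfg = toy_cfg(lambda_l=1e-6, alpha=1.0)
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)) + 1j * rng.standard_normal((3, 3)))
        U1 = solve_U(H, V, cfg)
        V1 = solve_V(H, U1, cfg)
        U2 = solve_U(H, q.conj().T @ V, cfg)
        V2 = solve_V(H, U2, cfg)
        np.testing.assert_allclose(U1 @ V1, U2 @ V2, atol=1e-8)

    def test_partial_gradient_stationarity(self, rng):
        """After each closed-form update the corresponding gradient vanishes."""
        H = rng.standard_normal((15, 8)) + 1j * rng.standard_normal((15, 8))
        V = rng.standard_normal((4, 8)) + 1j * rng.standard_normal((4, 8))
        cfg = toy_cfg(lambda_l=0.05, alpha=0.8)
        U = solve_U(H, V, cfg)
        gU = cfg.lambda_l * U + cfg.alpha * (U @ V - H) @ V.conj().T
        assert np.linalg.norm(gU) < 1e-6 * max(np.linalg.norm(H), 1.0)
        Vn = solve_V(H, U, cfg)
        gV = cfg.lambda_l * Vn + cfg.alpha * U.conj().T @ (U @ Vn - H)
        assert np.linalg.norm(gV) < 1e-6 * max(np.linalg.norm(H), 1.0)


class TestReconstruction:
    def test_single_slice_measurement_recovered(self, sms2, recon_cfg):
        """y containing one slice only (complement absent from y)."""
        comp = build_complement(sms2.slices, 0, sms2.schedule)
        N = estimate_nullspace(comp, 5, 0.05, slice_of_interest=0)
        state = reconstruct_slice(sms2.modulated[0], N, recon_cfg)
        img = rss_combine(ifft2c(caipi_demodulate(state.x, 0, sms2.schedule).data), axis=2)
        errs = [nrmse(sms2.truth_rss[0][:, :, p], img[:, :, p]) for p in range(3)]
        assert max(errs) < 0.01

    def test_cost_trace_monotone(self, sms2, recon_cfg):
        comp = build_complement(sms2.slices, 0, sms2.schedule)
        N = estimate_nullspace(comp, 5, 0.05, slice_of_interest=0)
        state = reconstruct_slice(sms2.collapsed, N, recon_cfg)
        trace = np.array(state.cost_trace)
        assert np.all(np.diff(trace) <= 1e-6 * trace[:-1] + 1e-12)

    def test_two_slice_unfolding_quality(self, sms2, recon_cfg, sms2_recon):
        imgs, states = sms2_recon
        for s in range(2):
            for p in range(3):
                assert nrmse(sms2.truth_rss[s][:, :, p], imgs.data[:, :, p, s]) < 0.05

    def test_leakage_below_one_percent(self, sms2, sms2_recon):
        imgs, _ = sms2_recon
        for i, j in ((0, 1), (1, 0)):
            leak = leakage_fraction(imgs.data[:, :, :, i],
                                    sms2.truth_rss[i], sms2.truth_rss[j])
            assert leak < 0.01

    def test_slice_symmetry(self, sms2, recon_cfg):
        """Swapping the two null spaces swaps the reconstructed outputs."""
        comp0 = build_complement(sms2.slices, 0, sms2.schedule)
        comp1 = build_complement(sms2.slices, 1, sms2.schedule)
        N0 = estimate_nullspace(comp0, 5, 0.05, slice_of_interest=0)
        N1 = estimate_nullspace(comp1, 5, 0.05, slice_of_interest=1)
        st0 = reconstruct_slice(sms2.collapsed, N0, recon_cfg)
        st1 = reconstruct_slice(sms2.collapsed, N1, recon_cfg)
        img0 = rss_combine(ifft2c(caipi_demodulate(st0.x, 0, sms2.schedule).data), axis=2)
        img1 = rss_combine(ifft2c(caipi_demodulate(st1.x, 1, sms2.schedule).data), axis=2)
        assert nrmse(sms2.truth_rss[0][:, :, 0], img0[:, :, 0]) < 0.05
        assert nrmse(sms2.truth_rss[1][:, :, 0], img1[:, :, 0]) < 0.05
        # each output matches its own slice far better than the other slice
        assert nrmse(sms2.truth_rss[1][:, :, 0], img0[:, :, 0]) > 0.2
        assert nrmse(sms2.truth_rss[0][:, :, 0], img1[:, :, 0]) > 0.2
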