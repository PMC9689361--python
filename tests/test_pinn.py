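import math

import numpy as np
import pytest

from mrept.autodiff import Tensor
from mrept.differentiation import central_derivatives
from mrept.grids_io import ScalarField2D, make_grid, make_ring_masks, ring_mask
from mrept.metrics_filters import mae as metric_mae
from mrept.metrics_filters import ssim as metric_ssim
from mrept.numerical_ept import std_ept
from mrept.phantom_forward import (
    AcquisitionSpec,
    PhantomSpec,
    add_phase_noise,
    build_phantom,
    quadratic_phase,
    solve_forward_phase,
)
from mrept.pinn_ept import (
    PINNConfig,
    _forward_with_derivs,
    _norm_coords,
    _StabAssembler,
    ad_derivatives,
    init_network,
    loss_phase,
    loss_sigma_bc,
    pinn_sigma,
    predict_phase,
    rho_value,
    train_pinn,
)


@pytest.fixture()
def small_setup(acq):
    """16x16 phantom with 3-pixel ring: small enough for fast training."""
    g = make_grid(16, 16, 0.002, 0.002)
    spec = PhantomSpec(g, 0.6, padding_thickness=3, padding_sigma=1.0)
    sigma, _, masks = build_phantom(spec)
    phase = solve_forward_phase(sigma, acq, refine=2)
    return g, masks, phase


class TestInit:
    def test_equal_seeds_give_identical_parameters(self, grid36, acq):
        phase = quadratic_phase(grid36, acq)
        a = init_network(PINNConfig(seed=11), phase)
        b = init_network(PINNConfig(seed=11), phase)
        for wa, wb in zip(a.weights, b.weights):
            np.testing.assert_array_equal(wa.data, wb.data)
        c = init_network(PINNConfig(seed=12), phase)
        assert any(
            not np.array_equal(wa.data, wc.data) for wa, wc in zip(a.weights, c.weights)
        )

    def test_parameter_count_of_stated_architecture(self, grid36, acq):
        # 2*50 + 3*50*50 + 50*1 parameters for 4 bias-free hidden layers
        net = init_network(PINNConfig(), quadratic_phase(grid36, acq))
        assert net.parameter_count() == 2 * 50 + 3 * 50 * 50 + 50 * 1 == 7650

    def test_output_bounded_by_phase_range(self, grid36, acq):
        phase = quadratic_phase(grid36, acq)
        net = init_network(PINNConfig(seed=0), phase)
        pred = predict_phase(net, grid36)
        assert pred.values.min() >= phase.values.min()
        assert pred.values.max() <= phase.values.max()

    def test_degenerate_phase_range_rejected(self, grid36):
        const = ScalarField2D(grid36, np.ones(grid36.shape), role="phase")
        with pytest.raises(ValueError, match="zero range"):
            init_network(PINNConfig(), const)


class TestRhoValue:
    def test_midpoint_at_zero(self):
        assert rho_value(0.0, (1e-6, 0.01)) == pytest.approx(0.0050005, abs=1e-10)

    def test_asymptotes(self):
        assert rho_value(-60.0, (1e-6, 0.01)) == pytest.approx(1e-6, rel=1e-6)
        assert rho_value(60.0, (1e-6, 0.01)) == pytest.approx(0.01, rel=1e-6)

    def test_monotone_in_theta(self):
        thetas = np.linspace(-8, 8, 33)
        vals = [rho_value(t, (1e-6, 0.01)) for t in thetas]
        assert np.all(np.diff(vals) > 0)


class TestADDerivatives:
    def test_gradient_matches_five_point_finite_differences(self, grid36, acq):
        phase = quadratic_phase(grid36, acq)
        net = init_network(PINNConfig(seed=3), phase)
        derivs = ad_derivatives(net, grid36)
        coords = _norm_coords(net, grid36)
        h = 1e-3

        def f(c):
            from mrept.pinn_ept import _forward_value

            return _forward_value(net, c).data

        for axis, lx, got in ((0, net.norm_lx, derivs.d_dx), (1, net.norm_ly, derivs.d_dy)):
            e = np.zeros_like(coords)
            e[:, axis] = h
            fd = (-f(coords + 2 * e) + 8 * f(coords + e)
                  - 8 * f(coords - e) + f(coords - 2 * e)) / (12 * h) / lx
            rel = np.max(np.abs(fd - got.values.ravel())) / np.max(np.abs(fd))
            assert rel < 1e-4

    def test_laplacian_matches_finite_differences(self, grid36, acq):
        phase = quadratic_phase(grid36, acq)
        net = init_network(PINNConfig(seed=3), phase)
        derivs = ad_derivatives(net, grid36)
        coords = _norm_coords(net, grid36)
        h = 1e-3

        def f(c):
            from mrept.pinn_ept import _forward_value

            return _forward_value(net, c).data

        lap_fd = np.zeros(coords.shape[0])
        for axis, lx in ((0, net.norm_lx), (1, net.norm_ly)):
            e = np.zeros_like(coords)
            e[:, axis] = h
            lap_fd += (-f(coords + 2 * e) + 16 * f(coords + e) - 30 * f(coords)
                       + 16 * f(coords - e) - f(coords - 2 * e)) / (12 * h**2) / lx**2
        rel = np.max(np.abs(lap_fd - derivs.laplacian.values.ravel())) / np.max(np.abs(lap_fd))
        assert rel < 1e-3

    def test_zero_output_layer_gives_constant_prediction(self, grid36, acq):
        phase = quadratic_phase(grid36, acq)
        net = init_network(PINNConfig(seed=0), phase)
        net.weights[-1].data[:] = 0.0
        pred = predict_phase(net, grid36)
        assert np.ptp(pred.values) == 0.0
        d = ad_derivatives(net, grid36)
        np.testing.assert_allclose(d.d_dx.values, 0.0, atol=1e-14)
        np.testing.assert_allclose(d.laplacian.values, 0.0, atol=1e-14)


class TestLosses:
    def test_identical_maps_give_zero_phase_loss(self, grid36, acq):
        phase = quadratic_phase(grid36, acq)
        assert loss_phase(phase, phase) == pytest.approx(0.0, abs=1e-12)

    def test_phase_loss_matches_independent_two_term_evaluation(self, rng):
        g = make_grid(16, 16, 1, 1)
        a = ScalarField2D(g, rng.normal(size=g.shape))
        b = ScalarField2D(g, rng.normal(size=g.shape))
        got = loss_phase(a, b)
        expect = np.mean((a.values - b.values) ** 2) + (1.0 - metric_ssim(a, b))
        assert got == pytest.approx(expect, rel=1e-10)
        assert got >= 0.0

    def test_bc_loss_zero_on_exact_ring(self, grid36):
        masks = make_ring_masks(grid36, 3)
        eval_mask = masks.padding & ~ring_mask(grid36, 0, 1)
        known = np.full(grid36.shape, 1.0)
        pred = ScalarField2D(grid36, np.full(grid36.shape, 1.0))
        assert loss_sigma_bc(pred, known, eval_mask) == pytest.approx(0.0, abs=1e-12)

    def test_bc_loss_positive_and_matches_recomputation(self, grid36):
        from mrept.metrics_filters import global_ssim

        masks = make_ring_masks(grid36, 3)
        eval_mask = masks.padding & ~ring_mask(grid36, 0, 1)
        known = np.full(grid36.shape, 1.0)
        vals = np.full(grid36.shape, 1.0)
        j, i = np.argwhere(eval_mask)[0]
        vals[j, i] = 1.5  # one perturbed ring pixel
        pred = ScalarField2D(grid36, vals)
        got = loss_sigma_bc(pred, known, eval_mask)
        pm, km = vals[eval_mask], known[eval_mask]
        expect = np.mean((pm - km) ** 2) + (1.0 - global_ssim(pm, km, km.max()))
        assert got == pytest.approx(expect, rel=1e-10)
        assert got > 0.0

    def test_empty_mask_rejected(self, grid36):
        pred = ScalarField2D(grid36, np.ones(grid36.shape))
        with pytest.raises(ValueError):
            loss_sigma_bc(pred, np.ones(grid36.shape), np.zeros(grid36.shape, bool))


class TestPinnSigma:
    def test_homogeneous_case_uniform_for_any_rho(self, grid36, masks36, acq):
        phase = quadratic_phase(grid36, acq, sigma0=1.0)
        derivs = central_derivatives(phase)
        for rho in (1e-6, 0.001, 0.01):
            sigma = pinn_sigma(derivs, rho, masks36, acq, "stab", padding_sigma=1.0)
            np.testing.assert_allclose(sigma.values, 1.0, rtol=1e-8)

    def test_std_variant_equals_numerical_std_on_ad_derivatives(self, grid36, masks36, acq):
        phase = quadratic_phase(grid36, acq)
        net = init_network(PINNConfig(seed=4), phase)
        derivs = ad_derivatives(net, grid36)
        a = pinn_sigma(derivs, 0.0, masks36, acq, "std")
        b = std_ept(derivs, acq)
        keep = ~np.isnan(b.values)
        np.testing.assert_allclose(a.values[keep], b.values[keep], rtol=1e-12)

    def test_rho_gradient_through_solve_matches_finite_differences(self, acq, rng):
        g = make_grid(8, 8, 0.002, 0.002)
        phase = quadratic_phase(g, acq)
        noisy = phase.copy_with(phase.values + rng.normal(0, 0.01, g.shape))
        d = central_derivatives(noisy)
        asm = _StabAssembler(g, ~ring_mask(g, 0, 1), np.ones(g.shape), acq)
        px = Tensor(d.d_dx.values.ravel())
        py = Tensor(d.d_dy.values.ravel())
        lap = Tensor(d.laplacian.values.ravel())

        def quad_loss(rho, grad=False):
            rt = Tensor(rho, requires_grad=grad)
            gam = asm.solve(px, py, lap, rt)
            L = (gam * gam).sum()
            if grad:
                L.backward()
                return L.item(), float(rt.grad)
            return L.item()

        rho0 = 0.004
        _, g_adj = quad_loss(rho0, grad=True)
        eps = 1e-8
        g_fd = (quad_loss(rho0 + eps) - quad_loss(rho0 - eps)) / (2 * eps)
        assert abs(g_adj - g_fd) / abs(g_fd) < 1e-4


class TestTraining:
    def test_short_run_contracts(self, small_setup, acq):
        g, masks, phase = small_setup
        noisy = add_phase_noise(phase, 100, seed=0)
        cfg = PINNConfig(iterations=60, stage1_iterations=40, seed=0)
        log, result = train_pinn(noisy, 1.0, masks, acq, cfg)
        # rho bound invariance at every logged iteration
        assert all(1e-6 <= r <= 0.01 for r in log.rho)
        # stage 1 never touches the linear solver
        assert log.solver_calls == 20
        assert len(log.total) == 60
        # best-model loss is the minimum of stage-2 totals
        stage2_totals = log.total[40:]
        assert log.best_total == pytest.approx(np.nanmin(stage2_totals))
        assert log.best_iteration >= 40
        assert result.formulation == "stab"
        assert result.sigma.grid.shape == g.shape

    def test_pure_stage1_run_is_phase_fitting_only(self, small_setup, acq):
        g, masks, phase = small_setup
        noisy = add_phase_noise(phase, 100, seed=0)
        cfg = PINNConfig(iterations=30, stage1_iterations=30, seed=0)
        log, result = train_pinn(noisy, 1.0, masks, acq, cfg)
        assert log.solver_calls == 0
        assert all(math.isnan(v) for v in log.l_bc)
        assert log.best_total <= log.total[-1]

    def test_training_reduces_phase_mse(self, small_setup, acq):
        g, masks, phase = small_setup
        cfg = PINNConfig(iterations=2000, stage1_iterations=2000, seed=1)
        net0 = init_network(cfg, phase)
        mse0 = np.mean((predict_phase(net0, g).values - phase.values) ** 2)
        log, result = train_pinn(phase, 1.0, masks, acq, cfg)
        mse1 = np.mean((result.phase_pred.values - phase.values) ** 2)
        assert mse1 < mse0

    def test_determinism_given_seed(self, small_setup, acq):
        g, masks, phase = small_setup
        noisy = add_phase_noise(phase, 100, seed=3)
        cfg = PINNConfig(iterations=25, stage1_iterations=15, seed=5)
        log1, res1 = train_pinn(noisy, 1.0, masks, acq, cfg)
        log2, res2 = train_pinn(noisy, 1.0, masks, acq, cfg)
        assert log1.total == log2.total
        np.testing.assert_array_equal(res1.sigma.values, res2.sigma.values)

    def test_std_formulation_runs(self, small_setup, acq):
        g, masks, phase = small_setup
        noisy = add_phase_noise(phase, 100, seed=0)
        cfg = PINNConfig(iterations=25, stage1_iterations=15, seed=0,
                         formulation="std")
        log, result = train_pinn(noisy, 1.0, masks, acq, cfg)
        assert log.solver_calls == 0  # std variant never assembles a system
        assert result.formulation == "std"
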