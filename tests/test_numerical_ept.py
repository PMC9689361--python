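import numpy as np
import pytest

from mrept.differentiation import central_derivatives, savgol_derivatives
from mrept.grids_io import make_grid, make_ring_masks
from mrept.numerical_ept import (
    EPTOptions,
    assemble_stab_system,
    grid_search_rho,
    reconstruct,
    solve_stab_ept,
    std_ept,
)
from mrept.phantom_forward import (
    PhantomSpec,
    add_phase_noise,
    build_phantom,
    quadratic_phase,
    solve_forward_phase,
)


def dense_stab_oracle(derivs, rho, gamma_known, masks, acq):
    """Independent dense assembly of the stabilized system (loop-based)."""
    g = derivs.grid
    unknown = masks.interior
    jj, ii = np.nonzero(unknown)
    idx = {(j, i): k for k, (j, i) in enumerate(zip(jj, ii))}
    n = len(idx)
    A = np.zeros((n, n))
    b = np.full(n, acq.source)
    dx, dy = g.dx, g.dy
    px, py, lap = derivs.d_dx.values, derivs.d_dy.values, derivs.laplacian.values
    for (j, i), k in idx.items():
        A[k, k] = lap[j, i] + 2 * rho / dx**2 + 2 * rho / dy**2
        for (dj, di, c) in (
            (0, 1, px[j, i] / (2 * dx) - rho / dx**2),
            (0, -1, -px[j, i] / (2 * dx) - rho / dx**2),
            (1, 0, py[j, i] / (2 * dy) - rho / dy**2),
            (-1, 0, -py[j, i] / (2 * dy) - rho / dy**2),
        ):
            key = (j + dj, i + di)
            if key in idx:
                A[k, idx[key]] = c
            else:
                b[k] -= c * gamma_known[key]
    return A, b


class TestStdEPT:
    def test_quadratic_phase_recovers_unit_conductivity(self, grid36, masks36, acq):
        phase = quadratic_phase(grid36, acq, sigma0=1.0)
        sigma = std_ept(central_derivatives(phase), acq)
        err = np.abs(sigma.values[masks36.interior] - 1.0)
        assert np.nanmax(err) < 1e-8

    def test_constant_phase_fully_masked(self, grid36, acq):
        from mrept.grids_io import ScalarField2D

        phase = ScalarField2D(grid36, np.full(grid36.shape, 0.3), role="phase")
        with pytest.warns(UserWarning, match="degenerate"):
            sigma = std_ept(central_derivatives(phase), acq)
        assert np.all(np.isnan(sigma.values))

    def test_linearity_in_phase_scaling(self, grid36, acq):
        phase = quadratic_phase(grid36, acq, sigma0=1.0)
        s1 = std_ept(central_derivatives(phase), acq)
        s2 = std_ept(central_derivatives(phase.copy_with(2.0 * phase.values)), acq)
        np.testing.assert_allclose(s2.values, 2.0 * s1.values, rtol=1e-10)


class TestStabAssembly:
    @pytest.mark.parametrize("n", [8, 10])
    @pytest.mark.parametrize("rho", [0.0, 0.001])
    def test_sparse_equals_dense_oracle(self, acq, rng, n, rho):
        g = make_grid(n, n, 0.002, 0.002)
        masks = make_ring_masks(g, 1)
        from mrept.grids_io import ScalarField2D

        phase = ScalarField2D(g, rng.normal(0, 0.1, g.shape), role="phase")
        derivs = central_derivatives(phase)
        gamma_known = np.full(g.shape, 1.3)
        sys_ = assemble_stab_system(derivs, rho, gamma_known, masks, acq)
        A_dense, b_dense = dense_stab_oracle(derivs, rho, gamma_known, masks, acq)
        np.testing.assert_allclose(sys_.matrix.toarray(), A_dense, atol=1e-12)
        np.testing.assert_allclose(sys_.rhs, b_dense, atol=1e-12)
        # solutions agree too
        x_sparse = solve_stab_ept(sys_)[1].values[masks.interior]
        x_dense = np.linalg.solve(A_dense, b_dense)
        np.testing.assert_allclose(x_sparse, x_dense, atol=1e-10)

    def test_rho_zero_reduces_to_convection_reaction(self, grid36, masks36, acq, rng):
        from mrept.grids_io import ScalarField2D

        phase = ScalarField2D(grid36, rng.normal(0, 0.1, grid36.shape), role="phase")
        derivs = central_derivatives(phase)
        gk = np.ones(grid36.shape)
        s0 = assemble_stab_system(derivs, 0.0, gk, masks36, acq)
        # with rho=0 no diffusion coupling: off-diagonals are pure convection
        px = derivs.d_dx.values
        jj, ii = np.nonzero(masks36.interior)
        k = 17
        j, i = jj[k], ii[k]
        row = s0.matrix.getrow(k).toarray().ravel()
        east = s0.unknown_index[j, i + 1]
        assert row[east] == pytest.approx(px[j, i] / (2 * grid36.dx))

    def test_open_stencil_rejected(self, grid36, masks36, acq):
        phase = quadratic_phase(grid36, acq)
        derivs = central_derivatives(phase)
        bad_unknown = np.ones(grid36.shape, dtype=bool)  # touches the border
        with pytest.raises(ValueError, match="open stencil"):
            assemble_stab_system(
                derivs, 0.0, np.ones(grid36.shape), masks36, acq, unknown=bad_unknown
            )


class TestStabSolve:
    def test_single_unknown_pixel_closed_form(self, acq):
        # one unknown surrounded by Dirichlet gammas under quadratic phase:
        # the 1x1 system solves to (2wmu0 - sum(c_nb * g_nb)) / c_center
        g = make_grid(5, 5, 0.002, 0.002)
        phase = quadratic_phase(g, acq, sigma0=1.0)
        derivs = central_derivatives(phase)
        masks = make_ring_masks(g, 2)
        unknown = np.zeros(g.shape, dtype=bool)
        unknown[2, 2] = True
        gk = np.full(g.shape, 2.0)
        sys_ = assemble_stab_system(derivs, 0.003, gk, masks, acq, unknown=unknown)
        assert sys_.matrix.shape == (1, 1)
        got = solve_stab_ept(sys_)[1].values[2, 2]
        # hand algebra
        rho, dx, dy = 0.003, g.dx, g.dy
        px, py = derivs.d_dx.values[2, 2], derivs.d_dy.values[2, 2]
        lap = derivs.laplacian.values[2, 2]
        cc = lap + 2 * rho * (1 / dx**2 + 1 / dy**2)
        nb = (
            (px / (2 * dx) - rho / dx**2)
            + (-px / (2 * dx) - rho / dx**2)
            + (py / (2 * dy) - rho / dy**2)
            + (-py / (2 * dy) - rho / dy**2)
        )
        expect = (acq.source - 2.0 * nb) / cc
        assert got == pytest.approx(expect, rel=1e-12)

    @pytest.mark.parametrize("deriv", ["central", "savgol"])
    @pytest.mark.parametrize("rho", [0.0, 0.001, 0.01])
    def test_homogeneous_quadratic_recovery_any_rho(
        self, grid36, masks36, acq, deriv, rho
    ):
        phase = quadratic_phase(grid36, acq, sigma0=1.0)
        opts = EPTOptions(formulation="stab", rho=rho, derivative_method=deriv)
        sigma = reconstruct(phase, masks36, acq, opts, padding_sigma=1.0)
        assert np.max(np.abs(sigma.values[masks36.interior] - 1.0)) < 1e-8

    def test_stab_beats_std_on_noisefree_phantom(self, phantom, clean_phase, acq):
        truth, _, masks = phantom
        stab = reconstruct(clean_phase, masks, acq,
                           EPTOptions(formulation="stab", rho=0.001))
        std = reconstruct(clean_phase, masks, acq, EPTOptions(formulation="std"))
        t = truth.values[masks.interior]
        mae_stab = np.mean(np.abs(stab.values[masks.interior] - t))
        mae_std = np.mean(np.abs(np.nan_to_num(std.values[masks.interior]) - t))
        assert mae_stab < mae_std


class TestGridSearchRho:
    def test_singleton_candidate(self, phantom, clean_phase, acq):
        truth, _, masks = phantom
        assert grid_search_rho(clean_phase, truth, [0.001], masks, acq) == 0.001

    def test_tie_returns_smaller_rho(self, monkeypatch, phantom, clean_phase, acq):
        truth, _, masks = phantom
        import mrept.numerical_ept as ne

        monkeypatch.setattr(ne, "ssim", lambda *a, **k: 0.5)  # force exact tie
        assert grid_search_rho(clean_phase, truth, [0.01, 0.001], masks, acq) == 0.001

    def test_noise_shifts_preference_to_larger_rho(self, phantom, acq):
        # trend check: the SSIM-optimal viscosity grows once noise appears
        truth, _, masks = phantom
        clean = solve_forward_phase(truth, acq, refine=1)
        cands = [1e-5, 1e-4, 1e-3, 1e-2]
        rho_clean = grid_search_rho(clean, truth, cands, masks, acq)
        assert rho_clean <= 1e-3
        larger = 0
        for seed in range(5):
            noisy = add_phase_noise(clean, 50, seed=seed)
            if grid_search_rho(noisy, truth, cands, masks, acq) > rho_clean:
                larger += 1
        assert larger >= 4

    def test_empty_candidates_rejected(self, phantom, clean_phase, acq):
        truth, _, masks = phantom
        with pytest.raises(ValueError):
            grid_search_rho(clean_phase, truth, [], masks, acq)


class TestNoiseDegradation:
    def test_std_ept_mae_monotone_as_snr_falls(self, phantom, clean_phase, acq):
        truth, _, masks = phantom
        t = truth.values[masks.interior]
        maes = []
        for snr in (200, 100, 50):
            trial_maes = []
            for trial in range(5):
                noisy = add_phase_noise(clean_phase, snr, seed=trial)
                sigma = reconstruct(noisy, masks, acq, EPTOptions(formulation="std"))
                vals = np.nan_to_num(sigma.values[masks.interior])
                trial_maes.append(np.mean(np.abs(vals - t)))
            maes.append(np.mean(trial_maes))
        assert maes[0] <= maes[1] <= maes[2]
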