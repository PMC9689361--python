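"""Physics-informed reconstruction of conductivity from a single phase map.

A small coordinate network (four 50-neuron sigmoid layers, no biases) maps
normalized pixel coordinates to a predicted transceive phase. Exact spatial
derivatives of the prediction are obtained by forward-propagating value,
gradient and second-derivative streams through the network (the layers are
closed-form differentiable), so no numerical differentiation of noisy data
ever occurs. The derivatives feed the stabilized convection-reaction-
diffusion system in gamma = 1/sigma, solved sparsely *inside* the training
graph: the backward pass through the solve is the adjoint system, making the
reconstruction differentiable with respect to the network weights and the
diffusion coefficient rho.

rho is a trainable scalar squashed into (1e-6, 0.01) by a sigmoid; the lower
bound keeps the viscosity term present, the upper bound caps the smoothing
at the largest artifact-free value.

Training is full-batch Adam on the weighted loss lambda1 * L_phase +
lambda2 * L_bc in two stages: phase fitting only (lambda = (100, 0), PDE
solve skipped), then joint fitting (lambda = (100, 1)) where the boundary
loss compares the predicted conductivity with the known reference-padding
ring. The snapshot with minimal weighted loss is returned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Literal

import numpy as np
import scipy.ndimage as ndi
import scipy.sparse as sp

from scipy.special import expit as ad_expit

from .autodiff import Adam, Tensor, concatenate, sigmoid, sparse_mm, sparse_solve
from .differentiation import DerivativeSet
from .grids_io import Grid2D, RegionMasks, ScalarField2D, ring_mask
from .phantom_forward import AcquisitionSpec

__all__ = [
    "PINNConfig",
    "NetworkState",
    "TrainLog",
    "ReconResult",
    "init_network",
    "predict_phase",
    "ad_derivatives",
    "rho_value",
    "loss_phase",
    "loss_sigma_bc",
    "pinn_sigma",
    "train_pinn",
]

_SSIM_K1, _SSIM_K2 = 0.01, 0.03


@dataclass
class PINNConfig:
    """Hyper-parameters of the physics-informed reconstruction."""

    hidden_layers: int = 4
    width: int = 50
    lr: float = 0.001
    iterations: int = 60_000
    stage1_iterations: int = 10_000
    lambda1: float = 100.0
    lambda2: float = 1.0
    rho_bounds: tuple[float, float] = (1e-6, 0.01)
    formulation: Literal["stab", "std"] = "stab"
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.rho_bounds
        if not (0 < lo < hi):
            raise ValueError("rho bounds must satisfy 0 < lo < hi")
        if self.stage1_iterations > self.iterations:
            raise ValueError("stage1_iterations cannot exceed iterations")
        if self.width < 1 or self.hidden_layers < 1:
            raise ValueError("network must have at least one layer and one neuron")


@dataclass
class NetworkState:
    """Weights, the unconstrained rho parameter, and the output scaling."""

    weights: list[Tensor]
    rho_raw: Tensor
    phase_min: float
    phase_max: float
    norm_lx: float  # physical length mapped to normalized coordinate 1 (x)
    norm_ly: float
    config: PINNConfig

    def parameter_count(self) -> int:
        return sum(w.data.size for w in self.weights)

    def copy_weights(self) -> list[np.ndarray]:
        return [w.data.copy() for w in self.weights]


@dataclass
class TrainLog:
    """Per-iteration training records plus instrumentation counters."""

    iteration: list[int] = field(default_factory=list)
    l_phase: list[float] = field(default_factory=list)
    l_bc: list[float] = field(default_factory=list)
    total: list[float] = field(default_factory=list)
    rho: list[float] = field(default_factory=list)
    best_iteration: int = -1
    best_total: float = math.inf
    solver_calls: int = 0
    solver_failures: int = 0

    def append(self, it: int, lp: float, lb: float, tot: float, rho: float) -> None:
        self.iteration.append(it)
        self.l_phase.append(lp)
        self.l_bc.append(lb)
        self.total.append(tot)
        self.rho.append(rho)


@dataclass
class ReconResult:
    """Best-model reconstruction: conductivity, predicted phase, learned rho."""

    sigma: ScalarField2D
    phase_pred: ScalarField2D
    rho: float
    best_iteration: int
    formulation: str


# ---------------------------------------------------------------------------
# network


def init_network(config: PINNConfig, measured_phase: ScalarField2D) -> NetworkState:
    """Create a Kaiming-initialized, bias-free sigmoid network.

    The output is a sigmoid rescaled to the [min, max] range of the measured
    phase - the only phase information available at inference. Deterministic
    given ``config.seed``.
    """
    vals = measured_phase.values
    pmin, pmax = float(vals.min()), float(vals.max())
    if pmax == pmin:
        raise ValueError("measured phase has zero range; cannot scale the output")
    rng = np.random.default_rng(config.seed)
    sizes = [2] + [config.width] * config.hidden_layers + [1]
    weights = []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        bound = 1.0 / math.sqrt(fan_in)  # Kaiming-uniform for bias-free layers
        weights.append(Tensor(rng.uniform(-bound, bound, size=(fan_in, fan_out)),
                              requires_grad=True))
    g = measured_phase.grid
    return NetworkState(
        weights=weights,
        rho_raw=Tensor(0.0, requires_grad=True),  # rho starts at the bounds' midpoint
        phase_min=pmin,
        phase_max=pmax,
        norm_lx=(g.nx - 1) * g.dx,
        norm_ly=(g.ny - 1) * g.dy,
        config=config,
    )


def rho_value(theta: float, bounds: tuple[float, float]) -> float:
    """Sigmoid-bounded diffusion coefficient: lo + (hi - lo) * sigmoid(theta)."""
    lo, hi = bounds
    if not (0 < lo < hi):
        raise ValueError("invalid rho bounds")
    return lo + (hi - lo) / (1.0 + math.exp(-theta))


def _rho_tensor(net: NetworkState) -> Tensor:
    lo, hi = net.config.rho_bounds
    return lo + (hi - lo) * sigmoid(net.rho_raw)


def _norm_coords(net: NetworkState, grid: Grid2D) -> np.ndarray:
    """Pixel-center coordinates normalized to [0, 1]^2, flattened row-major."""
    x, y = grid.pixel_centers()
    return np.column_stack([x.ravel() / net.norm_lx, y.ravel() / net.norm_ly])


def _forward_value(net: NetworkState, coords: np.ndarray) -> Tensor:
    """Plain forward pass: (N, 2) normalized coords -> (N,) phase tensor."""
    h = Tensor(coords)
    for w in net.weights[:-1]:
        h = sigmoid(h @ w)
    z = h @ net.weights[-1]
    out = sigmoid(z)
    span = net.phase_max - net.phase_min
    return (net.phase_min + span * out).reshape(-1)


def _sigmoid_streams(t: Tensor, n: int) -> Tensor:
    """Fused sigmoid layer acting on stacked (u, ux, uy, uxx, uyy) streams.

    Applies v = s(u) and propagates the derivative streams with the chain
    rule (s' = v(1-v), s'' = s'(1-2v)); the backward pass additionally uses
    s''' = s'(1 - 6v + 6v^2). One tape node instead of ~15 keeps the
    training loop memory-bandwidth-friendly; the math is identical to
    composing the elementwise primitives.
    """
    z = t.data
    u, ux, uy, uxx, uyy = z[0:n], z[n:2 * n], z[2 * n:3 * n], z[3 * n:4 * n], z[4 * n:5 * n]
    v = ad_expit(u)
    d1 = v * (1.0 - v)
    d2 = d1 * (1.0 - 2.0 * v)
    out = np.empty_like(z)
    out[0:n] = v
    out[n:2 * n] = d1 * ux
    out[2 * n:3 * n] = d1 * uy
    out[3 * n:4 * n] = d2 * ux * ux + d1 * uxx
    out[4 * n:5 * n] = d2 * uy * uy + d1 * uyy
    res = Tensor(out, _prev=(t,))

    def bw(g):
        if not t.requires_grad:
            return
        gv, gx, gy = g[0:n], g[n:2 * n], g[2 * n:3 * n]
        gxx, gyy = g[3 * n:4 * n], g[4 * n:5 * n]
        d3 = d1 * (1.0 - 6.0 * v + 6.0 * v * v)
        gi = np.empty_like(z)
        gi[0:n] = (
            gv * d1
            + (gx * ux + gy * uy) * d2
            + gxx * (d3 * ux * ux + d2 * uxx)
            + gyy * (d3 * uy * uy + d2 * uyy)
        )
        gi[n:2 * n] = d1 * gx + 2.0 * (d2 * ux) * gxx
        gi[2 * n:3 * n] = d1 * gy + 2.0 * (d2 * uy) * gyy
        gi[3 * n:4 * n] = d1 * gxx
        gi[4 * n:5 * n] = d1 * gyy
        t._accum(gi)

    res._backward = bw
    return res


def _forward_with_derivs(net: NetworkState, coords: np.ndarray):
    """Forward pass propagating value + first/second derivative streams.

    The five streams (u, du/dx, du/dy, d2u/dx2, d2u/dy2, derivatives w.r.t.
    the *normalized* inputs) are stacked along the batch axis so each linear
    layer is a single matrix product; the sigmoid layer recombines them with
    the chain rule using s' = s(1-s) and s'' = s(1-s)(1-2s). Returned
    derivatives are converted to physical units (1/Lx, 1/Lx^2 factors).
    """
    n = coords.shape[0]
    zeros = np.zeros_like(coords)
    ex = np.tile([1.0, 0.0], (n, 1))
    ey = np.tile([0.0, 1.0], (n, 1))
    stack = Tensor(np.vstack([coords, ex, ey, zeros, zeros]))

    def split(t: Tensor):
        return (t[0:n], t[n:2 * n], t[2 * n:3 * n], t[3 * n:4 * n], t[4 * n:5 * n])

    h = stack
    for w in net.weights[:-1]:
        h = _sigmoid_streams(h @ w, n)
    z = h @ net.weights[-1]
    u, ux, uy, uxx, uyy = split(z)
    s = sigmoid(u)
    d1 = s * (1.0 - s)
    d2 = d1 * (1.0 - 2.0 * s)
    span = net.phase_max - net.phase_min
    phi = (net.phase_min + span * s).reshape(-1)
    lx, ly = net.norm_lx, net.norm_ly
    phi_x = (span * d1 * ux).reshape(-1) * (1.0 / lx)
    phi_y = (span * d1 * uy).reshape(-1) * (1.0 / ly)
    phi_xx = (span * (d2 * ux * ux + d1 * uxx)).reshape(-1) * (1.0 / lx**2)
    phi_yy = (span * (d2 * uy * uy + d1 * uyy)).reshape(-1) * (1.0 / ly**2)
    return phi, phi_x, phi_y, phi_xx, phi_yy


def predict_phase(net: NetworkState, grid: Grid2D) -> ScalarField2D:
    """Evaluate the network at every pixel center (full-image batch)."""
    phi = _forward_value(net, _norm_coords(net, grid))
    return ScalarField2D(grid, phi.data.reshape(grid.shape), role="phase")


def ad_derivatives(net: NetworkState, grid: Grid2D) -> DerivativeSet:
    """Exact network derivatives w.r.t. physical coordinates on the grid."""
    _, px, py, pxx, pyy = _forward_with_derivs(net, _norm_coords(net, grid))
    shape = grid.shape
    return DerivativeSet(
        d_dx=ScalarField2D(grid, px.data.reshape(shape)),
        d_dy=ScalarField2D(grid, py.data.reshape(shape)),
        laplacian=ScalarField2D(grid, (pxx.data + pyy.data).reshape(shape)),
    )


# ---------------------------------------------------------------------------
# differentiable losses


@lru_cache(maxsize=8)
def _gaussian_conv_matrix(ny: int, nx: int) -> sp.csr_matrix:
    """Sparse operator applying the 11x11 Gaussian SSIM window (reflect)."""

    def axis_op(n: int) -> sp.csr_matrix:
        dense = ndi.gaussian_filter1d(np.eye(n), sigma=1.5, axis=0, mode="reflect",
                                      truncate=3.5)
        return sp.csr_matrix(dense)

    return sp.kron(axis_op(ny), axis_op(nx), format="csr")


def _ssim_windowed_t(a: Tensor, b_const: np.ndarray, grid_shape: tuple[int, int]) -> Tensor:
    """Windowed mean SSIM (window-radius border cropped), differentiable in a.

    Matches metrics_filters.ssim with region=None: data range is the
    reference's max - min.
    """
    ny, nx = grid_shape
    data_range = float(np.ptp(b_const))
    c1 = (_SSIM_K1 * data_range) ** 2
    c2 = (_SSIM_K2 * data_range) ** 2
    G = _gaussian_conv_matrix(ny, nx)
    b = b_const.ravel()
    ub = G @ b
    vb = G @ (b * b) - ub * ub
    ua = sparse_mm(G, a)
    va = sparse_mm(G, a * a) - ua * ua
    vab = sparse_mm(G, a * Tensor(b)) - ua * Tensor(ub)
    smap = ((2.0 * ua * Tensor(ub) + c1) * (2.0 * vab + c2)) / (
        (ua * ua + Tensor(ub * ub) + c1) * (va + Tensor(vb) + c2)
    )
    pad = 5
    core = smap.reshape(ny, nx)[pad:ny - pad, pad:nx - pad]
    return core.mean()


def _ssim_global_t(a: Tensor, b_const: np.ndarray, data_range: float) -> Tensor:
    """Global-statistics SSIM over sample vectors, differentiable in a."""
    c1 = (_SSIM_K1 * data_range) ** 2
    c2 = (_SSIM_K2 * data_range) ** 2
    n = b_const.size
    ua = a.mean()
    ub = float(b_const.mean())
    da = a - ua
    db = b_const - ub
    va = (da * da).sum() * (1.0 / n)
    vb = float((db * db).mean())
    vab = (da * Tensor(db)).sum() * (1.0 / n)
    return ((2.0 * ua * ub + c1) * (2.0 * vab + c2)) / (
        (ua * ua + ub * ub + c1) * (va + vb + c2)
    )


def _loss_phase_t(pred: Tensor, measured: np.ndarray, grid_shape) -> Tensor:
    diff = pred - Tensor(measured.ravel())
    mse = (diff * diff).mean()
    return mse + (1.0 - _ssim_windowed_t(pred, measured, grid_shape))


def _loss_bc_t(pred_eval: Tensor, known_eval: np.ndarray) -> Tensor:
    """Boundary-conductivity loss on the padding evaluation pixels.

    MSE plus (1 - SSIM); the SSIM uses global statistics over the ring (an
    11x11 windowed map is ill-defined on a 2-pixel ring) with the known
    conductivity magnitude as the data range, so identical constant rings
    score exactly 1.
    """
    diff = pred_eval - Tensor(known_eval)
    mse = (diff * diff).mean()
    data_range = float(np.max(np.abs(known_eval)))
    return mse + (1.0 - _ssim_global_t(pred_eval, known_eval, data_range))


def loss_phase(pred: ScalarField2D, measured: ScalarField2D) -> float:
    """Phase-fitting loss: MSE(pred, measured) + (1 - SSIM(pred, measured))."""
    if pred.grid.shape != measured.grid.shape:
        raise ValueError("fields must share a grid")
    return _loss_phase_t(
        Tensor(pred.values.ravel()), measured.values, measured.grid.shape
    ).item()


def loss_sigma_bc(
    pred_sigma: ScalarField2D,
    known_sigma: np.ndarray,
    padding_eval_mask: np.ndarray,
) -> float:
    """Boundary loss restricted to padding evaluation pixels.

    ``known_sigma`` is a full-grid array of reference conductivities.
    """
    m = np.asarray(padding_eval_mask, dtype=bool)
    if not m.any():
        raise ValueError("empty padding evaluation mask")
    return _loss_bc_t(
        Tensor(pred_sigma.values[m]), np.asarray(known_sigma, dtype=float)[m]
    ).item()


# ---------------------------------------------------------------------------
# differentiable stabilized-EPT solve


class _StabAssembler:
    """Precomputed sparsity structure of the stabilized system.

    Unknowns are every pixel except the outermost one-pixel ring, whose known
    gamma closes the stencil (Dirichlet). The remaining padding pixels stay
    unknowns so the boundary-conductivity loss over them is informative.
    """

    def __init__(self, grid: Grid2D, unknown: np.ndarray, gamma_known: np.ndarray,
                 acq: AcquisitionSpec):
        ny, nx = grid.shape
        self.grid = grid
        self.unknown = np.asarray(unknown, dtype=bool)
        jj, ii = np.nonzero(self.unknown)
        if jj.min() == 0 or ii.min() == 0 or jj.max() == ny - 1 or ii.max() == nx - 1:
            raise ValueError("open stencil: unknowns touch the grid border")
        self.n = jj.size
        idx = -np.ones((ny, nx), dtype=int)
        idx[self.unknown] = np.arange(self.n)
        self.flat_unknown = jj * nx + ii
        self.source = acq.source
        ar = np.arange(self.n)
        rows = [ar]
        cols = [ar]
        self.dir_info = []
        for dj, di in ((0, 1), (0, -1), (1, 0), (-1, 0)):
            nj, ni = jj + dj, ii + di
            nb_unknown = self.unknown[nj, ni]
            rows.append(ar[nb_unknown])
            cols.append(idx[nj, ni][nb_unknown])
            kg = np.where(nb_unknown, 0.0, gamma_known[nj, ni])
            self.dir_info.append((nb_unknown, kg))
        self.rows = np.concatenate(rows)
        self.cols = np.concatenate(cols)
        dx, dy = grid.dx, grid.dy
        self.inv2dx, self.inv2dy = 1.0 / (2 * dx), 1.0 / (2 * dy)
        self.invdx2, self.invdy2 = 1.0 / dx**2, 1.0 / dy**2
        # embedding of the unknown gamma vector into the full sigma image
        base = np.zeros(ny * nx)
        known_flat = ~self.unknown.ravel()
        base[known_flat] = 1.0 / gamma_known.ravel()[known_flat]
        self.base_sigma = base
        self.embed = sp.csr_matrix(
            (np.ones(self.n), (self.flat_unknown, ar)), shape=(ny * nx, self.n)
        )

    def solve(self, px: Tensor, py: Tensor, lap: Tensor, rho: Tensor) -> Tensor:
        """Assemble and solve for gamma at the unknowns (differentiable)."""
        f = self.flat_unknown
        px_u, py_u, lap_u = px[f], py[f], lap[f]
        center = lap_u + rho * (2.0 * (self.invdx2 + self.invdy2))
        c_e = px_u * self.inv2dx - rho * self.invdx2
        c_w = px_u * (-self.inv2dx) - rho * self.invdx2
        c_n = py_u * self.inv2dy - rho * self.invdy2
        c_s = py_u * (-self.inv2dy) - rho * self.invdy2
        coeffs = (c_e, c_w, c_n, c_s)
        data = [center]
        rhs = Tensor(np.full(self.n, self.source))
        for c, (nb_unknown, kg) in zip(coeffs, self.dir_info):
            data.append(c[nb_unknown])
            rhs = rhs - c * Tensor(kg)
        return sparse_solve(concatenate(data), self.rows, self.cols, self.n, rhs)

    def sigma_image(self, gamma_u: Tensor) -> Tensor:
        """Full-grid conductivity image (Dirichlet ring filled from knowns)."""
        sigma_u = gamma_u ** -1.0
        return sparse_mm(self.embed, sigma_u) + Tensor(self.base_sigma)


def pinn_sigma(
    derivs: DerivativeSet,
    rho: float,
    masks: RegionMasks,
    acq: AcquisitionSpec,
    formulation: Literal["stab", "std"] = "stab",
    padding_sigma: float = 1.0,
) -> ScalarField2D:
    """Conductivity from a derivative set, the way the PINN computes it.

    ``stab``: solve the stabilized system with the outermost one-pixel ring
    as Dirichlet closure (all other pixels, padding included, are unknowns).
    ``std``: pointwise sigma = laplacian / (2*omega*mu0).
    """
    g = derivs.grid
    if formulation == "std":
        return ScalarField2D(g, derivs.laplacian.values / acq.source, role="conductivity")
    unknown = ~ring_mask(g, 0, 1)
    gamma_known = np.full(g.shape, 1.0 / padding_sigma)
    asm = _StabAssembler(g, unknown, gamma_known, acq)
    gamma_u = asm.solve(
        Tensor(derivs.d_dx.values.ravel()),
        Tensor(derivs.d_dy.values.ravel()),
        Tensor(derivs.laplacian.values.ravel()),
        Tensor(float(rho)),
    )
    sigma = asm.sigma_image(gamma_u)
    return ScalarField2D(g, sigma.data.reshape(g.shape), role="conductivity")


# ---------------------------------------------------------------------------
# training


def train_pinn(
    measured_phase: ScalarField2D,
    known_padding_sigma: float,
    masks: RegionMasks,
    acq: AcquisitionSpec,
    config: PINNConfig,
) -> tuple[TrainLog, ReconResult]:
    """Two-stage full-batch Adam training; returns the best-loss snapshot.

    Stage 1 (first ``stage1_iterations``): lambda = (lambda1, 0); only the
    phase loss is optimized and the PDE solve never runs. Stage 2: lambda =
    (lambda1, lambda2); the differentiable stabilized solve (or the pointwise
    std formula) produces sigma-hat and the boundary loss on the padding
    evaluation ring. rho receives gradient only in stage 2. The returned
    reconstruction comes from the snapshot with minimal weighted total loss
    (phase loss alone for pure stage-1 runs). Deterministic given the seed.
    """
    grid = measured_phase.grid
    net = init_network(config, measured_phase)
    opt = Adam(net.weights + [net.rho_raw], lr=config.lr)
    coords = _norm_coords(net, grid)
    meas = measured_phase.values
    log = TrainLog()

    stab = config.formulation == "stab"
    gamma_known = np.full(grid.shape, 1.0 / known_padding_sigma)
    if stab:
        unknown = ~ring_mask(grid, 0, 1)
        asm = _StabAssembler(grid, unknown, gamma_known, acq)
        # evaluation ring: padding pixels that are NOT Dirichlet closure
        eval_mask = masks.padding & unknown
    else:
        asm = None
        eval_mask = masks.padding
    eval_flat = np.flatnonzero(eval_mask.ravel())
    known_eval = np.full(eval_flat.size, known_padding_sigma)

    best_weights: list[np.ndarray] | None = None
    best_rho_raw = 0.0

    for it in range(config.iterations):
        stage2 = it >= config.stage1_iterations
        opt.zero_grad()
        if not stage2:
            phi = _forward_value(net, coords)
            lphi = _loss_phase_t(phi, meas, grid.shape)
            total = config.lambda1 * lphi
            lbc_val = math.nan
        else:
            phi, px, py, pxx, pyy = _forward_with_derivs(net, coords)
            lphi = _loss_phase_t(phi, meas, grid.shape)
            lap = pxx + pyy
            rho_t = _rho_tensor(net)
            try:
                if stab:
                    log.solver_calls += 1
                    gamma_u = asm.solve(px, py, lap, rho_t)
                    sigma_img = asm.sigma_image(gamma_u)
                else:
                    sigma_img = lap * (1.0 / acq.source)
                sigma_eval = sigma_img[eval_flat]
                lbc = _loss_bc_t(sigma_eval, known_eval)
            except RuntimeError:
                log.solver_failures += 1
                log.append(it, float(lphi.item()), math.nan, math.nan,
                           rho_value(float(net.rho_raw.data), config.rho_bounds))
                continue  # skip the update this iteration
            total = config.lambda1 * lphi + config.lambda2 * lbc
            lbc_val = float(lbc.item())
        tot_val = float(total.item())
        if not math.isfinite(tot_val):
            raise FloatingPointError(
                f"training diverged at iteration {it}: total loss {tot_val}"
            )
        total.backward()
        opt.step()
        rho_now = rho_value(float(net.rho_raw.data), config.rho_bounds)
        log.append(it, float(lphi.item()), lbc_val, tot_val, rho_now)
        # best-model tracking: stage-2 totals, or stage-1 for pure-fit runs
        track = stage2 or config.iterations <= config.stage1_iterations
        if track and tot_val < log.best_total:
            log.best_total = tot_val
            log.best_iteration = it
            best_weights = net.copy_weights()
            best_rho_raw = float(net.rho_raw.data)

    if best_weights is None:  # e.g. every stage-2 solve failed
        best_weights = net.copy_weights()
        best_rho_raw = float(net.rho_raw.data)
        log.best_iteration = config.iterations - 1

    for w, bw in zip(net.weights, best_weights):
        w.data = bw
    net.rho_raw.data = np.asarray(best_rho_raw)
    rho_best = rho_value(best_rho_raw, config.rho_bounds)
    phase_pred = predict_phase(net, grid)
    derivs = ad_derivatives(net, grid)
    sigma = pinn_sigma(derivs, rho_best, masks, acq, config.formulation,
                       padding_sigma=known_padding_sigma)
    result = ReconResult(
        sigma=sigma,
        phase_pred=phase_pred,
        rho=rho_best,
        best_iteration=log.best_iteration,
        formulation=config.formulation,
    )
    return log, result
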