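"""Numerical phase-based EPT baselines.

Two reconstructions of conductivity sigma from a transceive-phase map:

* **std-EPT** - assumes locally homogeneous conductivity (grad(gamma) = 0),
  giving the pointwise formula sigma = laplacian(phi) / (2*omega*mu0).
* **stab-EPT** - keeps the grad(gamma) convection term and adds an artificial
  diffusion (viscosity) term -rho * laplacian(gamma) that damps the spurious
  oscillations of the plain convection-reaction form; discretized with
  central differences into a sparse 5-point linear system in gamma = 1/sigma
  with Dirichlet values on the reference padding ring. ``rho = 0`` recovers
  the unstabilized convection-reaction (cr-EPT) system.

The stencil for an unknown pixel (i, j) encodes

    2*omega*mu0 = gamma_ij * lap(phi)
                + dphi/dx * (g_{i+1,j} - g_{i-1,j}) / (2 dx)
                + dphi/dy * (g_{i,j+1} - g_{i,j-1}) / (2 dy)
                - rho * [5-point laplacian of gamma]

with rho applied over the physical spacing exactly as written, so a given
rho value transfers between implementations that honor the spacing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .differentiation import DerivativeSet, central_derivatives, savgol_derivatives
from .grids_io import RegionMasks, ScalarField2D
from .metrics_filters import ssim
from .phantom_forward import AcquisitionSpec, NumericalFailure

__all__ = [
    "EPTOptions",
    "StabSystem",
    "std_ept",
    "assemble_stab_system",
    "solve_stab_ept",
    "grid_search_rho",
    "reconstruct",
]


@dataclass
class EPTOptions:
    """Reconstruction options: formulation, diffusion coefficient, derivatives."""

    formulation: Literal["std", "cr", "stab"] = "stab"
    rho: float = 0.001
    derivative_method: Literal["central", "savgol"] = "central"
    savgol_window: int = 5

    def __post_init__(self) -> None:
        if self.rho < 0:
            raise ValueError("rho must be non-negative")


@dataclass
class StabSystem:
    """Sparse linear system A gamma = b for the stabilized formulation."""

    matrix: sp.csr_matrix
    rhs: np.ndarray
    unknown_index: np.ndarray  # (ny, nx) int map, -1 where not an unknown
    unknown: np.ndarray  # boolean mask of unknowns
    dirichlet_values: np.ndarray  # full map; consulted at non-unknown pixels
    grid: "object" = field(default=None, repr=False)


def std_ept(
    derivs: DerivativeSet, acq: AcquisitionSpec, sigma_floor: float = 1e-6
) -> ScalarField2D:
    """Pointwise std-EPT: sigma = lap(phi) / (2*omega*mu0).

    Pixels whose Laplacian magnitude falls below ``sigma_floor`` (expressed
    as the conductivity it would imply, S/m) are masked as NaN rather than
    exploding toward +/-inf.
    """
    lap = derivs.laplacian.values
    sigma = lap / acq.source
    masked = np.abs(sigma) < sigma_floor
    sigma = np.where(masked, np.nan, sigma)
    if masked.all():
        warnings.warn("std-EPT: all pixels below Laplacian threshold (degenerate input)")
    return derivs.laplacian.copy_with(sigma, role="conductivity")


def _stab_coefficients(derivs: DerivativeSet, rho: float, acq: AcquisitionSpec):
    """Per-pixel stencil coefficients (center, east, west, north, south)."""
    g = derivs.grid
    dx, dy = g.dx, g.dy
    px = derivs.d_dx.values
    py = derivs.d_dy.values
    lap = derivs.laplacian.values
    center = lap + 2.0 * rho * (1.0 / dx**2 + 1.0 / dy**2)
    east = px / (2 * dx) - rho / dx**2
    west = -px / (2 * dx) - rho / dx**2
    north = py / (2 * dy) - rho / dy**2
    south = -py / (2 * dy) - rho / dy**2
    return center, east, west, north, south


def assemble_stab_system(
    derivs: DerivativeSet,
    rho: float,
    gamma_known: np.ndarray,
    masks: RegionMasks,
    acq: AcquisitionSpec,
    unknown: np.ndarray | None = None,
) -> StabSystem:
    """Assemble the central-difference system in gamma for the unknown pixels.

    ``unknown`` defaults to the interior ROI with the full padding ring as
    Dirichlet knowns (the classic boundary treatment of the convection-
    reaction formulation). ``gamma_known`` is a full-grid array consulted at
    Dirichlet pixels. Every unknown's 5-point stencil must be closed by
    unknowns or Dirichlet pixels.
    """
    g = derivs.grid
    ny, nx = g.shape
    if unknown is None:
        unknown = masks.interior.copy()
    unknown = np.asarray(unknown, dtype=bool)
    jj, ii = np.nonzero(unknown)
    if jj.size == 0:
        raise ValueError("no unknown pixels to solve for")
    if (jj.min() == 0 or ii.min() == 0 or jj.max() == ny - 1 or ii.max() == nx - 1):
        raise ValueError("open stencil: unknown pixels touch the grid border")
    idx = -np.ones((ny, nx), dtype=int)
    idx[unknown] = np.arange(jj.size)
    center, east, west, north, south = _stab_coefficients(derivs, rho, acq)
    gamma_known = np.asarray(gamma_known, dtype=float)

    rows = [idx[jj, ii]]
    cols = [idx[jj, ii]]
    data = [center[jj, ii]]
    rhs = np.full(jj.size, acq.source, dtype=float)
    for coeff, dj, di in ((east, 0, 1), (west, 0, -1), (north, 1, 0), (south, -1, 0)):
        nj, ni = jj + dj, ii + di
        c = coeff[jj, ii]
        nb_unknown = unknown[nj, ni]
        rows.append(idx[jj, ii][nb_unknown])
        cols.append(idx[nj, ni][nb_unknown])
        data.append(c[nb_unknown])
        rhs[~nb_unknown] -= c[~nb_unknown] * gamma_known[nj[~nb_unknown], ni[~nb_unknown]]
    A = sp.csr_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
        shape=(jj.size, jj.size),
    )
    return StabSystem(
        matrix=A,
        rhs=rhs,
        unknown_index=idx,
        unknown=unknown,
        dirichlet_values=gamma_known,
        grid=g,
    )


def solve_stab_ept(
    system: StabSystem,
) -> tuple[ScalarField2D, ScalarField2D, np.ndarray]:
    """Direct sparse solve of the assembled system.

    Returns ``(sigma, gamma, nonphysical)`` fields on the full grid: Dirichlet
    pixels are filled from the known gamma values; pixels with gamma <= 0 are
    flagged in the boolean ``nonphysical`` mask (reported, never clipped).
    """
    with warnings.catch_warnings():
        warnings.simplefilter("error", spla.MatrixRankWarning)
        try:
            gvec = spla.spsolve(system.matrix.tocsc(), system.rhs)
        except (spla.MatrixRankWarning, RuntimeError) as exc:
            raise NumericalFailure(f"stab-EPT system is singular: {exc}") from exc
    if not np.all(np.isfinite(gvec)):
        raise NumericalFailure("stab-EPT solve returned non-finite gamma")
    gamma = system.dirichlet_values.astype(float).copy()
    gamma[system.unknown] = gvec
    nonphysical = gamma <= 0
    with np.errstate(divide="ignore"):
        sigma = 1.0 / gamma
    grid = system.grid
    return (
        ScalarField2D(grid, sigma, role="conductivity"),
        ScalarField2D(grid, gamma, role="gamma"),
        nonphysical,
    )


def reconstruct(
    phase: ScalarField2D,
    masks: RegionMasks,
    acq: AcquisitionSpec,
    options: EPTOptions,
    padding_sigma: float = 1.0,
) -> ScalarField2D:
    """One-call numerical reconstruction from a phase map.

    Computes derivatives with the configured method, then applies std-EPT or
    assembles and solves the (cr/stab)-EPT system with the padding ring as
    Dirichlet knowns at ``1 / padding_sigma``.
    """
    if options.derivative_method == "central":
        derivs = central_derivatives(phase)
    elif options.derivative_method == "savgol":
        derivs = savgol_derivatives(phase, window=options.savgol_window)
    else:
        raise ValueError(f"unknown derivative method {options.derivative_method!r}")
    if options.formulation == "std":
        return std_ept(derivs, acq)
    rho = 0.0 if options.formulation == "cr" else options.rho
    gamma_known = np.full(phase.grid.shape, 1.0 / padding_sigma)
    system = assemble_stab_system(derivs, rho, gamma_known, masks, acq)
    sigma, _, _ = solve_stab_ept(system)
    return sigma


def grid_search_rho(
    phase: ScalarField2D,
    truth: ScalarField2D,
    candidates: Sequence[float],
    masks: RegionMasks,
    acq: AcquisitionSpec,
    derivative_method: str = "central",
    padding_sigma: float = 1.0,
) -> float:
    """Pick the diffusion coefficient maximizing interior SSIM against truth.

    Ties break toward the smaller rho (least smoothing that achieves the
    score). Raises if every candidate fails to solve.
    """
    cand = sorted(float(r) for r in candidates)
    if len(cand) < 1 or any(r < 0 for r in cand):
        raise ValueError("need at least one non-negative candidate rho")
    best_rho, best_score = None, -np.inf
    for r in cand:
        opts = EPTOptions(formulation="stab", rho=r, derivative_method=derivative_method)
        try:
            sigma = reconstruct(phase, masks, acq, opts, padding_sigma=padding_sigma)
        except NumericalFailure:
            continue
        score = ssim(sigma, truth, region=masks.interior)
        if score > best_score:  # strict: ties keep the earlier (smaller) rho
            best_rho, best_score = r, score
    if best_rho is None:
        raise NumericalFailure("all candidate rho values failed to solve")
    return best_rho
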