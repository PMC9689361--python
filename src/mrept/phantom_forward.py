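"""Synthetic phantom construction and the forward phase simulator.

The generator builds piecewise-constant conductivity maps - a uniform
background with circular inclusions mimicking tissues and small tumors,
surrounded by a border ring of known reference conductivity - and then
synthesizes a transceive-phase map that is *self-consistent* with the
phase-based convection-reaction PDE the reconstruction methods invert:

    div( gamma * grad(phi) ) = 2 * omega * mu0,   gamma = 1 / sigma

solved with homogeneous Dirichlet conditions on the outer border. Because the
reconstructors use only derivatives of the phase, the forward gauge (phi = 0
at the border) is immaterial; it is fixed for determinism. Solving on a
refined mesh (``refine`` = 2 by default downstream) and block-averaging back
avoids committing the inverse crime of generating and inverting data on the
identical discretization.

Measurement noise follows the phase-noise convention for MR transceive-phase
maps: i.i.d. zero-mean Gaussian with standard deviation 1/(2*SNR) radians.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .grids_io import Grid2D, RegionMasks, ScalarField2D, make_grid, make_ring_masks

__all__ = [
    "Inclusion",
    "PhantomSpec",
    "AcquisitionSpec",
    "LabelMap",
    "build_phantom",
    "solve_forward_phase",
    "add_phase_noise",
    "quadratic_phase",
    "default_phantom_spec",
    "NumericalFailure",
]

MU0 = 4e-7 * np.pi  # permeability of free space, H/m


class NumericalFailure(RuntimeError):
    """A linear solve failed (singular or severely ill-conditioned system)."""


@dataclass(frozen=True)
class Inclusion:
    """A circular region of uniform conductivity (position/radius in meters)."""

    center_x: float
    center_y: float
    radius: float
    sigma: float
    label: int


@dataclass
class PhantomSpec:
    """Geometric description of a piecewise-constant phantom with padding ring."""

    grid: Grid2D
    background_sigma: float
    inclusions: Sequence[Inclusion] = field(default_factory=tuple)
    padding_thickness: int = 3
    padding_sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.background_sigma <= 0 or self.padding_sigma <= 0:
            raise ValueError("conductivities must be positive")
        if any(inc.sigma <= 0 for inc in self.inclusions):
            raise ValueError("inclusion conductivities must be positive")
        if self.padding_thickness < 1:
            raise ValueError("padding ring must be at least 1 pixel thick")


@dataclass
class AcquisitionSpec:
    """Acquisition constants: Larmor frequency, mu0, SNR and RNG seed.

    ``snr`` may be a positive number or ``None`` / ``inf`` for noise-free.
    """

    frequency_hz: float = 127.78e6  # 3 T proton Larmor frequency
    mu0: float = MU0
    snr: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.frequency_hz <= 0 or self.mu0 <= 0:
            raise ValueError("frequency and mu0 must be positive")

    @property
    def omega(self) -> float:
        return 2 * np.pi * self.frequency_hz

    @property
    def source(self) -> float:
        """The PDE source constant 2*omega*mu0 (rad / (Ohm m^2) scale)."""
        return 2 * self.omega * self.mu0


@dataclass
class LabelMap:
    """Per-pixel tissue labels: 0 background, k = inclusion label k, -1 padding."""

    grid: Grid2D
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != self.grid.shape:
            raise ValueError("labels shape does not match grid")


def build_phantom(spec: PhantomSpec) -> tuple[ScalarField2D, LabelMap, RegionMasks]:
    """Rasterize a phantom spec into a conductivity map, label map and masks.

    A pixel belongs to an inclusion iff its center lies strictly inside the
    circle; later inclusions override earlier ones. The padding ring is set to
    ``padding_sigma`` last. An inclusion that reaches into the padding ring is
    rejected.
    """
    g = spec.grid
    masks = make_ring_masks(g, spec.padding_thickness)
    x, y = g.pixel_centers()
    sigma = np.full(g.shape, spec.background_sigma, dtype=float)
    labels = np.zeros(g.shape, dtype=int)
    for inc in spec.inclusions:
        inside = (x - inc.center_x) ** 2 + (y - inc.center_y) ** 2 < inc.radius**2
        if np.any(inside & masks.padding):
            raise ValueError(
                f"inclusion {inc.label} overlaps the padding ring; shrink or move it"
            )
        sigma[inside] = inc.sigma
        labels[inside] = inc.label
    sigma[masks.padding] = spec.padding_sigma
    labels[masks.padding] = -1
    return (
        ScalarField2D(g, sigma, role="conductivity"),
        LabelMap(g, labels),
        masks,
    )


def _forward_system(gamma: np.ndarray, dx: float, dy: float, source: float):
    """Assemble the 5-point divergence-form system with phi=0 on the border.

    Face conductivities are arithmetic means of the adjacent pixel gammas.
    Returns (A, b, index map of unknown pixels).
    """
    ny, nx = gamma.shape
    unknown = np.zeros((ny, nx), dtype=bool)
    unknown[1:-1, 1:-1] = True
    idx = -np.ones((ny, nx), dtype=int)
    idx[unknown] = np.arange(unknown.sum())
    rows, cols, data = [], [], []
    b = np.full(unknown.sum(), source, dtype=float)
    jj, ii = np.nonzero(unknown)
    for dj, di, h in ((0, 1, dx), (0, -1, dx), (1, 0, dy), (-1, 0, dy)):
        nj, ni = jj + dj, ii + di
        face = 0.5 * (gamma[jj, ii] + gamma[nj, ni]) / h**2
        # center contribution
        rows.append(idx[jj, ii])
        cols.append(idx[jj, ii])
        data.append(-face)
        nb_unknown = unknown[nj, ni]
        rows.append(idx[jj, ii][nb_unknown])
        cols.append(idx[nj, ni][nb_unknown])
        data.append(face[nb_unknown])
        # Dirichlet phi=0 neighbors contribute nothing to the RHS
    A = sp.csr_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
        shape=(b.size, b.size),
    )
    return A, b, idx, unknown


def solve_forward_phase(
    sigma: ScalarField2D,
    acq: AcquisitionSpec,
    refine: int = 2,
    return_refined: bool = False,
) -> ScalarField2D | tuple[ScalarField2D, ScalarField2D]:
    """Solve div(gamma grad phi) = 2*omega*mu0 for the transceive phase.

    The conductivity map is upsampled to a ``refine``-times finer grid by
    nearest-neighbor replication, the PDE is solved there with phi = 0 on the
    outer border, and the solution is block-averaged back to the original
    grid. ``refine=1`` reproduces the reconstruction stencil family exactly
    and is reserved for discrete-consistency tests.

    With ``return_refined=True`` the refined-grid solution (on which the
    discrete residual is exactly zero to solver tolerance) is returned too.
    """
    if refine not in (1, 2, 4):
        raise ValueError("refine must be one of 1, 2, 4")
    vals = sigma.values
    if np.any(vals <= 0):
        raise ValueError("conductivity must be positive everywhere")
    g = sigma.grid
    r = int(refine)
    fine = np.kron(vals, np.ones((r, r)))
    gamma = 1.0 / fine
    dxf, dyf = g.dx / r, g.dy / r
    A, b, idx, unknown = _forward_system(gamma, dxf, dyf, acq.source)
    phi_vec = spla.spsolve(A.tocsc(), b)
    if not np.all(np.isfinite(phi_vec)):
        raise NumericalFailure(
            "forward solve produced non-finite phase; the system is singular "
            "or ill-conditioned (check conductivity positivity and grid size)"
        )
    fine_phi = np.zeros_like(gamma)
    fine_phi[unknown] = phi_vec
    coarse = fine_phi.reshape(g.ny, r, g.nx, r).mean(axis=(1, 3))
    result = ScalarField2D(g, coarse, role="phase")
    if return_refined:
        fine_grid = make_grid(g.nx * r, g.ny * r, dxf, dyf)
        return result, ScalarField2D(fine_grid, fine_phi, role="phase")
    return result


def add_phase_noise(
    phase: ScalarField2D, snr: float | None, seed: int | None = None
) -> ScalarField2D:
    """Add i.i.d. zero-mean Gaussian noise of std 1/(2*SNR) radians.

    ``snr=None`` or ``inf`` returns the phase unchanged (noise-free).
    Deterministic given ``seed``.
    """
    if snr is None or np.isinf(snr):
        return phase.copy_with(phase.values)
    if snr <= 0:
        raise ValueError("snr must be positive")
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, 1.0 / (2.0 * snr), size=phase.values.shape)
    return phase.copy_with(phase.values + noise)


def quadratic_phase(grid: Grid2D, acq: AcquisitionSpec, sigma0: float = 1.0) -> ScalarField2D:
    """Analytic phase phi = a (x^2 + y^2) with a = omega*mu0*sigma0 / 2.

    Its Laplacian is exactly 4a = 2*omega*mu0*sigma0, so every phase-based
    reconstruction must recover the homogeneous conductivity ``sigma0``;
    central differences are exact on quadratics, making this the analytic
    exactness fixture.
    """
    a = acq.omega * acq.mu0 * sigma0 / 2.0
    x, y = grid.pixel_centers()
    return ScalarField2D(grid, a * (x**2 + y**2), role="phase")


def default_phantom_spec(
    grid: Grid2D | None = None,
    tumor_radius: float = 0.003,
    tumor_sigma: float = 1.2,
) -> PhantomSpec:
    """The default brain-like study phantom.

    A 36x36 grid at 2 mm spacing whose 3-pixel reference ring (1.0 S/m)
    encloses a 30x30 region of interest; the interior holds a 0.5 S/m
    brain-average background, a CSF-like 1.8 S/m circle, a white-matter-like
    0.3 S/m circle, and a tumor-like 1.2 S/m circle of configurable radius.
    """
    g = grid or make_grid(36, 36, 0.002, 0.002)
    inclusions = [
        Inclusion(0.024, 0.040, 0.008, 1.8, label=1),
        Inclusion(0.044, 0.026, 0.007, 0.3, label=2),
    ]
    if tumor_radius > 0:
        inclusions.append(Inclusion(0.040, 0.046, tumor_radius, tumor_sigma, label=3))
    return PhantomSpec(
        grid=g,
        background_sigma=0.5,
        inclusions=inclusions,
        padding_thickness=3,
        padding_sigma=1.0,
    )
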