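"""Numerical spatial-derivative operators for phase maps.

Two families are provided: plain second-order central differences (the
discretization the convection-reaction-diffusion reconstruction assembles
with) and Savitzky-Golay polynomial-fit derivatives, which trade a little
bias for substantial noise suppression - the reason they are the preferred
numerical differentiator for measured phase maps.

All derivatives are returned in physical units (rad/m, rad/m^2): operators
divide by the grid spacing carried on the input field.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .grids_io import ScalarField2D

__all__ = ["DerivativeSet", "central_derivatives", "savgol_derivatives"]


@dataclass
class DerivativeSet:
    """First derivatives and Laplacian of a scalar field, sharing its grid."""

    d_dx: ScalarField2D
    d_dy: ScalarField2D
    laplacian: ScalarField2D

    @property
    def grid(self):
        return self.d_dx.grid


def _central_1d(values: np.ndarray, h: float, axis: int) -> tuple[np.ndarray, np.ndarray]:
    """Second-order first/second derivatives along ``axis``; one-sided at edges."""
    v = np.moveaxis(values, axis, 0)
    n = v.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples per axis for central differences")
    d1 = np.empty_like(v)
    d2 = np.empty_like(v)
    d1[1:-1] = (v[2:] - v[:-2]) / (2 * h)
    d2[1:-1] = (v[2:] - 2 * v[1:-1] + v[:-2]) / h**2
    # second-order one-sided stencils on the outermost ring
    d1[0] = (-3 * v[0] + 4 * v[1] - v[2]) / (2 * h)
    d1[-1] = (3 * v[-1] - 4 * v[-2] + v[-3]) / (2 * h)
    if n >= 4:
        d2[0] = (2 * v[0] - 5 * v[1] + 4 * v[2] - v[3]) / h**2
        d2[-1] = (2 * v[-1] - 5 * v[-2] + 4 * v[-3] - v[-4]) / h**2
    else:  # only a first-order one-sided second derivative exists on 3 points
        d2[0] = (v[0] - 2 * v[1] + v[2]) / h**2
        d2[-1] = (v[-1] - 2 * v[-2] + v[-3]) / h**2
    return np.moveaxis(d1, 0, axis), np.moveaxis(d2, 0, axis)


def central_derivatives(field: ScalarField2D) -> DerivativeSet:
    """3-point central-difference gradient and Laplacian of a field.

    Interior pixels use the standard central stencils; the outermost ring
    falls back to second-order one-sided stencils so every pixel carries a
    derivative estimate.
    """
    g = field.grid
    if g.nx < 3 or g.ny < 3:
        raise ValueError("grid too small for central differences")
    # axis 1 is x (columns), axis 0 is y (rows)
    dx1, dx2 = _central_1d(field.values, g.dx, axis=1)
    dy1, dy2 = _central_1d(field.values, g.dy, axis=0)
    lap = dx2 + dy2
    return DerivativeSet(
        d_dx=field.copy_with(dx1, role="derivative"),
        d_dy=field.copy_with(dy1, role="derivative"),
        laplacian=field.copy_with(lap, role="derivative"),
    )


def savgol_derivatives(field: ScalarField2D, window: int = 5, order: int = 2) -> DerivativeSet:
    """Savitzky-Golay smoothed derivatives, applied separably per axis.

    A polynomial of ``order`` is least-squares fitted in a sliding window of
    ``window`` pixels along each axis; analytic derivatives of the fit give
    smoothed d/dx, d/dy, d2/dx2, d2/dy2, scaled by the physical spacing. Edges
    are handled by evaluating the polynomial fitted to the last full window
    (scipy's ``mode='interp'``). The Laplacian is d2/dx2 + d2/dy2; no cross
    term is needed by any reconstruction here.
    """
    window = int(window)
    order = int(order)
    if window % 2 == 0:
        raise ValueError("Savitzky-Golay window must be odd")
    if window < order + 1:
        raise ValueError("window must be at least order+1")
    g = field.grid
    if window > min(g.nx, g.ny):
        raise ValueError(f"window {window} exceeds the {g.nx}x{g.ny} grid")
    if order < 2:
        raise ValueError("second derivatives require polynomial order >= 2")
    v = field.values
    dx1 = savgol_filter(v, window, order, deriv=1, delta=g.dx, axis=1, mode="interp")
    dx2 = savgol_filter(v, window, order, deriv=2, delta=g.dx, axis=1, mode="interp")
    dy1 = savgol_filter(v, window, order, deriv=1, delta=g.dy, axis=0, mode="interp")
    dy2 = savgol_filter(v, window, order, deriv=2, delta=g.dy, axis=0, mode="interp")
    return DerivativeSet(
        d_dx=field.copy_with(dx1, role="derivative"),
        d_dy=field.copy_with(dy1, role="derivative"),
        laplacian=field.copy_with(dx2 + dy2, role="derivative"),
    )
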