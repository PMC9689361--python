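"""Evaluation metrics (SSIM, MAE, line-profile correlations, per-tissue
statistics) and the Gaussian pre-filter used as an optional denoising step.

The SSIM here is the classic windowed form (11x11 Gaussian window of sigma
1.5 pixels, K1 = 0.01, K2 = 0.03, no sample-covariance correction) with the
data range taken from the reference map (max - min of ``b``). Reconstruction
metrics are evaluated over the interior region of interest only: the padding
ring is imposed as known by Dirichlet-based methods and would inflate scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi

from .grids_io import ScalarField2D
from .phantom_forward import LabelMap

__all__ = [
    "ssim",
    "ssim_map",
    "global_ssim",
    "mae",
    "line_profile_cc",
    "LineProfile",
    "tissue_stats",
    "gaussian_denoise",
]

_K1, _K2 = 0.01, 0.03
_SIGMA, _TRUNCATE = 1.5, 3.5  # 11x11 Gaussian window
_PAD = 5


def _win_filter(img: np.ndarray) -> np.ndarray:
    return ndi.gaussian_filter(img, sigma=_SIGMA, truncate=_TRUNCATE, mode="reflect")


def ssim_map(a: np.ndarray, b: np.ndarray, data_range: float) -> np.ndarray:
    """Per-pixel SSIM map with the standard windowed statistics."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c1 = (_K1 * data_range) ** 2
    c2 = (_K2 * data_range) ** 2
    ua, ub = _win_filter(a), _win_filter(b)
    va = _win_filter(a * a) - ua * ua
    vb = _win_filter(b * b) - ub * ub
    vab = _win_filter(a * b) - ua * ub
    return ((2 * ua * ub + c1) * (2 * vab + c2)) / ((ua**2 + ub**2 + c1) * (va + vb + c2))


def ssim(a: ScalarField2D, b: ScalarField2D, region: np.ndarray | None = None) -> float:
    """Mean SSIM of ``a`` against the reference ``b``.

    Without ``region`` the window-radius border is cropped before averaging
    (the conventional mean SSIM); with a boolean ``region`` the SSIM map is
    averaged over those pixels instead.
    """
    if a.grid.shape != b.grid.shape:
        raise ValueError("fields must share a grid")
    data_range = float(np.ptp(b.values))
    if data_range == 0:
        # constant reference: score is 1 for maps equal to numerical precision,
        # undefined otherwise
        scale = max(float(np.max(np.abs(b.values))), 1e-300)
        if np.allclose(a.values, b.values, rtol=1e-7, atol=1e-7 * scale):
            return 1.0
        raise ValueError("reference map is constant: SSIM data range is zero")
    smap = ssim_map(a.values, b.values, data_range)
    if region is None:
        core = smap[_PAD:-_PAD, _PAD:-_PAD]
        if core.size == 0:
            raise ValueError("map too small to crop the SSIM window border")
        return float(core.mean())
    region = np.asarray(region, dtype=bool)
    if not region.any():
        raise ValueError("empty evaluation region")
    return float(smap[region].mean())


def global_ssim(a: np.ndarray, b: np.ndarray, data_range: float) -> float:
    """Unwindowed SSIM using global statistics of the two sample vectors.

    Used where a windowed map is ill-defined, e.g. on a thin boundary ring.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    c1 = (_K1 * data_range) ** 2
    c2 = (_K2 * data_range) ** 2
    ua, ub = a.mean(), b.mean()
    va = ((a - ua) ** 2).mean()
    vb = ((b - ub) ** 2).mean()
    vab = ((a - ua) * (b - ub)).mean()
    return float(
        ((2 * ua * ub + c1) * (2 * vab + c2)) / ((ua**2 + ub**2 + c1) * (va + vb + c2))
    )


def mae(a: ScalarField2D, b: ScalarField2D, region: np.ndarray | None = None) -> float:
    """Mean absolute error over ``region`` (or the whole map)."""
    if a.grid.shape != b.grid.shape:
        raise ValueError("fields must share a grid")
    diff = np.abs(a.values - b.values)
    if region is None:
        return float(diff.mean())
    region = np.asarray(region, dtype=bool)
    if not region.any():
        raise ValueError("empty evaluation region")
    return float(diff[region].mean())


@dataclass
class LineProfile:
    """A horizontal line profile pair and its Pearson correlation."""

    row: int
    recon: np.ndarray
    truth: np.ndarray
    cc: float  # NaN when either profile has zero variance


def line_profile_cc(
    recon: ScalarField2D,
    truth: ScalarField2D,
    rows: list[int],
    interior: np.ndarray | None = None,
) -> list[LineProfile]:
    """Pearson correlation of reconstruction vs truth along horizontal rows.

    With ``interior`` given, only the interior segment of each row enters the
    profile. Zero-variance profiles yield ``cc = NaN`` with a warning.
    """
    out = []
    for r in rows:
        cols = slice(None) if interior is None else interior[r]
        pr = np.asarray(recon.values[r, cols], dtype=float)
        pt = np.asarray(truth.values[r, cols], dtype=float)
        if pr.std() == 0 or pt.std() == 0:
            warnings.warn(f"zero-variance profile at row {r}; cc undefined", stacklevel=2)
            cc = float("nan")
        else:
            cc = float(np.corrcoef(pr, pt)[0, 1])
        out.append(LineProfile(row=r, recon=pr, truth=pt, cc=cc))
    return out


def tissue_stats(
    sigma_map: ScalarField2D, labels: LabelMap, include_padding: bool = False
) -> dict[int, tuple[float, float]]:
    """Population mean/std of the conductivity map per tissue label.

    The padding label (-1) is excluded unless requested; labels absent from
    the map are skipped with a warning by callers that expect them.
    """
    if sigma_map.grid.shape != labels.grid.shape:
        raise ValueError("map and labels must share a grid")
    stats: dict[int, tuple[float, float]] = {}
    for lab in np.unique(labels.labels):
        if lab == -1 and not include_padding:
            continue
        vals = sigma_map.values[labels.labels == lab]
        stats[int(lab)] = (float(vals.mean()), float(vals.std()))
    return stats


def gaussian_denoise(phase: ScalarField2D, sigma_px: float = 1.0) -> ScalarField2D:
    """Low-pass Gaussian filter (default one pixel std, reflective borders)."""
    return phase.copy_with(
        ndi.gaussian_filter(phase.values, sigma=sigma_px, mode="reflect")
    )
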