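"""Core 2-D field/grid containers and file I/O shared by all modules.

Conventions
-----------
Pixel indices are 0-based. ``values`` arrays are stored row-major with shape
``(ny, nx)``: the first axis is the row index *j* (increasing with physical
``y``) and the second is the column index *i* (increasing with ``x``). Pixel
(i, j) is centered at physical coordinates ``(i*dx, j*dy)`` in meters.

Physical spacing is carried on every field; derivative operators consume it
rather than assuming unit spacing (a 2 mm grid materially scales a Laplacian).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

__all__ = [
    "Grid2D",
    "ScalarField2D",
    "RegionMasks",
    "make_grid",
    "make_ring_masks",
    "read_field",
    "write_field",
    "FieldFormatError",
]

#: roles a ScalarField2D may carry; purely informational metadata
FIELD_ROLES = ("phase", "conductivity", "gamma", "derivative")


class FieldFormatError(ValueError):
    """Raised when an on-disk map violates the expected format."""


@dataclass(frozen=True)
class Grid2D:
    """Regular 2-D pixel grid: counts and physical spacing in meters."""

    nx: int
    ny: int
    dx: float
    dy: float

    def __post_init__(self) -> None:
        if self.nx < 5 or self.ny < 5:
            raise ValueError(f"grid must be at least 5x5, got {self.nx}x{self.ny}")
        if not (self.dx > 0 and self.dy > 0):
            raise ValueError(f"spacings must be positive, got dx={self.dx}, dy={self.dy}")

    @property
    def shape(self) -> tuple[int, int]:
        """Array shape ``(ny, nx)`` of fields living on this grid."""
        return (self.ny, self.nx)

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(x, y)`` coordinate arrays of shape (ny, nx), meters."""
        x = np.arange(self.nx) * self.dx
        y = np.arange(self.ny) * self.dy
        return np.meshgrid(x, y)


def make_grid(nx: int, ny: int, dx: float, dy: float) -> Grid2D:
    """Construct a :class:`Grid2D`, validating counts and spacings."""
    return Grid2D(int(nx), int(ny), float(dx), float(dy))


@dataclass
class ScalarField2D:
    """A scalar map (phase [rad], conductivity [S/m], gamma [Ohm*m], ...) on a grid."""

    grid: Grid2D
    values: np.ndarray
    role: str = "derivative"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        if self.role not in FIELD_ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {FIELD_ROLES}")

    def copy_with(self, values: np.ndarray, role: str | None = None) -> "ScalarField2D":
        return ScalarField2D(self.grid, np.array(values, dtype=float), role or self.role)


@dataclass
class RegionMasks:
    """Partition of the grid into a border padding ring and the interior ROI.

    The padding ring is the reference region of known conductivity that
    surrounds the region of interest; the interior is everything else.
    """

    padding: np.ndarray
    interior: np.ndarray
    thickness: int = field(default=0)

    def __post_init__(self) -> None:
        self.padding = np.asarray(self.padding, dtype=bool)
        self.interior = np.asarray(self.interior, dtype=bool)
        if self.padding.shape != self.interior.shape:
            raise ValueError("padding and interior masks must share a shape")
        if np.any(self.padding & self.interior):
            raise ValueError("padding and interior masks overlap")
        if not np.all(self.padding | self.interior):
            raise ValueError("padding and interior masks must cover the grid")


def make_ring_masks(grid: Grid2D, thickness: int) -> RegionMasks:
    """Build masks for a uniform border ring of ``thickness`` pixels."""
    t = int(thickness)
    if t < 1:
        raise ValueError("padding thickness must be >= 1 pixel")
    if 2 * t >= min(grid.nx, grid.ny):
        raise ValueError(f"padding thickness {t} leaves no interior on {grid.nx}x{grid.ny}")
    interior = np.zeros(grid.shape, dtype=bool)
    interior[t:-t, t:-t] = True
    return RegionMasks(padding=~interior, interior=interior, thickness=t)


def ring_mask(grid: Grid2D, outer: int = 0, inner: int = 1) -> np.ndarray:
    """Boolean mask of border rings from depth ``outer`` (inclusive) to ``inner`` (exclusive).

    ``ring_mask(g, 0, 1)`` is the outermost 1-pixel ring; ``ring_mask(g, 1, 3)``
    the next two rings inward.
    """
    if not 0 <= outer < inner:
        raise ValueError("need 0 <= outer < inner")
    m = np.zeros(grid.shape, dtype=bool)
    m[outer:-outer or None, outer:-outer or None] = True
    m[inner:-inner, inner:-inner] = False
    return m


# ---------------------------------------------------------------------------
# I/O: NIfTI-1 single slice or headerless CSV with a YAML sidecar for spacing.


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def write_field(fld: ScalarField2D, path: str | Path) -> None:
    """Write a field to NIfTI-1 (``.nii``/``.nii.gz``) or CSV (+ YAML sidecar).

    CSV is comma-separated, no header, row-major; spacing and role go to a
    ``<name>.csv.yaml`` sidecar. NIfTI stores spacing (mm) in the header zooms.
    """
    path = Path(path)
    if path.suffix in (".nii", ".gz"):
        # NIfTI zooms are conventionally millimeters
        img = nib.Nifti1Image(fld.values.T.astype(np.float64), affine=np.eye(4))
        img.header.set_zooms((fld.grid.dx * 1e3, fld.grid.dy * 1e3))
        img.header["descrip"] = fld.role.encode()
        nib.save(img, str(path))
    elif path.suffix == ".csv":
        np.savetxt(path, fld.values, delimiter=",", fmt="%.17g")
        meta = {"dx": fld.grid.dx, "dy": fld.grid.dy, "role": fld.role}
        _sidecar_path(path).write_text(yaml.safe_dump(meta))
    else:
        raise FieldFormatError(f"unsupported extension {path.suffix!r}; use .nii[.gz] or .csv")


def read_field(path: str | Path, role: str | None = None) -> ScalarField2D:
    """Read a 2-D map from NIfTI-1 or CSV; see :func:`write_field` for layout."""
    path = Path(path)
    if path.suffix in (".nii", ".gz"):
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        data = np.squeeze(data)
        if data.ndim != 2:
            raise FieldFormatError(
                f"{path} holds a {data.ndim}-D volume; select a single 2-D slice "
                "before loading (this reader handles one slice only)"
            )
        zooms = img.header.get_zooms()[:2]
        grid = make_grid(data.shape[0], data.shape[1], zooms[0] * 1e-3, zooms[1] * 1e-3)
        stored_role = img.header["descrip"].tobytes().split(b"\x00")[0].decode() or "derivative"
        values = np.asarray(data, dtype=float).T
    elif path.suffix == ".csv":
        try:
            values = np.loadtxt(path, delimiter=",", ndmin=2, dtype=float)
        except ValueError as exc:
            raise FieldFormatError(f"non-numeric cell in {path}: {exc}") from exc
        meta = {}
        sc = _sidecar_path(path)
        if sc.exists():
            meta = yaml.safe_load(sc.read_text()) or {}
        grid = make_grid(
            values.shape[1], values.shape[0], meta.get("dx", 1.0), meta.get("dy", 1.0)
        )
        stored_role = meta.get("role", "derivative")
    else:
        raise FieldFormatError(f"unsupported extension {path.suffix!r}; use .nii[.gz] or .csv")
    if not np.all(np.isfinite(values)):
        raise FieldFormatError(f"{path} contains non-finite values")
    return ScalarField2D(grid, values, role or stored_role)
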