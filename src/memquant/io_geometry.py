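"""Volume, point-set and mask I/O plus landmark affine registration.

Conventions used throughout the package
---------------------------------------
* Array axes are ``(Z, Y, X)`` — the MRC section order.
* Physical coordinates are reported as ``(x, y, z)`` in nanometres.
* Voxel/pixel coordinates are voxel-center based and 0-based:
  ``physical = origin + (index + 0.5) * voxel_size``.
* MRC headers store spacing in Ångström; everything user-facing is nm.
"""

from __future__ import annotations

import csv
import io
import os
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

__all__ = [
    "VoxelGrid",
    "PointSet3D",
    "Affine2D",
    "read_volume",
    "write_volume",
    "read_points",
    "write_points",
    "fit_affine2d",
    "apply_affine2d",
]

ANGSTROM_PER_NM = 10.0


def _as_triple(value, name: str) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if arr.size == 1:
        arr = np.repeat(arr, 3)
    if arr.shape != (3,):
        raise ValueError(f"{name} must be a scalar or length-3 sequence, got {value!r}")
    return arr


@dataclass
class VoxelGrid:
    """A 3D scalar field (confidence map or binary mask) with physical scale.

    Parameters
    ----------
    data:
        3D array in ``(Z, Y, X)`` order.
    voxel_size_nm:
        Isotropic scalar or per-axis ``(z, y, x)`` triple, in nm.
    origin_nm:
        Physical position of the corner of voxel ``(0, 0, 0)`` as an
        ``(x, y, z)`` triple in nm.  Defaults to zeros.
    """

    data: np.ndarray
    voxel_size_nm: float | tuple[float, float, float]
    origin_nm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"VoxelGrid data must be 3D, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError("VoxelGrid dimensions must all be >= 1")
        vs = _as_triple(self.voxel_size_nm, "voxel_size_nm")
        if not np.all(np.isfinite(vs)) or np.any(vs <= 0):
            raise ValueError(f"voxel_size_nm must be positive on every axis, got {vs}")
        self.voxel_size_nm = tuple(float(v) for v in vs)
        self.origin_nm = tuple(float(v) for v in _as_triple(self.origin_nm, "origin_nm"))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_size_zyx(self) -> np.ndarray:
        """Per-axis voxel size in array (z, y, x) order, nm."""
        return np.asarray(self.voxel_size_nm, dtype=float)

    @property
    def extent_xyz_nm(self) -> np.ndarray:
        """Physical extent of the volume along (x, y, z), nm."""
        return np.asarray(self.data.shape[::-1], float) * self.voxel_size_zyx[::-1]

    def index_to_physical(self, indices_zyx: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) ``(z, y, x)`` indices to ``(x, y, z)`` nm."""
        idx = np.atleast_2d(np.asarray(indices_zyx, dtype=float))
        phys_zyx = (idx + 0.5) * self.voxel_size_zyx
        out = phys_zyx[:, ::-1] + np.asarray(self.origin_nm, float)
        return out if np.asarray(indices_zyx).ndim == 2 else out[0]

    def physical_to_index(self, points_xyz: np.ndarray) -> np.ndarray:
        """Map ``(x, y, z)`` nm coordinates to fractional ``(z, y, x)`` indices."""
        pts = np.atleast_2d(np.asarray(points_xyz, dtype=float))
        rel = pts - np.asarray(self.origin_nm, float)
        idx = rel[:, ::-1] / self.voxel_size_zyx - 0.5
        return idx if np.asarray(points_xyz).ndim == 2 else idx[0]

    def is_binary(self) -> bool:
        return bool(np.isin(self.data, (0, 1)).all())


@dataclass
class PointSet3D:
    """N points in physical ``(x, y, z)`` nm, with an optional boolean flag."""

    points: np.ndarray
    flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(self.points)):
            raise ValueError("PointSet3D coordinates must be finite")
        if self.flags is not None:
            self.flags = np.asarray(self.flags, dtype=bool).ravel()
            if self.flags.shape[0] != self.points.shape[0]:
                raise ValueError(
                    f"flags length {self.flags.shape[0]} != number of points "
                    f"{self.points.shape[0]}"
                )

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass
class Affine2D:
    """2D affine map ``y = A x + b`` in the destination nm frame."""

    matrix: np.ndarray
    offset: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(2, 2)
        self.offset = np.asarray(self.offset, dtype=float).reshape(2)

    def inverse(self) -> "Affine2D":
        if abs(np.linalg.det(self.matrix)) < 1e-300:
            raise ValueError("affine linear part is singular; cannot invert")
        inv = np.linalg.inv(self.matrix)
        return Affine2D(inv, -inv @ self.offset)


# ---------------------------------------------------------------------------
# MRC volumes (via gemmi's CCP4/MRC map support)
# ---------------------------------------------------------------------------

def read_volume(path: str | os.PathLike) -> VoxelGrid:
    """Read an MRC2014 volume into a :class:`VoxelGrid`.

    The header spacing (Å) is converted to nm.  A zero or missing voxel size
    is an error, never silently defaulted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    try:
        ccp4 = gemmi.read_ccp4_map(str(path))
        ccp4.setup(float("nan"), gemmi.MapSetup.ReorderOnly)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"{path}: not a readable MRC/CCP4 map ({exc})") from exc
    cell = ccp4.grid.unit_cell
    if not (
        np.isclose(cell.alpha, 90) and np.isclose(cell.beta, 90) and np.isclose(cell.gamma, 90)
    ):
        raise ValueError(f"{path}: non-orthogonal cell angles are not supported")
    spacing_xyz_ang = np.asarray(ccp4.grid.spacing, dtype=float)
    if np.any(~np.isfinite(spacing_xyz_ang)) or np.any(spacing_xyz_ang <= 0):
        raise ValueError(
            f"{path}: header voxel size {spacing_xyz_ang} Å is not positive; refusing to guess"
        )
    data_xyz = np.array(ccp4.grid, copy=True)
    data = np.ascontiguousarray(data_xyz.transpose(2, 1, 0))  # -> (Z, Y, X)
    voxel_zyx_nm = tuple(spacing_xyz_ang[::-1] / ANGSTROM_PER_NM)
    origin_xyz_nm = tuple(
        np.array(
            [ccp4.header_float(50), ccp4.header_float(51), ccp4.header_float(52)], dtype=float
        )
        / ANGSTROM_PER_NM
    )
    return VoxelGrid(data=data, voxel_size_nm=voxel_zyx_nm, origin_nm=origin_xyz_nm)


def write_volume(grid: VoxelGrid, path: str | os.PathLike) -> None:
    """Write a :class:`VoxelGrid` as an MRC2014 mode-2 (float32) file.

    nm voxel sizes are stored as Å in the header, so a 1.08 nm grid round-trips
    through a 10.8 Å header entry.
    """
    if not isinstance(grid, VoxelGrid):
        grid = VoxelGrid(**grid) if isinstance(grid, dict) else VoxelGrid(grid, 1.0)
    path = Path(path)
    vs_zyx = grid.voxel_size_zyx
    data_xyz = np.ascontiguousarray(grid.data.transpose(2, 1, 0).astype(np.float32))
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = gemmi.FloatGrid(data_xyz)
    nx, ny, nz = data_xyz.shape
    sx, sy, sz = vs_zyx[::-1] * ANGSTROM_PER_NM
    ccp4.grid.unit_cell = gemmi.UnitCell(nx * sx, ny * sy, nz * sz, 90.0, 90.0, 90.0)
    ccp4.update_ccp4_header()
    ox, oy, oz = (np.asarray(grid.origin_nm, float) * ANGSTROM_PER_NM)
    ccp4.set_header_float(50, float(ox))
    ccp4.set_header_float(51, float(oy))
    ccp4.set_header_float(52, float(oz))
    try:
        ccp4.write_ccp4_map(str(path))
    except (RuntimeError, OSError) as exc:
        raise OSError(f"cannot write volume to {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Point lists
# ---------------------------------------------------------------------------

def read_points(path: str | os.PathLike) -> PointSet3D:
    """Read a 3D point list in nm.

    Accepts either a CSV with a ``x_nm,y_nm,z_nm[,flag]`` header row or
    header-less whitespace/comma-delimited 3- or 4-column numeric text (the
    form of an IMOD ASCII point export).  An empty file yields an empty set.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such point file: {path}")
    text = path.read_text()
    rows = [line.strip() for line in text.splitlines()]
    rows = [r for r in rows if r and not r.startswith("#")]
    if not rows:
        return PointSet3D(np.empty((0, 3)))

    def _tokenize(row: str) -> list[str]:
        tokens = next(csv.reader(io.StringIO(row))) if "," in row else row.split()
        return [t for t in (tok.strip() for tok in tokens) if t]

    header_cols: list[str] | None = None
    first = _tokenize(rows[0])
    if any(not _is_number(tok) for tok in first):
        header_cols = [c.strip().lower() for c in first]
        expected = ["x_nm", "y_nm", "z_nm"]
        if header_cols[:3] != expected:
            raise ValueError(
                f"{path}: unrecognized point-file header {header_cols!r}; "
                f"expected columns {expected} (optional 4th 'flag')"
            )
        rows = rows[1:]

    pts, flags = [], []
    for lineno, row in enumerate(rows, start=2 if header_cols else 1):
        tokens = _tokenize(row)
        if len(tokens) not in (3, 4):
            raise ValueError(
                f"{path}:{lineno}: expected 3 or 4 columns, got {len(tokens)}"
            )
        try:
            values = [float(t) for t in tokens]
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric value in {tokens!r}") from exc
        pts.append(values[:3])
        if len(values) == 4:
            flags.append(bool(values[3]))
        elif flags:
            raise ValueError(f"{path}:{lineno}: inconsistent column count")
    if flags and len(flags) != len(pts):
        raise ValueError(f"{path}: flag column present on only some rows")
    return PointSet3D(np.asarray(pts), np.asarray(flags) if flags else None)


def write_points(points: PointSet3D, path: str | os.PathLike) -> None:
    """Write a point set as ``x_nm,y_nm,z_nm[,flag]`` CSV."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        if points.flags is None:
            writer.writerow(["x_nm", "y_nm", "z_nm"])
            writer.writerows([f"{v:.9g}" for v in p] for p in points.points)
        else:
            writer.writerow(["x_nm", "y_nm", "z_nm", "flag"])
            for p, f in zip(points.points, points.flags):
                writer.writerow([f"{v:.9g}" for v in p] + [int(f)])


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# Landmark affine registration (CLEM fluorescence -> EM atlas)
# ---------------------------------------------------------------------------

def fit_affine2d(src: np.ndarray, dst: np.ndarray) -> Affine2D:
    """Least-squares affine registration of 2D landmark pairs.

    Finds ``A`` (2x2) and ``b`` minimizing ``sum_i ||A src_i + b - dst_i||^2``.
    With exactly three non-collinear pairs the fit interpolates (zero
    residual).  Collinear landmarks leave the system singular and raise.
    """
    src = np.asarray(src, dtype=float).reshape(-1, 2)
    dst = np.asarray(dst, dtype=float).reshape(-1, 2)
    if src.shape != dst.shape:
        raise ValueError(f"landmark counts differ: {src.shape[0]} vs {dst.shape[0]}")
    m = src.shape[0]
    if m < 3:
        raise ValueError(f"need at least 3 landmark pairs, got {m}")
    design = np.hstack([src, np.ones((m, 1))])
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("landmarks are collinear; affine registration is singular")
    coef, *_ = np.linalg.lstsq(design, dst, rcond=None)
    return Affine2D(matrix=coef[:2].T, offset=coef[2])


def apply_affine2d(a: Affine2D, pts: np.ndarray) -> np.ndarray:
    """Apply ``y = A x + b`` to an M×2 array of points."""
    pts = np.asarray(pts, dtype=float)
    single = pts.ndim == 1
    out = np.atleast_2d(pts) @ a.matrix.T + a.offset
    return out[0] if single else out
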