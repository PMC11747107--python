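"""Air-water-interface (AWI) surface modeling and particle depth profiling.

A vitrified unroofed-membrane sample is a thin buffer slab bounded by two
near-horizontal AWIs.  Both interfaces are modeled as height fields
``z(x, y)`` interpolated from manually picked model points: piecewise-linear
over the Delaunay triangulation of the picks, with nearest-pick extrapolation
outside their convex hull.  Particle-to-AWI distances are vertical (along z);
for surface slopes under ~10 degrees this agrees with the true 3D
point-to-surface distance to better than 2%, and it makes the conservation
law ``d_top + d_bottom = local slab thickness`` exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator
from scipy.spatial import QhullError

from .io_geometry import PointSet3D

__all__ = [
    "HeightField",
    "SurfacePair",
    "DepthProfile",
    "interpolate_surface",
    "particle_awi_distances",
    "depth_profile",
    "tomogram_thickness",
]


class HeightField:
    """Height field z(x, y) nm backed by control points.

    Piecewise-linear inside the convex hull of the picks; nearest-control-point
    outside it.  Evaluation at a pick returns its z exactly.
    """

    def __init__(self, points_xyz: np.ndarray):
        points_xyz = np.asarray(points_xyz, dtype=float).reshape(-1, 3)
        if points_xyz.shape[0] < 3:
            raise ValueError(
                f"surface interpolation needs >= 3 picks, got {points_xyz.shape[0]}"
            )
        xy, z = points_xyz[:, :2], points_xyz[:, 2]
        try:
            self._linear = LinearNDInterpolator(xy, z)
        except QhullError as exc:
            raise ValueError("surface picks are collinear; cannot triangulate") from exc
        self._nearest = NearestNDInterpolator(xy, z)
        self.control_points = points_xyz

    def __call__(self, x, y) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        z = self._linear(x, y)
        outside = np.isnan(z)
        if np.any(outside):
            z = np.where(outside, self._nearest(x, y), z)
        return z


def interpolate_surface(picks: PointSet3D | np.ndarray) -> HeightField:
    """Build a :class:`HeightField` from picked AWI model points (nm)."""
    pts = picks.points if isinstance(picks, PointSet3D) else np.asarray(picks, float)
    return HeightField(pts)


@dataclass
class SurfacePair:
    """Top and bottom AWI height fields over the tomogram footprint."""

    top: HeightField
    bottom: HeightField

    @classmethod
    def from_picks(cls, top_picks, bottom_picks) -> "SurfacePair":
        return cls(top=interpolate_surface(top_picks), bottom=interpolate_surface(bottom_picks))

    def thickness_at(self, x, y) -> np.ndarray:
        return self.top(x, y) - self.bottom(x, y)


@dataclass
class DepthProfile:
    """Binned particle counts vs. distance to one AWI.

    ``fraction`` is flagged/total per bin and NaN (undefined, not zero) for
    empty bins.
    """

    bin_edges_nm: np.ndarray
    counts_total: np.ndarray
    counts_flagged: np.ndarray
    fraction: np.ndarray
    side: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lo_nm": self.bin_edges_nm[:-1],
                "hi_nm": self.bin_edges_nm[1:],
                "count_total": self.counts_total,
                "count_flagged": self.counts_flagged,
                "fraction": self.fraction,
            }
        )

    @property
    def modal_bin(self) -> tuple[float, float]:
        """[lo, hi) of the most populated bin (total counts)."""
        i = int(np.argmax(self.counts_total))
        return float(self.bin_edges_nm[i]), float(self.bin_edges_nm[i + 1])


def particle_awi_distances(
    particles: PointSet3D, surfaces: SurfacePair
) -> pd.DataFrame:
    """Vertical distances from each particle to both AWIs.

    ``d_top = z_top(x, y) - z`` and ``d_bottom = z - z_bottom(x, y)``; both can
    be negative for particles outside the slab, which are flagged via
    ``in_slab`` rather than dropped.
    """
    pts = particles.points
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    d_top = surfaces.top(x, y) - z
    d_bottom = z - surfaces.bottom(x, y)
    return pd.DataFrame(
        {
            "d_bottom_nm": d_bottom,
            "d_top_nm": d_top,
            "in_slab": (d_top >= 0) & (d_bottom >= 0),
        }
    )


def depth_profile(
    particles: PointSet3D,
    flags: np.ndarray | None,
    surfaces: SurfacePair,
    bin_nm: float = 5.0,
) -> dict[str, DepthProfile]:
    """Particle-count depth profiles for both AWIs, in half-open 5-nm bins.

    Returns ``{"top": ..., "bottom": ...}``.  ``flags`` marks the subset of
    interest (e.g. particles that aligned well in subtomogram averaging); if
    None, ``particles.flags`` is used, else all-False.
    """
    if bin_nm <= 0:
        raise ValueError("bin_nm must be positive")
    if flags is None:
        flags = particles.flags
    if flags is None:
        flags = np.zeros(len(particles), dtype=bool)
    flags = np.asarray(flags, dtype=bool).ravel()
    if flags.shape[0] != len(particles):
        raise ValueError("flags must align with particles")
    dist = particle_awi_distances(particles, surfaces)
    out: dict[str, DepthProfile] = {}
    for side, col in (("bottom", "d_bottom_nm"), ("top", "d_top_nm")):
        d = dist[col].to_numpy()
        keep = d >= 0
        d_kept, f_kept = d[keep], flags[keep]
        n_bins = max(1, int(np.ceil((d_kept.max() + 1e-9) / bin_nm))) if d_kept.size else 1
        edges = np.arange(n_bins + 1, dtype=float) * bin_nm
        idx = np.minimum((d_kept / bin_nm).astype(int), n_bins - 1)
        total = np.bincount(idx, minlength=n_bins)
        flagged = np.bincount(idx[f_kept], minlength=n_bins)
        with np.errstate(invalid="ignore", divide="ignore"):
            fraction = np.where(total > 0, flagged / np.maximum(total, 1), np.nan)
        out[side] = DepthProfile(
            bin_edges_nm=edges,
            counts_total=total,
            counts_flagged=flagged,
            fraction=fraction,
            side=side,
        )
    return out


def tomogram_thickness(
    surfaces: SurfacePair,
    footprint_xy_nm: tuple[float, float],
    voxel_size_nm: float,
    crop_px: int = 200,
    n_positions: int = 9,
) -> tuple[np.ndarray, float]:
    """Tomogram thickness sampled at nine equally spaced XY positions.

    The positions are a 3×3 grid of crop centers at footprint fractions
    {1/6, 1/2, 5/6} per axis.  At each position a ``crop_px``-voxel square is
    sampled at voxel-size pitch and the mean top-bottom surface gap over the
    crop is recorded; the mean of the nine values is the tomogram thickness.
    """
    if n_positions != 9:
        raise ValueError("the sampling scheme is defined for nine positions (3x3 grid)")
    ext_x, ext_y = float(footprint_xy_nm[0]), float(footprint_xy_nm[1])
    crop_nm = crop_px * float(voxel_size_nm)
    if crop_nm > ext_x or crop_nm > ext_y:
        raise ValueError(
            f"crop of {crop_nm:g} nm exceeds footprint {ext_x:g} x {ext_y:g} nm"
        )
    fracs = np.array([1 / 6, 1 / 2, 5 / 6])
    # sample points inside one crop, at voxel pitch, centered on the crop center
    offs = (np.arange(crop_px) - (crop_px - 1) / 2.0) * float(voxel_size_nm)
    ox, oy = np.meshgrid(offs, offs, indexing="ij")
    values = []
    for fy in fracs:
        for fx in fracs:
            cx = np.clip(fx * ext_x, crop_nm / 2, ext_x - crop_nm / 2)
            cy = np.clip(fy * ext_y, crop_nm / 2, ext_y - crop_nm / 2)
            gap = surfaces.thickness_at(cx + ox, cy + oy)
            values.append(float(np.mean(gap)))
    values = np.asarray(values)
    return values, float(values.mean())
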