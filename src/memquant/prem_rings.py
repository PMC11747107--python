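"""Concentric-ring morphometry of clathrin classes on platinum-replica masks.

Clathrin-coated structures on unroofed plasma membranes fall into three
morphological classes — flat (no visible curvature), dome (curved lattice with
a visible edge) and sphere (curved beyond a hemisphere) — and their spatial
organization is measured relative to the edge of the Quantifoil carbon-film
hole.  The hole edge is the radial reference: concentric rings of 50 nm
thickness cover 500 nm inside and outside the edge (20 rings; 10 inside, 10
outside), and per ring the structure count, areal density and the fraction of
membrane pixels occupied by each class are reported.

Offsets are signed: negative inside the hole, zero on the edge, positive on
the carbon film.  Rings are half-open intervals ``[lo, hi)``, so an offset of
exactly 0 belongs to the first outside ring and no structure is counted twice.
A structure is assigned to the ring containing its centroid's offset to its
nearest hole (ties between holes break toward the lower hole index); its
pixels still contribute to the occupancy of whichever ring each pixel falls
in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "CLASSES",
    "HoleSpec",
    "LabelImage2D",
    "structure_centroids",
    "signed_edge_offset",
    "ring_profile",
    "class_density",
    "membrane_area_fraction",
]

CLASSES = ("flat", "dome", "sphere")


@dataclass(frozen=True)
class HoleSpec:
    """A Quantifoil hole: center ``(x, y)`` nm and radius nm."""

    center_xy_nm: tuple[float, float]
    radius_nm: float

    def __post_init__(self) -> None:
        if not self.radius_nm > 0:
            raise ValueError(f"hole radius must be positive, got {self.radius_nm}")


@dataclass
class LabelImage2D:
    """2D clathrin class segmentation over the analyzed membrane area.

    ``labels`` is an integer array (0 = background); ``class_of`` maps each
    positive label to one of :data:`CLASSES`.  ``analyzed_mask`` marks the
    membrane area actually analyzed and must contain every labeled pixel
    (None means the whole image).  Pixel centers are at
    ``(index + 0.5) * pixel_size_nm``.
    """

    labels: np.ndarray
    pixel_size_nm: float
    class_of: dict[int, str]
    analyzed_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2 or not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be a 2D integer array")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        if not self.pixel_size_nm > 0:
            raise ValueError(f"pixel_size_nm must be positive, got {self.pixel_size_nm}")
        for label, cls in self.class_of.items():
            if label <= 0:
                raise ValueError(f"class_of keys must be positive labels, got {label}")
            if cls not in CLASSES:
                raise ValueError(f"unknown clathrin class {cls!r} for label {label}")
        if self.analyzed_mask is None:
            self.analyzed_mask = np.ones(self.labels.shape, dtype=bool)
        else:
            self.analyzed_mask = np.asarray(self.analyzed_mask, dtype=bool)
            if self.analyzed_mask.shape != self.labels.shape:
                raise ValueError("analyzed_mask shape must match labels")
            if np.any((self.labels > 0) & ~self.analyzed_mask):
                raise ValueError("analyzed_mask must contain every labeled pixel")

    def pixel_centers_nm(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) physical coordinates of every pixel center, as 2D arrays."""
        ny, nx = self.labels.shape
        x = (np.arange(nx) + 0.5) * self.pixel_size_nm
        y = (np.arange(ny) + 0.5) * self.pixel_size_nm
        return np.meshgrid(x, y)


def structure_centroids(img: LabelImage2D) -> pd.DataFrame:
    """Per-structure centroid and projected area.

    The centroid is the unweighted mean of pixel centers in nm; the projected
    area is the pixel count times the pixel area, in µm².  Rows are ordered by
    label id.  A label declared in ``class_of`` but absent from the raster is
    an error.
    """
    labels = img.labels
    ids = sorted(img.class_of)
    if not ids:
        return pd.DataFrame(
            columns=["label", "class", "centroid_x_nm", "centroid_y_nm", "area_um2"]
        )
    counts = np.bincount(labels.ravel(), minlength=max(ids) + 1)
    missing = [i for i in ids if counts[i] == 0]
    if missing:
        raise ValueError(f"labels with zero pixels: {missing}")
    yy, xx = np.indices(labels.shape)
    sum_x = ndimage.sum_labels(xx, labels, ids)
    sum_y = ndimage.sum_labels(yy, labels, ids)
    px = img.pixel_size_nm
    n = counts[ids].astype(float)
    return pd.DataFrame(
        {
            "label": ids,
            "class": [img.class_of[i] for i in ids],
            "centroid_x_nm": (sum_x / n + 0.5) * px,
            "centroid_y_nm": (sum_y / n + 0.5) * px,
            "area_um2": n * px**2 / 1e6,
        }
    )


def signed_edge_offset(p, hole: HoleSpec):
    """Signed distance (nm) from point(s) ``p`` to the hole edge.

    ``||p - center|| - radius``: negative inside the hole, zero on the edge,
    positive on the film.
    """
    p = np.asarray(p, dtype=float)
    center = np.asarray(hole.center_xy_nm, dtype=float)
    off = np.linalg.norm(np.atleast_2d(p) - center, axis=1) - hole.radius_nm
    return float(off[0]) if p.ndim == 1 else off


def _nearest_hole_offsets(px_or_pts_x, pts_y, holes) -> np.ndarray:
    """Offset to the nearest hole (smallest |offset|; ties to lower index)."""
    offs = np.stack(
        [
            np.hypot(px_or_pts_x - h.center_xy_nm[0], pts_y - h.center_xy_nm[1])
            - h.radius_nm
            for h in holes
        ]
    )
    pick = np.argmin(np.abs(offs), axis=0)  # argmin is stable -> lower index wins ties
    return np.take_along_axis(offs, pick[None], axis=0)[0]


def ring_profile(
    img: LabelImage2D,
    holes,
    structures: pd.DataFrame | None = None,
    ring_width_nm: float = 50.0,
    half_range_nm: float = 500.0,
) -> pd.DataFrame:
    """Concentric-ring profile of structure counts, densities and occupancy.

    Returns one row per ring with columns ``ring``, ``lo_nm``, ``hi_nm``,
    ``analyzed_area_um2``, and per class ``count_<c>``, ``density_<c>``
    (structures per µm² of analyzed ring area) and ``occupancy_<c>`` (fraction
    of analyzed ring pixels covered by that class).  Rings with zero analyzed
    area carry NaN density/occupancy and ``undefined=True`` — never a silent
    zero.  Structures whose centroid offset falls outside ``±half_range_nm``
    are excluded from the rings but counted in ``df.attrs["n_total"]``.
    """
    holes = list(holes)
    if not holes:
        raise ValueError("at least one hole is required")
    if ring_width_nm <= 0 or half_range_nm <= 0:
        raise ValueError("ring_width_nm and half_range_nm must be positive")
    n_side = half_range_nm / ring_width_nm
    if abs(n_side - round(n_side)) > 1e-9:
        raise ValueError(
            f"half_range_nm={half_range_nm} must be divisible by ring_width_nm={ring_width_nm}"
        )
    n_rings = 2 * int(round(n_side))
    edges = -half_range_nm + ring_width_nm * np.arange(n_rings + 1)

    if structures is None:
        structures = structure_centroids(img)

    # pixel-wise ring assignment for occupancy and ring areas
    xx, yy = img.pixel_centers_nm()
    pix_off = _nearest_hole_offsets(xx, yy, holes)
    ring_idx = np.floor((pix_off + half_range_nm) / ring_width_nm).astype(int)
    in_range = (ring_idx >= 0) & (ring_idx < n_rings) & img.analyzed_mask
    flat_idx = ring_idx[in_range]
    analyzed_px = np.bincount(flat_idx, minlength=n_rings).astype(float)
    px_area_um2 = img.pixel_size_nm**2 / 1e6
    analyzed_area = analyzed_px * px_area_um2

    class_of_label = np.zeros(int(img.labels.max()) + 1, dtype=int)
    for label, cls in img.class_of.items():
        class_of_label[label] = CLASSES.index(cls) + 1
    pix_class = class_of_label[img.labels]

    out = pd.DataFrame(
        {
            "ring": np.arange(n_rings),
            "lo_nm": edges[:-1],
            "hi_nm": edges[1:],
            "analyzed_area_um2": analyzed_area,
            "undefined": analyzed_px == 0,
        }
    )

    # structure-wise ring assignment by centroid offset to the nearest hole
    cent_off = (
        _nearest_hole_offsets(
            structures["centroid_x_nm"].to_numpy(), structures["centroid_y_nm"].to_numpy(), holes
        )
        if len(structures)
        else np.empty(0)
    )
    cent_ring = np.floor((cent_off + half_range_nm) / ring_width_nm).astype(int)
    cent_ok = (cent_ring >= 0) & (cent_ring < n_rings)

    with np.errstate(invalid="ignore", divide="ignore"):
        for ci, cls in enumerate(CLASSES, start=1):
            sel = cent_ok & (structures["class"].to_numpy() == cls) if len(structures) else cent_ok
            counts = np.bincount(cent_ring[sel], minlength=n_rings) if len(structures) else np.zeros(n_rings)
            occ_px = np.bincount(flat_idx[pix_class[in_range] == ci], minlength=n_rings)
            out[f"count_{cls}"] = counts
            out[f"density_{cls}"] = np.where(analyzed_px > 0, counts / np.where(analyzed_area > 0, analyzed_area, np.nan), np.nan)
            out[f"occupancy_{cls}"] = np.where(analyzed_px > 0, occ_px / np.where(analyzed_px > 0, analyzed_px, np.nan), np.nan)

    out.attrs["n_total"] = int(len(structures))
    out.attrs["n_out_of_range"] = int((~cent_ok).sum()) if len(structures) else 0
    out.attrs["ring_width_nm"] = float(ring_width_nm)
    out.attrs["half_range_nm"] = float(half_range_nm)
    return out


def class_density(structures: pd.DataFrame, analyzed_area_um2: float) -> dict[str, float]:
    """Structures per µm² of analyzed membrane, per class plus total."""
    if not analyzed_area_um2 > 0:
        raise ValueError(f"analyzed_area_um2 must be positive, got {analyzed_area_um2}")
    classes = structures["class"].to_numpy() if len(structures) else np.empty(0, dtype=object)
    out = {cls: float((classes == cls).sum()) / analyzed_area_um2 for cls in CLASSES}
    out["total"] = float(len(structures)) / analyzed_area_um2
    return out


def membrane_area_fraction(img: LabelImage2D) -> float:
    """Percent of analyzed membrane pixels covered by clathrin of any class."""
    n_analyzed = int(img.analyzed_mask.sum())
    if n_analyzed == 0:
        raise ValueError("analyzed_mask is empty")
    clathrin = (img.labels > 0) & img.analyzed_mask
    return 100.0 * float(clathrin.sum()) / n_analyzed
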