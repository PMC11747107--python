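"""The FerriTag detection-and-distance pipeline.

FerriTag is a rapamycin-inducible, genetically encoded ~12-nm hollow ferritin
cage visible in cryo-electron tomograms.  Given a per-voxel detection
confidence map, the pipeline measures how far each tag sits from the
clathrin-coated membrane:

1. threshold the confidence map at 1.4 (inclusive) to a 3D mask;
2. separate touching tags by marker-controlled watershed;
3. discard regions with fewer than 100 voxels (strictly fewer: exactly 100
   survives);
4. take the unweighted voxel-center centroid of each region as the tag
   position;
5. exclude tags within 25 nm of either air-water interface (AWI) or within
   75 nm of the tomogram XY edge (both inclusive);
6. for each retained tag, measure the Euclidean distance in nm to the
   nearest membrane-mask voxel center via a physical-unit distance transform
   of the membrane complement, sampled at the (sub-voxel) centroid with
   trilinear interpolation;
7. summarize as a 5-nm-bin histogram with the count, fraction, mean and sd
   of the sub-100-nm population.

Numerical conventions: connected components use 26-connectivity; watershed
markers are distance-transform maxima of the hole-filled mask with 6-nm
minimum separation (one seed per tag); distances are measured to membrane
voxel centers, biasing them small by up to about half a voxel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

from .awi_profile import SurfacePair
from .io_geometry import PointSet3D, VoxelGrid

__all__ = [
    "DistanceHistogram",
    "threshold_map",
    "split_touching",
    "filter_small",
    "detection_centroids",
    "apply_exclusions",
    "membrane_distances",
    "distance_histogram",
    "run_tag_pipeline",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class DistanceHistogram:
    """Tag-to-membrane distance histogram in half-open 5-nm bins.

    ``mean_nm``/``sd_nm`` describe the sub-``within_nm`` population
    (population sd, ddof=0).  ``fraction_within`` is NaN, not 0, when there
    are no distances at all.
    """

    bin_edges_nm: np.ndarray
    counts: np.ndarray
    n_total: int
    n_within: int
    fraction_within: float
    mean_nm: float
    sd_nm: float
    within_nm: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lo_nm": self.bin_edges_nm[:-1],
                "hi_nm": self.bin_edges_nm[1:],
                "count": self.counts,
            }
        )


def threshold_map(conf: VoxelGrid, level: float = 1.4) -> VoxelGrid:
    """Binary mask of voxels with confidence >= ``level`` (inclusive)."""
    data = np.asarray(conf.data)
    if not np.all(np.isfinite(data)):
        raise ValueError("confidence map contains non-finite values")
    return VoxelGrid(
        (data >= level).astype(np.uint8),
        voxel_size_nm=conf.voxel_size_nm,
        origin_nm=conf.origin_nm,
    )


def split_touching(mask: VoxelGrid, min_marker_separation_nm: float = 6.0) -> VoxelGrid:
    """Separate touching tags with a marker-controlled watershed.

    Markers are local maxima of the physical-unit distance transform of the
    *hole-filled* mask (a hollow shell has a flat distance ridge on the shell
    itself, which would over-seed; filling gives one interior maximum per
    12-nm tag), kept at least ``min_marker_separation_nm`` (default one tag
    radius) apart.  Components with a single marker pass through unchanged.
    The watershed runs per connected component on a cropped subvolume, and
    labels are restricted back to the original mask.  An empty mask yields
    empty labels.
    """
    data = np.asarray(mask.data) > 0
    vs_zyx = mask.voxel_size_zyx
    labels = np.zeros(data.shape, dtype=np.int32)
    if not data.any():
        return VoxelGrid(labels, mask.voxel_size_nm, mask.origin_nm)
    comp, n_comp = ndimage.label(data, structure=_CONN26)
    objects = ndimage.find_objects(comp)
    next_id = 1
    for i, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        padded = tuple(
            slice(max(s.start - 1, 0), min(s.stop + 1, dim))
            for s, dim in zip(sl, data.shape)
        )
        sub = comp[padded] == i
        filled = ndimage.binary_fill_holes(sub)
        edt = ndimage.distance_transform_edt(filled, sampling=tuple(vs_zyx))
        # strict 1-voxel local maxima first: a wider max-filter footprint can
        # swallow the shallower peak of a touching pair when the slope toward
        # the deeper peak enters its neighborhood
        peaks = peak_local_max(edt, min_distance=1, labels=filled, exclude_border=False)
        if len(peaks) > 1:
            # then greedy physical-distance suppression at the minimum
            # marker separation, keeping higher peaks first
            vals = edt[tuple(peaks.T)]
            order = np.lexsort((*peaks.T[::-1], -vals))
            kept: list[np.ndarray] = []
            for j in order:
                p_nm = peaks[j] * vs_zyx
                if all(
                    np.linalg.norm(p_nm - q) >= min_marker_separation_nm for q in kept
                ):
                    kept.append(p_nm)
                    if len(kept) == 1:
                        peaks_kept = peaks[j][None]
                    else:
                        peaks_kept = np.vstack([peaks_kept, peaks[j]])
            peaks = peaks_kept
        if len(peaks) <= 1:
            labels[padded][sub] = next_id
            next_id += 1
            continue
        markers = np.zeros(sub.shape, dtype=np.int32)
        markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
        ws = watershed(-edt, markers=markers, mask=filled)
        ws_on_mask = np.where(sub, ws, 0)
        for wid in range(1, len(peaks) + 1):
            region = ws_on_mask == wid
            if region.any():
                labels[padded][region] = next_id
                next_id += 1
    return VoxelGrid(labels, mask.voxel_size_nm, mask.origin_nm)


def filter_small(labels: VoxelGrid, min_voxels: int = 100) -> VoxelGrid:
    """Delete regions with strictly fewer than ``min_voxels`` voxels.

    Surviving regions keep their ids (a 100-voxel region survives the default
    filter; a 99-voxel region does not).
    """
    lab = np.asarray(labels.data)
    if lab.size and lab.max() > 0:
        counts = np.bincount(lab.ravel())
        kill = np.flatnonzero(counts < min_voxels)
        keep_lut = np.arange(counts.size, dtype=lab.dtype)
        keep_lut[kill] = 0
        keep_lut[0] = 0
        lab = keep_lut[lab]
    return VoxelGrid(lab, labels.voxel_size_nm, labels.origin_nm)


def detection_centroids(labels: VoxelGrid) -> pd.DataFrame:
    """Tag table of per-region centroids (nm) and voxel counts.

    The centroid is the unweighted mean of voxel centers, converted to
    physical ``(x, y, z)`` via the voxel-center convention.
    """
    lab = np.asarray(labels.data)
    fg = np.argwhere(lab > 0)
    if fg.size == 0:
        return pd.DataFrame(
            columns=["id", "x_nm", "y_nm", "z_nm", "voxel_count"]
        ).astype({"id": int, "voxel_count": int})
    ids_per_voxel = lab[tuple(fg.T)]
    order = np.unique(ids_per_voxel)
    sums = np.zeros((order.max() + 1, 3))
    np.add.at(sums, ids_per_voxel, fg)
    counts = np.bincount(ids_per_voxel, minlength=order.max() + 1)
    mean_idx = sums[order] / counts[order, None]
    xyz = labels.index_to_physical(mean_idx)
    return pd.DataFrame(
        {
            "id": order.astype(int),
            "x_nm": xyz[:, 0],
            "y_nm": xyz[:, 1],
            "z_nm": xyz[:, 2],
            "voxel_count": counts[order].astype(int),
        }
    )


def apply_exclusions(
    table: pd.DataFrame,
    surfaces: SurfacePair,
    footprint_xy_nm: tuple[float, float],
    awi_margin_nm: float = 25.0,
    xy_margin_nm: float = 75.0,
) -> pd.DataFrame:
    """Flag tags near the AWIs or the tomogram XY edge.

    ``excluded_awi`` marks tags whose signed vertical distance to either AWI
    height field is <= ``awi_margin_nm`` (inclusive; tags outside the slab
    have negative distance and are excluded too).  ``excluded_xy`` marks tags
    within ``xy_margin_nm`` of any XY boundary of the footprint.  Tags outside
    the footprint are an error.  Returns a copy with the two flag columns and
    ``retained``.
    """
    out = table.copy()
    x = out["x_nm"].to_numpy(float)
    y = out["y_nm"].to_numpy(float)
    z = out["z_nm"].to_numpy(float)
    ext_x, ext_y = float(footprint_xy_nm[0]), float(footprint_xy_nm[1])
    if np.any((x < 0) | (x > ext_x) | (y < 0) | (y > ext_y)):
        raise ValueError("tag centroid outside the tomogram XY footprint")
    d_top = surfaces.top(x, y) - z
    d_bottom = z - surfaces.bottom(x, y)
    out["excluded_awi"] = (d_top <= awi_margin_nm) | (d_bottom <= awi_margin_nm)
    edge_dist = np.minimum.reduce([x, ext_x - x, y, ext_y - y])
    out["excluded_xy"] = edge_dist <= xy_margin_nm
    out["retained"] = ~(out["excluded_awi"] | out["excluded_xy"])
    return out


def membrane_distances(table: pd.DataFrame, membrane: VoxelGrid) -> pd.DataFrame:
    """Nearest distance (nm) from each retained tag to the membrane mask.

    Computed as a physical-unit Euclidean distance transform of the membrane
    complement (distance to the nearest membrane voxel center), sampled at
    each centroid with trilinear interpolation to honor sub-voxel positions.
    Excluded tags carry NaN.
    """
    mem = np.asarray(membrane.data) > 0
    if not mem.any():
        raise ValueError("membrane mask is empty")
    out = table.copy()
    retained = (
        out["retained"].to_numpy(bool)
        if "retained" in out.columns
        else np.ones(len(out), dtype=bool)
    )
    out["membrane_distance_nm"] = np.nan
    if retained.any():
        edt = ndimage.distance_transform_edt(
            ~mem, sampling=tuple(membrane.voxel_size_zyx)
        )
        pts = out.loc[retained, ["x_nm", "y_nm", "z_nm"]].to_numpy(float)
        idx_zyx = membrane.physical_to_index(pts)
        sampled = ndimage.map_coordinates(
            edt, idx_zyx.T, order=1, mode="nearest"
        )
        out.loc[retained, "membrane_distance_nm"] = sampled
    return out


def distance_histogram(
    table: pd.DataFrame, bin_nm: float = 5.0, within_nm: float = 100.0
) -> DistanceHistogram:
    """5-nm-bin histogram of tag-membrane distances with sub-100-nm summary.

    Bins are half-open ``[k*bin, (k+1)*bin)`` covering at least [0, 600) nm
    and extended if any distance exceeds 600, so counts always sum to
    ``n_total``.
    """
    if bin_nm <= 0:
        raise ValueError("bin_nm must be positive")
    d = table["membrane_distance_nm"].to_numpy(float)
    d = d[np.isfinite(d)]
    hi = 600.0
    if d.size and d.max() >= hi:
        hi = bin_nm * np.ceil((d.max() + 1e-9) / bin_nm)
    edges = np.arange(0.0, hi + bin_nm / 2, bin_nm)
    counts, _ = np.histogram(d, bins=edges)
    n_total = int(d.size)
    within = d[d < within_nm]
    n_within = int(within.size)
    return DistanceHistogram(
        bin_edges_nm=edges,
        counts=counts,
        n_total=n_total,
        n_within=n_within,
        fraction_within=(n_within / n_total) if n_total else float("nan"),
        mean_nm=float(within.mean()) if n_within else float("nan"),
        sd_nm=float(within.std(ddof=0)) if n_within else float("nan"),
        within_nm=float(within_nm),
    )


def run_tag_pipeline(
    conf: VoxelGrid,
    membrane: VoxelGrid,
    awi_top_picks: PointSet3D,
    awi_bottom_picks: PointSet3D,
    threshold: float = 1.4,
    min_voxels: int = 100,
    awi_margin_nm: float = 25.0,
    xy_margin_nm: float = 75.0,
    bin_nm: float = 5.0,
    within_nm: float = 100.0,
) -> tuple[pd.DataFrame, DistanceHistogram]:
    """End-to-end FerriTag pipeline: confidence map to distance histogram.

    The XY footprint is taken from the confidence grid's physical extent.
    Returns the full tag table (with exclusion flags and distances) and the
    histogram summary.
    """
    mask = threshold_map(conf, level=threshold)
    labels = filter_small(split_touching(mask), min_voxels=min_voxels)
    table = detection_centroids(labels)
    surfaces = SurfacePair.from_picks(awi_top_picks, awi_bottom_picks)
    ext = conf.extent_xyz_nm
    table = apply_exclusions(
        table,
        surfaces,
        footprint_xy_nm=(float(ext[0]), float(ext[1])),
        awi_margin_nm=awi_margin_nm,
        xy_margin_nm=xy_margin_nm,
    )
    table = membrane_distances(table, membrane)
    hist = distance_histogram(table, bin_nm=bin_nm, within_nm=within_nm)
    return table, hist
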