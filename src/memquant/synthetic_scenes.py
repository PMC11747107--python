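"""Synthetic 2D/3D scenes with planted ground truth.

Every analysis stage in this package is exercised on generated data whose
ground truth is known by construction:

* :func:`gen_prem_scene` — a 2D platinum-replica-style label mask of flat,
  dome and sphere clathrin structures placed at controlled signed offsets
  from a Quantifoil hole edge.
* :func:`gen_tag_scene` — a 3D confidence map of hollow 12-nm FerriTag
  shells planted at known analytic distances above a gently curved
  clathrin-coated membrane patch, bounded by two flat air-water interfaces
  (AWIs).  A controllable fraction of tags is planted as touching pairs to
  exercise watershed separation.
* :func:`gen_particle_scene` — a ribosome-like particle cloud between two
  AWI surfaces, with an optional Gaussian accumulation layer under the top
  interface and an independent per-particle "well-aligned" flag.

Every generator is a pure function of its configuration and seed; the seed is
recorded in the truth table's ``attrs``.  The confidence maps use a radial
cosine-tapered shell kernel rather than CNN-realistic output: only the
threshold contract (in-tag confidence above 1.4, background below) matters to
the downstream pipeline, and the generator defines the confidence scale on
which that threshold is meaningful (kernel amplitude 2.0 on a zero
background).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_geometry import PointSet3D, VoxelGrid
from .prem_rings import CLASSES, HoleSpec, LabelImage2D

__all__ = [
    "PremScene",
    "TagScene",
    "ParticleScene",
    "gen_prem_scene",
    "gen_tag_scene",
    "gen_particle_scene",
]

# 12-nm outer-diameter hollow FerriTag shell, rendered as a radial
# cosine-tapered kernel: amplitude at the 6-nm shell radius, zero beyond
# +/- TAG_TAPER_NM.  At threshold 1.4 the shell is ~2 nm thick.
TAG_SHELL_RADIUS_NM = 6.0
TAG_TAPER_NM = 2.0
TAG_AMPLITUDE = 2.0
TAG_KERNEL_EXTENT_NM = TAG_SHELL_RADIUS_NM + TAG_TAPER_NM


@dataclass
class PremScene:
    image: LabelImage2D
    holes: list[HoleSpec]
    truth: pd.DataFrame

    def __iter__(self):
        return iter((self.image, self.holes, self.truth))


@dataclass
class TagScene:
    confidence: VoxelGrid
    membrane: VoxelGrid
    awi_top_picks: PointSet3D
    awi_bottom_picks: PointSet3D
    truth: pd.DataFrame

    def __iter__(self):
        return iter(
            (self.confidence, self.membrane, self.awi_top_picks, self.awi_bottom_picks, self.truth)
        )


@dataclass
class ParticleScene:
    particles: PointSet3D
    top_picks: PointSet3D
    bottom_picks: PointSet3D
    truth: pd.DataFrame

    def __iter__(self):
        return iter((self.particles, self.top_picks, self.bottom_picks, self.truth))


# ---------------------------------------------------------------------------
# 2D platinum-replica scenes
# ---------------------------------------------------------------------------

# default structure radii (nm) back-computed from typical per-class projected
# areas (flat ~0.032 um^2, dome ~0.019, sphere ~0.013)
DEFAULT_STRUCT_RADIUS_NM = {"flat": 100.0, "dome": 78.0, "sphere": 64.0}


def gen_prem_scene(
    n_structures: int | dict[str, int],
    hole_radius_nm: float = 1000.0,
    pixel_size_nm: float = 5.0,
    edge_enrichment: dict[str, tuple[float, float]] | None = None,
    image_shape_px: tuple[int, int] = (680, 680),
    seed: int | None = None,
    struct_radius_nm: dict[str, float] | None = None,
    half_range_nm: float = 500.0,
    max_retries: int = 500,
) -> PremScene:
    """Generate a 2D clathrin class mask around a single Quantifoil hole.

    Parameters
    ----------
    n_structures:
        Structures per class (an int applies to all three classes).
    edge_enrichment:
        Optional per-class ``(lo, hi)`` interval of signed edge offsets (nm)
        from which that class's centroids are drawn uniformly.  Classes not
        listed draw uniformly from ``[-half_range_nm, half_range_nm)``.
    struct_radius_nm:
        Per-class mean radius; each structure jitters by ±20%.  Flat
        structures are rendered as irregular (random-axis-ratio, rotated)
        ellipses, domes and spheres as discs.

    Structures are placed without overlap (bounded retries, then an error
    naming the constraint) and fully inside the image, so the raster centroid
    of each symmetric structure matches its planted center to within half a
    pixel.  The hole sits at the image center.
    """
    rng = np.random.default_rng(seed)
    if isinstance(n_structures, int):
        n_structures = {cls: n_structures for cls in CLASSES}
    struct_radius_nm = {**DEFAULT_STRUCT_RADIUS_NM, **(struct_radius_nm or {})}
    edge_enrichment = edge_enrichment or {}
    ny, nx = image_shape_px
    size_x, size_y = nx * pixel_size_nm, ny * pixel_size_nm
    cx, cy = size_x / 2.0, size_y / 2.0
    if hole_radius_nm + half_range_nm > min(cx, cy):
        raise ValueError(
            "hole plus the +/-500 nm ring range does not fit in the image; "
            "enlarge image_shape_px or shrink hole_radius_nm"
        )

    placed: list[tuple[float, float, float]] = []  # (x, y, bounding radius)
    rows = []
    for cls in CLASSES:
        lo, hi = edge_enrichment.get(cls, (-half_range_nm, half_range_nm))
        if not -hole_radius_nm < lo < hi:
            raise ValueError(f"invalid enrichment interval for {cls}: ({lo}, {hi})")
        for _ in range(int(n_structures[cls])):
            base_r = struct_radius_nm[cls]
            for _attempt in range(max_retries):
                offset = rng.uniform(lo, hi)
                theta = rng.uniform(0, 2 * np.pi)
                radius = base_r * (1 + 0.2 * rng.uniform(-1, 1))
                if cls == "flat":  # irregular patch: anisotropic ellipse
                    axis_ratio = rng.uniform(0.6, 1.0)
                    ax_a, ax_b = radius / np.sqrt(axis_ratio), radius * np.sqrt(axis_ratio)
                    tilt = rng.uniform(0, np.pi)
                else:
                    ax_a = ax_b = radius
                    tilt = 0.0
                bound = max(ax_a, ax_b)
                r_pos = hole_radius_nm + offset
                x = cx + r_pos * np.cos(theta)
                y = cy + r_pos * np.sin(theta)
                if not (bound < x < size_x - bound and bound < y < size_y - bound):
                    continue
                if all(
                    np.hypot(x - px_, y - py_) > bound + pb + 2 * pixel_size_nm
                    for px_, py_, pb in placed
                ):
                    placed.append((x, y, bound))
                    rows.append(
                        {
                            "class": cls,
                            "centroid_x_nm": x,
                            "centroid_y_nm": y,
                            "offset_nm": offset,
                            "ax_a_nm": ax_a,
                            "ax_b_nm": ax_b,
                            "tilt_rad": tilt,
                        }
                    )
                    break
            else:
                raise ValueError(
                    f"could not place a {cls} structure without overlap after "
                    f"{max_retries} retries; reduce n_structures or structure radii"
                )

    truth = pd.DataFrame(rows)
    truth.insert(0, "label", np.arange(1, len(truth) + 1))

    labels = np.zeros((ny, nx), dtype=np.int32)
    xpix = (np.arange(nx) + 0.5) * pixel_size_nm
    ypix = (np.arange(ny) + 0.5) * pixel_size_nm
    areas = []
    for row in truth.itertuples():
        pad = max(row.ax_a_nm, row.ax_b_nm) + pixel_size_nm
        ix = np.flatnonzero(np.abs(xpix - row.centroid_x_nm) <= pad)
        iy = np.flatnonzero(np.abs(ypix - row.centroid_y_nm) <= pad)
        gx, gy = np.meshgrid(xpix[ix] - row.centroid_x_nm, ypix[iy] - row.centroid_y_nm)
        c, s = np.cos(row.tilt_rad), np.sin(row.tilt_rad)
        u = gx * c + gy * s
        v = -gx * s + gy * c
        inside = (u / row.ax_a_nm) ** 2 + (v / row.ax_b_nm) ** 2 <= 1.0
        block = labels[np.ix_(iy, ix)]
        block[inside] = row.label
        labels[np.ix_(iy, ix)] = block
        areas.append(int(inside.sum()))
    truth["area_nm2"] = np.asarray(areas, dtype=float) * pixel_size_nm**2
    truth = truth.drop(columns=["ax_a_nm", "ax_b_nm", "tilt_rad"])
    truth.attrs["seed"] = seed
    truth.attrs["pixel_size_nm"] = pixel_size_nm
    truth.attrs["hole_radius_nm"] = hole_radius_nm

    image = LabelImage2D(
        labels=labels,
        pixel_size_nm=pixel_size_nm,
        class_of=dict(zip(truth["label"].astype(int), truth["class"])),
    )
    hole = HoleSpec(center_xy_nm=(cx, cy), radius_nm=hole_radius_nm)
    return PremScene(image=image, holes=[hole], truth=truth)


# ---------------------------------------------------------------------------
# 3D FerriTag scenes
# ---------------------------------------------------------------------------

def gen_tag_scene(
    n_tags: int,
    distance_law: tuple[float, float] = (50.0, 17.0),
    slab_thickness_nm: float = 163.0,
    voxel_size_nm: float = 1.08,
    touching_pair_fraction: float = 0.0,
    noise_sd: float = 0.1,
    seed: int | None = None,
    footprint_xy_nm: float = 800.0,
    membrane_sphere_radius_nm: float = 18000.0,
    min_center_separation_nm: float = 18.0,
    max_retries: int = 1000,
) -> TagScene:
    """Generate a 3D FerriTag scene with exact analytic membrane distances.

    The clathrin-coated membrane is the upper cap of a large sphere
    (default radius 18 µm, apex 36 nm above the bottom AWI), so it appears as
    a gently curved, near-horizontal patch and the planted distance of a tag
    at position ``p`` is exactly ``| ||p - c|| - R |``.  Tags are placed along
    the outward surface normal at membrane distances drawn from a normal law
    truncated at 0 (``distance_law = (mean, sd)`` nm; (50, 17) emulates the
    Hip1R adapter, (35, 15) clathrin light chain).  ``touching_pair_fraction``
    of the tags are planted as pairs with 8-nm center separation, which merge
    into one connected component at the 1.4 threshold.

    The bottom AWI is a flat plane 4 nm above z = 0 and the top AWI is
    ``slab_thickness_nm`` above it (valid range 78–221 nm); both are returned
    as 5x5 pick grids.  The membrane mask is a 3-voxel-thick raster of the
    analytic surface.  Per-tag truth records the exact distance and the
    noiseless thresholded voxel count.
    """
    mean_nm, sd_nm = float(distance_law[0]), float(distance_law[1])
    if sd_nm <= 0:
        raise ValueError("distance_law sd must be positive")
    if voxel_size_nm <= 0:
        raise ValueError("voxel_size_nm must be positive")
    if not 78.0 <= slab_thickness_nm <= 221.0:
        raise ValueError(
            f"slab_thickness_nm={slab_thickness_nm} outside the supported 78-221 nm range"
        )
    if not 0.0 <= touching_pair_fraction <= 1.0:
        raise ValueError("touching_pair_fraction must be in [0, 1]")

    vs = float(voxel_size_nm)
    ext = float(footprint_xy_nm)
    z_bottom_awi = 4.0
    z_top_awi = z_bottom_awi + float(slab_thickness_nm)
    apex_z = z_bottom_awi + 36.0
    z_extent = z_top_awi + 10.0
    nx = ny = int(np.ceil(ext / vs))
    nz = int(np.ceil(z_extent / vs))
    R = float(membrane_sphere_radius_nm)
    center = np.array([ext / 2.0, ext / 2.0, apex_z - R])  # (x, y, z)

    # feasibility: the law's mean must put tags inside the slab
    if apex_z + mean_nm + TAG_KERNEL_EXTENT_NM >= z_top_awi + 10.0:
        raise ValueError(
            f"distance law mean {mean_nm} nm does not fit inside a "
            f"{slab_thickness_nm} nm slab above the membrane"
        )
    rng = np.random.default_rng(seed)
    law = stats.truncnorm(a=-mean_nm / sd_nm, b=np.inf, loc=mean_nm, scale=sd_nm)

    n_pair_tags = 2 * int(round(n_tags * touching_pair_fraction / 2.0))
    n_singles = n_tags - n_pair_tags

    # spatial hash for the minimum 3D center separation
    cell = min_center_separation_nm
    grid_hash: dict[tuple[int, int, int], list[np.ndarray]] = {}

    def _far_enough(p: np.ndarray) -> bool:
        key = tuple((p // cell).astype(int))
        for dk in np.ndindex(3, 3, 3):
            neigh = (key[0] + dk[0] - 1, key[1] + dk[1] - 1, key[2] + dk[2] - 1)
            for q in grid_hash.get(neigh, ()):
                if np.linalg.norm(p - q) < min_center_separation_nm:
                    return False
        return True

    def _insert(p: np.ndarray) -> None:
        grid_hash.setdefault(tuple((p // cell).astype(int)), []).append(p)

    pad = TAG_KERNEL_EXTENT_NM + vs
    lo_xy, hi_xy = pad, ext - pad

    def _sample_tag(d: float) -> np.ndarray | None:
        """Place one tag at distance ``d`` along the surface normal.

        Only the lateral position is redrawn on a collision — redrawing the
        distance too would thin the densest distance layer and flatten the
        planted law.
        """
        for _ in range(max_retries):
            x = rng.uniform(lo_xy, hi_xy)
            y = rng.uniform(lo_xy, hi_xy)
            dx, dy = x - center[0], y - center[1]
            surf_z = center[2] + np.sqrt(R**2 - dx**2 - dy**2)
            p_surf = np.array([x, y, surf_z])
            u = (p_surf - center) / R
            p = center + (R + d) * u
            if not (pad <= p[2] <= z_extent - pad):
                continue
            if not (lo_xy <= p[0] <= hi_xy and lo_xy <= p[1] <= hi_xy):
                continue
            if _far_enough(p):
                return p
        return None

    distances = np.atleast_1d(law.rvs(n_singles + n_pair_tags // 2, random_state=rng))
    centers: list[np.ndarray] = []
    pair_flags: list[bool] = []
    for k in range(n_singles):
        p = _sample_tag(float(distances[k]))
        if p is None:
            raise ValueError(
                "could not place a tag satisfying the distance law inside the "
                "slab with the required separation; enlarge footprint_xy_nm "
                "or reduce n_tags"
            )
        _insert(p)
        centers.append(p)
        pair_flags.append(False)
    for k in range(n_pair_tags // 2):
        for _ in range(max_retries):
            p1 = _sample_tag(float(distances[n_singles + k]))
            if p1 is None:
                break
            u = p1 - center
            u /= np.linalg.norm(u)
            t = np.cross(u, rng.standard_normal(3))
            t /= np.linalg.norm(t)
            p2 = p1 + 8.0 * t  # < one 12-nm tag diameter -> merges at threshold
            # p1 is not yet in the hash, so only third tags constrain p2
            if (
                lo_xy <= p2[0] <= hi_xy
                and lo_xy <= p2[1] <= hi_xy
                and pad <= p2[2] <= z_extent - pad
                and _far_enough(p2)
            ):
                _insert(p1)
                _insert(p2)
                centers.extend([p1, p2])
                pair_flags.extend([True, True])
                break
        else:
            raise ValueError("could not place a touching tag pair; enlarge footprint_xy_nm")
    if len(centers) != n_tags:
        raise ValueError("could not place a touching tag pair; enlarge footprint_xy_nm")

    centers_arr = np.asarray(centers).reshape(-1, 3)

    # render the confidence map: sum of radial cosine-tapered shell kernels
    conf = np.zeros((nz, ny, nx), dtype=np.float32)
    half_w = int(np.ceil(TAG_KERNEL_EXTENT_NM / vs)) + 1
    planted_voxels = []
    for p in centers_arr:
        iz, iy, ix = (p[::-1] / vs - 0.5).round().astype(int)
        zsl = slice(max(iz - half_w, 0), min(iz + half_w + 1, nz))
        ysl = slice(max(iy - half_w, 0), min(iy + half_w + 1, ny))
        xsl = slice(max(ix - half_w, 0), min(ix + half_w + 1, nx))
        zc = (np.arange(zsl.start, zsl.stop) + 0.5) * vs - p[2]
        yc = (np.arange(ysl.start, ysl.stop) + 0.5) * vs - p[1]
        xc = (np.arange(xsl.start, xsl.stop) + 0.5) * vs - p[0]
        r = np.sqrt(
            zc[:, None, None] ** 2 + yc[None, :, None] ** 2 + xc[None, None, :] ** 2
        )
        delta = np.abs(r - TAG_SHELL_RADIUS_NM)
        kern = np.where(
            delta < TAG_TAPER_NM,
            TAG_AMPLITUDE * np.cos(np.pi * delta / (2.0 * TAG_TAPER_NM)),
            0.0,
        ).astype(np.float32)
        planted_voxels.append(int((kern >= 1.4).sum()))
        conf[zsl, ysl, xsl] += kern
    if noise_sd > 0:
        noise = rng.standard_normal(conf.shape, dtype=np.float32)
        noise *= np.float32(noise_sd)
        conf += noise
        del noise

    # membrane mask: 3-voxel-thick raster of the spherical cap
    xpix = (np.arange(nx) + 0.5) * vs
    ypix = (np.arange(ny) + 0.5) * vs
    gx, gy = np.meshgrid(xpix - center[0], ypix - center[1])
    z_surf = center[2] + np.sqrt(R**2 - gx**2 - gy**2)
    mem = np.zeros((nz, ny, nx), dtype=np.uint8)
    k_lo = int(np.floor(z_surf.min() / vs - 2)) - 1
    k_hi = int(np.ceil(z_surf.max() / vs + 2)) + 1
    for k in range(max(k_lo, 0), min(k_hi, nz)):
        zc = (k + 0.5) * vs
        mem[k][np.abs(zc - z_surf) <= 1.5 * vs] = 1

    # AWI pick grids (flat planes)
    g = np.linspace(0.0, ext, 5)
    gxp, gyp = np.meshgrid(g, g)
    top_picks = PointSet3D(
        np.column_stack([gxp.ravel(), gyp.ravel(), np.full(gxp.size, z_top_awi)])
    )
    bottom_picks = PointSet3D(
        np.column_stack([gxp.ravel(), gyp.ravel(), np.full(gxp.size, z_bottom_awi)])
    )

    exact_d = np.abs(np.linalg.norm(centers_arr - center, axis=1) - R)
    truth = pd.DataFrame(
        {
            "x_nm": centers_arr[:, 0],
            "y_nm": centers_arr[:, 1],
            "z_nm": centers_arr[:, 2],
            "distance_nm": exact_d,
            "voxel_count": planted_voxels,
            "pair_member": pair_flags,
        }
    )
    truth.attrs.update(
        seed=seed,
        membrane_sphere_center_xyz_nm=tuple(center),
        membrane_sphere_radius_nm=R,
        z_bottom_awi_nm=z_bottom_awi,
        z_top_awi_nm=z_top_awi,
        slab_thickness_nm=float(slab_thickness_nm),
        footprint_xy_nm=ext,
        voxel_size_nm=vs,
        distance_law=(mean_nm, sd_nm),
    )

    grid_kwargs = dict(voxel_size_nm=vs, origin_nm=(0.0, 0.0, 0.0))
    return TagScene(
        confidence=VoxelGrid(conf, **grid_kwargs),
        membrane=VoxelGrid(mem, **grid_kwargs),
        awi_top_picks=top_picks,
        awi_bottom_picks=bottom_picks,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Particle (ribosome-like) scenes
# ---------------------------------------------------------------------------

def gen_particle_scene(
    n_particles: int,
    top_peak: tuple[float, float] = (27.0, 0.4),
    aligned_fraction: float = 0.5,
    roughness_nm: float = 0.0,
    seed: int | None = None,
    footprint_xy_nm: tuple[float, float] = (1000.0, 1000.0),
    slab_base_nm: tuple[float, float] = (0.0, 150.0),
    peak_sd_nm: float = 2.5,
    pick_grid: int = 7,
) -> ParticleScene:
    """Generate a particle cloud between two AWI surfaces.

    The depth distribution is a mixture: with probability ``top_peak[1]`` a
    particle sits in a Gaussian accumulation layer ``top_peak[0]`` nm under
    the top AWI (sd ``peak_sd_nm``), otherwise uniformly in the slab.  Each
    particle is flagged "well-aligned" with probability ``aligned_fraction``,
    independent of depth — emulating the observation that particle quality is
    roughly constant through the slab.

    The true surfaces are themselves piecewise-linear over a ``pick_grid`` ×
    ``pick_grid`` control grid (base heights ``slab_base_nm`` perturbed by
    ±``roughness_nm``), and the returned picks are exactly those control
    points, so planted distances are reproduced exactly by surface
    interpolation.  All particles lie strictly between the surfaces.
    """
    peak_offset, weight = float(top_peak[0]), float(top_peak[1])
    if not 0.0 <= weight <= 1.0:
        raise ValueError(f"accumulation weight must be in [0, 1], got {weight}")
    if not 0.0 <= aligned_fraction <= 1.0:
        raise ValueError(f"aligned_fraction must be in [0, 1], got {aligned_fraction}")
    z_b0, z_t0 = float(slab_base_nm[0]), float(slab_base_nm[1])
    if roughness_nm < 0 or 2 * roughness_nm >= z_t0 - z_b0:
        raise ValueError("roughness_nm must be >= 0 and small vs. the slab gap")
    rng = np.random.default_rng(seed)
    ext_x, ext_y = float(footprint_xy_nm[0]), float(footprint_xy_nm[1])

    gx = np.linspace(0.0, ext_x, pick_grid)
    gy = np.linspace(0.0, ext_y, pick_grid)
    mx, my = np.meshgrid(gx, gy)
    z_bot = z_b0 + roughness_nm * rng.uniform(-1, 1, mx.shape)
    z_top = z_t0 + roughness_nm * rng.uniform(-1, 1, mx.shape)
    bottom_picks = PointSet3D(np.column_stack([mx.ravel(), my.ravel(), z_bot.ravel()]))
    top_picks = PointSet3D(np.column_stack([mx.ravel(), my.ravel(), z_top.ravel()]))

    from .awi_profile import SurfacePair  # local import to avoid a cycle

    surfaces = SurfacePair.from_picks(top_picks, bottom_picks)

    x = rng.uniform(0.0, ext_x, n_particles)
    y = rng.uniform(0.0, ext_y, n_particles)
    zt = surfaces.top(x, y)
    zb = surfaces.bottom(x, y)
    thickness = zt - zb
    in_peak = rng.uniform(size=n_particles) < weight
    # uniform component, strictly inside the slab
    z = zb + rng.uniform(size=n_particles) * thickness
    # accumulation layer: resample until inside (0, thickness) from the top
    todo = np.flatnonzero(in_peak)
    d_top = np.empty(n_particles)
    d_top[todo] = -1.0
    while todo.size:
        draw = rng.normal(peak_offset, peak_sd_nm, todo.size)
        ok = (draw > 0) & (draw < thickness[todo])
        d_top[todo[ok]] = draw[ok]
        todo = todo[~ok]
    z[in_peak] = zt[in_peak] - d_top[in_peak]
    flags = rng.uniform(size=n_particles) < aligned_fraction

    particles = PointSet3D(np.column_stack([x, y, z]), flags=flags)
    truth = pd.DataFrame(
        {
            "x_nm": x,
            "y_nm": y,
            "z_nm": z,
            "d_top_nm": zt - z,
            "d_bottom_nm": z - zb,
            "in_peak": in_peak,
            "well_aligned": flags,
        }
    )
    truth.attrs.update(
        seed=seed,
        top_peak=(peak_offset, weight),
        aligned_fraction=float(aligned_fraction),
        roughness_nm=float(roughness_nm),
        slab_base_nm=(z_b0, z_t0),
        footprint_xy_nm=(ext_x, ext_y),
    )
    return ParticleScene(
        particles=particles, top_picks=top_picks, bottom_picks=bottom_picks, truth=truth
    )
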