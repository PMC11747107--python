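# Methods

This note documents the models and procedures memquant implements, the
conventions it pins down, what the synthetic-data generators do and do not
emulate, and the numerical choices made where the design was open.

## Coordinate and unit conventions

* Arrays are `(Z, Y, X)` ordered, matching MRC section order; all physical
  coordinates are reported `(x, y, z)` in nanometres.
* Indexing is voxel-center based and 0-based:
  `physical = origin + (index + 0.5) · voxel_size`. Centroid and distance
  math uses this convention everywhere.
* MRC headers carry Å; `read_volume` converts to nm and refuses zero or
  missing header voxel sizes rather than guessing. Anisotropic voxel sizes
  are accepted throughout; all distances are computed in physical nm.
* Point files standardize on nm. Where picked model points originate in
  voxel units they must be converted on import; the half-voxel center
  convention above defines that conversion.

## Ring morphometry (2D replica masks)

Clathrin classes are *flat* (no visible curvature), *dome* (curved lattice
with a visible edge) and *sphere* (curved beyond a hemisphere). The hole
edge is the radial reference; the signed offset of a point is
`‖p − c‖ − R` (negative inside the hole). Defaults: 50-nm rings spanning
±500 nm, i.e. 20 rings with 10 inside.

Pinned choices:

* Rings are half-open `[lo, hi)`; offset 0 belongs to the first outside
  ring. No structure can be counted twice.
* A structure is assigned by its **centroid** offset to its **nearest**
  hole (smallest absolute offset; ties break to the lower hole index).
  Structures straddling a ring edge still contribute each *pixel* to the
  occupancy of the ring that pixel falls in.
* Ring density is `count / analyzed ring area (µm²)`; occupancy is the
  fraction of analyzed ring pixels covered by the class. A ring with no
  analyzed pixels yields NaN and an `undefined` flag, never a silent zero.
* Both densities and occupancies are emitted per ring; they answer related
  but distinct questions (number vs. covered area) and neither is derivable
  from the other.
* Projected area is a raw pixel count times the pixel area; centroids are
  unweighted means of pixel centers.

## FerriTag pipeline (3D)

Stages and conventions, in execution order:

1. **Threshold** at confidence ≥ 1.4 (inclusive). Non-finite values in the
   map are an error.
2. **Watershed separation.** Connected components use 26-connectivity.
   Markers are local maxima of the physical-unit Euclidean distance
   transform (EDT) of the **hole-filled** component: a hollow 12-nm shell
   has a flat EDT ridge on the shell itself, which would seed one marker
   per ridge voxel, while the filled ball has a single interior maximum.
   Candidate maxima (strict 1-voxel neighborhood) are thinned by greedy
   suppression at a 6-nm minimum separation (one tag radius), keeping
   higher peaks first. A wider max-filter footprint is deliberately not
   used: for two tags 8 nm apart the slope toward the deeper peak enters
   the shallower peak's neighborhood and swallows it. Components with one
   marker pass through unchanged; the watershed runs per component on a
   cropped subvolume and labels are restricted to the original mask.
3. **Size filter**: regions with strictly fewer than 100 voxels are
   removed; a 100-voxel region survives. Ids are preserved.
4. **Centroids** are unweighted voxel-center means. For an isolated
   (symmetric) shell the centroid is essentially exact; for a
   watershed-split pair the voxel-quantized cut plane can shift it by up to
   about one voxel diagonal.
5. **Exclusions** (inclusive): vertical distance ≤ 25 nm to either AWI
   height field, or ≤ 75 nm to any XY boundary. Tags outside the slab
   (negative signed distance) are likewise excluded. A tag outside the XY
   footprint is an error, not a flag.
6. **Membrane distance**: EDT of the membrane-mask complement with the
   voxel size as sampling, evaluated at the sub-voxel centroid by trilinear
   interpolation. Distances are measured to membrane voxel **centers**, not
   to a sub-voxel surface, so they are biased small by up to about half a
   voxel (~0.5 nm at 1.08 nm voxels); this is visible as a ~1 nm downward
   shift of recovered means and is within the stated tolerances.
7. **Histogram**: half-open 5-nm bins covering at least [0, 600) nm,
   extended if needed so counts always sum to the total. The sub-100-nm
   population is summarized by its count, fraction, mean and *population*
   sd (ddof = 0). An empty input yields a NaN fraction, not zero.

## AWI surfaces, depth profiles, thickness

Surfaces are height fields `z(x, y)` interpolated piecewise-linearly over
the Delaunay triangulation of the picks, with nearest-pick extrapolation
outside the convex hull; evaluation at a pick is exact. Distances to the
surfaces are **vertical** (along z), which makes
`d_top + d_bottom = local slab thickness` an exact identity and agrees with
the true 3D point-to-surface distance to better than 2% for surface slopes
under ~10°; the AWIs of a blotted slab are near-horizontal. (A true 3D
distance could be added behind an option flag; it is not the default
because it breaks the conservation identity.)

Depth profiles use half-open 5-nm bins per side; the per-bin "well-aligned"
fraction is NaN for empty bins.

Tomogram thickness samples a 3×3 grid of crop centers at footprint
fractions {1/6, 1/2, 5/6} per axis — a concrete reading of "nine equally
spaced positions" — and averages `z_top − z_bot` over a 200-pixel-square
crop at voxel pitch per position; the mean of the nine values is the
tomogram thickness. This is a surface-model definition; manual readings of
minimum-intensity projections may differ and parity with them is not
claimed.

## Landmark affine registration

`fit_affine2d` solves the least-squares problem
`min Σ‖A·src_i + b − dst_i‖²` from ≥ 3 landmark pairs via the normal
equations of the stacked design `[x y 1]`; three non-collinear pairs
interpolate exactly, and collinear landmarks raise (singular system).
Seeded random affines are recovered to better than 1e-9.

## Statistics

* Integer percentages round half away from zero (633/784 → 81%).
* Mann-Whitney U uses rank sums with tie correction; p-values by exact
  enumeration when `n·m ≤ 400` with no ties, otherwise the tie- and
  continuity-corrected normal approximation. Published analyses of this
  kind were run in commercial software whose exact variant is not
  documented; parity with any particular implementation is not claimed.
  Two-sided is the default with one-sided available, since source analyses
  are described inconsistently as one- and two-tailed.
* Box summaries: quartiles by linear interpolation between closest ranks,
  SEM with ddof = 1 (0 for a single observation).

## Synthetic scenes: what they emulate, and what not

All generators are pure functions of (configuration, seed) with a single
RNG stream; the seed is recorded in the truth table. Truth tables and
rasters are mutually consistent: re-deriving centroids and areas from the
rasters reproduces the truth to within half a pixel/voxel.

**PREM scenes** place non-overlapping flat (irregular ellipse), dome and
sphere (disc) structures at controlled signed edge offsets around a
centered hole (default radius 1 µm, 5-nm pixels). Default structure radii
(100/78/64 nm) are back-computed from typical per-class projected areas
(~0.032/0.019/0.013 µm²). Placement that cannot satisfy the non-overlap
constraint raises after bounded retries.

**Tag scenes** model the clathrin-coated membrane as the upper cap of an
18-µm sphere with its apex 36 nm above the bottom AWI — gently curved and
near-horizontal, with the decisive property that the planted distance of a
tag at `p` is the exact analytic value `|‖p − c‖ − R|`. Tags are placed
along the outward surface normal at distances drawn once per tag from a
normal law truncated at zero ((50, 17) nm emulates the Hip1R adapter;
(35, 15) nm clathrin light chain); on a placement collision only the
lateral position is redrawn, never the distance, so the marginal law is
preserved. A configurable fraction of tags is planted as 8-nm-separation
pairs that merge into one component at threshold. The confidence map is a
sum of radial cosine-tapered shell kernels (outer diameter 12 nm, taper
2 nm, amplitude 2.0 on a zero background) plus Gaussian noise (sd 0.1):
the real detector is a CNN whose output scale is not defined here, so the
generator defines its own scale on which the 1.4 threshold is meaningful —
in-shell confidence is above it and background is below it before noise.
The membrane raster is 3 voxels thick, emulating dilated manual contour
masks. Defaults: 1.08-nm voxels (a bin-10 tomogram), a 163-nm slab
(within the observed 78–221 nm range), bottom AWI 4 nm above the volume
floor, flat AWI planes returned as 5×5 pick grids. The 800-nm footprint
was chosen so that 2000 tags fit well below the random-sequential-packing
limit of the densest distance layer while ~1350 tags survive the 75-nm
edge exclusion.

**Particle scenes** mix a uniform slab component with a Gaussian
accumulation layer under the top AWI (default 27 nm, sd 2.5 nm, weight
0.4 — reproducing the observed 25–30 nm accumulation bin) and flag each
particle "well-aligned" with a constant, depth-independent probability.
The true surfaces are themselves piecewise-linear over the returned pick
grid, so planted distances are reproduced exactly by the interpolation
path.

Not emulated: missing-wedge artifacts, CTF, cytoskeletal texture,
CNN-realistic confidence statistics, detector false positives, and any
correlation of particle quality with depth. Passing tests therefore
demonstrate the correctness of the measurement code under the stated
geometric and statistical conditions, not detector performance on real
tomograms.

## Problem sizes and tolerances

The standard verification runs use: 2000-tag scenes (~60 µm³ at 1.08-nm
voxels, ≈ 74 million voxels) for distance-law recovery, where the
recovered sub-100-nm mean and sd match the planted values within 2 nm; a
300-tag noiseless scene for exact count recovery including watershed pair
splitting; 100 random ≤ 32³ volumes for EDT-vs-exhaustive-minimum
agreement within one voxel diagonal; and 10000-particle scenes for depth
profiles, with per-bin aligned fractions within 3 binomial SE of the
planted probability. Larger scenes change none of the conventions, only
the sampling error.

## Known limitations

* Distances to the membrane are to voxel centers; sub-voxel surface
  recovery is out of scope.
* Watershed splitting assumes roughly spherical tags of one size; heavily
  overlapping clusters (3+ tags within a diameter) may not be fully
  separated, and under noise an occasional 8-nm pair merges.
* Vertical AWI distances deviate from true 3D distances on steep surfaces.
* The Mann-Whitney exact path is limited to tie-free small samples.
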