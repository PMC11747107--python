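"""Ring morphometry: centroids, offsets, ring assignment, densities."""

import numpy as np
import pandas as pd
import pytest

import memquant as mq
from memquant.prem_rings import HoleSpec, LabelImage2D, _nearest_hole_offsets


def _square_image(px=10.0):
    """One 10x10-px square structure with its top-left pixel at (10, 10)."""
    labels = np.zeros((40, 40), dtype=np.int32)
    labels[10:20, 10:20] = 1
    return LabelImage2D(labels=labels, pixel_size_nm=px, class_of={1: "flat"})


class TestStructureCentroids:
    def test_square_closed_form(self):
        cent = mq.structure_centroids(_square_image())
        row = cent.iloc[0]
        assert row.area_um2 == pytest.approx(0.01)  # 100 px * (10 nm)^2
        assert row.centroid_x_nm == pytest.approx(150.0)  # center of cols 10..19
        assert row.centroid_y_nm == pytest.approx(150.0)

    def test_two_labels_ordered_by_id(self):
        labels = np.zeros((20, 20), dtype=np.int32)
        labels[1:3, 1:3] = 2
        labels[10:12, 10:14] = 1
        img = LabelImage2D(labels, 5.0, {1: "dome", 2: "sphere"})
        cent = mq.structure_centroids(img)
        assert list(cent["label"]) == [1, 2]
        assert list(cent["class"]) == ["dome", "sphere"]

    def test_missing_label_raises(self):
        labels = np.zeros((5, 5), dtype=np.int32)
        labels[0, 0] = 1
        img = LabelImage2D(labels, 5.0, {1: "flat"})
        img.class_of = {1: "flat", 7: "dome"}  # label 7 has no pixels
        with pytest.raises(ValueError, match="zero pixels"):
            mq.structure_centroids(img)

    def test_area_matches_brute_force_recount(self, prem_scene):
        cent = mq.structure_centroids(prem_scene.image)
        for row in cent.itertuples():
            n_px = int((prem_scene.image.labels == row.label).sum())
            assert row.area_um2 == pytest.approx(
                n_px * prem_scene.image.pixel_size_nm**2 / 1e6
            )


class TestSignedEdgeOffset:
    @pytest.mark.parametrize(
        "point,radius,expected",
        [((0.0, 0.0), 1000.0, -1000.0), ((1000.0, 0.0), 1000.0, 0.0), ((1500.0, 0.0), 1000.0, 500.0)],
    )
    def test_arithmetic(self, point, radius, expected):
        hole = HoleSpec(center_xy_nm=(0.0, 0.0), radius_nm=radius)
        assert mq.signed_edge_offset(np.array(point), hole) == pytest.approx(expected)

    def test_invalid_radius(self):
        with pytest.raises(ValueError):
            HoleSpec((0.0, 0.0), -5.0)


class TestRingProfile:
    def test_default_config_has_20_rings_10_inside(self, prem_scene):
        prof = mq.ring_profile(prem_scene.image, prem_scene.holes)
        assert len(prof) == 20
        assert int((prof["lo_nm"] < 0).sum()) == 10
        # intervals tile [-500, 500) without gaps
        np.testing.assert_allclose(prof["hi_nm"].to_numpy()[:-1], prof["lo_nm"].to_numpy()[1:])
        assert prof["lo_nm"].iloc[0] == -500 and prof["hi_nm"].iloc[-1] == 500

    def test_structures_planted_in_one_ring(self):
        scene = mq.gen_prem_scene(
            {"flat": 10, "dome": 0, "sphere": 0},
            edge_enrichment={"flat": (0.0, 50.0)},
            seed=8,
        )
        prof = mq.ring_profile(scene.image, scene.holes)
        ring = prof[(prof.lo_nm == 0.0)].iloc[0]
        assert ring["count_flat"] == 10
        assert prof["count_flat"].sum() == 10

    def test_counts_match_brute_force_membership(self, prem_scene):
        """Independent loop over structures and interval membership."""
        prof = mq.ring_profile(prem_scene.image, prem_scene.holes)
        truth = prem_scene.truth
        hole = prem_scene.holes[0]
        for _, ring in prof.iterrows():
            for cls in mq.CLASSES:
                expected = 0
                for row in truth[truth["class"] == cls].itertuples():
                    off = (
                        np.hypot(
                            row.centroid_x_nm - hole.center_xy_nm[0],
                            row.centroid_y_nm - hole.center_xy_nm[1],
                        )
                        - hole.radius_nm
                    )
                    if ring.lo_nm <= off < ring.hi_nm:
                        expected += 1
                assert ring[f"count_{cls}"] == expected

    def test_boundary_offsets_counted_once(self, prem_scene):
        """A centroid exactly on a ring edge lands in the upper ring only."""
        hole = prem_scene.holes[0]
        cx, cy = hole.center_xy_nm
        # offsets exactly on every ring boundary, placed along +x
        structures = pd.DataFrame(
            {
                "label": np.arange(1, 20),
                "class": ["dome"] * 19,
                "centroid_x_nm": cx + hole.radius_nm + np.arange(-450, 500, 50),
                "centroid_y_nm": np.full(19, cy),
                "area_um2": np.full(19, 0.01),
            }
        )
        prof = mq.ring_profile(prem_scene.image, prem_scene.holes, structures=structures)
        assert prof["count_dome"].sum() == 19  # every structure counted exactly once
        # offset 0 belongs to the first outside ring [0, 50)
        assert prof.loc[prof.lo_nm == 0.0, "count_dome"].iloc[0] >= 1

    def test_multi_hole_nearest_assignment(self):
        holes = [HoleSpec((0.0, 0.0), 100.0), HoleSpec((1000.0, 0.0), 100.0)]
        x = np.array([130.0, 930.0])  # 30 nm outside hole 1; 30 nm inside hole 2
        y = np.zeros(2)
        offs = _nearest_hole_offsets(x, y, holes)
        np.testing.assert_allclose(offs, [30.0, -30.0])

    def test_empty_ring_is_flagged_not_zero(self):
        labels = np.zeros((100, 100), dtype=np.int32)
        labels[50, 50] = 1
        analyzed = np.zeros_like(labels, dtype=bool)
        analyzed[40:60, 40:60] = True  # only the hole center region analyzed
        img = LabelImage2D(labels, 10.0, {1: "sphere"}, analyzed_mask=analyzed)
        prof = mq.ring_profile(img, [HoleSpec((500.0, 500.0), 400.0)])
        outer = prof.iloc[-1]
        assert outer["undefined"]
        assert np.isnan(outer["density_sphere"])

    def test_requires_a_hole(self, prem_scene):
        with pytest.raises(ValueError, match="hole"):
            mq.ring_profile(prem_scene.image, [])

    def test_range_must_divide_into_rings(self, prem_scene):
        with pytest.raises(ValueError, match="divisible"):
            mq.ring_profile(prem_scene.image, prem_scene.holes, ring_width_nm=70.0)


class TestDensityAndOccupancy:
    def test_published_count_ratio(self):
        """844 structures over 749.46 um^2 -> 1.126 per um^2."""
        structures = pd.DataFrame({"class": ["flat"] * 844})
        dens = mq.class_density(structures, 749.46)
        assert dens["total"] == pytest.approx(1.126, abs=5e-4)

    def test_zero_structures(self):
        dens = mq.class_density(pd.DataFrame({"class": []}), 10.0)
        assert all(dens[c] == 0 for c in mq.CLASSES)

    def test_density_halves_when_area_doubles(self, prem_scene):
        cent = mq.structure_centroids(prem_scene.image)
        d1 = mq.class_density(cent, 100.0)
        d2 = mq.class_density(cent, 200.0)
        for cls in mq.CLASSES:
            assert d2[cls] == pytest.approx(d1[cls] / 2)

    def test_zero_area_raises(self):
        with pytest.raises(ValueError):
            mq.class_density(pd.DataFrame({"class": []}), 0.0)

    def test_half_coverage_is_50_percent(self):
        labels = np.zeros((10, 10), dtype=np.int32)
        labels[:5] = 1
        img = LabelImage2D(labels, 5.0, {1: "flat"})
        assert mq.membrane_area_fraction(img) == pytest.approx(50.0)

    def test_no_clathrin_is_0_percent(self):
        img = LabelImage2D(np.zeros((5, 5), dtype=np.int32), 5.0, {})
        assert mq.membrane_area_fraction(img) == 0.0

    def test_area_fraction_matches_pixel_ratio(self, prem_scene):
        img = prem_scene.image
        brute = 100.0 * (img.labels > 0).sum() / img.analyzed_mask.sum()
        assert mq.membrane_area_fraction(img) == pytest.approx(brute)

    def test_relabeling_invariance(self, prem_scene):
        """Occupancy/density are unchanged by permuting structure ids."""
        img = prem_scene.image
        ids = sorted(img.class_of)
        perm = {old: new for old, new in zip(ids, ids[::-1])}
        lut = np.zeros(max(ids) + 1, dtype=np.int32)
        for old, new in perm.items():
            lut[old] = new
        img2 = LabelImage2D(
            lut[img.labels],
            img.pixel_size_nm,
            {perm[i]: img.class_of[i] for i in ids},
            analyzed_mask=img.analyzed_mask,
        )
        p1 = mq.ring_profile(img, prem_scene.holes)
        p2 = mq.ring_profile(img2, prem_scene.holes)
        for cls in mq.CLASSES:
            np.testing.assert_allclose(p1[f"occupancy_{cls}"], p2[f"occupancy_{cls}"])
            np.testing.assert_array_equal(p1[f"count_{cls}"], p2[f"count_{cls}"])
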