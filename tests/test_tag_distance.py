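"""FerriTag pipeline stages: threshold, watershed, filter, distances."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

import memquant as mq
from memquant.io_geometry import VoxelGrid


def _ball_mask(shape, center_zyx, radius_vox):
    zz, yy, xx = np.indices(shape)
    return (
        (zz - center_zyx[0]) ** 2 + (yy - center_zyx[1]) ** 2 + (xx - center_zyx[2]) ** 2
    ) <= radius_vox**2


class TestThreshold:
    def test_boundary_value_is_inclusive(self):
        grid = VoxelGrid(np.full((3, 3, 3), 1.4, np.float32), 1.0)
        assert np.all(mq.threshold_map(grid).data == 1)

    def test_zero_map_is_empty(self):
        grid = VoxelGrid(np.zeros((3, 3, 3), np.float32), 1.0)
        assert np.all(mq.threshold_map(grid).data == 0)

    def test_non_finite_raises(self):
        data = np.zeros((3, 3, 3), np.float32)
        data[1, 1, 1] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            mq.threshold_map(VoxelGrid(data, 1.0))


class TestSplitTouching:
    def test_single_sphere_one_label(self):
        mask = _ball_mask((24, 24, 24), (12, 12, 12), 6).astype(np.uint8)
        labels = mq.split_touching(VoxelGrid(mask, 1.0))
        assert np.asarray(labels.data).max() == 1

    def test_separated_spheres_match_connected_components(self):
        mask = (
            _ball_mask((24, 48, 24), (12, 12, 12), 5)
            | _ball_mask((24, 48, 24), (12, 36, 12), 5)
        ).astype(np.uint8)
        labels = np.asarray(mq.split_touching(VoxelGrid(mask, 1.0)).data)
        cc, n = ndimage.label(mask, structure=np.ones((3, 3, 3)))
        assert labels.max() == n == 2
        # identical partition up to label naming
        for i in (1, 2):
            region = labels == i
            assert len(np.unique(cc[region])) == 1

    def test_planted_pair_split_to_planted_centers(self):
        """Two shells 8 nm apart merge at threshold but watershed splits them."""
        scene = mq.gen_tag_scene(
            2, touching_pair_fraction=1.0, noise_sd=0.0, footprint_xy_nm=120.0, seed=1
        )
        mask = mq.threshold_map(scene.confidence)
        labels = mq.split_touching(mask)
        table = mq.detection_centroids(labels)
        assert len(table) == 2
        det = table[["x_nm", "y_nm", "z_nm"]].to_numpy()
        planted = scene.truth[["x_nm", "y_nm", "z_nm"]].to_numpy()
        dists = np.linalg.norm(det[:, None] - planted[None], axis=2)
        assert dists.min(axis=1).max() < 1.08  # within one voxel of a planted center
        assert set(dists.argmin(axis=1)) == {0, 1}

    def test_empty_mask_gives_empty_labels(self):
        labels = mq.split_touching(VoxelGrid(np.zeros((4, 4, 4), np.uint8), 1.0))
        assert np.all(np.asarray(labels.data) == 0)


class TestFilterSmall:
    def _labels_with_sizes(self, sizes):
        data = np.zeros((len(sizes), 1, max(sizes)), dtype=np.int32)
        for i, s in enumerate(sizes):
            data[i, 0, :s] = i + 1
        return VoxelGrid(data, 1.0)

    def test_99_removed_100_kept(self):
        filtered = mq.filter_small(self._labels_with_sizes([99, 100, 150]))
        remaining = set(np.unique(filtered.data)) - {0}
        assert remaining == {2, 3}  # ids preserved, 99-voxel region gone

    def test_all_large_passthrough(self):
        grid = self._labels_with_sizes([120, 130])
        out = mq.filter_small(grid)
        assert np.array_equal(out.data, grid.data)


class TestCentroids:
    def test_single_voxel_closed_form(self):
        data = np.zeros((20, 20, 20), dtype=np.int32)
        data[10, 10, 10] = 1
        table = mq.detection_centroids(VoxelGrid(data, 1.08))
        row = table.iloc[0]
        assert row.x_nm == pytest.approx(10.5 * 1.08)
        assert row.y_nm == pytest.approx(10.5 * 1.08)
        assert row.z_nm == pytest.approx(10.5 * 1.08)
        assert row.voxel_count == 1

    def test_symmetric_sphere_centroid_at_center(self):
        data = _ball_mask((25, 25, 25), (12, 12, 12), 6).astype(np.int32)
        table = mq.detection_centroids(VoxelGrid(data, 1.0))
        np.testing.assert_allclose(
            table[["x_nm", "y_nm", "z_nm"]].to_numpy()[0], 12.5, atol=0.5
        )


class TestExclusions:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["x_nm", "y_nm", "z_nm"]).assign(
            id=lambda d: np.arange(1, len(d) + 1), voxel_count=500
        )

    def test_awi_and_xy_rules(self, flat_surfaces):
        table = self._table(
            [
                [500.0, 500.0, 130.0],  # 20 nm below the top AWI -> excluded
                [500.0, 500.0, 75.0],  # slab middle, but x/y fine -> retained
                [50.0, 500.0, 75.0],  # 50 nm from the x=0 edge -> excluded
                [100.0, 500.0, 75.0],  # 100 nm from the edge -> retained
            ]
        )
        out = mq.apply_exclusions(table, flat_surfaces, footprint_xy_nm=(1000.0, 1000.0))
        assert list(out.excluded_awi) == [True, False, False, False]
        assert list(out.excluded_xy) == [False, False, True, False]
        assert list(out.retained) == [False, True, False, True]

    def test_tag_outside_footprint_raises(self, flat_surfaces):
        table = self._table([[1500.0, 500.0, 75.0]])
        with pytest.raises(ValueError, match="footprint"):
            mq.apply_exclusions(table, flat_surfaces, footprint_xy_nm=(1000.0, 1000.0))


class TestMembraneDistances:
    def _run(self, table, mem, vs=1.08):
        return mq.membrane_distances(table, VoxelGrid(mem.astype(np.uint8), vs))

    def test_centroid_on_membrane_voxel_is_zero(self):
        mem = np.zeros((10, 10, 10))
        mem[5, 5, 5] = 1
        table = pd.DataFrame({"x_nm": [5.5 * 1.08], "y_nm": [5.5 * 1.08], "z_nm": [5.5 * 1.08]})
        out = self._run(table, mem)
        assert out.membrane_distance_nm.iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_height_above_plane(self):
        mem = np.zeros((40, 12, 12))
        mem[5] = 1  # flat plane of voxels at z index 5
        table = pd.DataFrame({"x_nm": [6.0 * 1.08], "y_nm": [6.0 * 1.08], "z_nm": [25.5 * 1.08]})
        out = self._run(table, mem)
        assert out.membrane_distance_nm.iloc[0] == pytest.approx(21.6, abs=1.08 / 2)

    def test_matches_exhaustive_minimum(self):
        """Trilinear-sampled EDT vs brute-force min over membrane voxels."""
        rng = np.random.default_rng(0)
        for _ in range(10):
            shape = tuple(rng.integers(8, 32, 3))
            mem = rng.random(shape) < 0.02
            if not mem.any():
                mem[0, 0, 0] = True
            grid = VoxelGrid(mem.astype(np.uint8), 1.08)
            pts = rng.uniform(
                [2, 2, 2], np.array(shape[::-1]) * 1.08 - 2, size=(20, 3)
            )
            table = pd.DataFrame(pts, columns=["x_nm", "y_nm", "z_nm"])
            out = mq.membrane_distances(table, grid)
            centers = grid.index_to_physical(np.argwhere(mem))
            brute = np.linalg.norm(
                pts[:, None, :] - centers[None, :, :], axis=2
            ).min(axis=1)
            diag = np.linalg.norm(grid.voxel_size_zyx)
            assert np.max(np.abs(out.membrane_distance_nm.to_numpy() - brute)) <= diag

    def test_empty_membrane_raises(self):
        table = pd.DataFrame({"x_nm": [1.0], "y_nm": [1.0], "z_nm": [1.0]})
        with pytest.raises(ValueError, match="empty"):
            self._run(table, np.zeros((5, 5, 5)))


class TestHistogram:
    def test_counts_in_5nm_bins(self):
        table = pd.DataFrame({"membrane_distance_nm": [2.0, 7.0, 12.0]})
        hist = mq.distance_histogram(table)
        assert list(hist.counts[:3]) == [1, 1, 1]
        assert hist.counts.sum() == hist.n_total == 3

    def test_all_within_100(self):
        table = pd.DataFrame({"membrane_distance_nm": np.linspace(1, 99, 25)})
        hist = mq.distance_histogram(table)
        assert hist.fraction_within == 1.0

    def test_empty_input_flagged(self):
        hist = mq.distance_histogram(pd.DataFrame({"membrane_distance_nm": []}))
        assert hist.n_total == 0
        assert np.isnan(hist.fraction_within)
        assert np.all(hist.counts == 0)

    def test_far_distances_extend_bins(self):
        table = pd.DataFrame({"membrane_distance_nm": [3.0, 712.0]})
        hist = mq.distance_histogram(table)
        assert hist.counts.sum() == hist.n_total == 2
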