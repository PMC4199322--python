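"""Surface clusters, proximity arithmetic, resampling, group maps."""

import numpy as np
import pytest

from hgmap import (SurfaceCluster, centroid_radius, cluster_pair_distance,
                   equivalent_group_threshold, extract_clusters, group_average,
                   grow_patch, normal_confidence_level, proximity,
                   resample_clusters, resample_significance)
from hgmap.clustermatch import cluster_table

from conftest import flat_grid_mesh


def _ball(c, r, vertex_ids=None):
    return SurfaceCluster(
        vertex_ids=np.asarray(vertex_ids if vertex_ids is not None else [0]),
        centroid=np.asarray(c, dtype=float), mean_radius=float(r))


class TestExtraction:
    def test_two_separated_blobs(self, grid_mesh):
        vmap = np.zeros(grid_mesh.n_vertices)
        blob_a = [0, 1, 10]          # corner vertices of the 10x10 grid
        blob_b = [88, 89, 98, 99]
        vmap[blob_a] = 5.0
        vmap[blob_b] = 4.0
        clusters = extract_clusters(vmap, grid_mesh, 2.3, mode="z")
        assert len(clusters) == 2
        members = sorted(tuple(sorted(c.vertex_ids)) for c in clusters)
        assert members == [tuple(blob_a), tuple(blob_b)]

    def test_nothing_above_threshold(self, grid_mesh):
        assert extract_clusters(np.zeros(grid_mesh.n_vertices), grid_mesh,
                                2.3, mode="z") == []

    def test_p_mode_nesting(self, grid_mesh):
        rng = np.random.default_rng(0)
        pmap = rng.uniform(0.0, 1.0, grid_mesh.n_vertices)
        tight = extract_clusters(pmap, grid_mesh, 0.05, mode="p")
        loose = extract_clusters(pmap, grid_mesh, 0.1, mode="p")
        for c in tight:
            assert any(set(c.vertex_ids) <= set(l.vertex_ids) for l in loose)

    def test_wrong_length_raises(self, grid_mesh):
        with pytest.raises(ValueError):
            extract_clusters(np.zeros(3), grid_mesh, 1.0)


class TestCentroidRadius:
    def test_single_vertex(self, grid_mesh):
        c = centroid_radius([7], grid_mesh)
        np.testing.assert_allclose(c.centroid, grid_mesh.vertices[7])
        assert c.mean_radius == 0.0

    def test_two_vertices(self, grid_mesh):
        # vertices 0 and 2 are 10 mm apart on the 5 mm grid
        c = centroid_radius([0, 2], grid_mesh)
        np.testing.assert_allclose(c.centroid, [0.0, 5.0, 0.0])
        assert c.mean_radius == pytest.approx(5.0)

    def test_square_corners(self, grid_mesh):
        # 2x2 cell: side 5 mm, radius = s/sqrt(2)
        c = centroid_radius([0, 1, 10, 11], grid_mesh)
        assert c.mean_radius == pytest.approx(5.0 / np.sqrt(2))

    def test_empty_raises(self, grid_mesh):
        with pytest.raises(ValueError):
            centroid_radius([], grid_mesh)


class TestProximity:
    def test_overlap_floors_at_zero(self):
        a = _ball([0, 0, 0], 4.0)
        b = _ball([6.0, 0, 0], 3.0)
        assert cluster_pair_distance(a, b) == 0.0

    def test_separation_arithmetic(self):
        a = _ball([0, 0, 0], 5.0)
        b = _ball([20.0, 0, 0], 3.0)
        assert cluster_pair_distance(a, b) == pytest.approx(12.0)

    def test_fmri_surplus_selection(self):
        eeg = [_ball([0, 0, 0], 0.0)]
        fmri = [_ball([4.0, 0, 0], 0.0), _ball([10.0, 0, 0], 0.0),
                _ball([25.0, 0, 0], 0.0)]
        res = proximity(eeg, fmri)
        np.testing.assert_allclose(res.pair_distances, [4.0])
        assert res.compound == pytest.approx(4.0)

    def test_median_compound(self):
        eeg = [_ball([0, 0, 0], 0.0), _ball([100.0, 0, 0], 0.0)]
        fmri = [_ball([6.0, 0, 0], 0.0), _ball([112.0, 0, 0], 0.0)]
        assert proximity(eeg, fmri).compound == pytest.approx(9.0)

    def test_empty_side_is_na(self):
        res = proximity([], [_ball([0, 0, 0], 1.0)])
        assert res.is_na and "EEG" in res.reason

    def test_radius_symmetry_and_rigid_motion(self, grid_mesh):
        """The pair distance uses both radii symmetrically and survives
        a rigid rotation+translation of all coordinates."""
        a, b = _ball([0, 0, 0], 2.0), _ball([15.0, 3.0, 0], 5.0)
        a_sw = _ball([0, 0, 0], 5.0)
        b_sw = _ball([15.0, 3.0, 0], 2.0)
        assert cluster_pair_distance(a, b) == pytest.approx(
            cluster_pair_distance(a_sw, b_sw))
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        shift = np.array([3.0, -8.0, 2.0])
        a2 = _ball(rot @ a.centroid + shift, a.mean_radius)
        b2 = _ball(rot @ b.centroid + shift, b.mean_radius)
        assert cluster_pair_distance(a2, b2) == pytest.approx(
            cluster_pair_distance(a, b))


class TestResampling:
    def test_count_and_sizes_preserved(self, grid_mesh):
        rng = np.random.default_rng(0)
        fmri = [centroid_radius([0, 1, 10], grid_mesh),
                centroid_radius([55, 56], grid_mesh)]
        for _ in range(20):
            sur = resample_clusters(fmri, grid_mesh, rng)
            assert [c.size for c in sur] == [3, 2]
            all_ids = np.concatenate([c.vertex_ids for c in sur])
            assert len(set(all_ids.tolist())) == all_ids.size  # disjoint

    def test_grow_patch_connected(self, grid_mesh):
        rng = np.random.default_rng(1)
        patch = grow_patch(grid_mesh, 45, 12, rng)
        assert patch.size == 12
        sub = grid_mesh.adjacency[np.ix_(patch, patch)]
        from scipy.sparse.csgraph import connected_components
        assert connected_components(sub, directed=False)[0] == 1

    def test_oversized_cluster_raises(self, grid_mesh):
        rng = np.random.default_rng(2)
        big = SurfaceCluster(vertex_ids=np.arange(grid_mesh.n_vertices + 10),
                             centroid=np.zeros(3), mean_radius=1.0)
        with pytest.raises(ValueError):
            resample_clusters([big], grid_mesh, rng)

    def test_significance_deterministic(self, grid_mesh):
        eeg = [centroid_radius([44, 45, 54], grid_mesh)]
        fmri = [centroid_radius([44, 45, 55], grid_mesh),
                centroid_radius([0, 1], grid_mesh)]
        r1 = resample_significance(fmri, eeg, grid_mesh, n_resamples=50, seed=3)
        r2 = resample_significance(fmri, eeg, grid_mesh, n_resamples=50, seed=3)
        assert r1.p_value == r2.p_value
        assert r1.compound == pytest.approx(0.0)  # overlapping pair

    def test_na_propagates(self, grid_mesh):
        res = resample_significance([], [], grid_mesh, n_resamples=10, seed=0)
        assert res.is_na and res.p_value is None


class TestGroupMaps:
    def test_identical_maps(self):
        maps = np.tile(np.arange(5.0), (4, 1))
        np.testing.assert_allclose(group_average(maps), np.arange(5.0))

    def test_map_plus_negation_cancels(self):
        m = np.random.default_rng(0).standard_normal(50)
        np.testing.assert_allclose(group_average([m, -m]), 0.0, atol=1e-15)

    def test_mean_of_normals_shrinks_as_sqrt_n(self):
        rng = np.random.default_rng(1)
        maps = rng.standard_normal((10, 4000))
        sd = group_average(maps).std()
        assert sd == pytest.approx(1 / np.sqrt(10), rel=0.1)

    def test_group_threshold_value(self):
        thr = equivalent_group_threshold(2.3, 10)
        assert thr == pytest.approx(2.3 / np.sqrt(10), rel=1e-12)
        assert equivalent_group_threshold(2.3, 1) == 2.3
        with pytest.raises(ValueError):
            equivalent_group_threshold(2.3, 0)

    def test_confidence_level(self):
        assert round(100 * normal_confidence_level(2.3)) == 99


def test_cluster_table_columns(grid_mesh):
    t = cluster_table([centroid_radius([0, 1], grid_mesh)])
    assert list(t.columns) == ["cluster_id", "size", "centroid_x_mm",
                               "centroid_y_mm", "centroid_z_mm", "radius_mm"]
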