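from dataclasses import replace

import numpy as np
import pytest

import starchseg as ss
from .test_region_metrics import make_record


class TestFcm:
    def test_single_cluster_center_is_weighted_mean(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(7, 3))
        res = ss.fcm(x, x[:1].copy())
        assert (res.memberships == 1).all()
        np.testing.assert_allclose(res.centers[0], x.mean(axis=0), atol=1e-6)

    def test_two_separated_clusters_recovered(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 0.01, size=(5, 2))
        b = rng.normal(0, 0.01, size=(5, 2)) + 10.0
        x = np.vstack([a, b])
        res = ss.fcm(x, np.array([[1.0, 1.0], [9.0, 9.0]]), tol=1e-12, max_iter=500)
        np.testing.assert_allclose(res.centers[0], a.mean(axis=0), atol=1e-6)
        np.testing.assert_allclose(res.centers[1], b.mean(axis=0), atol=1e-6)
        assert (res.memberships[:5, 0] > 0.99).all()
        assert (res.memberships[5:, 1] > 0.99).all()

    def test_long_run_fixed_point_from_multiple_inits(self):
        # independent oracle: the converged centres do not depend on where
        # (reasonably) the centres start
        rng = np.random.default_rng(2)
        a = rng.normal(0, 0.05, size=(5, 2))
        b = rng.normal(0, 0.05, size=(5, 2)) + 8.0
        x = np.vstack([a, b])
        finals = []
        for init in ([[0.5, -0.5], [7.0, 8.5]], [[-1.0, 1.0], [9.0, 7.0]]):
            res = ss.fcm(x, np.array(init, float), tol=1e-13, max_iter=1000)
            finals.append(res.centers)
        np.testing.assert_allclose(finals[0], finals[1], atol=1e-6)

    def test_memberships_row_stochastic(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n, c, p = rng.integers(3, 12), rng.integers(1, 3), rng.integers(1, 4)
            x = rng.normal(size=(n, p))
            res = ss.fcm(x, x[rng.choice(n, size=c, replace=False)].copy())
            np.testing.assert_allclose(res.memberships.sum(axis=1), 1.0, atol=1e-12)

    def test_objective_non_increasing(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            x = rng.normal(size=(rng.integers(4, 15), 2))
            res = ss.fcm(x, x[:2].copy() + rng.normal(0, 0.1, (2, 2)), tol=0.0, max_iter=40)
            tr = res.objective_trace
            assert (np.diff(tr) <= 1e-10).all()

    def test_datum_at_center_gets_crisp_membership(self):
        x = np.array([[0.0, 0.0], [5.0, 5.0], [9.0, 1.0]])
        res = ss.fcm(x, np.array([[0.0, 0.0], [5.0, 5.0]]), max_iter=0)
        assert res.memberships[0, 0] == 1.0
        assert res.memberships[0, 1] == 0.0
        assert res.memberships[1, 1] == 1.0

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(9, 2))
        init = np.array([[0.0, 0.0], [1.0, 1.0]])
        r1 = ss.fcm(x, init.copy(), tol=1e-12, max_iter=500)
        perm = rng.permutation(9)
        r2 = ss.fcm(x[perm], init.copy(), tol=1e-12, max_iter=500)
        np.testing.assert_allclose(r1.centers, r2.centers, atol=1e-8)

    def test_invalid_inputs_rejected(self):
        x = np.zeros((3, 2))
        with pytest.raises(ValueError):
            ss.fcm(x, np.zeros((0, 2)))
        with pytest.raises(ValueError):
            ss.fcm(x, np.zeros((1, 2)), m=1.0)
        with pytest.raises(ValueError):
            ss.fcm(np.zeros((1, 2)), np.zeros((2, 2)))


class TestExtractFeatures:
    def _group(self, members=(1,), cores=(1,), center=(0.0, 0.0)):
        return ss.MergeGroup(1, tuple(members), tuple(cores), center)

    def test_direct_scaling(self):
        rec = replace(make_record(1, 0.9), centroid=(0.0, 10.0))
        rec = replace(rec, mean_intensity=100.0, intensity_variance=16.0)
        feats = ss.extract_features(self._group(), [rec], weights=(0.25, 0.25, 1.0))
        np.testing.assert_allclose(feats[0], [25.0, 4.0, 10.0])

    def test_zero_weights_rejected(self):
        rec = make_record(1, 0.9)
        with pytest.raises(ValueError):
            ss.extract_features(self._group(), [rec], weights=(0.0, 0.25, 1.0))

    def test_symmetric_segments_identical_vectors(self):
        r1 = replace(make_record(1, 0.9), centroid=(0.0, 5.0), mean_intensity=60.0)
        r2 = replace(make_record(2, 0.9), centroid=(0.0, -5.0), mean_intensity=60.0)
        feats = ss.extract_features(self._group((1, 2), (1,)), [r1, r2])
        np.testing.assert_allclose(feats[0], feats[1])

    def test_centroid_coordinate_mode_disambiguates_sides(self):
        r1 = replace(make_record(1, 0.9), centroid=(0.0, 5.0))
        r2 = replace(make_record(2, 0.9), centroid=(0.0, -5.0))
        feats = ss.extract_features(
            self._group((1, 2), (1,)), [r1, r2], use_centroid_coords=True
        )
        assert not np.allclose(feats[0], feats[1])


class TestBuildMergeGroups:
    def test_disjoint_blobs_one_member_each(self, disk_mask):
        m = disk_mask((40, 80), [(20, 20, 10), (20, 60, 10)])
        lab = np.zeros_like(m, int)
        from scipy import ndimage

        lab, _ = ndimage.label(m, structure=np.ones((3, 3)))
        labels = ss.LabelMap(lab)
        img = ss.GrayImage(np.where(m, 60.0, 180.0))
        recs = ss.measure_regions(labels, img)
        groups = ss.build_merge_groups(labels, ss.BinaryMask(m), recs)
        assert len(groups) == 2
        assert all(len(g.member_labels) == 1 for g in groups)

    def test_split_blob_collects_all_members(self, disk_mask):
        m = disk_mask((50, 50), [(25, 25, 15)])
        lab = np.zeros_like(m, int)
        yy, xx = np.mgrid[0:50, 0:50]
        lab[m] = 1
        lab[m & (xx > 25)] = 2
        lab[m & (xx > 32)] = 3
        labels = ss.LabelMap(lab)
        img = ss.GrayImage(np.where(m, 60.0, 180.0))
        recs = ss.measure_regions(labels, img)
        (group,) = ss.build_merge_groups(labels, ss.BinaryMask(m), recs)
        assert set(group.member_labels) == {1, 2, 3}
        assert group.roi_center == pytest.approx((25.0, 25.0), abs=1.0)


class TestMergeOversegments:
    def test_split_disk_merges_back_to_one(self, single_disk_scene):
        scene = single_disk_scene(radius=22, seed=7, size=96)
        lab = (scene.truth_labels.labels > 0).astype(int)
        yy, xx = np.mgrid[0 : lab.shape[0], 0 : lab.shape[1]]
        cx = scene.centers[0][1]
        lab[(lab > 0) & (xx < cx - 8)] = 2  # sliver cap
        result = ss.merge_only(scene.image, ss.LabelMap(lab))
        assert result.n_granules == 1
        assert result.merged_labels.n_segments == 1

    def test_no_oversegments_identity(self, single_disk_scene):
        scene = single_disk_scene(radius=20, seed=8, size=96)
        labels = ss.LabelMap((scene.truth_labels.labels > 0).astype(int))
        result = ss.merge_only(scene.image, labels)
        np.testing.assert_array_equal(result.merged_labels.labels, labels.labels)

    def test_merge_preserves_foreground_support(self, single_disk_scene):
        scene = single_disk_scene(radius=22, seed=9, size=96)
        lab = (scene.truth_labels.labels > 0).astype(int)
        yy, xx = np.mgrid[0 : lab.shape[0], 0 : lab.shape[1]]
        lab[(lab > 0) & (xx < scene.centers[0][1] - 10)] = 2
        result = ss.merge_only(scene.image, ss.LabelMap(lab))
        np.testing.assert_array_equal(result.merged_labels.labels > 0, lab > 0)

    def test_group_without_core_left_unmerged(self, disk_mask, caplog):
        import logging

        m = disk_mask((30, 30), [(15, 15, 8)])
        lab = np.zeros_like(m, int)
        yy, xx = np.mgrid[0:30, 0:30]
        lab[m] = 1
        lab[m & (xx > 15)] = 2
        labels = ss.LabelMap(lab)
        img = ss.GrayImage(np.where(m, 60.0, 180.0))
        recs = ss.measure_regions(labels, img)
        recs = [replace(r, classification=ss.OVERSEGMENT) for r in recs]
        groups = ss.build_merge_groups(labels, ss.BinaryMask(m), recs)
        with caplog.at_level(logging.WARNING, logger="starchseg.fcm_merge"):
            merged = ss.merge_oversegments(labels, groups, recs)
        assert merged.n_segments == 2  # unchanged
        assert any("no core" in r.message for r in caplog.records)
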