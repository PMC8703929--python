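"""Hypothesis generation: frontier clusters, DPlanes, visibility, scoring."""

import math

import numpy as np
import pytest

from nbvscan import (CameraIntrinsics, Label, LabeledCloud, Pose, ScanConfig,
                     count_visible, generate_dplane_hypotheses,
                     generate_frontier_hypotheses, rank_hypotheses,
                     score_hypothesis, update_dplane_overlap)
from nbvscan.hypotheses import DPlane, Hypothesis, Provenance, fit_plane_ransac

from conftest import make_cloud


def frontier_cloud(points, normals):
    n = len(points)
    cloud = LabeledCloud(positions=np.asarray(points, float),
                         normals=np.asarray(normals, float),
                         labels=np.full(n, Label.FRONTIER, dtype=np.uint8),
                         normal_valid=np.ones(n, dtype=bool))
    return cloud


class TestFrontierHypotheses:
    def test_single_frontier_direct_formula(self):
        cloud = frontier_cloud([[0, 0, 0]], [[0, 0, 1]])
        hyps = generate_frontier_hypotheses(cloud, [0], d_rec=650.0, min_c=1)
        assert len(hyps) == 1
        h = hyps[0]
        np.testing.assert_allclose(h.pose.position, [0, 0, 650], atol=1e-9)
        np.testing.assert_allclose(h.pose.view_dir, [0, 0, -1], atol=1e-9)
        assert h.n_h == 1
        assert h.provenance == Provenance.FRONTIER_CLUSTER

    def test_degenerate_reference_axis_fallback(self):
        # normal exactly (0,0,-1): cross([0,0,1], Z) vanishes
        cloud = frontier_cloud([[0, 0, 0]], [[0, 0, -1]])
        hyps = generate_frontier_hypotheses(cloud, [0], d_rec=650.0)
        h = hyps[0]
        np.testing.assert_allclose(h.pose.position, [0, 0, -650], atol=1e-9)
        R = h.pose.rotation
        assert np.allclose(R @ R.T, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(h.pose.view_dir, [0, 0, 1], atol=1e-9)

    def test_invalid_normal_skipped_with_warning(self):
        cloud = frontier_cloud([[0, 0, 0], [5, 0, 0]], [[0, 0, 1], [0, 0, 1]])
        cloud.normal_valid[1] = False
        with pytest.warns(UserWarning, match="invalid"):
            hyps = generate_frontier_hypotheses(cloud, [0, 1], d_rec=650.0)
        assert len(hyps) == 1
        assert hyps[0].n_h == 1

    def test_empty_frontier_list(self):
        cloud = frontier_cloud(np.empty((0, 3)), np.empty((0, 3)))
        assert generate_frontier_hypotheses(cloud, [], 650.0) == []

    def test_two_groups_recover_group_means(self):
        """K-means with 2 clusters separates two spatial groups; centers agree
        with the per-group means computed directly."""
        rng = np.random.default_rng(0)
        a = rng.normal([0, 0, 0], 2.0, (30, 3))
        b = rng.normal([500, 0, 0], 2.0, (30, 3))
        pts = np.vstack([a, b])
        normals = np.tile([0, 0, 1.0], (60, 1))
        cloud = frontier_cloud(pts, normals)
        hyps = generate_frontier_hypotheses(cloud, np.arange(60), d_rec=650.0,
                                            min_c=2, step_c=1000, seed=0)
        assert len(hyps) == 2
        assert sorted(h.n_h for h in hyps) == [30, 30]
        got = sorted(h.pose.position[0] for h in hyps)
        expect = sorted([a[:, 0].mean(), b[:, 0].mean()])
        np.testing.assert_allclose(got, expect, atol=1.0)
        for h in hyps:
            # view axis opposes the (shared) frontier normal
            assert h.pose.view_dir @ [0, 0, 1] < -0.99

    def test_cluster_count_capped_by_frontier_count(self):
        cloud = frontier_cloud([[0, 0, 0], [3, 0, 0]], [[0, 0, 1], [0, 0, 1]])
        hyps = generate_frontier_hypotheses(cloud, [0, 1], 650.0, min_c=10)
        assert len(hyps) <= 2


class TestDPlanes:
    def _state(self, pts, recording_index=0):
        n = len(pts)
        return LabeledCloud(positions=np.asarray(pts, float),
                            recording_index=np.full(n, recording_index, np.int32))

    def test_collinear_cluster_discarded(self):
        cfg = ScanConfig()
        pts = np.column_stack([np.linspace(0, 30, 12), np.zeros(12), np.zeros(12)])
        state = self._state(pts)
        pix = np.column_stack([np.zeros(12, int), np.arange(12)])
        hyps, planes = generate_dplane_hypotheses(
            state, pix, np.arange(12), Pose.looking_at((0, 0, 650), (0, 0, 0)),
            cfg, [], current_recording=0)
        assert planes == [] and hyps == []

    def _rim_fixture(self, cfg, view_from):
        """A planar square rim of edge points in the plane x = 0."""
        ys = np.linspace(-20, 20, 12)
        zs = np.linspace(-20, 20, 12)
        ring = [(y, z) for y in ys for z in (zs[0], zs[-1])] + \
               [(y, z) for y in (ys[0], ys[-1]) for z in zs[1:-1]]
        pts = np.array([[0.0, y, z] for (y, z) in ring])
        state = self._state(pts)
        pix = np.column_stack([np.arange(len(pts)) // 8, np.arange(len(pts)) % 8])
        pose = Pose.looking_at(view_from, (0, 0, 0))
        return generate_dplane_hypotheses(state, pix, np.arange(len(pts)),
                                          pose, cfg, [], 0)

    def test_oblique_view_orients_normal_toward_camera(self):
        cfg = ScanConfig()
        hyps, planes = self._rim_fixture(cfg, view_from=(500, 0, 400))
        assert len(planes) == 1
        dp = planes[0]
        np.testing.assert_allclose(np.abs(dp.normal), [1, 0, 0], atol=1e-6)
        # normal faces the camera: opposite hemisphere to the view direction
        view_dir = Pose.looking_at((500, 0, 400), (0, 0, 0)).view_dir
        assert dp.normal @ view_dir < 0
        assert len(hyps) == 1
        np.testing.assert_allclose(hyps[0].pose.position,
                                   dp.center + cfg.d_rec * dp.normal, atol=1e-6)
        np.testing.assert_allclose(hyps[0].pose.view_dir, -dp.normal, atol=1e-9)

    def test_perpendicular_band_duplicates_plane(self):
        cfg = ScanConfig()
        # view direction ~86 deg to the plane normal (within the 80-90 band)
        hyps, planes = self._rim_fixture(cfg, view_from=(45, 0, 650))
        assert len(planes) == 2
        n0, n1 = planes[0].normal, planes[1].normal
        np.testing.assert_allclose(n0, -n1, atol=1e-12)
        assert len(hyps) == 2

    def test_plane_fit_residual_within_consensus(self):
        rng = np.random.default_rng(4)
        pts = np.column_stack([rng.uniform(-10, 10, 60), rng.uniform(-10, 10, 60),
                               rng.normal(0, 0.3, 60)])
        centroid, normal, inliers = fit_plane_ransac(pts, 2.0, 500,
                                                     np.random.default_rng(0))
        assert inliers.mean() > 0.9
        assert abs(normal[2]) > 0.99
        res = np.abs((pts[inliers] - centroid) @ normal)
        assert res.max() < 2.0 + 0.3


class TestOverlapUpdate:
    def _dplane(self, edge_idx, n_edges):
        return DPlane(center=np.zeros(3), normal=np.array([0, 0, 1.0]),
                      edge_points=np.asarray(edge_idx),
                      overlap_flags=np.zeros(n_edges, dtype=bool))

    def test_no_qualifying_points_leaves_overlap(self):
        cloud = make_cloud([[0, 0, 0], [100, 0, 0]])
        dp = self._dplane([0], 1)
        update_dplane_overlap(dp, cloud, 2.0, lambda idx: np.zeros(len(idx), bool))
        assert dp.overlap == 0 and not dp.overlap_flags.any()

    def test_all_edges_flagged(self):
        cloud = make_cloud([[0, 0, 0], [1, 0, 0], [0.5, 0, 0]])
        dp = self._dplane([0, 1], 2)
        update_dplane_overlap(dp, cloud, 2.0,
                              lambda idx: np.isin(idx, [2]))
        assert dp.overlap == 2 and dp.overlap_flags.all()

    def test_idempotent_for_fixed_cloud(self):
        cloud = make_cloud([[0, 0, 0], [1, 0, 0], [0.5, 0, 0]])
        dp = self._dplane([0, 1], 2)
        pred = lambda idx: np.isin(idx, [2])
        update_dplane_overlap(dp, cloud, 2.0, pred)
        once = (dp.overlap, dp.overlap_flags.copy())
        update_dplane_overlap(dp, cloud, 2.0, pred)
        assert dp.overlap == once[0]
        np.testing.assert_array_equal(dp.overlap_flags, once[1])


class TestVisibilityAndScore:
    def _hyp(self, position, target):
        return Hypothesis(pose=Pose.looking_at(position, target),
                          provenance=Provenance.FRONTIER_CLUSTER)

    def test_single_frontier_ahead(self):
        intr = CameraIntrinsics()
        cloud = frontier_cloud([[0, 0, 0]], [[0, 0, 1]])
        h = self._hyp((0, 0, 650), (0, 0, 0))
        assert count_visible(h, cloud, [0], [], intr, 0.5) == 1

    def test_frontier_behind_camera(self):
        intr = CameraIntrinsics()
        cloud = frontier_cloud([[0, 0, 1300]], [[0, 0, 1]])
        h = self._hyp((0, 0, 650), (0, 0, 0))
        assert count_visible(h, cloud, [0], [], intr, 0.5) == 0

    def test_dplane_adds_edge_point_total(self):
        intr = CameraIntrinsics()
        pts = [[0, 0, 0], [1, 0, 0], [2, 0, 0]]
        cloud = frontier_cloud(pts, [[0, 0, 1]] * 3)
        dp = DPlane(center=np.array([0, 0, 0.0]), normal=np.array([0, 0, 1.0]),
                    edge_points=np.arange(12), overlap_flags=np.zeros(12, bool))
        h = self._hyp((0, 0, 650), (0, 0, 0))
        assert count_visible(h, cloud, [0, 1, 2], [dp], intr, 0.5) == 15

    def test_visibility_cone_excludes_side_facing(self):
        intr = CameraIntrinsics()
        cloud = frontier_cloud([[0, 0, 0]], [[1, 0, 0]])   # normal _|_ view
        h = self._hyp((0, 0, 650), (0, 0, 0))
        assert count_visible(h, cloud, [0], [], intr, 0.5) == 0

    def test_brute_force_visibility_oracle(self):
        """count_visible equals an explicit loop over deficiencies."""
        from nbvscan.geometry import in_frustum
        rng = np.random.default_rng(12)
        intr = CameraIntrinsics()
        for _ in range(10):
            n = 40
            pts = rng.uniform(-120, 120, (n, 3))
            normals = rng.normal(size=(n, 3))
            normals /= np.linalg.norm(normals, axis=1, keepdims=True)
            cloud = frontier_cloud(pts, normals)
            dplanes = []
            for _ in range(3):
                k = rng.integers(3, 9)
                dplanes.append(DPlane(center=rng.uniform(-120, 120, 3),
                                      normal=normals[rng.integers(n)],
                                      edge_points=np.arange(k),
                                      overlap_flags=np.zeros(k, bool)))
            h = self._hyp(rng.uniform(-100, 100, 3) + [0, 0, 700], (0, 0, 0))
            z = h.pose.view_dir
            expect = sum(1 for i in range(n)
                         if in_frustum(pts[i], h.pose, intr)
                         and normals[i] @ z <= -0.5)
            expect += sum(len(dp.edge_points) for dp in dplanes
                          if in_frustum(dp.center, h.pose, intr)
                          and dp.normal @ z <= -0.5)
            assert count_visible(h, cloud, np.arange(n), dplanes, intr, 0.5) == expect

    def test_score_reference_values(self):
        cfg = ScanConfig()
        prev = Pose.identity()
        h = Hypothesis(pose=Pose.identity(), provenance=Provenance.DPLANE,
                       n_h=0, n_v=0)
        assert score_hypothesis(h, prev, cfg) == pytest.approx(100.0)
        h2 = Hypothesis(pose=Pose.looking_at((3000.0, 0, 0), (3000.0, 0, 650)),
                        provenance=Provenance.DPLANE, n_h=5, n_v=10)
        assert score_hypothesis(h2, prev, cfg) == pytest.approx(
            0.8 * 10 + 100 * math.exp(-6.0) + 0.2 * 5, rel=1e-12)

    def test_score_monotonicity_random_triples(self):
        cfg = ScanConfig()
        prev = Pose.identity()
        rng = np.random.default_rng(77)
        def s(nv, nh, d_mm):
            h = Hypothesis(pose=Pose.looking_at((d_mm, 0, 0), (d_mm, 0, 650)),
                           provenance=Provenance.DPLANE, n_h=nh, n_v=nv)
            return score_hypothesis(h, prev, cfg)
        for _ in range(1000):
            nv = int(rng.integers(0, 100))
            nh = int(rng.integers(0, 100))
            d = float(rng.uniform(0, 2000))
            base = s(nv, nh, d)
            assert s(nv + 1, nh, d) > base
            assert s(nv, nh + 1, d) > base
            assert s(nv, nh, d + 10) < base


class TestRanking:
    def _h(self, score, prov=Provenance.FRONTIER_CLUSTER, n_h=0):
        h = Hypothesis(pose=Pose.identity(), provenance=prov, n_h=n_h)
        h.score = score
        return h

    def test_descending_scores(self):
        out = rank_hypotheses([self._h(5), self._h(9), self._h(1)])
        assert [h.score for h in out] == [9, 5, 1]

    def test_tie_break_provenance_size_insertion(self):
        a = self._h(5, Provenance.DPLANE, n_h=10)
        b = self._h(5, Provenance.FRONTIER_CLUSTER, n_h=2)
        c = self._h(5, Provenance.FRONTIER_CLUSTER, n_h=7)
        d = self._h(5, Provenance.FRONTIER_CLUSTER, n_h=7)
        out = rank_hypotheses([a, b, c, d])
        assert out == [c, d, b, a]

    def test_empty(self):
        assert rank_hypotheses([]) == []
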