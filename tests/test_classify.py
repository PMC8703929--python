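"""Edge detection and core/outlier/frontier classification vs brute-force oracles."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from nbvscan import (CameraIntrinsics, DepthImage, Label, LabeledCloud, Pose,
                     classify_points, define_roi, detect_edge_points)
from nbvscan.scene import backproject, render_depth

from conftest import make_cloud


def edge_oracle(values: np.ndarray, pixels: np.ndarray, d_thr: float) -> set:
    """Literal per-pixel 8-neighborhood scan (independent of the vectorized path)."""
    h, w = values.shape
    out = set()
    for r, c in pixels:
        d = values[r, c]
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and abs(d - values[rr, cc]) > d_thr:
                    out.add((r, c))
    return out


def classify_oracle(positions: np.ndarray, labels: np.ndarray,
                    new_idx: np.ndarray, r: float, n_thr: int) -> np.ndarray:
    """O(n^2) re-implementation of the density classification step."""
    labels = labels.copy()
    labels[labels == Label.FRONTIER] = Label.CORE
    D = cdist(positions, positions)
    counts = (D <= r).sum(axis=1) - 1
    candidates = set(new_idx.tolist()) | set(np.flatnonzero(labels == Label.OUTLIER).tolist())
    for p in candidates:
        labels[p] = Label.CORE if counts[p] > n_thr else Label.OUTLIER
    for o in np.flatnonzero(labels == Label.OUTLIER):
        for q in np.flatnonzero((D[o] <= r) & (labels == Label.CORE)):
            labels[q] = Label.FRONTIER
    return labels


class TestDetectEdgePoints:
    def _image(self, values):
        values = np.asarray(values, dtype=float)
        h, w = values.shape
        intr = CameraIntrinsics(width=w, height=h, fx=100, fy=100,
                                cx=w / 2 - 0.5, cy=h / 2 - 0.5,
                                near=1.0, far=10000.0)
        return DepthImage(values=values, intrinsics=intr, pose=Pose.identity())

    def test_constant_image_no_edges(self):
        img = self._image(np.full((8, 8), 500.0))
        pix = np.argwhere(img.values > 0)
        assert len(detect_edge_points(img, pix, 15.0)) == 0

    def test_two_half_planes_step(self):
        values = np.full((10, 12), 100.0)
        values[:, 6:] = 120.0
        img = self._image(values)
        pix = np.argwhere(values > 0)
        got = detect_edge_points(img, pix, 15.0)
        # exactly the two pixel columns flanking the step, on both sides
        assert {tuple(p) for p in got} == {(r, c) for r in range(10) for c in (5, 6)}

    def test_step_below_threshold_ignored(self):
        values = np.full((10, 12), 100.0)
        values[:, 6:] = 110.0
        img = self._image(values)
        pix = np.argwhere(values > 0)
        assert len(detect_edge_points(img, pix, 15.0)) == 0

    def test_invalid_neighbor_counts_as_discontinuity(self):
        values = np.full((6, 6), 500.0)
        values[2, 3] = 0.0
        img = self._image(values)
        pix = np.argwhere(values > 0)
        got = {tuple(p) for p in detect_edge_points(img, pix, 15.0)}
        assert got == {(r, c) for r in (1, 2, 3) for c in (2, 3, 4)} - {(2, 3)}

    def test_row_major_output_order(self):
        rng = np.random.default_rng(0)
        values = rng.uniform(100, 200, (16, 16))
        img = self._image(values)
        pix = np.argwhere(values > 0)
        got = detect_edge_points(img, pix, 30.0)
        assert (np.lexsort((got[:, 1], got[:, 0])) == np.arange(len(got))).all()

    def test_oracle_equivalence_random_images(self):
        """Exact agreement with the brute-force oracle on random depth images."""
        rng = np.random.default_rng(42)
        for _ in range(10):
            values = rng.uniform(50, 120, (64, 64))
            values[rng.random((64, 64)) < 0.05] = 0.0
            img = self._image(values)
            pix = np.argwhere(values > 0)
            sel = pix[rng.random(len(pix)) < 0.7]
            got = {tuple(p) for p in detect_edge_points(img, sel, 15.0)}
            assert got == edge_oracle(values, sel, 15.0)


class TestClassifyPoints:
    def test_isolated_point_is_outlier(self):
        cloud = make_cloud([[0, 0, 0]])
        classify_points(cloud, [0], r=2.0, n_thr=60)
        assert cloud.labels[0] == Label.OUTLIER

    def test_dense_disk_core_rim_outlier_frontier_ring(self):
        # 0.35 mm grid disk: interior points have ~100 neighbors in r=2;
        # rim points see roughly a half neighborhood (~50 < 60) -> outliers
        xs = np.arange(-10, 10.001, 0.35)
        gx, gy = np.meshgrid(xs, xs)
        m = gx ** 2 + gy ** 2 <= 10.0 ** 2
        pts = np.column_stack([gx[m], gy[m], np.zeros(m.sum())])
        cloud = make_cloud(pts)
        idx = np.arange(len(pts))
        classify_points(cloud, idx, r=2.0, n_thr=60)
        expect = classify_oracle(pts, np.full(len(pts), Label.UNLABELED, dtype=np.uint8),
                                 idx, 2.0, 60)
        np.testing.assert_array_equal(cloud.labels, expect)
        # deep interior is core; the rim ring is outlier with a frontier
        # band of cores just inside it (within r of an outlier)
        r = np.linalg.norm(pts[:, :2], axis=1)
        assert (cloud.labels[r < 6.5] == Label.CORE).all()
        assert (cloud.labels == Label.OUTLIER).any()
        assert (cloud.labels == Label.FRONTIER).any()

    def test_outlier_promoted_by_second_recording(self):
        rng = np.random.default_rng(5)
        sparse = rng.uniform(-2, 2, (20, 3)) * [1, 1, 0.01]
        cloud = make_cloud(sparse)
        classify_points(cloud, np.arange(20), r=2.0, n_thr=60)
        assert (cloud.labels == Label.OUTLIER).all()
        dense = rng.uniform(-2, 2, (400, 3)) * [1, 1, 0.01]
        extra = LabeledCloud(positions=dense)
        off = cloud.append(extra)
        new_idx = np.arange(off, len(cloud))
        classify_points(cloud, new_idx, r=2.0, n_thr=60)
        expect = classify_oracle(cloud.positions,
                                 np.concatenate([np.full(20, Label.OUTLIER),
                                                 np.full(400, Label.UNLABELED)]).astype(np.uint8),
                                 new_idx, 2.0, 60)
        np.testing.assert_array_equal(cloud.labels, expect)
        # the original sparse points now have plenty of neighbors
        assert (cloud.labels[:20] != Label.OUTLIER).all()

    def test_partition_and_monotonicity_random_two_cycle(self):
        """Random two-cycle scenario: oracle equality, label partition, and
        no core point demoted by new data."""
        rng = np.random.default_rng(9)
        a = rng.uniform(0, 12, (600, 3)) * [1, 1, 0.05]
        cloud = make_cloud(a)
        classify_points(cloud, np.arange(len(a)), r=1.5, n_thr=20)
        core_before = set(np.flatnonzero(cloud.labels == Label.CORE)) | \
            set(np.flatnonzero(cloud.labels == Label.FRONTIER))
        labels_snapshot = cloud.labels.copy()
        b = rng.uniform(0, 12, (600, 3)) * [1, 1, 0.05]
        off = cloud.append(LabeledCloud(positions=b))
        new_idx = np.arange(off, len(cloud))
        classify_points(cloud, new_idx, r=1.5, n_thr=20)
        expect = classify_oracle(cloud.positions,
                                 np.concatenate([labels_snapshot,
                                                 np.full(600, Label.UNLABELED)]).astype(np.uint8),
                                 new_idx, 1.5, 20)
        np.testing.assert_array_equal(cloud.labels, expect)
        # partition: every point has exactly one label; E untouched here
        assert set(np.unique(cloud.labels)) <= {Label.CORE, Label.OUTLIER,
                                                Label.FRONTIER, Label.UNLABELED}
        # monotonicity: nothing that was core (or frontier, i.e. core at
        # cycle start) fell back to outlier
        after = cloud.labels[sorted(core_before)]
        assert not np.any(after == Label.OUTLIER)

    def test_edge_points_rejected_from_candidates(self):
        cloud = make_cloud([[0, 0, 0], [1, 0, 0]])
        cloud.labels[1] = Label.EDGE
        with pytest.raises(ValueError, match="edge"):
            classify_points(cloud, [0, 1], r=2.0, n_thr=5)


class TestDefineRoi:
    def _patch_image(self):
        intr = CameraIntrinsics(width=100, height=80, fx=500, fy=500,
                                cx=49.5, cy=39.5, near=100, far=2000)
        import trimesh
        v = [[-50, -50, 650], [50, -50, 650], [50, 50, 650], [-50, 50, 650]]
        mesh = trimesh.Trimesh(vertices=v, faces=[[0, 1, 2], [0, 2, 3]],
                               process=False)
        return render_depth(mesh, Pose.identity(), intr), intr

    def test_planar_patch_extent(self):
        img, intr = self._patch_image()
        rect = (15, 15, 75, 55)  # interior pixel rect, fully on the patch
        box = define_roi(img, rect, inflation=0.10)
        w_mm = (rect[2] - rect[0]) * 650.0 / intr.fx
        h_mm = (rect[3] - rect[1]) * 650.0 / intr.fy
        ext = np.sort(2 * box.half_extents)[::-1]
        assert ext[0] == pytest.approx(1.1 * w_mm, rel=0.02)
        assert ext[1] == pytest.approx(1.1 * h_mm, rel=0.02)

    def test_containment_without_inflation(self):
        img, _ = self._patch_image()
        box = define_roi(img, (20, 20, 60, 60), inflation=0.0)
        cloud = backproject(img)
        rows, cols = cloud.pixel_index[:, 0], cloud.pixel_index[:, 1]
        inside = (cols >= 20) & (cols <= 60) & (rows >= 20) & (rows <= 60)
        assert box.contains(cloud.positions[inside]).all()

    def test_empty_roi_raises(self):
        intr = CameraIntrinsics(width=40, height=30, fx=100, fy=100,
                                cx=19.5, cy=14.5, near=10, far=100)
        img = DepthImage(values=np.zeros((30, 40)), intrinsics=intr,
                         pose=Pose.identity())
        with pytest.raises(ValueError, match="ROI"):
            define_roi(img, (0, 0, 10, 10))
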