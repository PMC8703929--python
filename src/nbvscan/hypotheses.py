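"""Candidate recording poses from surface deficiencies.

Two generators feed one ranked hypothesis list:

* **frontier clusters** — every frontier point proposes a sub-pose at the
  recording distance along its normal, looking back at the point; the
  7-D (position, quaternion) features are k-means clustered and each
  cluster center becomes a hypothesis whose size ``N_h`` is the member
  count;
* **discontinuity planes (DPlanes)** — edge pixels of the current depth
  image are k-means clustered in 2D; each sufficiently planar cluster is
  fitted with a sample-consensus plane bounding the unseen surface behind
  the discontinuity.  DPlanes persist across cycles until the hidden
  surface is actually scanned (their edge points overlap newer surface),
  and each live DPlane proposes a hypothesis along its oriented normal.

Hypotheses are scored by

    score = alpha * N_v + beta * exp(-2 d) + gamma * N_h

with ``N_v`` the number of deficiencies visible from the pose (frontier
points count 1, a visible DPlane counts its edge points), ``d`` the
distance to the previous recording position *in meters*, and ``N_h`` the
hypothesis size.  With millimeter distances the exp term would be
identically zero for any realistic motion; meters make the beta = 100
weight meaningfully reward nearby poses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.spatial import cKDTree
from sklearn.cluster import KMeans

from .config import ScanConfig
from .geometry import (CameraIntrinsics, LabeledCloud, Pose,
                       in_frustum_mask)


class Provenance(str, Enum):
    FRONTIER_CLUSTER = "frontier_cluster"
    DPLANE = "dplane"
    SPHERE_FALLBACK = "sphere_fallback"


# tie-break order: frontier-cluster hypotheses first
_PROVENANCE_RANK = {Provenance.FRONTIER_CLUSTER: 0, Provenance.DPLANE: 1,
                    Provenance.SPHERE_FALLBACK: 2}


@dataclass
class Hypothesis:
    pose: Pose
    provenance: Provenance
    n_h: int = 0
    focus: np.ndarray | None = None   # surface point the pose looks at
    n_v: int = 0
    score: float = float("nan")

    def to_dict(self) -> dict:
        return {"position": self.pose.position.tolist(),
                "quaternion_wxyz": self.pose.quaternion.tolist(),
                "provenance": self.provenance.value,
                "n_h": int(self.n_h), "n_v": int(self.n_v),
                "score": float(self.score)}


@dataclass
class DPlane:
    """Bounded discontinuity plane with its generating edge points."""

    center: np.ndarray
    normal: np.ndarray                  # unit, oriented
    edge_points: np.ndarray             # indices into the global cloud
    overlap_flags: np.ndarray           # per edge point
    overlap: int = 0
    source_recording: int = 0
    fit_stats: dict = field(default_factory=dict)

    @property
    def overlap_fraction(self) -> float:
        return self.overlap / max(len(self.edge_points), 1)

    def duplicate_flipped(self) -> "DPlane":
        return DPlane(center=self.center.copy(), normal=-self.normal,
                      edge_points=self.edge_points.copy(),
                      overlap_flags=self.overlap_flags.copy(),
                      overlap=self.overlap,
                      source_recording=self.source_recording,
                      fit_stats=dict(self.fit_stats))

    def to_dict(self) -> dict:
        return {"center": self.center.tolist(), "normal": self.normal.tolist(),
                "n_edge_points": int(len(self.edge_points)),
                "overlap": int(self.overlap),
                "source_recording": int(self.source_recording)}


def _view_pose(position: np.ndarray, z_axis: np.ndarray) -> Pose:
    """Pose with the given view axis; X = cross([0,0,1], Z) with a fallback
    reference axis when the view axis is (anti)parallel to +Z."""
    z = z_axis / np.linalg.norm(z_axis)
    x = np.cross([0.0, 0.0, 1.0], z)
    if np.linalg.norm(x) < 1e-9:
        x = np.cross([0.0, 1.0, 0.0], z)
    x = x / np.linalg.norm(x)
    y = np.cross(z, x)
    return Pose(position, np.column_stack([x, y, z]))


def _n_clusters(count: int, min_c: int, step_c: int) -> int:
    return min(count, min_c + count // step_c)


def generate_frontier_hypotheses(cloud: LabeledCloud, frontier_idx,
                                 d_rec: float, min_c: int = 1,
                                 step_c: int = 100, seed: int = 0
                                 ) -> list[Hypothesis]:
    """Cluster per-frontier-point sub-poses into recording hypotheses.

    Positions are divided by ``d_rec`` before clustering so the position
    and quaternion parts of the 7-D feature are both O(1); quaternions are
    canonicalized to w >= 0 so the double cover cannot split a cluster.
    """
    frontier_idx = np.asarray(frontier_idx, dtype=np.int64).reshape(-1)
    valid = cloud.normal_valid[frontier_idx]
    if not valid.all():
        warnings.warn(f"skipping {int((~valid).sum())} frontier point(s) "
                      "with invalid normals")
        frontier_idx = frontier_idx[valid]
    if len(frontier_idx) == 0:
        return []
    p = cloud.positions[frontier_idx]
    n = cloud.normals[frontier_idx]
    positions = p + d_rec * n
    feats = np.empty((len(frontier_idx), 7))
    feats[:, :3] = positions / d_rec
    for k in range(len(frontier_idx)):
        feats[k, 3:] = _view_pose(positions[k], -n[k]).quaternion
    no_c = _n_clusters(len(feats), min_c, step_c)
    if no_c == 1:
        labels = np.zeros(len(feats), dtype=int)
        centers = feats.mean(axis=0, keepdims=True)
    else:
        km = KMeans(n_clusters=no_c, random_state=seed, n_init=10)
        labels = km.fit_predict(feats)
        centers = km.cluster_centers_
    out: list[Hypothesis] = []
    for c in range(len(centers)):
        members = int(np.sum(labels == c))
        if members == 0:
            continue
        pos = centers[c, :3] * d_rec
        quat = centers[c, 3:]
        quat = quat / np.linalg.norm(quat)
        pose = Pose.from_quaternion(pos, quat)
        out.append(Hypothesis(pose=pose, provenance=Provenance.FRONTIER_CLUSTER,
                              n_h=members, focus=pos + d_rec * pose.view_dir))
    return out


# ---------------------------------------------------------------------------
# DPlanes
# ---------------------------------------------------------------------------

def fit_plane_ransac(points: np.ndarray, inlier_dist: float, iters: int,
                     rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample-consensus plane fit; returns (centroid, unit normal, inlier mask)."""
    n = len(points)
    if n < 3:
        raise ValueError("need >= 3 points to fit a plane")
    best_mask = None
    best_count = -1
    for _ in range(iters):
        sel = rng.choice(n, size=3, replace=False)
        a, b, c = points[sel]
        nrm = np.cross(b - a, c - a)
        ln = np.linalg.norm(nrm)
        if ln < 1e-12:
            continue
        nrm = nrm / ln
        mask = np.abs((points - a) @ nrm) <= inlier_dist
        cnt = int(mask.sum())
        if cnt > best_count:
            best_count, best_mask = cnt, mask
    if best_mask is None:
        raise ValueError("degenerate point set: no plane found")
    inl = points[best_mask]
    centroid = inl.mean(axis=0)
    _, _, Vt = np.linalg.svd(inl - centroid)
    normal = Vt[2] / np.linalg.norm(Vt[2])
    return centroid, normal, best_mask


def update_dplane_overlap(dplane: DPlane, cloud: LabeledCloud, r: float,
                          idx_predicate) -> DPlane:
    """Flag edge points that have a qualifying cloud point within radius r.

    ``idx_predicate(indices) -> bool mask`` selects which recordings'
    points count.  Flagged edge points are never re-examined, so repeated
    calls only grow the overlap (idempotent for a fixed cloud).
    """
    todo = np.flatnonzero(~dplane.overlap_flags)
    if len(todo) == 0 or len(cloud) == 0:
        return dplane
    tree = cKDTree(cloud.positions)
    hits = tree.query_ball_point(cloud.positions[dplane.edge_points[todo]], r)
    for e, idx in zip(todo, hits):
        idx = np.asarray(idx, dtype=np.int64)
        if len(idx) and np.any(idx_predicate(idx)):
            dplane.overlap_flags[e] = True
            dplane.overlap += 1
    return dplane


def generate_dplane_hypotheses(state: LabeledCloud, edge_pixels: np.ndarray,
                               edge_cloud_idx: np.ndarray, current_pose: Pose,
                               cfg: ScanConfig, dplanes: list[DPlane],
                               current_recording: int) -> tuple[list[Hypothesis], list[DPlane]]:
    """DPlane lifecycle for one cycle, then hypotheses from all live DPlanes.

    Steps: (1) re-check stored DPlanes against the new recording and drop
    those whose overlap fraction reaches ``o_thr`` — an edge point counts
    as overlapped only when *new surface* (current-recording points that do
    not re-sample previously recorded surface) appears within radius ``r``
    of it, i.e. when the deficiency the plane bounds has actually been
    scanned; (2) cluster the current image's edge pixels
    in 2D, discard line-like clusters by eigenvalue ratio, fit consensus
    planes, discard new DPlanes defined over previously scanned surface,
    orient normals toward the camera hemisphere — duplicating the plane
    when the normal is within the undecidable 80-90 degree band to the view
    direction; (3) every surviving DPlane yields one hypothesis at
    ``center + d_rec * normal`` viewing along ``-normal``.
    """
    rng = np.random.default_rng(cfg.seed + 104729 + current_recording)
    rec = state.recording_index

    # A DPlane bounds *unscanned* surface, so an old plane is only retired
    # by the presence of new-surface samples near its edge points: points of
    # the current recording that do not merely re-sample surface already
    # present in earlier recordings.  A bare re-view therefore leaves the
    # plane standing (its hidden surface is still hidden).
    prior_mask = rec < current_recording
    new_surface = np.zeros(len(state), dtype=bool)
    cur_idx = np.flatnonzero(rec == current_recording)
    if len(cur_idx):
        if prior_mask.any():
            prior_tree = cKDTree(state.positions[prior_mask])
            d_prior, _ = prior_tree.query(state.positions[cur_idx])
            new_surface[cur_idx] = d_prior > cfg.r / 2.0
        else:
            new_surface[cur_idx] = True

    # (1) old DPlanes vs the new recording
    survivors: list[DPlane] = []
    for dp in dplanes:
        update_dplane_overlap(dp, state, cfg.r, lambda idx: new_surface[idx])
        if dp.overlap_fraction < cfg.o_thr:
            survivors.append(dp)

    # (2) new DPlanes from the current image's edge pixels
    edge_pixels = np.asarray(edge_pixels, dtype=float).reshape(-1, 2)
    edge_cloud_idx = np.asarray(edge_cloud_idx, dtype=np.int64).reshape(-1)
    if len(edge_pixels) >= 3:
        feats = edge_pixels[:, ::-1].copy()      # (x, y) = (col, row)
        no_c = _n_clusters(len(feats), cfg.min_c_edge, cfg.step_c_edge)
        if no_c == 1:
            labels = np.zeros(len(feats), dtype=int)
        else:
            labels = KMeans(n_clusters=no_c, random_state=cfg.seed,
                            n_init=10).fit_predict(feats)
        view_dir = current_pose.view_dir
        v_thr = np.cos(np.radians(cfg.perp_band_deg[0]))
        for c in range(labels.max() + 1):
            members = np.flatnonzero(labels == c)
            if len(members) < 3:
                continue
            pts = state.positions[edge_cloud_idx[members]]
            mu = pts.mean(axis=0)
            cov = np.cov((pts - mu).T, bias=True)
            evals = np.sort(np.linalg.eigvalsh(cov))[::-1]
            if evals[0] > cfg.e_thr * max(evals[1], 1e-12):
                continue                         # line-like cluster
            try:
                centroid, normal, _ = fit_plane_ransac(
                    pts, cfg.ransac_inlier_dist, cfg.ransac_iters, rng)
            except ValueError:
                continue
            dp = DPlane(center=centroid, normal=normal,
                        edge_points=edge_cloud_idx[members],
                        overlap_flags=np.zeros(len(members), dtype=bool),
                        source_recording=current_recording,
                        fit_stats={"mean": mu.tolist(),
                                   "eigenvalues": evals.tolist()})
            # discard new DPlanes detected over previously recorded surface
            # (self-occlusion of a region some earlier view already scanned)
            update_dplane_overlap(dp, state, cfg.r,
                                  lambda idx: prior_mask[idx])
            if dp.overlap_fraction >= cfg.o_thr:
                continue
            dot_res = float(view_dir @ dp.normal)
            if abs(dot_res) > v_thr:
                if dot_res > 0:                  # face the camera
                    dp.normal = -dp.normal
                survivors.append(dp)
            else:                                # undecidable: keep both
                survivors.append(dp)
                survivors.append(dp.duplicate_flipped())

    # (3) hypotheses from every live DPlane
    hyps = [Hypothesis(pose=_view_pose(dp.center + cfg.d_rec * dp.normal, -dp.normal),
                       provenance=Provenance.DPLANE, n_h=len(dp.edge_points),
                       focus=dp.center.copy())
            for dp in survivors]
    return hyps, survivors


# ---------------------------------------------------------------------------
# visibility, scoring, ranking
# ---------------------------------------------------------------------------

def count_visible(h: Hypothesis, cloud: LabeledCloud, frontier_idx,
                  dplanes: list[DPlane], intr: CameraIntrinsics,
                  vis_cos_max: float) -> int:
    """Deficiencies visible from the hypothesis pose.

    A frontier point counts 1 when it is inside the view frustum and its
    normal faces the camera within the visibility cone
    (dot(n, Z) <= -vis_cos_max); a DPlane counts its full edge-point total
    when its center passes the same two checks.
    """
    frontier_idx = np.asarray(frontier_idx, dtype=np.int64).reshape(-1)
    z = h.pose.view_dir
    n_v = 0
    if len(frontier_idx):
        vis = in_frustum_mask(cloud.positions[frontier_idx], h.pose, intr)
        facing = cloud.normals[frontier_idx] @ z <= -vis_cos_max
        n_v += int(np.sum(vis & facing & cloud.normal_valid[frontier_idx]))
    for dp in dplanes:
        if (in_frustum_mask(dp.center[None, :], h.pose, intr)[0]
                and float(dp.normal @ z) <= -vis_cos_max):
            n_v += len(dp.edge_points)
    return n_v


def score_hypothesis(h: Hypothesis, prev_pose: Pose, cfg: ScanConfig) -> float:
    """score = alpha * N_v + beta * exp(-2 d[m]) + gamma * N_h (d in meters)."""
    d_m = float(np.linalg.norm(h.pose.position - prev_pose.position)) / 1000.0
    h.score = cfg.alpha * h.n_v + cfg.beta * np.exp(-2.0 * d_m) + cfg.gamma * h.n_h
    return h.score


def rank_hypotheses(hyps: list[Hypothesis]) -> list[Hypothesis]:
    """Stable descending sort by score; ties broken by provenance
    (frontier clusters first), then larger size, then insertion order."""
    return [h for _, h in sorted(
        enumerate(hyps),
        key=lambda t: (-t[1].score, _PROVENANCE_RANK[t[1].provenance],
                       -t[1].n_h, t[0]))]
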