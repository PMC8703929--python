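"""Recording-loop orchestration and next-pose selection.

The loop mirrors the six recording stages: detect the wound region, move
to the pose and record, align all recordings, classify surface
deficiencies, generate and score hypotheses, and pick the next reachable
pose.  It stops when no hypothesis remains (full reconstruction), when no
hypothesis or nearby fallback pose is reachable, or when the cycle budget
is exhausted; the final model is the 1 mm voxel-filtered global cloud.

Robot kinematics are abstracted behind a pure reachability predicate; the
analytic default accepts poses inside a spherical shell around the robot
base whose view axis stays within a cone of the toward-patient direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .alignment import multiway_align
from .classify import classify_points, define_roi, detect_edge_points
from .config import ScanConfig
from .geometry import (CameraIntrinsics, Label, LabeledCloud, OrientedBBox,
                       Pose, estimate_normals, voxel_filter)
from .hypotheses import (DPlane, Hypothesis, Provenance, count_visible,
                         generate_dplane_hypotheses,
                         generate_frontier_hypotheses, rank_hypotheses,
                         score_hypothesis)
from .scene import GroundTruth, backproject, render_depth


# ---------------------------------------------------------------------------
# reachability
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReachabilityModel:
    """Pure, deterministic pose feasibility predicate."""

    predicate: Callable[[Pose], bool]
    name: str = "custom"

    def __call__(self, pose: Pose) -> bool:
        return bool(self.predicate(pose))


def always_reachable() -> ReachabilityModel:
    return ReachabilityModel(predicate=lambda pose: True, name="always")


def shell_reachability(base_point, r_min: float, r_max: float,
                       toward=None, max_view_angle_deg: float | None = None
                       ) -> ReachabilityModel:
    """Analytic stand-in for an IK/physics reachability checker.

    A pose is reachable when its position lies in the spherical shell
    [r_min, r_max] around ``base_point`` and (optionally) its view axis is
    within ``max_view_angle_deg`` of the ``toward`` direction.
    """
    base_point = np.asarray(base_point, dtype=float).reshape(3)
    toward_v = None if toward is None else (
        np.asarray(toward, dtype=float) / np.linalg.norm(toward))
    cos_min = (None if max_view_angle_deg is None
               else np.cos(np.radians(max_view_angle_deg)))

    def pred(pose: Pose) -> bool:
        d = float(np.linalg.norm(pose.position - base_point))
        if not (r_min <= d <= r_max):
            return False
        if toward_v is not None and cos_min is not None:
            if float(pose.view_dir @ toward_v) < cos_min:
                return False
        return True

    return ReachabilityModel(predicate=pred, name="shell")


# ---------------------------------------------------------------------------
# sphere-slice fallback poses
# ---------------------------------------------------------------------------

def generate_sphere_poses(h: Hypothesis, focus, cfg: ScanConfig) -> list[Pose]:
    """Poses on a sphere slice around an unreachable hypothesis.

    All poses lie on the sphere of radius |h.position - focus| centered at
    the focus point, within a polar cap of ``cfg.sphere_cap_deg`` around
    the hypothesis direction, on an azimuth x elevation grid; every pose
    aims its view axis at the focus.  A zero cap returns the (re-aimed)
    original pose alone.
    """
    focus = np.asarray(focus, dtype=float).reshape(3)
    radial = h.pose.position - focus
    radius = float(np.linalg.norm(radial))
    if radius <= 0:
        raise ValueError("hypothesis position coincides with its focus")
    dir0 = radial / radius
    if cfg.sphere_cap_deg <= 0:
        return [Pose.looking_at(h.pose.position, focus)]
    e1 = np.cross([0.0, 0.0, 1.0], dir0)
    if np.linalg.norm(e1) < 1e-9:
        e1 = np.cross([0.0, 1.0, 0.0], dir0)
    e1 = e1 / np.linalg.norm(e1)
    e2 = np.cross(dir0, e1)
    cap = np.radians(cfg.sphere_cap_deg)
    poses: list[Pose] = []
    for i in range(1, cfg.sphere_n_elevation + 1):
        theta = cap * i / cfg.sphere_n_elevation
        for j in range(cfg.sphere_n_azimuth):
            phi = 2 * np.pi * j / cfg.sphere_n_azimuth
            d = (np.cos(theta) * dir0
                 + np.sin(theta) * (np.cos(phi) * e1 + np.sin(phi) * e2))
            poses.append(Pose.looking_at(focus + radius * d, focus))
    return poses


# ---------------------------------------------------------------------------
# pose selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionContext:
    """State needed to score fallback poses during selection."""

    cloud: LabeledCloud
    frontier_idx: np.ndarray
    dplanes: list[DPlane]
    intr: CameraIntrinsics
    prev_pose: Pose
    prev_positions: np.ndarray     # (k, 3) of past recording positions


@dataclass
class Selection:
    pose: Pose | None              # None means DONE
    provenance: Provenance | None = None
    score: float = float("nan")
    hypothesis: Hypothesis | None = None
    reason: str = ""


def _too_close(position: np.ndarray, prev_positions: np.ndarray,
               min_dist: float) -> bool:
    if len(prev_positions) == 0:
        return False
    return bool(np.min(np.linalg.norm(prev_positions - position, axis=1)) < min_dist)


def select_next_pose(ranked: list[Hypothesis], ctx: SelectionContext,
                     reach: ReachabilityModel, cfg: ScanConfig) -> Selection:
    """Best-first pose selection with proximity check and sphere fallback.

    Hypotheses too close to a previous recording position are skipped.  A
    reachable hypothesis is returned directly; for an unreachable one its
    sphere-slice poses are scored (with N_h = 0, since they come from no
    cluster), sorted, and the best reachable one is returned.  An
    exhausted list yields DONE.
    """
    for h in ranked:
        if _too_close(h.pose.position, ctx.prev_positions, cfg.proximity_min_dist):
            continue
        if reach(h.pose):
            return Selection(pose=h.pose, provenance=h.provenance,
                             score=h.score, hypothesis=h)
        focus = h.focus if h.focus is not None else (
            h.pose.position + cfg.d_rec * h.pose.view_dir)
        fallbacks = [Hypothesis(pose=p, provenance=Provenance.SPHERE_FALLBACK,
                                n_h=0, focus=np.asarray(focus, dtype=float))
                     for p in generate_sphere_poses(h, focus, cfg)]
        for fb in fallbacks:
            fb.n_v = count_visible(fb, ctx.cloud, ctx.frontier_idx,
                                   ctx.dplanes, ctx.intr, cfg.vis_cos_max)
            score_hypothesis(fb, ctx.prev_pose, cfg)
        for fb in rank_hypotheses(fallbacks):
            if _too_close(fb.pose.position, ctx.prev_positions,
                          cfg.proximity_min_dist):
                continue
            if reach(fb.pose):
                return Selection(pose=fb.pose, provenance=fb.provenance,
                                 score=fb.score, hypothesis=fb)
    return Selection(pose=None, reason="exhausted")


# ---------------------------------------------------------------------------
# the closed recording loop
# ---------------------------------------------------------------------------

@dataclass
class CycleReport:
    cycle: int
    counts: dict[str, int]
    n_dplanes: int
    n_hypotheses: int
    chosen_position: list[float] | None
    chosen_quaternion: list[float] | None
    chosen_provenance: str | None
    chosen_score: float | None
    termination: str | None = None

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class LoopResult:
    final_cloud: LabeledCloud          # 1 mm voxel-filtered output model
    global_cloud: LabeledCloud         # full accumulated labeled cloud
    dplanes: list[DPlane]
    reports: list[CycleReport]
    recording_poses: list[Pose]
    termination: str
    bbox: OrientedBBox | None = None


def _initial_pose(scene: GroundTruth, cfg: ScanConfig,
                  intr: CameraIntrinsics) -> Pose:
    """First recording pose: at d_rec along the surface normal of the
    ROI-center point seen from the detection view."""
    det_pose = scene.detection_pose(cfg.d_rec)
    det = render_depth(scene.mesh, det_pose, intr)
    u0, v0, u1, v1 = scene.project_roi(det_pose, intr)
    cu, cv = (u0 + u1) / 2.0, (v0 + v1) / 2.0
    cloud = backproject(det)
    if len(cloud) == 0:
        raise ValueError("detection view sees no surface")
    d2 = ((cloud.pixel_index[:, 1] - cu) ** 2
          + (cloud.pixel_index[:, 0] - cv) ** 2)
    center_i = int(np.argmin(d2))
    estimate_normals(cloud, cfg.normal_radius, det_pose.position)
    if not cloud.normal_valid[center_i]:
        normal = -det_pose.view_dir
    else:
        normal = cloud.normals[center_i]
    p0 = cloud.positions[center_i]
    return Pose.looking_at(p0 + cfg.d_rec * normal, p0)


def run_loop(scene: GroundTruth, cfg: ScanConfig | None = None,
             reach: ReachabilityModel | None = None,
             intr: CameraIntrinsics | None = None,
             align: bool = True) -> LoopResult:
    """Run the full closed scanning loop on a virtual scene.

    Deterministic given ``cfg.seed``.  Termination reasons:
    ``"no deficiencies"`` (no hypothesis generated), ``"no reachable
    hypothesis"``, or ``"budget"`` (cfg.max_cycles reached).
    """
    cfg = cfg or ScanConfig()
    reach = reach or always_reachable()
    intr = intr or CameraIntrinsics()

    pose = _initial_pose(scene, cfg, intr)
    if not reach(pose):
        # the initial pose gets the same sphere fallback treatment
        seed_h = Hypothesis(pose=pose, provenance=Provenance.SPHERE_FALLBACK,
                            n_h=0, focus=pose.position + cfg.d_rec * pose.view_dir)
        for p in generate_sphere_poses(seed_h, seed_h.focus, cfg):
            if reach(p):
                pose = p
                break
        else:
            return LoopResult(LabeledCloud(), LabeledCloud(), [], [], [],
                              termination="no reachable hypothesis")

    state = LabeledCloud()
    raw_recordings: list[LabeledCloud] = []
    rec_slices: list[slice] = []
    recording_poses: list[Pose] = []
    pairwise_cache: dict = {}
    dplanes: list[DPlane] = []
    reports: list[CycleReport] = []
    bbox: OrientedBBox | None = None
    termination = "budget"

    for cycle in range(cfg.max_cycles):
        depth = render_depth(scene.mesh, pose, intr, recording_index=cycle)
        cloud_k = backproject(depth)
        estimate_normals(cloud_k, cfg.normal_radius, pose.position)
        raw_recordings.append(cloud_k)
        recording_poses.append(pose)

        offset = state.append(cloud_k)
        rec_slices.append(slice(offset, len(state)))

        if align and len(raw_recordings) >= 2:
            transforms = multiway_align(raw_recordings, cfg, pairwise_cache)
            for sl, raw, T in zip(rec_slices, raw_recordings, transforms):
                moved = raw.transformed(T)
                state.positions[sl] = moved.positions
                state.normals[sl] = moved.normals

        if cycle == 0:
            roi = scene.project_roi(pose, intr)
            bbox = define_roi(depth, roi, inflation=cfg.bbox_inflation)

        new_global = np.arange(offset, len(state))
        in_box = bbox.contains(state.positions[new_global])
        in_box_idx = new_global[in_box]

        # edge detection on this recording's in-box pixels
        pix = state.pixel_index[in_box_idx]
        edge_pix = detect_edge_points(depth, pix, cfg.d_thr)
        pix_to_global = {}
        for gi in in_box_idx:
            pix_to_global[(state.pixel_index[gi, 0], state.pixel_index[gi, 1])] = gi
        edge_idx = np.array([pix_to_global[(r, c)] for r, c in edge_pix],
                            dtype=np.int64)
        if len(edge_idx):
            state.labels[edge_idx] = Label.EDGE
        non_edge = in_box_idx[state.labels[in_box_idx] != Label.EDGE]

        classify_points(state, non_edge, cfg.r, cfg.n_thr)
        frontier_idx = state.indices_with(Label.FRONTIER)

        hyps = generate_frontier_hypotheses(
            state, frontier_idx, cfg.d_rec, cfg.min_c_frontier,
            cfg.step_c_frontier, cfg.seed)
        dp_hyps, dplanes = generate_dplane_hypotheses(
            state, edge_pix, edge_idx, pose, cfg, dplanes, cycle)
        hyps = hyps + dp_hyps

        for h in hyps:
            h.n_v = count_visible(h, state, frontier_idx, dplanes, intr,
                                  cfg.vis_cos_max)
            score_hypothesis(h, pose, cfg)
        ranked = rank_hypotheses(hyps)

        ctx = SelectionContext(
            cloud=state, frontier_idx=frontier_idx, dplanes=dplanes,
            intr=intr, prev_pose=pose,
            prev_positions=np.array([p.position for p in recording_poses]))
        sel = select_next_pose(ranked, ctx, reach, cfg)

        report = CycleReport(
            cycle=cycle, counts=state.label_counts(), n_dplanes=len(dplanes),
            n_hypotheses=len(ranked),
            chosen_position=None if sel.pose is None else sel.pose.position.tolist(),
            chosen_quaternion=None if sel.pose is None else sel.pose.quaternion.tolist(),
            chosen_provenance=None if sel.provenance is None else sel.provenance.value,
            chosen_score=None if sel.pose is None else float(sel.score))
        reports.append(report)

        if sel.pose is None:
            termination = ("no deficiencies" if len(ranked) == 0
                           else "no reachable hypothesis")
            break
        pose = sel.pose
    if reports:
        reports[-1].termination = termination

    final = voxel_filter(state, cfg.voxel_final)
    return LoopResult(final_cloud=final, global_cloud=state, dplanes=dplanes,
                      reports=reports, recording_poses=recording_poses,
                      termination=termination, bbox=bbox)
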