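"""Virtual wound scenes and the simulated range scanner.

This module replaces the physical robot + structured-light scanner with a
desk-scale stand-in: parametric triangle meshes of wound craters (optionally
undermined and tunneled, the two morphologies that cause self-occlusion) and
a pinhole depth renderer with z-buffer semantics.

The crater is a surface of revolution.  With profile parameter t in [0, 1]:

    r(t) = R (1 - t) + b sin(pi t),      z(t) = -depth (1 - cos(pi t)) / 2

where R is the opening radius and b = depth * tan(undermining_angle) the
rim bulge, tapered over an azimuth sector so the undermining forms a
directional pocket.  For b = 0 this is exactly the cosine-bell depression
z(r) = -depth (1 + cos(pi r / R)) / 2; for b > 0 the cavity wall passes
beyond the opening radius, so the pocket ceiling lies beneath intact skin
and is invisible from a top-down view (undermining).  A tunnel adds a
horizontal tube buried in the cavity wall whose interior no exterior ray
can reach.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import trimesh

from .geometry import CameraIntrinsics, DepthImage, Label, LabeledCloud, Pose


@dataclass
class WoundSceneParams:
    base_plane_size: float = 80.0       # mm, side of the surrounding skin patch
    crater_radius: float = 20.0         # mm, opening radius R
    crater_depth: float = 25.0          # mm
    rim_undermining_angle: float = 0.0  # degrees past vertical; 0 = simple bowl
    undermining_azimuth_deg: float = 0.0   # direction of the undermined pocket
    undermining_width_deg: float = 60.0    # half-width of the pocket sector
    tunnel: bool = False
    tunnel_direction: tuple[float, float] = (1.0, 0.0)  # horizontal unit axis
    mesh_resolution: float = 1.0        # vertices per mm
    surface_noise_sd: float = 0.0       # mm, vertex jitter along z
    seed: int = 0

    def __post_init__(self) -> None:
        if self.crater_radius <= 0:
            raise ValueError("crater_radius must be > 0")
        if self.crater_depth < 0:
            raise ValueError("crater_depth must be >= 0")
        if self.mesh_resolution <= 0:
            raise ValueError("mesh_resolution must be > 0")
        if self.mesh_resolution * self.crater_radius < 4:
            raise ValueError("mesh_resolution too low to represent the crater "
                             "(< 4 vertices across its radius)")

    @property
    def bulge(self) -> float:
        """Peak lateral rim bulge b (mm) of the undermined pocket.

        Scaled so that a moderate undermining angle buries a substantial
        part of the cavity depth beneath the lip, producing an occlusion
        step well above typical edge thresholds in a top-down view.
        """
        return self.crater_depth * math.tan(math.radians(self.rim_undermining_angle))

    def bulge_at(self, theta: np.ndarray) -> np.ndarray:
        """Azimuth-dependent bulge: undermining forms a pocket on one side
        (real wounds undermine directionally), tapering smoothly to zero
        outside the sector of half-width ``undermining_width_deg`` around
        ``undermining_azimuth_deg``."""
        delta = np.angle(np.exp(1j * (theta - math.radians(self.undermining_azimuth_deg))))
        w = math.radians(self.undermining_width_deg)
        x = np.clip(np.abs(delta) / max(w, 1e-9), 0.0, 1.0)
        return self.bulge * np.cos(np.pi * x / 2.0) ** 2

    @property
    def max_radius(self) -> float:
        """Largest lateral extent of the cavity (>= opening radius)."""
        t = np.linspace(0.0, 1.0, 512)
        r = self.crater_radius * (1 - t) + self.bulge * np.sin(np.pi * t)
        return float(r.max())


@dataclass
class GroundTruth:
    """Synthetic scene truth: mesh, wound ROI and per-triangle wound mask.

    Stands in for the 2D wound detector (the ROI rectangle) and for an
    independently scanned reference model (the mesh itself).
    """

    mesh: trimesh.Trimesh
    roi_rect: tuple[float, float, float, float]   # (u0, v0, u1, v1) in the detection image
    wound_mask: np.ndarray                        # per-face bool
    params: WoundSceneParams

    def detection_pose(self, d_rec: float = 650.0) -> Pose:
        """Canonical top-down detection view above the wound center."""
        return Pose.looking_at((0.0, 0.0, d_rec), (0.0, 0.0, 0.0), up=(0.0, 1.0, 0.0))

    def project_roi(self, pose: Pose, intr: CameraIntrinsics) -> tuple[float, float, float, float]:
        """Bounding rectangle of the wound extent circle in the given view.

        The circle of radius ``max_radius`` at skin level plays the role of
        the detector's bounding rectangle; it is clipped to image bounds.
        """
        ang = np.linspace(0, 2 * np.pi, 128, endpoint=False)
        rim = np.column_stack([np.cos(ang), np.sin(ang), np.zeros_like(ang)])
        rim *= self.params.max_radius
        cam = pose.inverse_transform(rim)
        cam = cam[cam[:, 2] > 1e-6]
        if len(cam) == 0:
            raise ValueError("wound not in front of the camera")
        uv = intr.project(cam)
        u0 = max(0.0, float(uv[:, 0].min()))
        v0 = max(0.0, float(uv[:, 1].min()))
        u1 = min(float(intr.width - 1), float(uv[:, 0].max()))
        v1 = min(float(intr.height - 1), float(uv[:, 1].max()))
        if u1 <= u0 or v1 <= v0:
            raise ValueError("wound projects outside the image")
        return (u0, v0, u1, v1)


def make_wound_mesh(params: WoundSceneParams,
                    intr: CameraIntrinsics | None = None,
                    d_rec: float = 650.0) -> GroundTruth:
    """Build the synthetic wound scene (deterministic given ``params.seed``)."""
    rng = np.random.default_rng(params.seed)
    R = params.crater_radius
    S = params.base_plane_size
    res = params.mesh_resolution

    n_az = max(16, int(round(2 * np.pi * R * res)))
    arc = math.hypot(max(R, params.max_radius), params.crater_depth) * 1.6
    n_prof = max(8, int(round(arc * res)))
    theta = np.arange(n_az) * 2 * np.pi / n_az
    ct, st = np.cos(theta), np.sin(theta)

    verts: list[np.ndarray] = []
    faces: list[list[int]] = []
    wound_face: list[bool] = []

    def add_ring(r_per_az: np.ndarray, z_per_az: np.ndarray) -> int:
        start = len(verts)
        for k in range(n_az):
            verts.append(np.array([r_per_az[k] * ct[k], r_per_az[k] * st[k], z_per_az[k]]))
        return start

    def bridge(ring_a: int, ring_b: int, is_wound: bool) -> None:
        for k in range(n_az):
            k2 = (k + 1) % n_az
            faces.append([ring_a + k, ring_a + k2, ring_b + k])
            faces.append([ring_a + k2, ring_b + k2, ring_b + k])
            wound_face.extend([is_wound, is_wound])

    # crater: revolved profile with azimuth-dependent bulge, rim ring at
    # t=0 shared with the plane
    t_prof = np.linspace(0.0, 1.0, n_prof + 1)
    z_prof = -params.crater_depth * (1 - np.cos(np.pi * t_prof)) / 2.0
    b_az = params.bulge_at(theta)
    rings = [add_ring(R * (1 - t_prof[j]) + b_az * np.sin(np.pi * t_prof[j]),
                      np.full(n_az, z_prof[j]))
             for j in range(n_prof)]
    apex = len(verts)
    verts.append(np.array([0.0, 0.0, z_prof[-1]]))
    for j in range(n_prof - 1):
        bridge(rings[j], rings[j + 1], True)
    for k in range(n_az):
        k2 = (k + 1) % n_az
        faces.append([rings[-1] + k, rings[-1] + k2, apex])
        wound_face.append(True)

    # surrounding skin: radial rings from the rim circle out to the square edge
    r_outer = (S / 2.0) / np.maximum(np.abs(ct), np.abs(st))
    n_skin = max(2, int(round((S / 2.0 - R) * res / 2.0)))
    prev = rings[0]
    for i in range(1, n_skin + 1):
        s = i / n_skin
        ring = add_ring(R + s * (r_outer - R), np.zeros(n_az))
        bridge(prev, ring, False)
        prev = ring

    # optional tunnel: an orifice in the cavity floor with an inclined bore
    # behind it — the interior is unreachable by exterior lines of sight,
    # while the mouth rim presents a frank range discontinuity
    if params.tunnel:
        d2 = np.asarray(params.tunnel_direction, dtype=float)
        d2 = d2 / np.linalg.norm(d2)
        horiz = np.array([d2[0], d2[1], 0.0])
        side = np.array([-d2[1], d2[0], 0.0])
        theta = math.radians(35.0)                     # bore dip below horizontal
        axis = math.cos(theta) * horiz + np.array([0, 0, -math.sin(theta)])
        r_m = 0.45 * R                                 # mouth center radius
        z_m = -params.crater_depth * (1 + math.cos(np.pi * r_m / R)) / 2.0
        mouth = horiz * r_m + np.array([0, 0, z_m])
        r_t = 0.35 * R
        length = 1.5 * R + 0.3 * params.crater_depth
        # cut the orifice: drop crater faces whose centroid is inside the bore
        n_crater_faces = len(faces)
        fc = np.array([(verts[a] + verts[b] + verts[c]) / 3.0
                       for a, b, c in faces[:n_crater_faces]])
        rel = fc - mouth
        along = rel @ axis
        radial = np.linalg.norm(rel - np.outer(along, axis), axis=1)
        cut = (radial < 0.95 * r_t) & (along > -2.0 * r_t)
        faces = [f for f, c in zip(faces, cut) if not c] + faces[n_crater_faces:]
        wound_face = [wf for wf, c in zip(wound_face, cut) if not c] \
            + wound_face[n_crater_faces:]
        # the bore: open at the mouth, capped at depth
        perp = np.cross(axis, side)
        n_seg = max(4, int(round(length * res / 2.0)))
        n_circ = max(12, int(round(2 * np.pi * r_t * res / 2.0)))
        phi = np.arange(n_circ) * 2 * np.pi / n_circ
        tube_rings = []
        for a in np.linspace(-0.5 * r_t, length, n_seg + 1):
            start = len(verts)
            for p in phi:
                verts.append(mouth + axis * a
                             + r_t * (np.cos(p) * side + np.sin(p) * perp))
            tube_rings.append(start)
        for j in range(n_seg):
            ra, rb = tube_rings[j], tube_rings[j + 1]
            for k in range(n_circ):
                k2 = (k + 1) % n_circ
                faces.append([ra + k, rb + k, ra + k2])
                faces.append([ra + k2, rb + k, rb + k2])
                wound_face.extend([True, True])
        cap = len(verts)
        verts.append(mouth + axis * length)
        rb = tube_rings[-1]
        for k in range(n_circ):
            k2 = (k + 1) % n_circ
            faces.append([rb + k, cap, rb + k2])
            wound_face.append(True)

    vertices = np.array(verts)
    if params.surface_noise_sd > 0:
        vertices = vertices + np.column_stack([
            np.zeros((len(vertices), 2)),
            rng.normal(0.0, params.surface_noise_sd, len(vertices))])
    mesh = trimesh.Trimesh(vertices=vertices, faces=np.array(faces), process=False)

    gt = GroundTruth(mesh=mesh, roi_rect=(0, 0, 0, 0),
                     wound_mask=np.array(wound_face, dtype=bool), params=params)
    intr = intr or CameraIntrinsics()
    gt.roi_rect = gt.project_roi(gt.detection_pose(d_rec), intr)
    return gt


# ---------------------------------------------------------------------------
# depth rendering (z-buffer rasterizer) and back-projection
# ---------------------------------------------------------------------------

def render_depth(mesh: trimesh.Trimesh, pose: Pose, intr: CameraIntrinsics,
                 recording_index: int = 0, noise_sd: float = 0.0,
                 rng: np.random.Generator | None = None,
                 incidence_limit_deg: float | None = 80.0) -> DepthImage:
    """Render a depth image: per-pixel nearest surface hit along the optical axis.

    Pixels with no hit, or whose nearest hit falls outside [near, far], are 0.
    Perspective-correct depth interpolation (1/z linear in screen space);
    optional additive Gaussian noise on valid pixels.  Surface struck beyond
    ``incidence_limit_deg`` from its normal returns no measurement, emulating
    how structured light fails on near-grazing surfaces (pass ``None`` for an
    ideal scanner).
    """
    h, w = intr.height, intr.width
    zbuf = np.full((h, w), np.inf)
    cosbuf = np.ones((h, w))            # incidence cosine of the nearest hit
    cos_lim = (0.0 if incidence_limit_deg is None
               else float(np.cos(np.radians(incidence_limit_deg))))
    if len(mesh.faces) > 0:
        vcam = pose.inverse_transform(mesh.vertices)
        tri = vcam[mesh.faces]                       # (M,3,3)
        # cull triangles not fully in front of the camera (no clipping; scenes
        # keep the surface well inside the working range)
        front = np.all(tri[:, :, 2] > 1e-6, axis=1)
        tri = tri[front]
        z = tri[:, :, 2]
        u = intr.fx * tri[:, :, 0] / z + intr.cx
        v = intr.fy * tri[:, :, 1] / z + intr.cy
        inv_z = 1.0 / z
        u0 = np.maximum(np.ceil(u.min(axis=1)), 0).astype(int)
        u1 = np.minimum(np.floor(u.max(axis=1)), w - 1).astype(int)
        v0 = np.maximum(np.ceil(v.min(axis=1)), 0).astype(int)
        v1 = np.minimum(np.floor(v.max(axis=1)), h - 1).astype(int)
        keep = (u1 >= u0) & (v1 >= v0)
        for i in np.flatnonzero(keep):
            ua, ub, uc = u[i]
            va, vb, vc = v[i]
            denom = (ub - ua) * (vc - va) - (uc - ua) * (vb - va)
            if abs(denom) < 1e-12:
                continue
            gu, gv = np.meshgrid(np.arange(u0[i], u1[i] + 1),
                                 np.arange(v0[i], v1[i] + 1))
            l1 = ((gu - ua) * (vc - va) - (uc - ua) * (gv - va)) / denom
            l2 = ((ub - ua) * (gv - va) - (gu - ua) * (vb - va)) / denom
            l0 = 1.0 - l1 - l2
            eps = -1e-9
            inside = (l0 >= eps) & (l1 >= eps) & (l2 >= eps)
            if not inside.any():
                continue
            zi = 1.0 / (l0 * inv_z[i, 0] + l1 * inv_z[i, 1] + l2 * inv_z[i, 2])
            rows = gv[inside]
            cols = gu[inside]
            zin = zi[inside]
            # the nearest hit wins the pixel even when struck at grazing
            # incidence (it still occludes what lies behind it)
            nrm = np.cross(tri[i, 1] - tri[i, 0], tri[i, 2] - tri[i, 0])
            nl = np.linalg.norm(nrm)
            if nl < 1e-12:
                continue
            nrm = nrm / nl
            rx = (cols - intr.cx) / intr.fx
            ry = (rows - intr.cy) / intr.fy
            rnorm = np.sqrt(rx * rx + ry * ry + 1.0)
            cosang = np.abs(rx * nrm[0] + ry * nrm[1] + nrm[2]) / rnorm
            m = zin < zbuf[rows, cols]
            zbuf[rows[m], cols[m]] = zin[m]
            cosbuf[rows[m], cols[m]] = cosang[m]
    values = np.where(np.isfinite(zbuf) & (zbuf >= intr.near) & (zbuf <= intr.far)
                      & (cosbuf >= cos_lim), zbuf, 0.0)
    if noise_sd > 0:
        rng = rng if rng is not None else np.random.default_rng(0)
        mask = values > 0
        values = values + mask * rng.normal(0.0, noise_sd, values.shape)
        values = np.maximum(values, 0.0)
    return DepthImage(values=values, intrinsics=intr, pose=pose,
                      recording_index=recording_index)


def backproject(depth: DepthImage) -> LabeledCloud:
    """Lift valid depth pixels to an unlabeled point cloud in the base frame."""
    intr = depth.intrinsics
    rows, cols = np.nonzero(depth.valid_mask)
    d = depth.values[rows, cols]
    x = d * (cols - intr.cx) / intr.fx
    y = d * (rows - intr.cy) / intr.fy
    pts_cam = np.column_stack([x, y, d])
    pts = depth.pose.transform(pts_cam)
    n = len(pts)
    return LabeledCloud(
        positions=pts,
        recording_index=np.full(n, depth.recording_index, dtype=np.int32),
        pixel_index=np.column_stack([rows, cols]).astype(np.int32),
        labels=np.full(n, Label.UNLABELED, dtype=np.uint8),
    )
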