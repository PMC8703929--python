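"""Shared geometric types and primitive operations.

Conventions used throughout the package:

* units are millimeters, in the (simulated) robot base frame;
* a camera looks along the +Z column of its pose rotation matrix;
* voxel grids are anchored at the world origin with half-open cells,
  cell membership by ``floor(p / voxel)``;
* point normals are sign-flipped toward the viewpoint of the recording
  that created the point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation


# ---------------------------------------------------------------------------
# poses and cameras
# ---------------------------------------------------------------------------

class Pose:
    """Rigid camera/tool pose: position (mm) + orientation.

    The rotation matrix columns are the X, Y, Z axes of the posed frame
    expressed in the base frame; Z is the viewing direction.
    """

    __slots__ = ("position", "rotation")

    def __init__(self, position, rotation) -> None:
        self.position = np.asarray(position, dtype=float).reshape(3)
        R = np.asarray(rotation, dtype=float).reshape(3, 3)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or np.linalg.det(R) < 0:
            raise ValueError("rotation must be orthonormal with det +1")
        self.rotation = R

    @classmethod
    def from_quaternion(cls, position, quat_wxyz) -> "Pose":
        w, x, y, z = np.asarray(quat_wxyz, dtype=float)
        n = np.sqrt(w * w + x * x + y * y + z * z)
        if abs(n - 1.0) > 1e-6:
            raise ValueError("quaternion must be unit norm")
        R = Rotation.from_quat([x / n, y / n, z / n, w / n]).as_matrix()
        return cls(position, R)

    @classmethod
    def identity(cls) -> "Pose":
        return cls(np.zeros(3), np.eye(3))

    @classmethod
    def looking_at(cls, position, target, up=(0.0, 0.0, 1.0)) -> "Pose":
        """Pose at ``position`` with the view axis Z aimed at ``target``."""
        position = np.asarray(position, dtype=float)
        z = np.asarray(target, dtype=float) - position
        nz = np.linalg.norm(z)
        if nz == 0:
            raise ValueError("position and target coincide")
        z = z / nz
        x = np.cross(np.asarray(up, dtype=float), z)
        if np.linalg.norm(x) < 1e-9:        # view along the reference axis
            x = np.cross([0.0, 1.0, 0.0], z)
        x = x / np.linalg.norm(x)
        y = np.cross(z, x)
        return cls(position, np.column_stack([x, y, z]))

    @property
    def quaternion(self) -> np.ndarray:
        """Unit quaternion (w, x, y, z), canonicalized to w >= 0."""
        x, y, z, w = Rotation.from_matrix(self.rotation).as_quat()
        q = np.array([w, x, y, z])
        if q[0] < 0:
            q = -q
        return q

    @property
    def view_dir(self) -> np.ndarray:
        return self.rotation[:, 2].copy()

    def matrix(self) -> np.ndarray:
        T = np.eye(4)
        T[:3, :3] = self.rotation
        T[:3, 3] = self.position
        return T

    def transform(self, points: np.ndarray) -> np.ndarray:
        """Map points from the posed frame into the base frame."""
        return np.asarray(points, dtype=float) @ self.rotation.T + self.position

    def inverse_transform(self, points: np.ndarray) -> np.ndarray:
        """Map base-frame points into the posed (camera) frame."""
        return (np.asarray(points, dtype=float) - self.position) @ self.rotation

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Pose(position={self.position.round(3)}, quat={self.quaternion.round(4)})"


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole model of the virtual range scanner (pixels / mm)."""

    # Defaults emulate the real structured-light scanner at desk scale:
    # pixel pitch ~0.29 mm at the 650 mm stand-off (so a 2 mm-radius disc
    # holds ~149 samples, comfortably above the 60-point density demand)
    # with a field of view that covers a whole wound in every recording.
    width: int = 450
    height: int = 340
    fx: float = 2240.0
    fy: float = 2240.0
    cx: float = 224.5
    cy: float = 169.5
    near: float = 300.0
    far: float = 1200.0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("image dimensions must be positive")
        if not (0 < self.near < self.far):
            raise ValueError("require 0 < near < far")

    def project(self, pts_cam: np.ndarray) -> np.ndarray:
        """Camera-frame points -> continuous pixel coords (u, v). z must be > 0."""
        pts_cam = np.asarray(pts_cam, dtype=float)
        z = pts_cam[..., 2]
        u = self.fx * pts_cam[..., 0] / z + self.cx
        v = self.fy * pts_cam[..., 1] / z + self.cy
        return np.stack([u, v], axis=-1)


@dataclass
class DepthImage:
    """Dense range image: per-pixel distance along the optical axis, mm.

    A value of 0 marks an invalid (no-return) measurement.
    """

    values: np.ndarray
    intrinsics: CameraIntrinsics
    pose: Pose
    recording_index: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("depth values must be a 2D array")
        if self.values.shape != (self.intrinsics.height, self.intrinsics.width):
            raise ValueError("depth shape does not match intrinsics")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("depth values must be finite and >= 0")

    @property
    def valid_mask(self) -> np.ndarray:
        return self.values > 0


# ---------------------------------------------------------------------------
# labeled point cloud
# ---------------------------------------------------------------------------

class Label(IntEnum):
    UNLABELED = 0
    CORE = 1
    OUTLIER = 2
    FRONTIER = 3
    EDGE = 4


class LabeledCloud:
    """Accumulating global point cloud with per-point attributes.

    Stored struct-of-arrays: positions (N,3) mm, unit normals (N,3) with a
    validity mask, source recording index, source pixel (row, col), and a
    label in {unlabeled, core, outlier, frontier, edge}.
    """

    def __init__(self, positions=None, normals=None, recording_index=None,
                 pixel_index=None, labels=None, normal_valid=None) -> None:
        if positions is None:
            positions = np.empty((0, 3), dtype=float)
        self.positions = np.asarray(positions, dtype=float).reshape(-1, 3)
        n = len(self.positions)
        self.normals = (np.zeros((n, 3)) if normals is None
                        else np.asarray(normals, dtype=float).reshape(-1, 3))
        self.recording_index = (np.zeros(n, dtype=np.int32) if recording_index is None
                                else np.asarray(recording_index, dtype=np.int32).reshape(-1))
        self.pixel_index = (np.full((n, 2), -1, dtype=np.int32) if pixel_index is None
                            else np.asarray(pixel_index, dtype=np.int32).reshape(-1, 2))
        self.labels = (np.full(n, Label.UNLABELED, dtype=np.uint8) if labels is None
                       else np.asarray(labels, dtype=np.uint8).reshape(-1))
        self.normal_valid = (np.zeros(n, dtype=bool) if normal_valid is None
                             else np.asarray(normal_valid, dtype=bool).reshape(-1))
        if not (len(self.normals) == len(self.recording_index) == len(self.pixel_index)
                == len(self.labels) == len(self.normal_valid) == n):
            raise ValueError("attribute arrays must share a common length")

    def __len__(self) -> int:
        return len(self.positions)

    def indices_with(self, label: Label) -> np.ndarray:
        return np.flatnonzero(self.labels == label)

    def label_counts(self) -> dict[str, int]:
        return {lab.name.lower(): int(np.sum(self.labels == lab)) for lab in Label}

    def append(self, other: "LabeledCloud") -> int:
        """Concatenate ``other``; returns the index offset of the new points."""
        offset = len(self)
        self.positions = np.vstack([self.positions, other.positions])
        self.normals = np.vstack([self.normals, other.normals])
        self.recording_index = np.concatenate([self.recording_index, other.recording_index])
        self.pixel_index = np.vstack([self.pixel_index, other.pixel_index])
        self.labels = np.concatenate([self.labels, other.labels])
        self.normal_valid = np.concatenate([self.normal_valid, other.normal_valid])
        return offset

    def subset(self, idx) -> "LabeledCloud":
        return LabeledCloud(self.positions[idx], self.normals[idx],
                            self.recording_index[idx], self.pixel_index[idx],
                            self.labels[idx], self.normal_valid[idx])

    def copy(self) -> "LabeledCloud":
        return self.subset(slice(None))

    def transformed(self, T: np.ndarray) -> "LabeledCloud":
        """Apply a rigid 4x4 transform (positions and normals)."""
        out = self.copy()
        R = np.asarray(T)[:3, :3]
        out.positions = self.positions @ R.T + np.asarray(T)[:3, 3]
        out.normals = self.normals @ R.T
        return out


# ---------------------------------------------------------------------------
# primitive operations
# ---------------------------------------------------------------------------

def voxel_filter(cloud: LabeledCloud, voxel: float) -> LabeledCloud:
    """Downsample to at most one point per occupied voxel cell.

    The output point is the centroid of the cell's points; the remaining
    per-point attributes are taken from the cell's first point in input
    order.  The grid is anchored at the origin (half-open cells).
    """
    if voxel <= 0:
        raise ValueError("voxel must be > 0")
    n = len(cloud)
    if n == 0:
        return cloud.copy()
    cells = np.floor(cloud.positions / voxel).astype(np.int64)
    # order-independent unique cell ids
    _, first_idx, inverse = np.unique(cells, axis=0, return_index=True, return_inverse=True)
    k = len(first_idx)
    sums = np.zeros((k, 3))
    np.add.at(sums, inverse, cloud.positions)
    counts = np.bincount(inverse, minlength=k).astype(float)
    centroids = sums / counts[:, None]
    # representative (first in input order) per cell, for the attributes
    rep = np.full(k, n, dtype=np.int64)
    np.minimum.at(rep, inverse, np.arange(n))
    out = cloud.subset(rep)
    out.positions = centroids
    return out


def estimate_normals(cloud: LabeledCloud, neighborhood_radius: float,
                     viewpoint) -> LabeledCloud:
    """Covariance-based normal estimation, oriented toward ``viewpoint``.

    The normal at p is the eigenvector of the covariance of the radius
    neighborhood (including p) with the smallest eigenvalue, sign-flipped
    so that dot(n, viewpoint - p) >= 0.  Neighborhoods with fewer than 3
    points are flagged invalid (such points are excluded from hypothesis
    generation downstream).  Modifies and returns ``cloud``.
    """
    viewpoint = np.asarray(viewpoint, dtype=float).reshape(3)
    n = len(cloud)
    if n == 0:
        return cloud
    tree = cKDTree(cloud.positions)
    neighbors = tree.query_ball_point(cloud.positions, neighborhood_radius)
    normals = np.zeros((n, 3))
    valid = np.zeros(n, dtype=bool)
    for i, idx in enumerate(neighbors):
        if len(idx) < 3:
            continue
        pts = cloud.positions[idx]
        cov = np.cov(pts.T, bias=True)
        w, v = np.linalg.eigh(cov)
        normal = v[:, 0]
        if normal @ (viewpoint - cloud.positions[i]) < 0:
            normal = -normal
        normals[i] = normal
        valid[i] = True
    cloud.normals = normals
    cloud.normal_valid = valid
    return cloud


@dataclass
class OrientedBBox:
    """Covariance-aligned bounding box (axes = eigenvectors)."""

    center: np.ndarray
    axes: np.ndarray          # 3x3 orthonormal, columns = box axes
    half_extents: np.ndarray  # mm, after inflation

    def contains(self, points: np.ndarray) -> np.ndarray:
        local = (np.atleast_2d(points) - self.center) @ self.axes
        return np.all(np.abs(local) <= self.half_extents + 1e-9, axis=1)


def compute_obbox(points: np.ndarray, inflation: float = 0.10) -> OrientedBBox:
    """Oriented bounding box from the covariance eigenvectors of ``points``.

    Half extents are the per-axis half range of the projected points,
    inflated by ``inflation`` (10% by default, to be certain the whole
    region of interest is enclosed).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if len(points) < 2 or np.allclose(points, points[0], atol=1e-12):
        raise ValueError("degenerate extent: need at least two distinct points")
    mean = points.mean(axis=0)
    cov = np.cov((points - mean).T, bias=True)
    _, axes = np.linalg.eigh(cov)
    if np.linalg.det(axes) < 0:
        axes = axes * np.array([1.0, 1.0, -1.0])
    local = (points - mean) @ axes
    lo, hi = local.min(axis=0), local.max(axis=0)
    center = mean + axes @ ((lo + hi) / 2.0)
    half = (hi - lo) / 2.0 * (1.0 + inflation)
    # keep the box 3-dimensional even for planar inputs so that radius-r
    # neighborhoods of in-plane points stay inside
    half = np.maximum(half, 1e-6)
    return OrientedBBox(center=center, axes=axes, half_extents=half)


def in_frustum(p, pose: Pose, intr: CameraIntrinsics) -> bool:
    """True iff point ``p`` lies inside the camera's pinhole view frustum."""
    pc = pose.inverse_transform(np.asarray(p, dtype=float).reshape(1, 3))[0]
    if not (intr.near <= pc[2] <= intr.far):
        return False
    u = intr.fx * pc[0] / pc[2] + intr.cx
    v = intr.fy * pc[1] / pc[2] + intr.cy
    return (0.0 <= u < intr.width) and (0.0 <= v < intr.height)


def in_frustum_mask(points: np.ndarray, pose: Pose, intr: CameraIntrinsics) -> np.ndarray:
    """Vectorized :func:`in_frustum` over an (N,3) array."""
    pts = np.atleast_2d(points)
    pc = pose.inverse_transform(pts)
    z = pc[:, 2]
    ok = (z >= intr.near) & (z <= intr.far)
    with np.errstate(divide="ignore", invalid="ignore"):
        u = intr.fx * pc[:, 0] / z + intr.cx
        v = intr.fy * pc[:, 1] / z + intr.cy
    ok &= (u >= 0) & (u < intr.width) & (v >= 0) & (v < intr.height)
    return ok
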