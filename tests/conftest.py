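import numpy as np
import pytest
import trimesh

from nbvscan import CameraIntrinsics, DepthImage, LabeledCloud, Pose


@pytest.fixture
def small_intr() -> CameraIntrinsics:
    """Coarse camera for fast unit tests (not the study-scale default)."""
    return CameraIntrinsics(width=64, height=48, fx=320.0, fy=320.0,
                            cx=31.5, cy=23.5, near=100.0, far=2000.0)


@pytest.fixture
def plane_mesh() -> trimesh.Trimesh:
    """A 200x200 mm square plane at z = 650 mm (camera at origin looks +z)."""
    v = [[-100, -100, 650], [100, -100, 650], [100, 100, 650], [-100, 100, 650]]
    return trimesh.Trimesh(vertices=v, faces=[[0, 1, 2], [0, 2, 3]], process=False)


def make_cloud(points, **kw) -> LabeledCloud:
    return LabeledCloud(positions=np.asarray(points, dtype=float), **kw)


def grid_cloud(spacing: float, nx: int, ny: int, z: float = 0.0) -> LabeledCloud:
    xs = np.arange(nx) * spacing
    ys = np.arange(ny) * spacing
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel(), np.full(gx.size, z)])
    return make_cloud(pts)
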