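"""Reconstruction quality metrics against simulator ground truth.

The physical system's precision study compared its output against an
industrial reference scan; at desk scale the virtual scene's own mesh is
the reference.  Two quantities are reported: coverage of the
camera-accessible wound surface at the required sampling density, and the
cloud-to-mesh RMS distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .config import ScanConfig
from .geometry import LabeledCloud
from .scene import GroundTruth


def sample_wound_surface(scene: GroundTruth, n_samples: int,
                         seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Area-weighted random samples on the wound triangles.

    Returns (points, face normals at the samples); deterministic given seed.
    """
    rng = np.random.default_rng(seed)
    faces = np.flatnonzero(scene.wound_mask)
    areas = scene.mesh.area_faces[faces]
    probs = areas / areas.sum()
    chosen = rng.choice(faces, size=n_samples, p=probs)
    tri = scene.mesh.vertices[scene.mesh.faces[chosen]]
    r1 = np.sqrt(rng.random(n_samples))
    r2 = rng.random(n_samples)
    pts = ((1 - r1)[:, None] * tri[:, 0]
           + (r1 * (1 - r2))[:, None] * tri[:, 1]
           + (r1 * r2)[:, None] * tri[:, 2])
    normals = scene.mesh.face_normals[chosen]
    # wound surface normals face the exterior (toward z+ half-space)
    flip = normals[:, 2] < 0
    normals = np.where(flip[:, None], -normals, normals)
    return pts, normals


def ray_hit_distances(mesh: trimesh.Trimesh, origins: np.ndarray,
                      direction: np.ndarray, chunk: int = 128) -> np.ndarray:
    """Nearest ray-mesh hit distance per origin (inf = no hit).

    Brute-force Moller-Trumbore over every triangle, vectorized in ray
    chunks; independent of any spatial index, so it doubles as a slow
    reference ray caster.
    """
    tri = mesh.vertices[mesh.faces]
    e1 = tri[:, 1] - tri[:, 0]
    e2 = tri[:, 2] - tri[:, 0]
    d = np.asarray(direction, dtype=float).reshape(3)
    pvec = np.cross(d, e2)                        # (M,3)
    det = np.einsum("ij,ij->i", e1, pvec)
    ok_tri = np.abs(det) > 1e-12
    inv_det = np.where(ok_tri, 1.0 / np.where(ok_tri, det, 1.0), 0.0)
    origins = np.atleast_2d(origins)
    out = np.full(len(origins), np.inf)
    for s in range(0, len(origins), chunk):
        o = origins[s:s + chunk]
        tvec = o[:, None, :] - tri[None, :, 0]    # (c,M,3)
        u = np.einsum("cmj,mj->cm", tvec, pvec) * inv_det
        qvec = np.cross(tvec, e1[None, :, :])
        v = np.einsum("cmj,j->cm", qvec, d) * inv_det
        t = np.einsum("cmj,mj->cm", qvec, e2) * inv_det
        hit = (ok_tri[None, :] & (u >= -1e-9) & (v >= -1e-9)
               & (u + v <= 1 + 1e-9) & (t > 1e-6))
        t = np.where(hit, t, np.inf)
        out[s:s + chunk] = t.min(axis=1)
    return out


def _probe_directions(n_azimuth: int = 8, polar_deg=(15.0, 40.0, 65.0)) -> np.ndarray:
    """Exterior viewing directions: top-down plus rings of oblique views."""
    dirs = [np.array([0.0, 0.0, 1.0])]
    for pol in polar_deg:
        t = np.radians(pol)
        for j in range(n_azimuth):
            phi = 2 * np.pi * j / n_azimuth
            dirs.append(np.array([np.sin(t) * np.cos(phi),
                                  np.sin(t) * np.sin(phi), np.cos(t)]))
    return np.array(dirs)


def accessible_mask(scene: GroundTruth, points: np.ndarray,
                    d_rec: float = 650.0,
                    directions: np.ndarray | None = None) -> np.ndarray:
    """True for samples visible from at least one exterior probe direction.

    A sample is accessible via direction d when the ray from the sample
    toward d escapes the scene unobstructed (line of sight to an exterior
    camera).  Tunneled cavity interiors fail every probe, matching what no
    exterior camera could record.
    """
    dirs = _probe_directions() if directions is None else np.asarray(directions)
    ok = np.zeros(len(points), dtype=bool)
    for d in dirs:
        cand = np.flatnonzero(~ok)
        if len(cand) == 0:
            break
        origins = points[cand] + 0.5 * d          # offset off the surface
        dist = ray_hit_distances(scene.mesh, origins, d)
        ok[cand[np.isinf(dist)]] = True
    return ok


@dataclass
class CoverageReport:
    n_samples: int
    n_accessible: int
    n_covered: int
    coverage: float            # covered / accessible
    rms_mm: float              # cloud-to-mesh RMS over covered samples

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def coverage_report(scene: GroundTruth, cloud: LabeledCloud,
                    cfg: ScanConfig | None = None, n_samples: int = 600,
                    seed: int = 0) -> CoverageReport:
    """Fraction of accessible wound surface sampled at the required density.

    A ground-truth sample is *covered* when strictly more than ``n_thr``
    cloud points lie within radius ``r`` of it — the same density rule the
    classifier enforces.  RMS is the distance from covered samples to
    their nearest cloud point.
    """
    cfg = cfg or ScanConfig()
    pts, _ = sample_wound_surface(scene, n_samples, seed=seed)
    acc = accessible_mask(scene, pts, d_rec=cfg.d_rec)
    n_acc = int(acc.sum())
    if len(cloud) == 0 or n_acc == 0:
        return CoverageReport(n_samples, n_acc, 0, 0.0, float("inf"))
    tree = cKDTree(cloud.positions)
    counts = tree.query_ball_point(pts[acc], cfg.r, return_length=True)
    covered = counts > cfg.n_thr
    n_cov = int(covered.sum())
    if n_cov:
        d, _ = tree.query(pts[acc][covered])
        rms = float(np.sqrt(np.mean(d ** 2)))
    else:
        rms = float("inf")
    return CoverageReport(n_samples, n_acc, n_cov, n_cov / n_acc, rms)


def cloud_to_mesh_rms(cloud: LabeledCloud, mesh: trimesh.Trimesh,
                      max_points: int = 5000, seed: int = 0,
                      surface_samples: int = 300_000) -> float:
    """Approximate RMS distance from (a subsample of) cloud points to the mesh.

    Measured against a dense random sampling of the surface (upward-biased
    by roughly half the sample spacing), which is adequate for the
    comparative before/after-alignment checks it serves.
    """
    if len(cloud) == 0:
        return float("nan")
    rng = np.random.default_rng(seed)
    idx = (np.arange(len(cloud)) if len(cloud) <= max_points
           else rng.choice(len(cloud), size=max_points, replace=False))
    surf, _ = trimesh.sample.sample_surface(mesh, surface_samples,
                                            seed=int(rng.integers(2 ** 31)))
    dist, _ = cKDTree(surf).query(cloud.positions[idx])
    return float(np.sqrt(np.mean(dist ** 2)))
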