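"""Coarse-to-fine rigid registration and multiway pose-graph alignment.

Pairwise alignment runs three steps: (1) feature-based coarse registration
on 20 mm-voxel clouds using FPFH descriptors matched by sample consensus,
(2) point-to-plane ICP on 2 mm-voxel clouds with a 10 mm correspondence
limit, (3) the same ICP with a 5 mm limit.  Multiway alignment builds a
pose graph — odometry edges between consecutive recordings plus loop
closures for every pair whose pairwise fitness clears a floor — and solves
a robust nonlinear least-squares problem over per-recording rigid
transforms, with the first recording fixed as the reference frame.

Everything here is deterministic given the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.optimize import least_squares
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .config import ScanConfig
from .geometry import LabeledCloud, voxel_filter

# rotation residuals (radians) are weighted into millimeters via an
# effective lever arm comparable to the scanning stand-off
_ROT_WEIGHT_MM = 500.0


@dataclass
class RegistrationResult:
    transform: np.ndarray    # 4x4 rigid, maps src coords into dst frame
    fitness: float           # fraction of src points with a correspondence
    inlier_rms: float        # mm
    ok: bool = True

    def __post_init__(self) -> None:
        self.transform = _orthonormalize(np.asarray(self.transform, dtype=float))


def _orthonormalize(T: np.ndarray) -> np.ndarray:
    """Project the rotation block onto SO(3) (exact rigidity)."""
    out = np.eye(4)
    U, _, Vt = np.linalg.svd(T[:3, :3])
    R = U @ Vt
    if np.linalg.det(R) < 0:
        R = U @ np.diag([1.0, 1.0, -1.0]) @ Vt
    out[:3, :3] = R
    out[:3, 3] = T[:3, 3]
    return out


def _apply(T: np.ndarray, pts: np.ndarray) -> np.ndarray:
    return pts @ T[:3, :3].T + T[:3, 3]


def _kabsch(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Least-squares rigid transform mapping src onto dst."""
    cs, cd = src.mean(axis=0), dst.mean(axis=0)
    H = (src - cs).T @ (dst - cd)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    T = np.eye(4)
    T[:3, :3] = R
    T[:3, 3] = cd - R @ cs
    return T


# ---------------------------------------------------------------------------
# FPFH descriptors
# ---------------------------------------------------------------------------

def compute_fpfh(points: np.ndarray, normals: np.ndarray, radius: float,
                 bins: int = 11) -> np.ndarray:
    """Fast point feature histograms (33-dim) over radius neighborhoods.

    Per point pair the three Darboux-frame angles (alpha, phi, theta) are
    binned into ``bins`` bins each; the final descriptor is the point's own
    histogram plus the distance-weighted mean of its neighbors'.
    """
    n = len(points)
    tree = cKDTree(points)
    neighbors = tree.query_ball_point(points, radius)
    spfh = np.zeros((n, 3 * bins))
    for i, idx in enumerate(neighbors):
        idx = [j for j in idx if j != i]
        if not idx:
            continue
        p, np_i = points[i], normals[i]
        q = points[idx]
        nq = normals[idx]
        diff = q - p
        dist = np.linalg.norm(diff, axis=1)
        good = dist > 1e-9
        if not good.any():
            continue
        diff, dist, nq = diff[good], dist[good], nq[good]
        u = np.broadcast_to(np_i, diff.shape)
        d = diff / dist[:, None]
        v = np.cross(d, u)
        vn = np.linalg.norm(v, axis=1)
        ok = vn > 1e-9
        if not ok.any():
            continue
        u, d, v, nq = u[ok], d[ok], v[ok] / vn[ok][:, None], nq[ok]
        w = np.cross(u, v)
        alpha = np.einsum("ij,ij->i", v, nq)
        phi = np.einsum("ij,ij->i", u, d)
        theta = np.arctan2(np.einsum("ij,ij->i", w, nq),
                           np.einsum("ij,ij->i", u, nq))
        for k, (vals, lo, hi) in enumerate([(alpha, -1, 1), (phi, -1, 1),
                                            (theta, -np.pi, np.pi)]):
            b = np.clip(((vals - lo) / (hi - lo) * bins).astype(int), 0, bins - 1)
            spfh[i, k * bins:(k + 1) * bins] += np.bincount(b, minlength=bins)
        s = spfh[i].sum()
        if s > 0:
            spfh[i] /= s
    fpfh = spfh.copy()
    for i, idx in enumerate(neighbors):
        idx = [j for j in idx if j != i]
        if not idx:
            continue
        wts = 1.0 / np.maximum(np.linalg.norm(points[idx] - points[i], axis=1), 1e-9)
        fpfh[i] += (wts[:, None] * spfh[idx]).sum(axis=0) / len(idx)
        s = fpfh[i].sum()
        if s > 0:
            fpfh[i] /= s
    return fpfh


def _coarse_ransac(src_pts, src_feat, dst_pts, dst_feat, dist_thresh,
                   rng: np.random.Generator, iters: int = 2000) -> np.ndarray:
    """Sample-consensus alignment over mutual-nearest descriptor matches."""
    D = cdist(src_feat, dst_feat)
    fwd = np.argmin(D, axis=1)
    bwd = np.argmin(D, axis=0)
    mutual = np.flatnonzero(bwd[fwd] == np.arange(len(src_pts)))
    pairs = np.column_stack([mutual, fwd[mutual]])
    if len(pairs) < 3:
        pairs = np.column_stack([np.arange(len(src_pts)), fwd])
    a, b = src_pts[pairs[:, 0]], dst_pts[pairs[:, 1]]
    best_T, best_inl = np.eye(4), -1
    for _ in range(iters):
        sel = rng.choice(len(pairs), size=3, replace=False)
        if np.linalg.matrix_rank(a[sel] - a[sel].mean(axis=0)) < 2:
            continue
        T = _kabsch(a[sel], b[sel])
        inl = int(np.sum(np.linalg.norm(_apply(T, a) - b, axis=1) < dist_thresh))
        if inl > best_inl:
            best_inl, best_T = inl, T
    mask = np.linalg.norm(_apply(best_T, a) - b, axis=1) < dist_thresh
    if mask.sum() >= 3:
        best_T = _kabsch(a[mask], b[mask])
    return best_T


# ---------------------------------------------------------------------------
# point-to-plane ICP
# ---------------------------------------------------------------------------

def icp_point_to_plane(src_pts: np.ndarray, dst_pts: np.ndarray,
                       dst_normals: np.ndarray, max_dist: float,
                       init: np.ndarray | None = None, max_iter: int = 50,
                       tol: float = 1e-6) -> RegistrationResult:
    """Point-to-plane ICP; converges on relative RMS change < ``tol``."""
    T = np.eye(4) if init is None else _orthonormalize(init)
    tree = cKDTree(dst_pts)
    prev_rms = np.inf
    fitness, rms = 0.0, np.inf
    for _ in range(max_iter):
        moved = _apply(T, src_pts)
        dist, j = tree.query(moved, distance_upper_bound=max_dist)
        m = np.isfinite(dist)
        fitness = float(m.mean()) if len(m) else 0.0
        if m.sum() < 6:
            break
        p = moved[m]
        q = dst_pts[j[m]]
        nrm = dst_normals[j[m]]
        r = np.einsum("ij,ij->i", p - q, nrm)
        rms = float(np.sqrt(np.mean(r ** 2)))
        # linearized rigid update x = (rotvec, t): J x = -r
        J = np.hstack([np.cross(p, nrm), nrm])
        H = J.T @ J + 1e-9 * np.eye(6)
        x = np.linalg.solve(H, -J.T @ r)
        dT = np.eye(4)
        dT[:3, :3] = Rotation.from_rotvec(x[:3]).as_matrix()
        dT[:3, 3] = x[3:]
        T = _orthonormalize(dT @ T)
        if abs(prev_rms - rms) < tol * max(prev_rms, 1e-12):
            break
        prev_rms = rms
    return RegistrationResult(transform=T, fitness=fitness,
                              inlier_rms=rms if np.isfinite(rms) else 0.0)


# ---------------------------------------------------------------------------
# pairwise and multiway alignment
# ---------------------------------------------------------------------------

def pairwise_align(src: LabeledCloud, dst: LabeledCloud,
                   cfg: ScanConfig | None = None) -> RegistrationResult:
    """Coarse-to-fine registration of ``src`` onto ``dst``.

    Raises ``ValueError`` on empty inputs; a result whose final fitness is
    below ``cfg.fitness_floor`` is returned with ``ok=False`` (the caller
    decides what to do with the edge).
    """
    cfg = cfg or ScanConfig()
    if len(src) == 0 or len(dst) == 0:
        raise ValueError("pairwise_align requires non-empty clouds")
    rng = np.random.default_rng(cfg.seed + 7919)
    src_c = voxel_filter(src, cfg.voxel_coarse)
    dst_c = voxel_filter(dst, cfg.voxel_coarse)
    feat_radius = 5.0 * cfg.voxel_coarse
    T0 = np.eye(4)
    if len(src_c) >= 3 and len(dst_c) >= 3:
        fs = compute_fpfh(src_c.positions, src_c.normals, feat_radius)
        fd = compute_fpfh(dst_c.positions, dst_c.normals, feat_radius)
        T0 = _coarse_ransac(src_c.positions, fs, dst_c.positions, fd,
                            dist_thresh=cfg.voxel_coarse, rng=rng)
    src_f = voxel_filter(src, cfg.voxel_fine)
    dst_f = voxel_filter(dst, cfg.voxel_fine)
    # the recordings arrive roughly pre-aligned (robot odometry), so the
    # identity is always kept as a rival initialization: a spurious
    # feature-consensus fit (e.g. a flipped match between two nearly flat
    # patches) must not be able to drag ICP into its local minimum
    candidates = [np.eye(4)]
    if np.linalg.norm(T0[:3, 3]) > 1e-9 or abs(np.trace(T0[:3, :3]) - 3) > 1e-12:
        candidates.append(T0)
    best: RegistrationResult | None = None
    for init in candidates:
        step2 = icp_point_to_plane(src_f.positions, dst_f.positions,
                                   dst_f.normals, max_dist=cfg.icp_coarse_dist,
                                   init=init)
        step3 = icp_point_to_plane(src_f.positions, dst_f.positions,
                                   dst_f.normals, max_dist=cfg.icp_fine_dist,
                                   init=step2.transform)
        if (best is None or step3.fitness > best.fitness + 1e-12
                or (abs(step3.fitness - best.fitness) <= 1e-12
                    and step3.inlier_rms < best.inlier_rms)):
            best = step3
    best.ok = best.fitness >= cfg.fitness_floor
    return best


def _se3_params(T: np.ndarray) -> np.ndarray:
    return np.concatenate([Rotation.from_matrix(T[:3, :3]).as_rotvec(), T[:3, 3]])


def _se3_matrix(x: np.ndarray) -> np.ndarray:
    T = np.eye(4)
    T[:3, :3] = Rotation.from_rotvec(x[:3]).as_matrix()
    T[:3, 3] = x[3:]
    return T


def multiway_align(clouds: list[LabeledCloud], cfg: ScanConfig | None = None,
                   pairwise_cache: dict[tuple[int, int], RegistrationResult] | None = None,
                   info: dict | None = None) -> list[np.ndarray]:
    """Global transforms expressing every recording in the first one's frame.

    One recording maps to the identity; two to the pairwise result; three
    or more run pose-graph optimization over odometry edges (consecutive
    recordings) plus loop closures (non-consecutive pairs whose fitness
    clears the floor), with a soft-L1 robust loss.  ``pairwise_cache`` maps
    (i, j) with i < j to a precomputed ``pairwise_align(clouds[j], clouds[i])``
    and is filled in-place, so repeated calls only align new pairs.
    """
    cfg = cfg or ScanConfig()
    n = len(clouds)
    if n == 0:
        raise ValueError("need at least one recording")
    if n == 1:
        return [np.eye(4)]
    cache = pairwise_cache if pairwise_cache is not None else {}

    def edge(i: int, j: int) -> RegistrationResult:
        if (i, j) not in cache:
            cache[(i, j)] = pairwise_align(clouds[j], clouds[i], cfg)
        return cache[(i, j)]

    if n == 2:
        return [np.eye(4), edge(0, 1).transform]

    edges: list[tuple[int, int, np.ndarray, bool]] = []   # (i, j, T_ij, is_loop)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            res = edge(i, j)
            if res.ok:
                edges.append((i, j, res.transform, j != i + 1))
                g.add_edge(i, j, transform=res.transform)
    comps = list(nx.connected_components(g))
    if len(comps) > 1:
        bad = sorted(sorted(c) for c in comps if 0 not in c)[0]
        raise ValueError(f"pose graph disconnected: recordings {bad} "
                         "have no edge to the reference component")

    # initialize along a BFS spanning tree rooted at the reference recording
    init: list[np.ndarray | None] = [None] * n
    init[0] = np.eye(4)
    for parent, child in nx.bfs_edges(g, 0):
        T = g.edges[parent, child]["transform"]
        if parent < child:                 # T maps child coords to parent frame
            init[child] = init[parent] @ T
        else:
            init[child] = init[parent] @ np.linalg.inv(T)
    x0 = np.concatenate([_se3_params(T) for T in init[1:]])

    def unpack(x: np.ndarray) -> list[np.ndarray]:
        Gs = [np.eye(4)]
        for k in range(n - 1):
            Gs.append(_se3_matrix(x[6 * k:6 * k + 6]))
        return Gs

    def residuals(x: np.ndarray) -> np.ndarray:
        Gs = unpack(x)
        out = []
        for (i, j, T_ij, _) in edges:
            # consistency: G_i @ T_ij should equal G_j
            E = np.linalg.inv(Gs[j]) @ Gs[i] @ T_ij
            rv = Rotation.from_matrix(_orthonormalize(E)[:3, :3]).as_rotvec()
            out.append(np.concatenate([rv * _ROT_WEIGHT_MM, E[:3, 3]]))
        return np.concatenate(out)

    sol = least_squares(residuals, x0, loss="soft_l1", f_scale=5.0,
                        xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=200)
    if info is not None:
        info["n_edges"] = len(edges)
        info["residual_rms"] = float(np.sqrt(np.mean(sol.fun ** 2)))
    return [_orthonormalize(T) for T in unpack(sol.x)]
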