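"""Surface deficiency labeling.

Two detectors drive view planning:

* **edge points** — depth-image pixels at a range discontinuity larger than
  ``d_thr`` against any of their 8 neighbors (self-occlusion boundaries and
  measurement dropouts);
* **density classes** — every non-edge point inside the region-of-interest
  box is *core* when more than ``n_thr`` other points of the global cloud
  lie within radius ``r``, else *outlier*; core points found within ``r``
  of a remaining outlier become *frontier* points, the boundary between
  densely and sparsely sampled surface.

Core/outlier/edge labels persist across recording cycles; frontier labels
are rebuilt from scratch each cycle (previous frontier points are returned
to core before reclassification).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .geometry import (DepthImage, Label, LabeledCloud, OrientedBBox,
                       compute_obbox)
from .scene import backproject

# 8-neighborhood offsets, row-major order
_NEIGHBOR_OFFSETS = [(-1, -1), (-1, 0), (-1, 1),
                     (0, -1), (0, 1),
                     (1, -1), (1, 0), (1, 1)]


def define_roi(first_depth: DepthImage, roi_rect, inflation: float = 0.10) -> OrientedBBox:
    """Lift a 2D wound rectangle of the first recording to an oriented box.

    The box is the covariance-aligned bounding box of the back-projected
    points whose pixels fall inside ``roi_rect = (u0, v0, u1, v1)``,
    inflated by ``inflation``.
    """
    u0, v0, u1, v1 = roi_rect
    if not (0 <= u0 <= u1 < first_depth.intrinsics.width
            and 0 <= v0 <= v1 < first_depth.intrinsics.height):
        raise ValueError("roi_rect outside image bounds")
    cloud = backproject(first_depth)
    rows = cloud.pixel_index[:, 0]
    cols = cloud.pixel_index[:, 1]
    inside = (cols >= u0) & (cols <= u1) & (rows >= v0) & (rows <= v1)
    if int(inside.sum()) < 4:
        raise ValueError("ROI empty: fewer than 4 valid pixels inside the rectangle")
    return compute_obbox(cloud.positions[inside], inflation=inflation)


def detect_edge_points(depth: DepthImage, in_bbox_pixels, d_thr: float) -> np.ndarray:
    """Depth-discontinuity detection over the given pixels.

    A pixel is an edge point when the absolute depth difference to at least
    one of its 8 neighbors exceeds ``d_thr``.  Neighbors outside the image
    are skipped; invalid (zero-depth) neighbors count as discontinuities,
    so missing-measurement boundaries produce edges.  Returns the edge
    pixels as an (K, 2) array of (row, col) in row-major order.
    """
    pix = np.asarray(in_bbox_pixels, dtype=np.int64).reshape(-1, 2)
    if len(pix) == 0:
        return np.empty((0, 2), dtype=np.int64)
    h, w = depth.values.shape
    # sentinel -1 marks out-of-image neighbors (skipped); 0 stays a
    # discontinuity because every valid depth exceeds d_thr
    padded = np.full((h + 2, w + 2), -1.0)
    padded[1:-1, 1:-1] = depth.values
    d = depth.values[pix[:, 0], pix[:, 1]]
    is_edge = np.zeros(len(pix), dtype=bool)
    for dr, dc in _NEIGHBOR_OFFSETS:
        dn = padded[pix[:, 0] + 1 + dr, pix[:, 1] + 1 + dc]
        is_edge |= (dn >= 0) & (np.abs(d - dn) > d_thr)
    out = pix[is_edge]
    order = np.lexsort((out[:, 1], out[:, 0]))
    return out[order]


def classify_points(state: LabeledCloud, new_in_bbox, r: float, n_thr: int) -> LabeledCloud:
    """Update core/outlier labels and rebuild frontier labels.

    ``new_in_bbox`` are indices (into ``state``) of the new recording's
    in-box points with edge points already excluded.  Candidates are those
    new points plus all previously-outlier points; a candidate becomes core
    when strictly more than ``n_thr`` *other* points of the whole cloud lie
    within ``r`` of it.  Previously-core points are never demoted.  Then
    every core point within ``r`` of a remaining outlier is relabeled
    frontier.  Modifies and returns ``state``.
    """
    labels = state.labels
    # frontier points were taken out of the core set last cycle; return them
    labels[labels == Label.FRONTIER] = Label.CORE

    new_idx = np.asarray(new_in_bbox, dtype=np.int64).reshape(-1)
    if np.any(labels[new_idx] == Label.EDGE):
        raise ValueError("edge points must be excluded from new_in_bbox")
    outlier_idx = state.indices_with(Label.OUTLIER)
    candidates = np.unique(np.concatenate([new_idx, outlier_idx]))
    if len(candidates) == 0:
        return state

    tree = cKDTree(state.positions)
    # count excludes the query point itself (strict: count > n_thr)
    counts = tree.query_ball_point(state.positions[candidates], r,
                                   return_length=True) - 1
    is_core = counts > n_thr
    labels[candidates[is_core]] = Label.CORE
    labels[candidates[~is_core]] = Label.OUTLIER

    # frontier: core points in the neighborhood of any remaining outlier
    outlier_idx = state.indices_with(Label.OUTLIER)
    if len(outlier_idx):
        hits = tree.query_ball_point(state.positions[outlier_idx], r)
        near = np.unique(np.concatenate([np.asarray(h, dtype=np.int64) for h in hits]))
        near = near[labels[near] == Label.CORE]
        labels[near] = Label.FRONTIER
    return state
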