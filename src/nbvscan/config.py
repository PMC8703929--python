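"""Scan configuration: every tunable parameter of the recording loop.

All distances are millimeters; angles are degrees unless a field name says
otherwise.  Defaults are the operating point of the scanning method: a 15 mm
depth-discontinuity threshold, a 60-neighbor / 2 mm density requirement, a
650 mm recording distance and score weights (0.8, 100, 0.2).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml


@dataclass
class ScanConfig:
    # --- surface deficiency detection ---
    d_thr: float = 15.0          # depth-image edge threshold, mm
    r: float = 2.0               # density neighborhood radius, mm
    n_thr: int = 60              # neighbor count required for a core point
    # --- recording geometry ---
    d_rec: float = 650.0         # recording (stand-off) distance, mm
    # --- hypothesis scoring: score = alpha*N_v + beta*exp(-2 d[m]) + gamma*N_h ---
    alpha: float = 0.8
    beta: float = 100.0
    gamma: float = 0.2
    # --- DPlane construction ---
    e_thr: float = 10.0          # eigenvalue ratio above which a cluster is line-like
    o_thr: float = 0.95          # overlap fraction that invalidates a DPlane
    perp_band_deg: tuple[float, float] = (80.0, 90.0)  # undecidable normal band
    vis_cos_max: float = math.cos(math.radians(60.0))  # visibility cone half-angle cosine
    ransac_inlier_dist: float = 2.0   # plane consensus inlier distance, mm
    ransac_iters: int = 1000
    # --- cluster-count scaling: no_c = min_c + floor(count / step_c) ---
    min_c_frontier: int = 1
    step_c_frontier: int = 100
    min_c_edge: int = 1
    step_c_edge: int = 250
    # --- downsampling / registration ---
    voxel_fine: float = 2.0      # mm, ICP working resolution
    voxel_coarse: float = 20.0   # mm, descriptor/coarse-match resolution
    icp_coarse_dist: float = 10.0   # mm, max correspondence, coarse ICP
    icp_fine_dist: float = 5.0      # mm, max correspondence, fine ICP
    fitness_floor: float = 0.2      # pairwise fitness below this flags failure
    voxel_final: float = 1.0        # mm, final output filtering
    bbox_inflation: float = 0.10
    normal_radius: float = 2.0      # mm, normal-estimation neighborhood
    # --- pose selection ---
    proximity_min_dist: float = 150.0  # mm, keep-away radius around past recordings
    sphere_cap_deg: float = 30.0       # sphere-slice polar cap half-angle
    sphere_n_azimuth: int = 12
    sphere_n_elevation: int = 4
    # --- loop control ---
    max_cycles: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("d_thr", "r", "d_rec", "voxel_fine", "voxel_coarse",
                     "icp_coarse_dist", "icp_fine_dist", "voxel_final",
                     "proximity_min_dist", "normal_radius", "ransac_inlier_dist"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0.0 < self.o_thr <= 1.0):
            raise ValueError("o_thr must be in (0, 1]")
        for name in ("alpha", "beta", "gamma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.perp_band_deg
        if not (0.0 <= lo < hi <= 90.0):
            raise ValueError("perp_band_deg must satisfy 0 <= lo < hi <= 90")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["perp_band_deg"] = list(d["perp_band_deg"])
        return d


_FIELD_TYPES = {f.name: f for f in dataclasses.fields(ScanConfig)}


def config_from_mapping(data: Mapping[str, Any] | None) -> ScanConfig:
    """Build a ScanConfig from a (possibly partial) mapping.

    Unknown keys are rejected; values of the wrong type raise a ``TypeError``
    naming the key.  Missing keys take the defaults above.
    """
    data = dict(data or {})
    kwargs: dict[str, Any] = {}
    for key, value in data.items():
        if key not in _FIELD_TYPES:
            raise KeyError(f"unknown config key: {key!r}")
        if key == "perp_band_deg":
            if (not isinstance(value, (list, tuple)) or len(value) != 2
                    or not all(isinstance(v, (int, float)) and not isinstance(v, bool) for v in value)):
                raise TypeError("config key 'perp_band_deg' must be a pair of numbers")
            kwargs[key] = (float(value[0]), float(value[1]))
            continue
        default = _FIELD_TYPES[key].default
        if isinstance(default, bool):
            if not isinstance(value, bool):
                raise TypeError(f"config key {key!r} must be a boolean")
            kwargs[key] = value
        elif isinstance(default, int):
            if isinstance(value, bool) or not isinstance(value, int):
                raise TypeError(f"config key {key!r} must be an integer")
            kwargs[key] = value
        elif isinstance(default, float):
            if isinstance(value, bool) or not isinstance(value, (int, float)):
                raise TypeError(f"config key {key!r} must be a number")
            kwargs[key] = float(value)
        else:
            kwargs[key] = value
    return ScanConfig(**kwargs)


def load_config(path: str) -> ScanConfig:
    """Load a YAML config file; an empty file yields all defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise TypeError("config file must contain a YAML mapping")
    return config_from_mapping(data)


def save_config(cfg: ScanConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
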