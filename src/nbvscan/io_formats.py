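"""Readers and writers for clouds, depth images, poses and configs.

Labeled point clouds round-trip through ASCII PLY or PCD with the custom
per-point scalars (label, recording index, source pixel) that no generic
mesh library preserves; depth images go to 16-bit PNG (1 unit = 1 mm) or
raw ``.npy`` float arrays, either with a JSON sidecar carrying intrinsics
and pose.  All persisted distances are millimeters; quaternions are
(w, x, y, z) with w >= 0.
"""

from __future__ import annotations

import dataclasses
import json
import os

import imageio.v3 as iio
import numpy as np

from .geometry import CameraIntrinsics, DepthImage, LabeledCloud, Pose

_PLY_FIELDS = [("x", "double"), ("y", "double"), ("z", "double"),
               ("nx", "double"), ("ny", "double"), ("nz", "double"),
               ("label", "uchar"), ("recording_index", "int"),
               ("pixel_row", "int"), ("pixel_col", "int"),
               ("normal_valid", "uchar")]


def write_cloud(path: str, cloud: LabeledCloud) -> None:
    """Write a labeled cloud as ASCII PLY or PCD (by extension)."""
    ext = os.path.splitext(path)[1].lower()
    if ext == ".ply":
        _write_ply(path, cloud)
    elif ext == ".pcd":
        _write_pcd(path, cloud)
    else:
        raise ValueError(f"unknown cloud extension {ext!r} (want .ply or .pcd)")


def read_cloud(path: str) -> LabeledCloud:
    ext = os.path.splitext(path)[1].lower()
    if ext == ".ply":
        return _read_ply(path)
    if ext == ".pcd":
        return _read_pcd(path)
    raise ValueError(f"unknown cloud extension {ext!r} (want .ply or .pcd)")


def _cloud_rows(cloud: LabeledCloud) -> np.ndarray:
    return np.column_stack([
        cloud.positions, cloud.normals, cloud.labels,
        cloud.recording_index, cloud.pixel_index,
        cloud.normal_valid.astype(int)])


def _cloud_from_columns(cols: dict[str, np.ndarray], n: int) -> LabeledCloud:
    def get(names, default):
        if all(name in cols for name in names):
            return np.column_stack([cols[n_] for n_ in names]) if len(names) > 1 \
                else cols[names[0]]
        return default
    positions = get(["x", "y", "z"], None)
    if positions is None:
        raise ValueError("cloud file lacks x/y/z fields")
    return LabeledCloud(
        positions=positions,
        normals=get(["nx", "ny", "nz"], np.zeros((n, 3))),
        labels=get(["label"], np.zeros(n)).astype(np.uint8),
        recording_index=get(["recording_index"], np.zeros(n)).astype(np.int32),
        pixel_index=get(["pixel_row", "pixel_col"],
                        np.full((n, 2), -1)).astype(np.int32),
        normal_valid=get(["normal_valid"],
                         np.zeros(n)).astype(bool))


def _write_ply(path: str, cloud: LabeledCloud) -> None:
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(cloud)}\n")
        for name, typ in _PLY_FIELDS:
            fh.write(f"property {typ} {name}\n")
        fh.write("end_header\n")
        for row in _cloud_rows(cloud):
            fh.write(" ".join(f"{v:.10g}" if i < 6 else str(int(v))
                              for i, v in enumerate(row)) + "\n")


def _read_ply(path: str) -> LabeledCloud:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].strip() != "ply":
        raise ValueError(f"{path}: not a PLY file (missing 'ply' magic)")
    names: list[str] = []
    n = None
    body_at = None
    element = None
    for i, line in enumerate(lines[1:], start=1):
        tok = line.split()
        if not tok:
            continue
        if tok[0] == "format" and tok[1] != "ascii":
            raise ValueError(f"{path}:{i + 1}: only ASCII PLY is supported")
        if tok[0] == "element":
            element = tok[1]
            if element == "vertex":
                n = int(tok[2])
        elif tok[0] == "property" and element == "vertex":
            names.append(tok[-1])
        elif tok[0] == "end_header":
            body_at = i + 1
            break
    if n is None or body_at is None:
        raise ValueError(f"{path}: malformed PLY header (no vertex element)")
    rows = []
    for j, line in enumerate(lines[body_at:body_at + n]):
        vals = line.split()
        if len(vals) != len(names):
            raise ValueError(f"{path}: line {body_at + j + 1}: expected "
                             f"{len(names)} fields, got {len(vals)}")
        rows.append([float(v) for v in vals])
    if len(rows) != n:
        raise ValueError(f"{path}: expected {n} vertex rows, got {len(rows)}")
    data = np.asarray(rows, dtype=float).reshape(len(rows), len(names))
    cols = {name: data[:, k] for k, name in enumerate(names)}
    return _cloud_from_columns(cols, n)


def _write_pcd(path: str, cloud: LabeledCloud) -> None:
    names = [f for f, _ in _PLY_FIELDS]
    with open(path, "w") as fh:
        fh.write("# .PCD v0.7 - Point Cloud Data file format\n")
        fh.write("VERSION 0.7\n")
        fh.write("FIELDS " + " ".join(names) + "\n")
        fh.write("SIZE " + " ".join(["8"] * 6 + ["4"] * 5) + "\n")
        fh.write("TYPE " + " ".join(["F"] * 6 + ["I"] * 5) + "\n")
        fh.write("COUNT " + " ".join(["1"] * 11) + "\n")
        fh.write(f"WIDTH {len(cloud)}\nHEIGHT 1\n")
        fh.write("VIEWPOINT 0 0 0 1 0 0 0\n")
        fh.write(f"POINTS {len(cloud)}\nDATA ascii\n")
        for row in _cloud_rows(cloud):
            fh.write(" ".join(f"{v:.10g}" if i < 6 else str(int(v))
                              for i, v in enumerate(row)) + "\n")


def _read_pcd(path: str) -> LabeledCloud:
    names: list[str] | None = None
    n = None
    rows = []
    with open(path) as fh:
        in_data = False
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tok = line.split()
            if not in_data:
                if tok[0] == "FIELDS":
                    names = tok[1:]
                elif tok[0] == "POINTS":
                    n = int(tok[1])
                elif tok[0] == "DATA":
                    if tok[1] != "ascii":
                        raise ValueError(f"{path}:{lineno}: only ASCII PCD is supported")
                    in_data = True
                continue
            if names is None:
                raise ValueError(f"{path}:{lineno}: data before FIELDS header")
            if len(tok) != len(names):
                raise ValueError(f"{path}:{lineno}: expected {len(names)} "
                                 f"fields, got {len(tok)}")
            rows.append([float(v) for v in tok])
    if names is None or n is None:
        raise ValueError(f"{path}: malformed PCD header")
    if len(rows) != n:
        raise ValueError(f"{path}: expected {n} points, got {len(rows)}")
    data = np.asarray(rows, dtype=float).reshape(len(rows), len(names))
    cols = {name: data[:, k] for k, name in enumerate(names)}
    return _cloud_from_columns(cols, n)


# ---------------------------------------------------------------------------
# poses and depth images
# ---------------------------------------------------------------------------

def pose_to_dict(pose: Pose) -> dict:
    return {"position_mm": pose.position.tolist(),
            "quaternion_wxyz": pose.quaternion.tolist()}


def pose_from_dict(d: dict) -> Pose:
    return Pose.from_quaternion(d["position_mm"], d["quaternion_wxyz"])


def _sidecar_path(path: str) -> str:
    return path + ".json"


def write_depth(path: str, image: DepthImage) -> None:
    """Write a depth image (.png 16-bit, 1 = 1 mm, or raw .npy) + sidecar."""
    ext = os.path.splitext(path)[1].lower()
    if ext == ".png":
        if np.any(image.values > 65535):
            raise ValueError("out of range: depth > 65535 mm cannot be "
                             "stored in 16-bit PNG")
        iio.imwrite(path, np.round(image.values).astype(np.uint16))
    elif ext == ".npy":
        np.save(path, image.values)
    else:
        raise ValueError(f"unknown depth extension {ext!r} (want .png or .npy)")
    meta = {"intrinsics": dataclasses.asdict(image.intrinsics),
            "pose": pose_to_dict(image.pose),
            "recording_index": image.recording_index}
    with open(_sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=1)


def read_depth(path: str) -> DepthImage:
    sidecar = _sidecar_path(path)
    if not os.path.exists(sidecar):
        raise FileNotFoundError(f"missing sidecar {sidecar}")
    with open(sidecar) as fh:
        meta = json.load(fh)
    ext = os.path.splitext(path)[1].lower()
    if ext == ".png":
        values = iio.imread(path).astype(float)
    elif ext == ".npy":
        values = np.load(path)
    else:
        raise ValueError(f"unknown depth extension {ext!r} (want .png or .npy)")
    return DepthImage(values=values,
                      intrinsics=CameraIntrinsics(**meta["intrinsics"]),
                      pose=pose_from_dict(meta["pose"]),
                      recording_index=meta.get("recording_index", 0))
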