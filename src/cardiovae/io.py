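"""File formats: labeled PLY point clouds, single-column ECG CSV, YAML configs.

PLY vertices carry float ``x, y, z`` plus a uchar ``class`` property
(0 = LV endocardium, 1 = LV epicardium, 2 = RV endocardium).  The reader
accepts ASCII and binary little-endian files; the writer emits binary
little-endian with float32 coordinates.  Round trips are bit-exact at
float32 precision and label-exact.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import yaml

from .structures import (
    AnatomyPointCloud, CLASS_ORDER, ECGTrace, Normalization, Phase, PointClass,
)

__all__ = [
    "read_labeled_pointcloud", "write_labeled_pointcloud",
    "read_ecg_csv", "write_ecg_csv", "load_config", "save_config",
]

_VALID_CLASS_IDS = {int(c) for c in CLASS_ORDER}


class PLYFormatError(ValueError):
    pass


def write_labeled_pointcloud(pc: AnatomyPointCloud, path: str | Path) -> None:
    """Write a labeled cloud as binary little-endian PLY (float32 + uchar class)."""
    stacked = pc.stacked()
    n = stacked.shape[0]
    dtype = np.dtype([("x", "<f4"), ("y", "<f4"), ("z", "<f4"), ("class", "u1")])
    rec = np.empty(n, dtype=dtype)
    rec["x"] = stacked[:, 0].astype(np.float32)
    rec["y"] = stacked[:, 1].astype(np.float32)
    rec["z"] = stacked[:, 2].astype(np.float32)
    rec["class"] = stacked[:, 3].astype(np.uint8)
    header = (
        "ply\n"
        "format binary_little_endian 1.0\n"
        f"comment phase {pc.phase.value}\n"
        f"element vertex {n}\n"
        "property float x\n"
        "property float y\n"
        "property float z\n"
        "property uchar class\n"
        "end_header\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(rec.tobytes())


_PLY_TYPES = {
    "float": "<f4", "float32": "<f4", "double": "<f8", "float64": "<f8",
    "uchar": "u1", "uint8": "u1", "char": "i1", "int8": "i1",
    "short": "<i2", "int16": "<i2", "ushort": "<u2", "uint16": "<u2",
    "int": "<i4", "int32": "<i4", "uint": "<u4", "uint32": "<u4",
}


def read_labeled_pointcloud(path: str | Path,
                            phase: Phase | str | None = None) -> AnatomyPointCloud:
    """Read a PLY with per-vertex class labels into an :class:`AnatomyPointCloud`.

    The phase is taken from the file's ``comment phase`` line unless given.
    """
    with open(path, "rb") as fh:
        raw = fh.read()
    if not raw.startswith(b"ply"):
        raise PLYFormatError("not a PLY file")
    end = raw.find(b"end_header\n")
    if end < 0:
        raise PLYFormatError("missing end_header")
    header = raw[:end].decode("ascii", errors="replace").splitlines()
    body = raw[end + len(b"end_header\n"):]

    fmt = None
    n_vertex = None
    props: list[tuple[str, str]] = []
    in_vertex = False
    file_phase = None
    for line in header[1:]:
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "format":
            fmt = parts[1]
        elif parts[0] == "comment" and len(parts) >= 3 and parts[1] == "phase":
            file_phase = parts[2]
        elif parts[0] == "element":
            in_vertex = parts[1] == "vertex"
            if in_vertex:
                n_vertex = int(parts[2])
        elif parts[0] == "property" and in_vertex:
            if parts[1] == "list":
                raise PLYFormatError("list properties unsupported for vertices")
            props.append((parts[2], parts[1]))
    if fmt not in ("ascii", "binary_little_endian"):
        raise PLYFormatError(f"unsupported PLY format {fmt!r}")
    if n_vertex is None:
        raise PLYFormatError("no vertex element")
    names = [p[0] for p in props]
    for needed in ("x", "y", "z"):
        if needed not in names:
            raise PLYFormatError(f"missing vertex property {needed!r}")
    if "class" not in names:
        raise PLYFormatError("missing per-vertex 'class' property")

    if fmt == "binary_little_endian":
        dtype = np.dtype([(nm, _PLY_TYPES[ty]) for nm, ty in props])
        rec = np.frombuffer(body, dtype=dtype, count=n_vertex)
    else:
        text = body.decode("ascii")
        table = np.loadtxt(_io.StringIO(text), max_rows=n_vertex, ndmin=2)
        if table.shape[1] != len(props):
            raise PLYFormatError("ascii vertex row width mismatch")
        rec = {nm: table[:, i] for i, (nm, _) in enumerate(props)}

    xyz = np.column_stack([np.asarray(rec["x"], dtype=np.float64),
                           np.asarray(rec["y"], dtype=np.float64),
                           np.asarray(rec["z"], dtype=np.float64)])
    labels = np.asarray(rec["class"]).astype(np.int64)
    bad = set(np.unique(labels)) - _VALID_CLASS_IDS
    if bad:
        raise PLYFormatError(f"unknown class id(s) {sorted(bad)}; expected 0/1/2")

    points_by_class = {}
    for cls in CLASS_ORDER:
        pts = xyz[labels == int(cls)]
        if pts.shape[0] == 0:
            raise PLYFormatError(f"class {cls.name} has no points")
        points_by_class[cls] = pts
    if phase is None:
        if file_phase is None:
            raise PLYFormatError("phase not stored in file; pass phase= explicitly")
        phase = file_phase
    return AnatomyPointCloud(points_by_class, Phase(phase))


def write_ecg_csv(trace: ECGTrace, path: str | Path) -> None:
    """Single column 'value', one sample per row."""
    with open(path, "w") as fh:
        fh.write("value\n")
        for v in trace.samples:
            fh.write(f"{float(v)!r}\n")


def read_ecg_csv(path: str | Path, expected_length: int | None = None,
                 normalization: Normalization | str = Normalization.RAW) -> ECGTrace:
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if lines and lines[0].lower() in ("value", '"value"'):
        lines = lines[1:]
    try:
        samples = np.array([float(v) for v in lines], dtype=np.float64)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in ECG CSV {path}: {exc}") from exc
    if expected_length is not None and samples.size != expected_length:
        raise ValueError(
            f"ECG CSV {path} has {samples.size} samples, expected {expected_length}")
    return ECGTrace(samples, Normalization(normalization))


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def save_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
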