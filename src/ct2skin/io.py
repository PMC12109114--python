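"""Point-cloud file I/O: PLY (ASCII and binary little-endian), PCD, XYZ.

The format is chosen by file extension.  All three formats store bare XYZ
coordinates in millimetres; readers accept the files this module writes (plus
common minor variations) and are intended for interchange with standard
point-cloud tooling, not as general-purpose parsers.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np

from .cloud import PointCloud

__all__ = ["write_cloud", "read_cloud"]


def write_cloud(cloud: PointCloud, path: str | os.PathLike, binary: bool = True) -> Path:
    """Write a cloud to ``path``; format from extension (.ply/.pcd/.xyz)."""
    path = Path(path)
    ext = path.suffix.lower()
    if ext == ".ply":
        _write_ply(cloud.points, path, binary=binary)
    elif ext == ".pcd":
        _write_pcd(cloud.points, path, binary=binary)
    elif ext == ".xyz":
        np.savetxt(path, cloud.points, fmt="%.6f")
    else:
        raise ValueError(f"unsupported point-cloud extension {ext!r} (use .ply/.pcd/.xyz)")
    return path


def read_cloud(path: str | os.PathLike, source_plane: str = "unknown") -> PointCloud:
    path = Path(path)
    ext = path.suffix.lower()
    if ext == ".ply":
        pts = _read_ply(path)
    elif ext == ".pcd":
        pts = _read_pcd(path)
    elif ext == ".xyz":
        pts = np.loadtxt(path, ndmin=2)[:, :3]
    else:
        raise ValueError(f"unsupported point-cloud extension {ext!r} (use .ply/.pcd/.xyz)")
    return PointCloud(points=pts, source_plane=source_plane)


# ---------------------------------------------------------------------------
# PLY
# ---------------------------------------------------------------------------


def _write_ply(points: np.ndarray, path: Path, binary: bool) -> None:
    fmt = "binary_little_endian" if binary else "ascii"
    header = (
        "ply\n"
        f"format {fmt} 1.0\n"
        f"element vertex {len(points)}\n"
        "property float x\n"
        "property float y\n"
        "property float z\n"
        "end_header\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        if binary:
            fh.write(points.astype("<f4").tobytes())
        else:
            np.savetxt(fh, points, fmt="%.6f")


def _read_ply(path: Path) -> np.ndarray:
    with open(path, "rb") as fh:
        line = fh.readline().strip()
        if line != b"ply":
            raise ValueError(f"{path} is not a PLY file")
        fmt = None
        n_vertex = None
        props: list[str] = []
        while True:
            line = fh.readline()
            if not line:
                raise ValueError("unterminated PLY header")
            tokens = line.decode("ascii").strip().split()
            if not tokens:
                continue
            if tokens[0] == "format":
                fmt = tokens[1]
            elif tokens[0] == "element" and tokens[1] == "vertex":
                n_vertex = int(tokens[2])
            elif tokens[0] == "property" and n_vertex is not None:
                props.append(tokens[2])
            elif tokens[0] == "end_header":
                break
        if n_vertex is None or fmt is None:
            raise ValueError("PLY header lacks a vertex element")
        if props[:3] != ["x", "y", "z"]:
            raise ValueError(f"expected x/y/z leading vertex properties, got {props}")
        if fmt == "ascii":
            data = np.loadtxt(fh, max_rows=n_vertex, ndmin=2)
            return data[:, :3].astype(np.float64)
        if fmt != "binary_little_endian":
            raise ValueError(f"unsupported PLY format {fmt}")
        raw = fh.read(4 * len(props) * n_vertex)
        arr = np.frombuffer(raw, dtype="<f4").reshape(n_vertex, len(props))
        return arr[:, :3].astype(np.float64)


# ---------------------------------------------------------------------------
# PCD
# ---------------------------------------------------------------------------


def _write_pcd(points: np.ndarray, path: Path, binary: bool) -> None:
    n = len(points)
    header = (
        "# .PCD v0.7 - Point Cloud Data file format\n"
        "VERSION 0.7\n"
        "FIELDS x y z\n"
        "SIZE 4 4 4\n"
        "TYPE F F F\n"
        "COUNT 1 1 1\n"
        f"WIDTH {n}\n"
        "HEIGHT 1\n"
        "VIEWPOINT 0 0 0 1 0 0 0\n"
        f"POINTS {n}\n"
        f"DATA {'binary' if binary else 'ascii'}\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        if binary:
            fh.write(points.astype("<f4").tobytes())
        else:
            np.savetxt(fh, points, fmt="%.6f")


def _read_pcd(path: Path) -> np.ndarray:
    with open(path, "rb") as fh:
        n = None
        data_mode = None
        fields = None
        while True:
            line = fh.readline()
            if not line:
                raise ValueError("unterminated PCD header")
            tokens = line.decode("ascii", errors="replace").strip().split()
            if not tokens or tokens[0].startswith("#"):
                continue
            if tokens[0] == "FIELDS":
                fields = tokens[1:]
            elif tokens[0] == "POINTS":
                n = int(tokens[1])
            elif tokens[0] == "DATA":
                data_mode = tokens[1]
                break
        if n is None or fields is None:
            raise ValueError("PCD header lacks POINTS/FIELDS")
        if fields[:3] != ["x", "y", "z"]:
            raise ValueError(f"expected x/y/z leading fields, got {fields}")
        if data_mode == "ascii":
            data = np.loadtxt(fh, max_rows=n, ndmin=2)
            return data[:, :3].astype(np.float64)
        if data_mode != "binary":
            raise ValueError(f"unsupported PCD data mode {data_mode}")
        raw = fh.read(4 * len(fields) * n)
        arr = np.frombuffer(raw, dtype="<f4").reshape(n, len(fields))
        return arr[:, :3].astype(np.float64)
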