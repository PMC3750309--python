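"""Point-cloud file I/O and preprocessing.

All coordinates are millimetres throughout the package; no unit
autodetection is attempted.  Three on-disk dialects are supported:

* plain ``xyz`` text — whitespace-separated columns, an optional fourth
  integer column holding a per-point class label, ``#`` comments ignored;
* PLY (ascii and binary little-endian) with float/double ``x y z`` vertex
  properties and an optional integer ``label`` property;
* PCD v0.7 (ascii and binary) with fields ``x y z`` and optional ``label``.

Labels are integers; ``-1`` is reserved for unlabeled / unclassifiable
points.  Preprocessing mirrors the manual steps a scan operator would
otherwise perform interactively: cropping by height and rasterization
(greedy minimum-distance thinning) to enforce a minimal point-to-point
distance, here called the cloud *resolution*.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "PointCloud",
    "read_cloud",
    "write_cloud",
    "read_label_sidecar",
    "write_label_sidecar",
    "crop_by_height",
    "rasterize",
    "greedy_thin_indices",
]

UNLABELED = -1


@dataclass
class PointCloud:
    """N points in mm with optional per-point integer labels.

    Parameters
    ----------
    points
        ``(n, 3)`` float array of coordinates in millimetres.
    labels
        Optional ``(n,)`` integer array; ``-1`` marks unlabeled points.
    viewpoint
        Optional sensor position used to orient normals.
    resolution_hint
        Minimal point-to-point distance of the cloud, when known (mm).
    """

    points: np.ndarray
    labels: Optional[np.ndarray] = None
    viewpoint: Optional[np.ndarray] = None
    resolution_hint: Optional[float] = None
    meta: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError(f"points must be (n, 3), got {self.points.shape}")
        if not np.isfinite(self.points).all():
            raise ValueError("points contain non-finite coordinates")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
            if self.labels.shape != (len(self.points),):
                raise ValueError("labels length must match point count")
        if self.viewpoint is not None:
            self.viewpoint = np.asarray(self.viewpoint, dtype=np.float64).reshape(3)
        if self.resolution_hint is not None and not self.resolution_hint > 0:
            raise ValueError("resolution_hint must be > 0")

    def __len__(self) -> int:
        return len(self.points)

    def subset(self, indices: np.ndarray) -> "PointCloud":
        """Return the cloud restricted to ``indices`` (order preserved)."""
        indices = np.asarray(indices)
        return PointCloud(
            points=self.points[indices],
            labels=None if self.labels is None else self.labels[indices],
            viewpoint=None if self.viewpoint is None else self.viewpoint.copy(),
            resolution_hint=self.resolution_hint,
            meta=dict(self.meta),
        )

    def with_labels(self, labels: np.ndarray) -> "PointCloud":
        return PointCloud(
            points=self.points,
            labels=labels,
            viewpoint=self.viewpoint,
            resolution_hint=self.resolution_hint,
            meta=dict(self.meta),
        )


# ---------------------------------------------------------------------------
# readers / writers


def _detect_format(path: str) -> str:
    ext = os.path.splitext(path)[1].lower()
    if ext == ".ply":
        return "ply"
    if ext == ".pcd":
        return "pcd"
    return "xyz"


def read_cloud(path: str, format: str = "auto") -> PointCloud:
    """Read a point cloud from ``path``.

    ``format`` is one of ``ply``, ``pcd``, ``xyz`` or ``auto`` (extension
    based).  A per-point integer scalar named ``label`` (PLY/PCD) or a
    fourth text column (xyz) populates ``labels``; point order is
    preserved.
    """
    if format == "auto":
        format = _detect_format(path)
    if format == "xyz":
        return _read_xyz(path)
    if format == "ply":
        return _read_ply(path)
    if format == "pcd":
        return _read_pcd(path)
    raise ValueError(f"unknown format {format!r}")


def write_cloud(cloud: PointCloud, path: str, format: str = "auto",
                binary: bool = False) -> str:
    """Write ``cloud`` to ``path``; returns the path written."""
    if len(cloud) == 0:
        raise ValueError("refusing to write an empty point cloud")
    if format == "auto":
        format = _detect_format(path)
    if format == "xyz":
        _write_xyz(cloud, path)
    elif format == "ply":
        _write_ply(cloud, path, binary=binary)
    elif format == "pcd":
        _write_pcd(cloud, path, binary=binary)
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def _read_xyz(path: str) -> PointCloud:
    try:
        data = np.loadtxt(path, comments="#", ndmin=2, dtype=np.float64)
    except ValueError as exc:
        raise ValueError(f"cannot parse xyz file {path}: {exc}") from exc
    if data.size == 0:
        raise ValueError(f"empty point cloud in {path}")
    if data.shape[1] == 3:
        return PointCloud(points=data)
    if data.shape[1] == 4:
        return PointCloud(points=data[:, :3], labels=data[:, 3].astype(np.int64))
    raise ValueError(
        f"xyz file {path} has {data.shape[1]} columns; expected 3 or 4")


def _write_xyz(cloud: PointCloud, path: str) -> None:
    if cloud.labels is None:
        np.savetxt(path, cloud.points, fmt="%.10g")
    else:
        with open(path, "w") as fh:
            for p, l in zip(cloud.points, cloud.labels):
                fh.write(f"{p[0]:.10g} {p[1]:.10g} {p[2]:.10g} {int(l)}\n")


_PLY_TYPES = {
    "char": "i1", "int8": "i1", "uchar": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2", "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4", "uint": "u4", "uint32": "u4",
    "float": "f4", "float32": "f4", "double": "f8", "float64": "f8",
}


def _read_ply(path: str) -> PointCloud:
    with open(path, "rb") as fh:
        line = fh.readline().strip()
        if line != b"ply":
            raise ValueError(f"{path}: not a PLY file (missing 'ply' magic)")
        fmt = None
        elements = []  # (name, count, [(prop, dtype_code)])
        while True:
            raw = fh.readline()
            if not raw:
                raise ValueError(f"{path}: unexpected EOF in PLY header")
            line = raw.decode("ascii", "replace").strip()
            if line.startswith("comment") or line.startswith("obj_info") or not line:
                continue
            tok = line.split()
            if tok[0] == "format":
                fmt = tok[1]
            elif tok[0] == "element":
                elements.append((tok[1], int(tok[2]), []))
            elif tok[0] == "property":
                if tok[1] == "list":
                    elements[-1][2].append((tok[-1], "list", tok[2], tok[3]))
                else:
                    if tok[1] not in _PLY_TYPES:
                        raise ValueError(f"{path}: unsupported PLY type {tok[1]}")
                    elements[-1][2].append((tok[2], _PLY_TYPES[tok[1]]))
            elif tok[0] == "end_header":
                break
        if fmt not in ("ascii", "binary_little_endian"):
            raise ValueError(f"{path}: unsupported PLY format {fmt!r}")
        vertex = next((e for e in elements if e[0] == "vertex"), None)
        if vertex is None or vertex[1] == 0:
            raise ValueError(f"{path}: PLY file contains no vertices")
        if elements[0][0] != "vertex":
            raise ValueError(f"{path}: expected 'vertex' as first PLY element")
        name_code = vertex[2]
        if any(len(p) > 2 for p in name_code):
            raise ValueError(f"{path}: list properties on vertices unsupported")
        names = [p[0] for p in name_code]
        if fmt == "ascii":
            rows = []
            for i in range(vertex[1]):
                raw = fh.readline()
                if not raw:
                    raise ValueError(f"{path}: truncated at vertex {i}")
                vals = raw.split()
                if len(vals) != len(names):
                    raise ValueError(f"{path}: bad vertex record at line {i}")
                rows.append([float(v) for v in vals])
            data = {n: np.array([r[k] for r in rows]) for k, n in enumerate(names)}
        else:
            dtype = np.dtype([(n, "<" + c) for n, c in name_code])
            buf = fh.read(dtype.itemsize * vertex[1])
            if len(buf) < dtype.itemsize * vertex[1]:
                raise ValueError(f"{path}: truncated PLY binary payload")
            rec = np.frombuffer(buf, dtype=dtype)
            data = {n: rec[n] for n in names}
    for c in ("x", "y", "z"):
        if c not in data:
            raise ValueError(f"{path}: vertex property {c!r} missing")
    pts = np.column_stack([data["x"], data["y"], data["z"]]).astype(np.float64)
    labels = data["label"].astype(np.int64) if "label" in data else None
    return PointCloud(points=pts, labels=labels)


def _write_ply(cloud: PointCloud, path: str, binary: bool = False) -> None:
    has_labels = cloud.labels is not None
    header = ["ply",
              f"format {'binary_little_endian' if binary else 'ascii'} 1.0",
              f"element vertex {len(cloud)}",
              "property double x", "property double y", "property double z"]
    if has_labels:
        header.append("property int label")
    header.append("end_header")
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if binary:
            fields = [("x", "<f8"), ("y", "<f8"), ("z", "<f8")]
            if has_labels:
                fields.append(("label", "<i4"))
            rec = np.empty(len(cloud), dtype=np.dtype(fields))
            rec["x"], rec["y"], rec["z"] = cloud.points.T
            if has_labels:
                rec["label"] = cloud.labels
            fh.write(rec.tobytes())
        else:
            for i, p in enumerate(cloud.points):
                row = f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}"
                if has_labels:
                    row += f" {int(cloud.labels[i])}"
                fh.write((row + "\n").encode("ascii"))


def _read_pcd(path: str) -> PointCloud:
    with open(path, "rb") as fh:
        header: dict[str, list[str]] = {}
        while True:
            raw = fh.readline()
            if not raw:
                raise ValueError(f"{path}: unexpected EOF in PCD header")
            line = raw.decode("ascii", "replace").strip()
            if line.startswith("#") or not line:
                continue
            tok = line.split()
            header[tok[0]] = tok[1:]
            if tok[0] == "DATA":
                break
        for key in ("FIELDS", "SIZE", "TYPE", "POINTS", "DATA"):
            if key not in header:
                raise ValueError(f"{path}: PCD header missing {key}")
        fields = header["FIELDS"]
        sizes = [int(s) for s in header["SIZE"]]
        types = header["TYPE"]
        counts = [int(c) for c in header.get("COUNT", ["1"] * len(fields))]
        if any(c != 1 for c in counts):
            raise ValueError(f"{path}: PCD COUNT != 1 unsupported")
        n = int(header["POINTS"][0])
        if n == 0:
            raise ValueError(f"{path}: empty point cloud")
        mode = header["DATA"][0]
        codes = [f"{'f' if t == 'F' else ('i' if t == 'I' else 'u')}{s}"
                 for t, s in zip(types, sizes)]
        if mode == "ascii":
            data = np.loadtxt(fh, ndmin=2, dtype=np.float64)
            if data.shape != (n, len(fields)):
                raise ValueError(f"{path}: PCD payload shape {data.shape} != "
                                 f"({n}, {len(fields)})")
            cols = {f: data[:, k] for k, f in enumerate(fields)}
        elif mode == "binary":
            dtype = np.dtype([(f, "<" + c) for f, c in zip(fields, codes)])
            buf = fh.read(dtype.itemsize * n)
            if len(buf) < dtype.itemsize * n:
                raise ValueError(f"{path}: truncated PCD binary payload")
            rec = np.frombuffer(buf, dtype=dtype)
            cols = {f: rec[f] for f in fields}
        else:
            raise ValueError(f"{path}: unsupported PCD data mode {mode!r}")
    for c in ("x", "y", "z"):
        if c not in cols:
            raise ValueError(f"{path}: PCD field {c!r} missing")
    pts = np.column_stack([cols["x"], cols["y"], cols["z"]]).astype(np.float64)
    labels = cols["label"].astype(np.int64) if "label" in cols else None
    viewpoint = None
    if "VIEWPOINT" in header:
        vp = np.array([float(v) for v in header["VIEWPOINT"][:3]])
        if np.any(vp != 0):
            viewpoint = vp
    return PointCloud(points=pts, labels=labels, viewpoint=viewpoint)


def _write_pcd(cloud: PointCloud, path: str, binary: bool = False) -> None:
    has_labels = cloud.labels is not None
    fields = ["x", "y", "z"] + (["label"] if has_labels else [])
    sizes = ["8", "8", "8"] + (["4"] if has_labels else [])
    types = ["F", "F", "F"] + (["I"] if has_labels else [])
    vp = cloud.viewpoint if cloud.viewpoint is not None else np.zeros(3)
    header = ["# .PCD v0.7 - Point Cloud Data file format",
              "VERSION 0.7",
              "FIELDS " + " ".join(fields),
              "SIZE " + " ".join(sizes),
              "TYPE " + " ".join(types),
              "COUNT " + " ".join(["1"] * len(fields)),
              f"WIDTH {len(cloud)}",
              "HEIGHT 1",
              f"VIEWPOINT {vp[0]:g} {vp[1]:g} {vp[2]:g} 1 0 0 0",
              f"POINTS {len(cloud)}",
              f"DATA {'binary' if binary else 'ascii'}"]
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if binary:
            spec = [("x", "<f8"), ("y", "<f8"), ("z", "<f8")]
            if has_labels:
                spec.append(("label", "<i4"))
            rec = np.empty(len(cloud), dtype=np.dtype(spec))
            rec["x"], rec["y"], rec["z"] = cloud.points.T
            if has_labels:
                rec["label"] = cloud.labels
            fh.write(rec.tobytes())
        else:
            for i, p in enumerate(cloud.points):
                row = f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}"
                if has_labels:
                    row += f" {int(cloud.labels[i])}"
                fh.write((row + "\n").encode("ascii"))


def read_label_sidecar(path: str, n_points: int) -> np.ndarray:
    """Read labels from a sidecar CSV with columns ``index,label``.

    Points not listed get ``-1``.
    """
    import pandas as pd

    df = pd.read_csv(path)
    if not {"index", "label"}.issubset(df.columns):
        raise ValueError(f"{path}: sidecar CSV needs columns index,label")
    labels = np.full(n_points, UNLABELED, dtype=np.int64)
    idx = df["index"].to_numpy(dtype=np.int64)
    if idx.min() < 0 or idx.max() >= n_points:
        raise ValueError(f"{path}: sidecar index out of range")
    labels[idx] = df["label"].to_numpy(dtype=np.int64)
    return labels


def write_label_sidecar(labels: np.ndarray, path: str) -> str:
    import pandas as pd

    pd.DataFrame({"index": np.arange(len(labels)), "label": labels}
                 ).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# preprocessing


def crop_by_height(cloud: PointCloud, z_min: float) -> PointCloud:
    """Keep exactly the points with z >= ``z_min`` (order preserved).

    Used to cut off pot/ground returns, or to keep only the canopy above
    the highest leaf before ear/stem classification.
    """
    keep = np.flatnonzero(cloud.points[:, 2] >= z_min)
    if keep.size == 0:
        raise ValueError(f"crop_by_height(z_min={z_min}) left no points")
    return cloud.subset(keep)


def rasterize(cloud: PointCloud, resolution: float) -> PointCloud:
    """Thin the cloud so the minimal pairwise distance is >= ``resolution``.

    Deterministic greedy thinning in input order: a point is kept iff no
    already-kept point lies within ``resolution``.  Kept points are a
    subset of the input (no new coordinates are synthesised), labels ride
    along, and ``resolution_hint`` is set on the result.
    """
    if len(cloud) == 0:
        raise ValueError("cannot rasterize an empty cloud")
    out = cloud.subset(greedy_thin_indices(cloud.points, resolution))
    out.resolution_hint = float(resolution)
    return out


def greedy_thin_indices(points: np.ndarray, resolution: float) -> np.ndarray:
    """Indices kept by greedy minimum-distance thinning in input order."""
    if not resolution > 0:
        raise ValueError("resolution must be > 0")
    points = np.asarray(points, dtype=np.float64)
    tree = cKDTree(points)
    neighbors = tree.query_ball_point(points, r=resolution, workers=-1)
    kept = np.zeros(len(points), dtype=bool)
    for i, nb in enumerate(neighbors):
        nbk = [j for j in nb if kept[j]]
        # strict: a point exactly at `resolution` from a kept point stays,
        # so the output's minimal pairwise distance is >= resolution
        if not nbk or not (np.linalg.norm(points[nbk] - points[i], axis=1)
                           < resolution).any():
            kept[i] = True
    return np.flatnonzero(kept)
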