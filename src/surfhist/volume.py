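"""Alpha-shape organ volumes and yield-parameter correlation.

The alpha complex of a 3D point set keeps exactly the Delaunay tetrahedra
whose circumsphere radius is at most ``alpha``; the enclosed volume is the
sum of their volumes.  Unlike the convex hull this follows concavities,
which is what makes it a usable proxy for the volume of a wheat ear.

A practical caveat for laser scans: the points sample only the *surface*
of an organ.  The tetrahedra spanning the interior of a closed surface
have circumradii on the order of the cross-section circumradius of the
organ (for a tube of radius R, about R), so ``alpha`` must exceed that —
not merely the sampling spacing — or the interior is not filled and the
volume collapses toward zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np
from scipy.spatial import ConvexHull, Delaunay, QhullError

from .io import PointCloud
from .regions import RegionSet

__all__ = ["VolumeReport", "alpha_shape_volume", "convex_hull_volume",
           "region_volumes", "yield_correlation"]


@dataclass
class VolumeReport:
    region_id: int
    alpha: float
    volume: float
    n_points: int

    def to_dict(self) -> dict:
        return {"region_id": self.region_id, "alpha": self.alpha,
                "volume": self.volume, "n_points": self.n_points}


def _tet_circumradii(verts: np.ndarray) -> np.ndarray:
    """Circumsphere radii of stacked tetrahedra ``(m, 4, 3)``.

    Near-degenerate (flat) tetrahedra get radius +inf so they are never
    kept by any finite alpha.
    """
    a = verts[:, 1] - verts[:, 0]
    b = verts[:, 2] - verts[:, 0]
    c = verts[:, 3] - verts[:, 0]
    aa = np.einsum("ij,ij->i", a, a)
    bb = np.einsum("ij,ij->i", b, b)
    cc = np.einsum("ij,ij->i", c, c)
    bxc = np.cross(b, c)
    cxa = np.cross(c, a)
    axb = np.cross(a, b)
    denom = 2.0 * np.einsum("ij,ij->i", a, bxc)
    num = (aa[:, None] * bxc + bb[:, None] * cxa + cc[:, None] * axb)
    scale = np.maximum.reduce([aa, bb, cc])
    with np.errstate(divide="ignore", invalid="ignore"):
        center = num / denom[:, None]
        r = np.linalg.norm(center, axis=1)
    degenerate = np.abs(denom) <= 1e-12 * np.power(scale, 1.5)
    r[degenerate] = np.inf
    return r


def _tet_volumes(verts: np.ndarray) -> np.ndarray:
    a = verts[:, 1] - verts[:, 0]
    b = verts[:, 2] - verts[:, 0]
    c = verts[:, 3] - verts[:, 0]
    return np.abs(np.einsum("ij,ij->i", a, np.cross(b, c))) / 6.0


def alpha_shape_volume(points: np.ndarray, alpha: float,
                       region_id: int = 0) -> VolumeReport:
    """Volume of the alpha complex of ``points`` (mm^3).

    Requires at least 4 non-coplanar points and ``alpha > 0``.  When no
    tetrahedron survives the circumradius filter the volume is 0 and a
    warning is issued (alpha smaller than the structure can support).
    """
    if not alpha > 0:
        raise ValueError("alpha must be > 0")
    points = np.asarray(points, dtype=np.float64)
    if points.ndim != 2 or points.shape[1] != 3:
        raise ValueError("points must be (n, 3)")
    if len(points) < 4:
        raise ValueError("need at least 4 points for a 3D alpha shape")
    try:
        tri = Delaunay(points)
    except QhullError as exc:
        raise ValueError(f"degenerate (coplanar?) point set: {exc}") from exc
    if tri.simplices.size == 0:
        raise ValueError("degenerate point set: no tetrahedra")
    verts = points[tri.simplices]
    radii = _tet_circumradii(verts)
    keep = radii <= alpha
    if not keep.any():
        warnings.warn(f"alpha={alpha} keeps no tetrahedron; volume 0")
        vol = 0.0
    else:
        vol = float(_tet_volumes(verts[keep]).sum())
    return VolumeReport(region_id=region_id, alpha=float(alpha),
                        volume=vol, n_points=len(points))


def convex_hull_volume(points: np.ndarray) -> float:
    return float(ConvexHull(np.asarray(points, dtype=np.float64)).volume)


def region_volumes(regions: RegionSet, cloud: PointCloud, target_label: int,
                   alpha: float) -> List[VolumeReport]:
    """One volume report per ``target_label`` region, ordered by region id.

    Degenerate regions (under 4 points, or coplanar) are reported with
    volume 0 and a warning rather than raising.
    """
    targets = [(rid, r) for rid, r in enumerate(regions.regions)
               if r.label == target_label]
    if not targets:
        raise ValueError(f"no region carries label {target_label}")
    reports = []
    for rid, r in targets:
        try:
            rep = alpha_shape_volume(cloud.points[r.ids], alpha, region_id=rid)
        except ValueError as exc:
            warnings.warn(f"region {rid}: {exc}; reporting volume 0")
            rep = VolumeReport(region_id=rid, alpha=float(alpha), volume=0.0,
                               n_points=r.size)
        reports.append(rep)
    return reports


def yield_correlation(table) -> Dict[str, Optional[float]]:
    """OLS coefficient of determination of each yield column vs volume.

    ``table`` is a DataFrame with a ``volume`` column plus measured yield
    parameters (e.g. ear weight, kernel weight, kernel count).  Columns
    with zero variance (or a zero-variance volume) get ``None`` with a
    warning.
    """
    import pandas as pd
    from scipy import stats

    table = pd.DataFrame(table)
    if "volume" not in table.columns:
        raise ValueError("table needs a 'volume' column")
    if len(table) < 3:
        raise ValueError("need at least 3 rows")
    vol = table["volume"].to_numpy(dtype=float)
    out: Dict[str, Optional[float]] = {}
    for col in table.columns:
        if col in ("volume", "ear_id"):
            continue
        y = table[col].to_numpy(dtype=float)
        if np.std(y) == 0 or np.std(vol) == 0:
            warnings.warn(f"column {col!r}: zero variance, R^2 undefined")
            out[col] = None
            continue
        res = stats.linregress(vol, y)
        out[col] = float(res.rvalue ** 2)
    return out
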