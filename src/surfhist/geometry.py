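"""Radius-neighborhood queries and PCA normal estimation.

Laser scanners deliver pure 3D coordinates, so surface normals must be
recovered from the data.  The normal at a point is the eigenvector of the
covariance of its radius-``r_n`` neighborhood (query point included)
belonging to the smallest eigenvalue, with the sign chosen so the normal
faces the sensor viewpoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy.spatial import cKDTree

from .io import PointCloud

__all__ = ["NeighborIndex", "NormalField", "build_index", "estimate_normals",
           "DEFAULT_VIEWPOINT"]

# Scans are taken from outside/above the plant; far overhead is a safe
# default sensor position for sign disambiguation.
DEFAULT_VIEWPOINT = np.array([0.0, 0.0, 1.0e6])


@dataclass
class NeighborIndex:
    """k-d tree over a cloud supporting fixed-radius queries."""

    cloud: PointCloud
    tree: cKDTree

    def query_radius(self, query: Union[int, np.ndarray], r: float) -> np.ndarray:
        """Indices of points within Euclidean distance ``r``.

        ``query`` is a point id (the point itself is excluded from its own
        neighborhood) or an explicit coordinate.
        """
        if isinstance(query, (int, np.integer)):
            idx = self.tree.query_ball_point(self.cloud.points[query], r)
            return np.array([j for j in idx if j != query], dtype=np.int64)
        return np.asarray(self.tree.query_ball_point(np.asarray(query), r),
                          dtype=np.int64)

    def pairs_within(self, r: float) -> np.ndarray:
        """All unordered point-id pairs (i < j) with distance <= ``r``."""
        return self.tree.query_pairs(r, output_type="ndarray")


def build_index(cloud: PointCloud) -> NeighborIndex:
    if len(cloud) == 0:
        raise ValueError("cannot index an empty cloud")
    return NeighborIndex(cloud=cloud, tree=cKDTree(cloud.points))


@dataclass
class NormalField:
    """Per-point unit normals aligned with a PointCloud.

    ``valid`` is False where estimation was impossible (fewer than 3
    support points or a degenerate covariance); those rows are (0,0,0).
    """

    normals: np.ndarray
    valid: np.ndarray

    def __len__(self) -> int:
        return len(self.normals)


def estimate_normals(cloud: PointCloud, index: Optional[NeighborIndex] = None,
                     r_n: float = 2.5,
                     viewpoint: Optional[np.ndarray] = None) -> NormalField:
    """PCA normals from radius-``r_n`` neighborhoods.

    The neighborhood radius must exceed the cloud resolution; when
    ``cloud.resolution_hint`` is set this is enforced.  Sign is flipped so
    ``normal . (viewpoint - point) >= 0``.
    """
    if not r_n > 0:
        raise ValueError("r_n must be > 0")
    if cloud.resolution_hint is not None and r_n <= cloud.resolution_hint:
        raise ValueError(
            f"r_n={r_n} must be bigger than the point cloud resolution "
            f"({cloud.resolution_hint})")
    if index is None:
        index = build_index(cloud)
    if viewpoint is None:
        viewpoint = cloud.viewpoint if cloud.viewpoint is not None else DEFAULT_VIEWPOINT
    viewpoint = np.asarray(viewpoint, dtype=np.float64)

    n = len(cloud)
    # Work in centred coordinates to limit cancellation in the moments.
    center = cloud.points.mean(axis=0)
    pts = cloud.points - center

    neighbor_lists = index.tree.query_ball_point(cloud.points, r=r_n, workers=-1)
    counts = np.array([len(nb) for nb in neighbor_lists])  # includes self
    flat = np.fromiter((j for nb in neighbor_lists for j in nb),
                       dtype=np.int64, count=int(counts.sum()))
    owner = np.repeat(np.arange(n), counts)

    # First and second moments of each neighborhood via bincount.
    sums = np.stack([np.bincount(owner, weights=pts[flat, k], minlength=n)
                     for k in range(3)], axis=1)
    mu = sums / np.maximum(counts, 1)[:, None]
    prods = {}
    for a in range(3):
        for b in range(a, 3):
            prods[(a, b)] = np.bincount(
                owner, weights=pts[flat, a] * pts[flat, b], minlength=n)
    cov = np.empty((n, 3, 3))
    for a in range(3):
        for b in range(a, 3):
            cab = prods[(a, b)] / np.maximum(counts, 1) - mu[:, a] * mu[:, b]
            cov[:, a, b] = cab
            cov[:, b, a] = cab

    eigvals, eigvecs = np.linalg.eigh(cov)
    normals = eigvecs[:, :, 0]

    # Degenerate: < 3 support points, or the two smallest eigenvalues both
    # (numerically) zero, i.e. the neighborhood is a point or a line.
    scale = np.maximum(eigvals[:, 2], 0.0)
    valid = (counts >= 3) & (eigvals[:, 1] > 1e-12 * np.maximum(scale, 1e-300))

    flip = np.einsum("ij,ij->i", normals, viewpoint - cloud.points) < 0
    normals[flip] *= -1.0
    normals[~valid] = 0.0
    # eigh returns unit vectors; renormalize valid rows defensively.
    nrm = np.linalg.norm(normals[valid], axis=1)
    normals[valid] /= nrm[:, None]
    return NormalField(normals=normals, valid=valid)
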