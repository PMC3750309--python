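"""Surface feature histograms: the core per-point descriptor.

For every ordered pair of oriented points (p_s, n_s), (p_t, n_t) a Darboux
frame is erected at the source point:

    t_hat = (p_t - p_s) / d,   u = n_s,
    v = normalize(u x t_hat),  w = u x v,

and three pose-invariant angular features are read off:

    alpha = v . n_t            in [-1, 1]
    phi   = u . t_hat          in [-1, 1]
    theta = atan2(w . n_t, u . n_t)   in (-pi, pi]

with the roles swapped beforehand so that the source is the point whose
normal makes the smaller (acute) angle with the connecting line; ties keep
input order.  The three features of all neighbor pairs within the
histogram radius ``r_h`` are binned into a joint histogram
(``bins_per_feature`` uniform divisions per feature, 5**3 = 125 bins by
default) and normalized to sum 1 — the *raw* histogram of the point.

The final descriptor of a source point is the weighted sum of its own raw
histogram (weight 1) and the raw histograms of its neighbors, each scaled
by the linear distance weight

    w_b(d) = 1 - (0.5 + d / r_h * 0.5) = 0.5 * (1 - d / r_h),

so a touching neighbor (d -> 0) counts 50:50 against the source itself and
a neighbor at the rim of the neighborhood contributes nothing.  The result
is normalized again; it is the input row for the SVM classifier.

The pair distance ``d`` is used only for weighting, never binned: binning
it would break the density invariance of the descriptor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import sparse

from .geometry import NeighborIndex, NormalField, build_index, estimate_normals
from .io import PointCloud

__all__ = [
    "PairFeature",
    "FeatureConfig",
    "FeatureHistogram",
    "FeatureMatrix",
    "darboux_pair_features",
    "distance_weight",
    "raw_point_histogram",
    "aggregate_histogram",
    "compute_features",
]

_FEATURE_ORDER = ("alpha", "phi", "theta")
_RANGES = {"alpha": (-1.0, 1.0), "phi": (-1.0, 1.0), "theta": (-np.pi, np.pi)}


@dataclass(frozen=True)
class PairFeature:
    """Darboux-frame features of one oriented point pair."""

    alpha: float
    phi: float
    theta: float
    d: float


@dataclass(frozen=True)
class FeatureConfig:
    """Radii and binning of the descriptor.

    The radii must satisfy ``resolution < r_n < r_h``; the normal radius
    is checked against the cloud's resolution hint when present.
    ``pair_radius`` selects which radius bounds the pair set of the raw
    histograms (the aggregation step always uses ``r_h``).
    """

    r_n: float = 2.5
    r_h: float = 12.0
    bins_per_feature: int = 5
    features_used: Tuple[str, ...] = _FEATURE_ORDER
    pair_radius: str = "r_h"

    def __post_init__(self) -> None:
        if not (self.r_n > 0 and self.r_h > 0):
            raise ValueError("radii must be positive")
        if not self.r_n < self.r_h:
            raise ValueError(
                f"invalid radii r_n={self.r_n}, r_h={self.r_h}: the "
                f"descriptor requires resolution < r_n < r_h")
        if self.bins_per_feature < 2:
            raise ValueError("bins_per_feature must be >= 2")
        used = tuple(f for f in _FEATURE_ORDER if f in self.features_used)
        if len(used) != len(self.features_used) or not used:
            raise ValueError(f"features_used must be a non-empty subset of "
                             f"{_FEATURE_ORDER}")
        object.__setattr__(self, "features_used", used)
        if self.pair_radius not in ("r_h", "r_n"):
            raise ValueError("pair_radius must be 'r_h' or 'r_n'")

    @property
    def n_bins(self) -> int:
        return self.bins_per_feature ** len(self.features_used)

    def fingerprint(self) -> tuple:
        return (self.r_n, self.r_h, self.bins_per_feature,
                self.features_used, self.pair_radius)

    def check_against(self, cloud: PointCloud) -> None:
        if cloud.resolution_hint is not None and self.r_n <= cloud.resolution_hint:
            raise ValueError(
                f"r_n={self.r_n} must be bigger than the point cloud "
                f"resolution ({cloud.resolution_hint}); the descriptor "
                f"requires resolution < r_n < r_h")


@dataclass
class FeatureHistogram:
    """A single normalized joint histogram (sum 1), or all-zero if invalid."""

    values: np.ndarray
    valid: bool


@dataclass
class FeatureMatrix:
    """One histogram row per cloud point plus the config that produced it."""

    histograms: np.ndarray          # (n, n_bins)
    valid: np.ndarray               # (n,) bool
    config: FeatureConfig
    normals: Optional[NormalField] = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.histograms)

    def to_dataframe(self):
        import pandas as pd

        cols = {"index": np.arange(len(self)), "valid": self.valid.astype(int)}
        for b in range(self.histograms.shape[1]):
            cols[f"b{b}"] = self.histograms[:, b]
        return pd.DataFrame(cols)

    def to_csv(self, path: str) -> str:
        self.to_dataframe().to_csv(path, index=False)
        return path


# ---------------------------------------------------------------------------
# pair features


def _pair_features_vec(ps: np.ndarray, ns: np.ndarray,
                       pt: np.ndarray, nt: np.ndarray
                       ) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Darboux pair features for stacked pairs.

    Inputs are (m, 3) arrays; returns (alpha, phi, theta, d) as (m,)
    arrays.  Implements the source-swap rule and the deterministic
    fallback frame for pairs whose connecting line is parallel to the
    source normal.
    """
    diff = pt - ps
    d = np.linalg.norm(diff, axis=1)
    if np.any(d <= 0):
        raise ValueError("coincident points in pair feature computation")
    t_hat = diff / d[:, None]

    # Source selection: the point whose normal makes the smaller acute
    # angle with the connecting line; strict inequality, ties keep order.
    cos_s = np.abs(np.einsum("ij,ij->i", ns, t_hat))
    cos_t = np.abs(np.einsum("ij,ij->i", nt, t_hat))
    swap = cos_t > cos_s

    u = np.where(swap[:, None], nt, ns)
    n_tgt = np.where(swap[:, None], ns, nt)
    t_eff = np.where(swap[:, None], -t_hat, t_hat)

    v = np.cross(u, t_eff)
    nv = np.linalg.norm(v, axis=1)
    degen = nv < 1e-12
    if np.any(degen):
        # u is parallel to the line: build v from the coordinate axis
        # least aligned with u (deterministic).
        ud = u[degen]
        axis = np.argmin(np.abs(ud), axis=1)
        a = np.zeros_like(ud)
        a[np.arange(len(ud)), axis] = 1.0
        vd = np.cross(ud, a)
        v[degen] = vd
        nv[degen] = np.linalg.norm(vd, axis=1)
    v /= nv[:, None]
    w = np.cross(u, v)

    alpha = np.einsum("ij,ij->i", v, n_tgt)
    phi = np.einsum("ij,ij->i", u, t_eff)
    theta = np.arctan2(np.einsum("ij,ij->i", w, n_tgt),
                       np.einsum("ij,ij->i", u, n_tgt))
    return alpha, phi, theta, d


def darboux_pair_features(p_s: np.ndarray, n_s: np.ndarray,
                          p_t: np.ndarray, n_t: np.ndarray) -> PairFeature:
    """Darboux-frame features of one oriented pair (see module docstring)."""
    p_s = np.asarray(p_s, dtype=np.float64).reshape(1, 3)
    p_t = np.asarray(p_t, dtype=np.float64).reshape(1, 3)
    n_s = np.asarray(n_s, dtype=np.float64).reshape(1, 3)
    n_t = np.asarray(n_t, dtype=np.float64).reshape(1, 3)
    for nvec in (n_s, n_t):
        if abs(np.linalg.norm(nvec) - 1.0) > 1e-6:
            raise ValueError("normals must be unit length")
    a, p, t, d = _pair_features_vec(p_s, n_s, p_t, n_t)
    return PairFeature(alpha=float(a[0]), phi=float(p[0]),
                       theta=float(t[0]), d=float(d[0]))


def distance_weight(d, r_h: float):
    """Linear neighbor weight ``0.5 * (1 - d / r_h)``.

    Maximal (0.5, the 50:50 ratio against the source) at ``d = 0`` and
    zero at ``d = r_h``; defined only on ``0 <= d <= r_h``.
    """
    if not r_h > 0:
        raise ValueError("r_h must be > 0")
    d = np.asarray(d, dtype=np.float64)
    if np.any(d < 0) or np.any(d > r_h):
        raise ValueError(f"distance must lie in [0, r_h={r_h}]")
    w = 1.0 - (0.5 + d / r_h * 0.5)
    return float(w) if w.ndim == 0 else w


# ---------------------------------------------------------------------------
# binning


def _bin_joint(alpha: np.ndarray, phi: np.ndarray, theta: np.ndarray,
               config: FeatureConfig) -> np.ndarray:
    """Joint bin index per pair. Left-closed right-open bins, last bin
    right-closed; values clamped to the invariant ranges first."""
    b = config.bins_per_feature
    vals = {"alpha": alpha, "phi": phi, "theta": theta}
    joint = np.zeros(len(alpha), dtype=np.int64)
    for f in config.features_used:
        lo, hi = _RANGES[f]
        x = np.clip(vals[f], lo, hi)
        idx = np.floor((x - lo) / (hi - lo) * b).astype(np.int64)
        np.clip(idx, 0, b - 1, out=idx)
        joint = joint * b + idx
    return joint


# ---------------------------------------------------------------------------
# per-point reference operations


def raw_point_histogram(cloud: PointCloud, normals: NormalField,
                        index: NeighborIndex, i: int,
                        config: FeatureConfig) -> FeatureHistogram:
    """Raw (un-aggregated) histogram of point ``i``.

    Bins the pair features between ``i`` and every neighbor with a valid
    normal inside the pair radius.  Returns an invalid (all-zero)
    histogram when ``i`` itself has no valid normal or no valid neighbor.
    """
    nb_r = config.r_h if config.pair_radius == "r_h" else config.r_n
    zeros = np.zeros(config.n_bins)
    if not normals.valid[i]:
        return FeatureHistogram(values=zeros, valid=False)
    nb = index.query_radius(int(i), nb_r)
    nb = nb[normals.valid[nb]]
    if nb.size == 0:
        return FeatureHistogram(values=zeros, valid=False)
    ps = np.broadcast_to(cloud.points[i], (nb.size, 3))
    ns = np.broadcast_to(normals.normals[i], (nb.size, 3))
    a, p, t, _ = _pair_features_vec(ps, ns, cloud.points[nb], normals.normals[nb])
    joint = _bin_joint(a, p, t, config)
    hist = np.bincount(joint, minlength=config.n_bins).astype(np.float64)
    return FeatureHistogram(values=hist / hist.sum(), valid=True)


def aggregate_histogram(raw: Sequence[FeatureHistogram], cloud: PointCloud,
                        index: NeighborIndex, i: int,
                        config: FeatureConfig) -> FeatureHistogram:
    """Distance-weighted aggregation of raw histograms around point ``i``.

    ``final_i = normalize(raw_i + sum_j w_b(d_ij) * raw_j)`` over the
    neighbors ``j`` within ``r_h`` whose raw histogram is valid.  The
    source term has weight 1, so a neighbor at ``d -> 0`` reaches the
    50:50 ratio.  Invalid if ``raw_i`` is invalid.
    """
    if not raw[i].valid:
        return FeatureHistogram(values=np.zeros(config.n_bins), valid=False)
    acc = raw[i].values.copy()
    nb = index.query_radius(int(i), config.r_h)
    if nb.size:
        d = np.linalg.norm(cloud.points[nb] - cloud.points[i], axis=1)
        for j, dij in zip(nb, d):
            if raw[j].valid:
                acc += distance_weight(dij, config.r_h) * raw[j].values
    return FeatureHistogram(values=acc / acc.sum(), valid=True)


# ---------------------------------------------------------------------------
# whole-cloud fast path

_CHUNK = 2_000_000


def compute_features(cloud: PointCloud, config: FeatureConfig,
                     viewpoint: Optional[np.ndarray] = None,
                     normals: Optional[NormalField] = None,
                     index: Optional[NeighborIndex] = None) -> FeatureMatrix:
    """Normals + raw histograms + aggregation for every point.

    Vectorized equivalent of calling :func:`raw_point_histogram` and
    :func:`aggregate_histogram` per point; pair features are evaluated in
    chunks over the symmetric neighbor-pair list and the aggregation is a
    sparse weighted adjacency product.  Rows where no descriptor exists
    (invalid normal or no valid neighbor) are flagged invalid and left
    all-zero.
    """
    config.check_against(cloud)
    if index is None:
        index = build_index(cloud)
    if normals is None:
        normals = estimate_normals(cloud, index, r_n=config.r_n,
                                   viewpoint=viewpoint)
    n = len(cloud)
    nb_r = config.r_h if config.pair_radius == "r_h" else config.r_n

    pairs = index.pairs_within(nb_r)
    if pairs.size:
        src = np.concatenate([pairs[:, 0], pairs[:, 1]])
        tgt = np.concatenate([pairs[:, 1], pairs[:, 0]])
        ok = normals.valid[src] & normals.valid[tgt]
        src, tgt = src[ok], tgt[ok]
    else:
        src = tgt = np.empty(0, dtype=np.int64)

    raw = np.zeros((n, config.n_bins))
    for lo in range(0, len(src), _CHUNK):
        s = slice(lo, lo + _CHUNK)
        a, p, t, _ = _pair_features_vec(
            cloud.points[src[s]], normals.normals[src[s]],
            cloud.points[tgt[s]], normals.normals[tgt[s]])
        joint = _bin_joint(a, p, t, config)
        raw += sparse.coo_matrix(
            (np.ones(len(joint)), (src[s], joint)),
            shape=(n, config.n_bins)).toarray()
    rowsum = raw.sum(axis=1)
    valid = normals.valid & (rowsum > 0)
    raw[valid] /= rowsum[valid, None]
    raw[~valid] = 0.0

    # Aggregation neighborhood always uses r_h.
    if config.pair_radius == "r_h":
        agg_pairs = pairs
    else:
        agg_pairs = index.pairs_within(config.r_h)
    if agg_pairs.size:
        ai = np.concatenate([agg_pairs[:, 0], agg_pairs[:, 1]])
        aj = np.concatenate([agg_pairs[:, 1], agg_pairs[:, 0]])
        ok = valid[ai] & valid[aj]
        ai, aj = ai[ok], aj[ok]
        d = np.linalg.norm(cloud.points[ai] - cloud.points[aj], axis=1)
        w = 0.5 * (1.0 - d / config.r_h)
        W = sparse.coo_matrix((w, (ai, aj)), shape=(n, n)).tocsr()
        final = raw + W.dot(raw)
    else:
        final = raw.copy()
    fsum = final.sum(axis=1)
    final[valid] /= fsum[valid, None]
    final[~valid] = 0.0
    return FeatureMatrix(histograms=final, valid=valid, config=config,
                         normals=normals)
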