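"""Independent brute-force reimplementation of the descriptor.

Pure Python loops, no spatial index, no shared code with the package
internals: used as the oracle that the vectorized fast path must match
bin-by-bin.  Takes precomputed normals so that exactly the histogram
pipeline (pair features, binning, weighting, aggregation) is under test.
"""

import math

import numpy as np


def _pair(ps, ns, pt, nt):
    d = math.sqrt((pt[0] - ps[0]) ** 2 + (pt[1] - ps[1]) ** 2
                  + (pt[2] - ps[2]) ** 2)
    t_hat = [(pt[k] - ps[k]) / d for k in range(3)]
    cos_s = abs(sum(ns[k] * t_hat[k] for k in range(3)))
    cos_t = abs(sum(nt[k] * t_hat[k] for k in range(3)))
    if cos_t > cos_s:
        u, n2 = list(nt), list(ns)
        t_hat = [-t for t in t_hat]
    else:
        u, n2 = list(ns), list(nt)
    v = [u[1] * t_hat[2] - u[2] * t_hat[1],
         u[2] * t_hat[0] - u[0] * t_hat[2],
         u[0] * t_hat[1] - u[1] * t_hat[0]]
    nv = math.sqrt(sum(c * c for c in v))
    if nv < 1e-12:
        axis = min(range(3), key=lambda k: abs(u[k]))
        a = [0.0, 0.0, 0.0]
        a[axis] = 1.0
        v = [u[1] * a[2] - u[2] * a[1],
             u[2] * a[0] - u[0] * a[2],
             u[0] * a[1] - u[1] * a[0]]
        nv = math.sqrt(sum(c * c for c in v))
    v = [c / nv for c in v]
    w = [u[1] * v[2] - u[2] * v[1],
         u[2] * v[0] - u[0] * v[2],
         u[0] * v[1] - u[1] * v[0]]
    alpha = sum(v[k] * n2[k] for k in range(3))
    phi = sum(u[k] * t_hat[k] for k in range(3))
    theta = math.atan2(sum(w[k] * n2[k] for k in range(3)),
                       sum(u[k] * n2[k] for k in range(3)))
    return alpha, phi, theta, d


def _bin(value, lo, hi, bins):
    x = min(max(value, lo), hi)
    idx = int(math.floor((x - lo) / (hi - lo) * bins))
    return min(max(idx, 0), bins - 1)


def naive_histograms(points, normals, valid, r_h, bins):
    """Raw + aggregated histograms by exhaustive pairwise loops.

    Returns (final, final_valid) matching the package's whole-cloud
    computation contract with pair radius = aggregation radius = r_h.
    """
    n = len(points)
    n_bins = bins ** 3
    raw = np.zeros((n, n_bins))
    raw_ok = np.zeros(n, dtype=bool)
    for i in range(n):
        if not valid[i]:
            continue
        count = 0
        for j in range(n):
            if j == i or not valid[j]:
                continue
            d = math.dist(points[i], points[j])
            if d > r_h:
                continue
            a, p, t, _ = _pair(points[i], normals[i], points[j], normals[j])
            k = (_bin(a, -1.0, 1.0, bins) * bins
                 + _bin(p, -1.0, 1.0, bins)) * bins \
                + _bin(t, -math.pi, math.pi, bins)
            raw[i, k] += 1.0
            count += 1
        if count:
            raw[i] /= raw[i].sum()
            raw_ok[i] = True
    final = np.zeros_like(raw)
    for i in range(n):
        if not raw_ok[i]:
            continue
        acc = raw[i].copy()
        for j in range(n):
            if j == i or not raw_ok[j]:
                continue
            d = math.dist(points[i], points[j])
            if d > r_h:
                continue
            acc += (1.0 - (0.5 + d / r_h * 0.5)) * raw[j]
        final[i] = acc / acc.sum()
    return final, raw_ok
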