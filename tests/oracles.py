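"""Independent brute-force reference implementations.

Every function here is a direct, loop-level transcription of the defining
formula, deliberately sharing no code path with the package (no cdist/pdist,
no vectorized shortcuts). They are only run on small fixtures.
"""

from __future__ import annotations

import math

import numpy as np


def tv_brute(x: np.ndarray) -> float:
    """Total variation: (1/(N-1)) * sum |x[n]-x[n-1]| / (max-min)."""
    n = len(x)
    acc = 0.0
    for i in range(1, n):
        acc += abs(x[i] - x[i - 1])
    return acc / ((n - 1) * (max(x) - min(x)))


def mi_brute(x: np.ndarray, lag: int, n_bins: int) -> float:
    """Mutual information (bits) by explicit double sum over amplitude cells."""
    a = x[: len(x) - lag]
    b = x[lag:]
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    width = (hi - lo) / n_bins

    def cell(v: float) -> int:
        c = int((v - lo) / width)
        return min(c, n_bins - 1)

    joint = np.zeros((n_bins, n_bins))
    for u, v in zip(a, b):
        joint[cell(u), cell(v)] += 1
    joint /= joint.sum()
    pa = joint.sum(axis=1)
    pb = joint.sum(axis=0)
    mi = 0.0
    for i in range(n_bins):
        for j in range(n_bins):
            if joint[i, j] > 0:
                mi += joint[i, j] * math.log2(joint[i, j] / (pa[i] * pb[j]))
    return mi


def embed_brute(x: np.ndarray, lag: int, dim: int) -> list[list[float]]:
    m = len(x) - lag * (dim - 1)
    return [[x[i + lag * j] for j in range(dim)] for i in range(m)]


def _dist(p, q) -> float:
    return math.sqrt(sum((a - b) ** 2 for a, b in zip(p, q)))


def _nearest(pts, i) -> int:
    """Index of the nearest neighbor of pts[i], self excluded, smallest-index ties."""
    best, best_d = -1, math.inf
    for j in range(len(pts)):
        if j == i:
            continue
        d = _dist(pts[i], pts[j])
        if d < best_d:
            best, best_d = j, d
    return best


def _maxdist(p, q) -> float:
    return max(abs(a - b) for a, b in zip(p, q))


def _nearest_max(pts, i) -> int:
    """Max-norm nearest neighbor of pts[i], self excluded, smallest-index ties."""
    best, best_d = -1, math.inf
    for j in range(len(pts)):
        if j == i:
            continue
        d = _maxdist(pts[i], pts[j])
        if d < best_d:
            best, best_d = j, d
    return best


def cao_brute(x: np.ndarray, lag: int, d_max: int) -> tuple[list[float], list[float]]:
    """Cao's e_d and e*_d by exhaustive max-norm neighbor search."""
    e, e_star = [], []
    for d in range(1, d_max + 1):
        m1 = len(x) - lag * d
        if m1 < 2:
            break
        y1 = embed_brute(x, lag, d + 1)
        yd = [p[:d] for p in y1]
        ratios = []
        extras = []
        for i in range(m1):
            nn = _nearest_max(yd, i)
            d_low = _maxdist(yd[i], yd[nn])
            if d_low > 0:
                ratios.append(_maxdist(y1[i], y1[nn]) / d_low)
            extras.append(abs(y1[i][-1] - y1[nn][-1]))
        e.append(sum(ratios) / len(ratios))
        e_star.append(sum(extras) / len(extras))
    return e, e_star


def correlation_sum_brute(points, eps: float) -> float:
    """C(eps) = (1/M^2) * #{ordered pairs i != j with d_ij < eps}."""
    m = len(points)
    count = 0
    for i in range(m):
        for j in range(m):
            if i != j and eps - _dist(points[i], points[j]) > 0:
                count += 1
    return count / (m * m)


def takens_brute(points, eps: float) -> float:
    """Takens estimator over pairs with 0 < distance < eps."""
    logs = []
    m = len(points)
    for i in range(m):
        for j in range(i + 1, m):
            d = _dist(points[i], points[j])
            if 0 < d < eps:
                logs.append(math.log(d / eps))
    return -1.0 / (sum(logs) / len(logs))


def divergence_brute(points, k: int, mode: str, theiler: int) -> list[float]:
    """Mean divergence per step by explicit loops (Wolf ratio / Sato log2)."""
    m = len(points)
    n_cand = m - k
    # fixed initial neighbor per reference, outside the Theiler window
    nbr = {}
    for i in range(n_cand):
        best, best_d = -1, math.inf
        for j in range(n_cand):
            if abs(i - j) <= theiler:
                continue
            d = _dist(points[i], points[j])
            if d < best_d:
                best, best_d = j, d
        if best >= 0:
            nbr[i] = best
    curve = []
    for s in range(1, k + 1):
        total, count = 0.0, 0
        for i, j in nbr.items():
            d0 = _dist(points[i], points[j])
            ds = _dist(points[i + s], points[j + s])
            if mode == "sato":
                if d0 > 0 and ds > 0:
                    total += math.log2(ds / d0)
                    count += 1
                elif d0 == 0 and ds == 0:
                    count += 1
            else:  # wolf
                if d0 > 0:
                    total += ds / d0
                    count += 1
                elif ds == 0:
                    total += 1.0
                    count += 1
        curve.append(total / count)
    return curve


def fisher_criterion(vz, nu0, za, zb, p1, p2) -> float:
    """f = (P1 eta1^2 + P2 eta2^2) / (P1 s1^2 + P2 s2^2) for h = vz.Z + nu0."""
    ha = za @ vz + nu0
    hb = zb @ vz + nu0
    num = p1 * ha.mean() ** 2 + p2 * hb.mean() ** 2
    den = p1 * ha.var() + p2 * hb.var()
    return num / den
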