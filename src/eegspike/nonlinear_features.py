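"""Delay-embedding nonlinear analysis: mutual information, Cao's method,
Takens correlation dimension, and the largest Lyapunov exponent.

The scalar signal is reconstructed in a lagged phase space
``y_d[i] = (x[i], x[i+m], ..., x[i+m(d-1)])`` with lag ``m`` chosen at the
first local minimum of the lag-mutual-information curve and embedding
dimension ``d_min`` chosen where Cao's embedding function saturates. Two
attractor statistics are then extracted: the correlation dimension (Takens
estimator over pairwise distances below a radius set to a fraction of the
attractor diameter) and the largest Lyapunov exponent (slope of the Sato
prediction-error curve).

All neighbor searches are brute-force Euclidean with deterministic
tie-breaking (smallest index); portraits larger than ``max_points`` are
first reduced by a seeded random subsample, trading a documented accuracy
cost for desk-scale runtime.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist

from .exceptions import EstimationError, FitError, LagError, SegmentLengthError

__all__ = [
    "EmbeddingSpec",
    "mutual_information",
    "mutual_information_curve",
    "optimal_lag",
    "embed",
    "cao_functions",
    "min_embedding_dimension",
    "attractor_radius",
    "correlation_sum",
    "correlation_dimension",
    "divergence_curve",
    "largest_lyapunov",
]


def _samples(x) -> np.ndarray:
    """Accept an EegSegment or a plain array."""
    if hasattr(x, "samples"):
        x = x.samples
    return np.asarray(x, dtype=float)


@dataclass(frozen=True)
class EmbeddingSpec:
    """Lag (samples), embedding dimension, and sampling period (s/sample)."""

    lag: int
    dim: int
    ts: float = 1.0

    def __post_init__(self) -> None:
        if self.lag < 1 or self.dim < 1 or not self.ts > 0:
            raise ValueError(f"invalid embedding spec {self}")


# ---------------------------------------------------------------------------
# Mutual information and optimal lag
# ---------------------------------------------------------------------------

def mutual_information(x, lag: int, n_bins: int = 16) -> float:
    """Mutual information (bits) between x[k] and x[k+lag].

    Equal-width amplitude bins over the joint range of the two sub-segments;
    empty cells (0*log 0) contribute nothing. Always >= 0 up to rounding.
    """
    x = _samples(x)
    n = x.size
    if lag >= n:
        raise LagError(f"lag {lag} >= signal length {n}")
    if n - lag < 10:
        raise SegmentLengthError(f"need at least 10 overlapping pairs, got {n - lag}")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    a, b = x[: n - lag], x[lag:]
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if hi == lo:
        return 0.0
    joint, _, _ = np.histogram2d(a, b, bins=n_bins, range=[[lo, hi], [lo, hi]])
    pj = joint / joint.sum()
    pa = pj.sum(axis=1)
    pb = pj.sum(axis=0)
    mask = pj > 0
    denom = np.outer(pa, pb)
    mi = float(np.sum(pj[mask] * np.log2(pj[mask] / denom[mask])))
    return max(mi, 0.0)


def mutual_information_curve(x, max_lag: int, n_bins: int = 16) -> np.ndarray:
    """MI at lags 1..max_lag (index 0 is lag 1)."""
    x = _samples(x)
    return np.array([mutual_information(x, m, n_bins) for m in range(1, max_lag + 1)])


def optimal_lag(x, max_lag: int = 40, n_bins: int = 16) -> int:
    """First local minimum of the lag-MI curve.

    Returns the smallest lag m in [2, max_lag-1] with MI(m) < MI(m-1) and
    MI(m) < MI(m+1). If the curve has no local minimum the fallback is the
    first lag where MI drops below 1/e of its lag-1 value, else max_lag//2,
    with a warning either way.
    """
    x = _samples(x)
    if not max_lag < x.size / 4:
        raise ValueError(f"max_lag {max_lag} must be < n/4 = {x.size / 4:.0f}")
    mi = mutual_information_curve(x, max_lag, n_bins)
    for m in range(2, max_lag):
        if mi[m - 1] < mi[m - 2] and mi[m - 1] < mi[m]:
            return m
    warnings.warn(
        "MI curve has no local minimum; using 1/e-drop fallback", stacklevel=2
    )
    below = np.nonzero(mi < mi[0] / np.e)[0]
    if below.size:
        return int(below[0]) + 1
    return max(max_lag // 2, 1)


# ---------------------------------------------------------------------------
# Embedding
# ---------------------------------------------------------------------------

def embed(x, lag: int, dim: int) -> np.ndarray:
    """Delay embedding: rows y[i] = (x[i], x[i+lag], ..., x[i+lag*(dim-1)]).

    Returns an (M, dim) array with M = n - lag*(dim-1).
    """
    x = _samples(x)
    m = x.size - lag * (dim - 1)
    if m < 1:
        raise SegmentLengthError(
            f"cannot embed {x.size} samples at dim {dim}, lag {lag}"
        )
    return np.column_stack([x[j * lag : j * lag + m] for j in range(dim)])


def _subsample(n_total: int, max_points: int, seed: int) -> np.ndarray | slice:
    if n_total <= max_points:
        return slice(None)
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(n_total, size=max_points, replace=False))


# ---------------------------------------------------------------------------
# Cao's method
# ---------------------------------------------------------------------------

def cao_functions(
    x,
    lag: int,
    d_max: int,
    max_points: int = 1000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Cao's embedding functions e_d and e*_d for d = 1..d_max.

    e_d is the mean ratio of each point's distance to its nearest neighbor
    in dimension d+1 over the distance to the same neighbor in dimension d;
    its saturation (e_{d+1}/e_d -> 1) marks a sufficient embedding dimension.
    e*_d is the mean extra-coordinate separation of the same neighbor pairs;
    an e*-ratio that stays at 1 for every d flags an i.i.d. (random) signal.

    Distances use the maximum (Chebyshev) norm, the metric of Cao's original
    formulation, under which the d- and (d+1)-dimensional distances nest
    cleanly. Nearest neighbors exclude self, with ties broken by smallest
    index; pairs at exactly zero distance are skipped for e_d and the mean
    renormalized. Sequences are truncated (with a warning) at the largest d
    the signal length supports.
    """
    x = _samples(x)
    n = x.size
    e = []
    e_star = []
    for d in range(1, d_max + 1):
        m1 = n - lag * d  # points embeddable at dimension d+1
        if m1 < 2:
            warnings.warn(
                f"signal too short for d={d} at lag {lag}; truncating Cao scan",
                stacklevel=2,
            )
            break
        y1 = embed(x, lag, d + 1)  # (m1, d+1)
        sel = _subsample(m1, max_points, seed)
        y1 = y1[sel]
        yd = y1[:, :d]
        dist = cdist(yd, yd, metric="chebyshev")
        np.fill_diagonal(dist, np.inf)
        nn = np.argmin(dist, axis=1)
        rows = np.arange(yd.shape[0])
        d_low = dist[rows, nn]
        d_high = np.max(np.abs(y1 - y1[nn]), axis=1)
        valid = d_low > 0
        if not np.any(valid):
            raise EstimationError(f"all nearest-neighbor distances zero at d={d}")
        e.append(float(np.mean(d_high[valid] / d_low[valid])))
        e_star.append(float(np.mean(np.abs(y1[:, -1] - y1[nn, -1]))))
    if not e:
        raise SegmentLengthError(f"cannot embed {n} samples at lag {lag}")
    return np.array(e), np.array(e_star)


def min_embedding_dimension(e: np.ndarray, threshold: float = 0.05) -> int:
    """Smallest d whose Cao-function ratio e_{d+1}/e_d is within ``threshold`` of 1.

    Returns d_max (the last d with a defined value) with a warning if the
    ratio never saturates.
    """
    e = np.asarray(e, dtype=float)
    if e.size < 2:
        raise ValueError("need at least two embedding-function values")
    for d in range(1, e.size):
        if e[d - 1] > 0 and abs(e[d] / e[d - 1] - 1.0) <= threshold:
            return d
    warnings.warn(
        f"embedding function never saturated at threshold {threshold}; "
        f"returning d_max={e.size}",
        stacklevel=2,
    )
    return int(e.size)


# ---------------------------------------------------------------------------
# Correlation dimension
# ---------------------------------------------------------------------------

def attractor_radius(
    points: np.ndarray,
    fraction: float = 0.05,
    sample_size: int = 1000,
    seed: int = 0,
) -> float:
    """``fraction`` times the attractor diameter (max pairwise distance).

    The diameter is estimated over a seeded random subsample of at most
    ``sample_size`` points; with M <= sample_size it is exact.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] < 2:
        raise EstimationError("attractor radius needs at least 2 points")
    sel = _subsample(points.shape[0], sample_size, seed)
    diam = float(pdist(points[sel]).max())
    return fraction * diam


def correlation_sum(points: np.ndarray, eps: float) -> float:
    """Fraction of ordered point pairs (i != j) closer than ``eps``.

    The finite-sample correlation sum C(eps) = (1/M^2) * #{(i,j): d_ij < eps};
    its log-log slope in eps is the correlation dimension that the Takens
    estimator computes in closed form.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    m = points.shape[0]
    if m < 2:
        raise EstimationError("correlation sum needs at least 2 points")
    d = pdist(points)
    return float(2.0 * np.count_nonzero(d < eps) / (m * m))


def correlation_dimension(
    points: np.ndarray,
    eps: float,
    mode: str = "takens",
    max_points: int = 1000,
    seed: int = 0,
) -> float:
    """Correlation dimension of an embedded point cloud.

    ``mode="takens"`` (default) is the standard maximum-likelihood Takens
    estimator restricted to pairs closer than ``eps``:
    d = -1 / mean(ln(d_ij / eps)), always positive. ``mode="literal"`` drops
    both the inverse and the pair restriction (an erratum-style variant kept
    for comparison; it can go negative and is not used by the pipeline).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    sel = _subsample(points.shape[0], max_points, seed)
    d = pdist(points[sel])
    if mode == "takens":
        d = d[(d > 0) & (d < eps)]
        if d.size == 0:
            raise EstimationError(
                f"no point pairs with 0 < distance < eps={eps:.3g}"
            )
        return float(-1.0 / np.mean(np.log(d / eps)))
    if mode == "literal":
        d = d[d > 0]
        if d.size == 0:
            raise EstimationError("no nonzero pairwise distances")
        return float(-np.mean(np.log(d / eps)))
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# Lyapunov exponent
# ---------------------------------------------------------------------------

def divergence_curve(
    points: np.ndarray,
    k: int,
    mode: str = "sato",
    theiler: int = 0,
    max_points: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Mean trajectory divergence after 1..k steps.

    For each reference point the Euclidean nearest neighbor outside the
    Theiler window (|i - n_i| > theiler) is located once; the curve entry at
    step s is then the mean over references of either the distance ratio
    after s steps (``wolf``) or its log2 (``sato``, the prediction error
    whose slope gives the largest Lyapunov exponent).

    Zero-distance guards: a pair whose initial and evolved distances are both
    zero contributes no divergence (0 for sato, ratio 1 for wolf); a pair
    whose log2 is undefined (one of the two distances zero) is skipped and
    the mean renormalized.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    m = pts.shape[0]
    if k >= m:
        raise EstimationError(f"prediction horizon k={k} >= number of points {m}")
    n_cand = m - k  # both i and n_i must have a valid s-step future
    if n_cand < 2:
        raise EstimationError("too few points for the requested horizon")
    cand = np.arange(n_cand)
    sel = _subsample(n_cand, max_points, seed)
    refs = cand[sel]
    dist = cdist(pts[refs], pts[cand])
    # Theiler exclusion (includes self at lag 0): a contiguous index band per row
    for row, i in enumerate(refs):
        dist[row, max(0, i - theiler) : i + theiler + 1] = np.inf
    if not np.isfinite(dist).any():
        raise EstimationError("Theiler window excludes every neighbor candidate")
    nn = np.argmin(dist, axis=1)
    finite = np.isfinite(dist[np.arange(refs.size), nn])
    refs, nn = refs[finite], nn[finite]
    d0 = np.linalg.norm(pts[refs] - pts[nn], axis=1)
    curve = np.empty(k)
    for s in range(1, k + 1):
        ds = np.linalg.norm(pts[refs + s] - pts[nn + s], axis=1)
        both_zero = (d0 == 0) & (ds == 0)
        if mode == "sato":
            ok = (d0 > 0) & (ds > 0)
            vals = np.log2(ds[ok] / d0[ok])
            total = float(vals.sum())  # both-zero pairs contribute 0
            count = int(ok.sum() + both_zero.sum())
        elif mode == "wolf":
            ok = d0 > 0
            vals = ds[ok] / d0[ok]
            total = float(vals.sum()) + float(both_zero.sum())  # ratio 1 each
            count = int(ok.sum() + both_zero.sum())
        else:
            raise ValueError(f"unknown mode {mode!r}")
        if count == 0:
            raise EstimationError(f"no valid neighbor pairs at step {s}")
        curve[s - 1] = total / count
    return curve


def largest_lyapunov(
    curve: np.ndarray,
    ts: float = 1.0,
    fit_lo: float = 0.1,
    fit_hi: float = 0.4,
) -> float:
    """Largest Lyapunov exponent (nats/second) from a Sato prediction-error curve.

    Least-squares slope of p_k versus k*Ts over the middle, approximately
    linear part k in [fit_lo*K, fit_hi*K], converted from bits to nats
    (multiplied by ln 2). The sign is preserved: positive values indicate
    exponential divergence (chaos).
    """
    curve = np.asarray(curve, dtype=float)
    big_k = curve.size
    if big_k < 4:
        raise FitError(f"need a curve of length >= 4, got {big_k}")
    ks = np.arange(1, big_k + 1)
    mask = (ks >= fit_lo * big_k) & (ks <= fit_hi * big_k)
    if mask.sum() < 2:
        raise FitError(
            f"fewer than 2 curve points in fit window [{fit_lo}, {fit_hi}]*{big_k}"
        )
    slope = np.polyfit(ks[mask] * ts, curve[mask], 1)[0]
    return float(slope * np.log(2.0))
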