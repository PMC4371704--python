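"""Supervised scatter-matrix dimension reduction and the KL-expansion baseline.

The supervised map maximizes the separability index J = tr(Sw^-1 Sb), where
Sw is the prior-weighted average of class covariances (within-class scatter)
and Sb the prior-weighted dispersion of class means (between-class scatter).
Its columns are the leading eigenvectors of Sw^-1 Sb; with L classes at most
L-1 eigenvalues are nonzero, so reduction to two dimensions is lossless in J
for a three-class problem. The unsupervised baseline (Karhunen-Loeve
expansion / principal axes) instead keeps the leading eigenvectors of the
overall covariance and can discard exactly the discriminative direction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.linalg

from .exceptions import ConditioningError, DegenerateClassError

_RIDGE_COND = 1e12
_RIDGE_DELTA = 1e-8


@dataclass
class ScatterStats:
    """Per-class first/second moments and the three scatter matrices."""

    labels: tuple[str, ...]
    class_means: np.ndarray  # (L, n)
    class_covs: np.ndarray  # (L, n, n), population convention
    priors: np.ndarray  # (L,), sums to 1
    overall_mean: np.ndarray  # (n,)
    sw: np.ndarray
    sb: np.ndarray
    sm: np.ndarray


@dataclass
class ReductionMap:
    """Linear map from feature space to the reduced space.

    Applying the map standardizes (if ``scale`` is set), centers by the
    training mean, and projects: Y = A^T ((x - center) / scale).
    """

    matrix: np.ndarray  # (n, m)
    eigenvalues: np.ndarray  # (m,), descending
    method: str  # "scatter" | "kl"
    center: np.ndarray
    scale: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "matrix": self.matrix.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "method": self.method,
            "center": self.center.tolist(),
            "scale": None if self.scale is None else self.scale.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ReductionMap":
        return cls(
            matrix=np.asarray(d["matrix"], dtype=float),
            eigenvalues=np.asarray(d["eigenvalues"], dtype=float),
            method=d["method"],
            center=np.asarray(d["center"], dtype=float),
            scale=None if d["scale"] is None else np.asarray(d["scale"], dtype=float),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ReductionMap":
        return cls.from_dict(json.loads(Path(path).read_text()))


def scatter_stats(
    features: np.ndarray,
    labels,
    priors: dict[str, float] | None = None,
) -> ScatterStats:
    """Class moments and scatter matrices Sw, Sb, Sm = Sw + Sb.

    Covariances use the population convention (divide by class count);
    priors default to the empirical class fractions.
    """
    x = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(labels)
    classes = tuple(str(c) for c in np.unique(y))
    if len(classes) < 2:
        raise DegenerateClassError("need at least 2 classes")
    n = x.shape[1]
    means, covs, p = [], [], []
    for c in classes:
        xc = x[y == c]
        if xc.shape[0] < 2:
            raise DegenerateClassError(f"class {c!r} has fewer than 2 members")
        means.append(xc.mean(axis=0))
        covs.append(np.cov(xc, rowvar=False, bias=True).reshape(n, n))
        p.append(
            priors[c] if priors is not None else xc.shape[0] / x.shape[0]
        )
    means = np.asarray(means)
    covs = np.asarray(covs)
    p = np.asarray(p, dtype=float)
    if not np.isclose(p.sum(), 1.0):
        raise ValueError(f"priors must sum to 1, got {p.sum()}")
    m0 = p @ means
    sw = np.einsum("i,ijk->jk", p, covs)
    dm = means - m0
    sb = np.einsum("i,ij,ik->jk", p, dm, dm)
    return ScatterStats(
        labels=classes,
        class_means=means,
        class_covs=covs,
        priors=p,
        overall_mean=m0,
        sw=sw,
        sb=sb,
        sm=sw + sb,
    )


def _regularized(sw: np.ndarray) -> np.ndarray:
    """Ridge repair: add delta*tr(Sw)/n * I only when badly conditioned."""
    if np.linalg.cond(sw) > _RIDGE_COND:
        n = sw.shape[0]
        sw = sw + _RIDGE_DELTA * np.trace(sw) / n * np.eye(n)
        if np.linalg.cond(sw) > 1 / np.finfo(float).eps:
            raise ConditioningError("within-class scatter singular beyond repair")
    return sw


def separability_index(stats: ScatterStats) -> float:
    """J = tr(Sw^-1 Sb); invariant under non-singular linear feature maps."""
    sw = _regularized(stats.sw)
    return float(np.trace(np.linalg.solve(sw, stats.sb)))


def scatter_reduction(stats: ScatterStats, m: int) -> ReductionMap:
    """Supervised map: leading m eigenvectors of Sw^-1 Sb.

    Eigenvalues of this (non-symmetric but symmetrizable) matrix are real and
    non-negative; at most L-1 exceed zero. Ordering is by eigenvalue
    descending then by original index; each eigenvector's largest-magnitude
    component is made positive so the map is deterministic.
    """
    n = stats.sw.shape[0]
    if m > n:
        raise ValueError(f"target dimension {m} exceeds feature dimension {n}")
    sw = _regularized(stats.sw)
    w = np.linalg.solve(sw, stats.sb)
    vals, vecs = scipy.linalg.eig(w)
    scale = max(np.abs(vals.real).max(), 1.0)
    if np.abs(vals.imag).max() > 1e-6 * scale:
        raise ConditioningError(
            "eigenvalues of Sw^-1 Sb have non-negligible imaginary parts"
        )
    vals = vals.real
    vecs = vecs.real
    order = np.lexsort((np.arange(vals.size), -vals))
    vals, vecs = vals[order], vecs[:, order]
    a = vecs[:, :m].copy()
    for j in range(m):
        if a[np.argmax(np.abs(a[:, j])), j] < 0:
            a[:, j] = -a[:, j]
    return ReductionMap(
        matrix=a,
        eigenvalues=vals[:m],
        method="scatter",
        center=stats.overall_mean.copy(),
    )


def kl_reduction(features: np.ndarray, m: int) -> ReductionMap:
    """Karhunen-Loeve expansion: leading m eigenvectors of the covariance.

    The transformed covariance is diagonal, the mean-squared reconstruction
    error equals the sum of the discarded eigenvalues, and with m = n the
    (orthonormal) map preserves Euclidean norms of centered vectors.
    """
    x = np.atleast_2d(np.asarray(features, dtype=float))
    n = x.shape[1]
    if m > n:
        raise ValueError(f"target dimension {m} exceeds feature dimension {n}")
    mu = x.mean(axis=0)
    cov = np.cov(x, rowvar=False, bias=True).reshape(n, n)
    vals, vecs = np.linalg.eigh(cov)
    order = np.lexsort((np.arange(vals.size), -vals))
    vals, vecs = vals[order], vecs[:, order]
    a = vecs[:, :m].copy()
    for j in range(m):
        if a[np.argmax(np.abs(a[:, j])), j] < 0:
            a[:, j] = -a[:, j]
    return ReductionMap(
        matrix=a, eigenvalues=vals[:m], method="kl", center=mu
    )


def apply_map(rmap: ReductionMap, features: np.ndarray) -> np.ndarray:
    """Project feature rows into the reduced space: Y = A^T (x - center)."""
    x = np.atleast_2d(np.asarray(features, dtype=float))
    if x.shape[1] != rmap.matrix.shape[0]:
        raise ValueError(
            f"feature dimension {x.shape[1]} does not match map rows "
            f"{rmap.matrix.shape[0]}"
        )
    xc = x - rmap.center
    if rmap.scale is not None:
        xc = xc / rmap.scale
    return xc @ rmap.matrix


def fit_reduction(
    features: np.ndarray,
    labels,
    m: int = 2,
    method: str = "scatter",
    standardize: bool = True,
    priors: dict[str, float] | None = None,
) -> ReductionMap:
    """Standardize (per-feature z-score) then fit the requested reduction.

    Standardization is fitted on the training set only and folded into the
    returned map, because the raw feature blocks mix very different scales
    (relative powers in [0, 1] against Lyapunov rates of tens per second).
    """
    x = np.atleast_2d(np.asarray(features, dtype=float))
    if standardize:
        mu = x.mean(axis=0)
        sd = x.std(axis=0)
        sd[sd == 0] = 1.0
        xs = (x - mu) / sd
    else:
        mu = np.zeros(x.shape[1])
        sd = None
        xs = x
    if method == "scatter":
        rmap = scatter_reduction(scatter_stats(xs, labels, priors=priors), m)
    elif method == "kl":
        rmap = kl_reduction(xs, m)
    else:
        raise ValueError(f"unknown reduction method {method!r}")
    # fold the z-score into the map: center in raw units, divide by sd
    if standardize:
        rmap.center = mu + sd * rmap.center
        rmap.scale = sd
    return rmap
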