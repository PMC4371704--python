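"""Closed-form quadratic classifier design and the piecewise two-stage scheme.

A quadratic discriminant h(Y) = Y'QY + V'Y + v0 in the reduced 2-D space is
linear in the lifted coordinates Z = (y1^2, 2 y1 y2, y2^2, y1, y2):
h = Vz'Z + v0. Maximizing the Fisher-type criterion
f = (P1 eta1^2 + P2 eta2^2) / (P1 s1^2 + P2 s2^2) over Vz has the closed-form
solution Vz = (P1 S1 + P2 S2)^-1 (M2 - M1) with v0 = -Vz'(P1 M1 + P2 M2),
where M_l, S_l are the Z-space class means and covariances. Three classes are
separated by two such classifiers in sequence: stage 1 splits the healthy
class from the pooled rest; stage 2 splits interictal from ictal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np

from .exceptions import (
    ConditioningError,
    DegenerateClassError,
    LabelError,
    StratificationError,
)
from .reduction import ReductionMap

_RIDGE_COND = 1e12
_RIDGE_DELTA = 1e-8


def lift_to_z(y) -> np.ndarray:
    """Lift a 2-vector to the quadratic coordinates (y1^2, 2y1y2, y2^2, y1, y2)."""
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y1, y2 = y
        return np.array([y1 * y1, 2 * y1 * y2, y2 * y2, y1, y2])
    y1, y2 = y[:, 0], y[:, 1]
    return np.column_stack([y1 * y1, 2 * y1 * y2, y2 * y2, y1, y2])


@dataclass
class QuadraticClassifier:
    """One quadratic discriminant; h < 0 decides ``class_neg``, h >= 0 ``class_pos``."""

    q: np.ndarray  # (2, 2) symmetric
    v: np.ndarray  # (2,)
    nu0: float
    class_neg: str = "neg"
    class_pos: str = "pos"

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.q.shape != (2, 2) or not np.isclose(self.q[0, 1], self.q[1, 0]):
            raise ValueError("Q must be a symmetric 2x2 matrix")

    @classmethod
    def from_coefficients(
        cls,
        q11: float,
        q12: float,
        q22: float,
        nu1: float,
        nu2: float,
        nu0: float,
        class_neg: str = "neg",
        class_pos: str = "pos",
    ) -> "QuadraticClassifier":
        return cls(
            q=np.array([[q11, q12], [q12, q22]]),
            v=np.array([nu1, nu2]),
            nu0=float(nu0),
            class_neg=class_neg,
            class_pos=class_pos,
        )

    def to_dict(self) -> dict:
        return {
            "q": self.q.tolist(),
            "v": self.v.tolist(),
            "nu0": self.nu0,
            "class_neg": self.class_neg,
            "class_pos": self.class_pos,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "QuadraticClassifier":
        return cls(
            q=np.asarray(d["q"], dtype=float),
            v=np.asarray(d["v"], dtype=float),
            nu0=float(d["nu0"]),
            class_neg=d["class_neg"],
            class_pos=d["class_pos"],
        )


def evaluate_h(clf: QuadraticClassifier, y) -> float | np.ndarray:
    """h(Y) = Y'QY + V'Y + v0 for one 2-vector or rows of 2-vectors."""
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        return float(y @ clf.q @ y + clf.v @ y + clf.nu0)
    return np.einsum("ij,jk,ik->i", y, clf.q, y) + y @ clf.v + clf.nu0


def design_quadratic(
    group_a: np.ndarray,
    group_b: np.ndarray,
    priors: tuple[float, float] | None = None,
    class_neg: str = "A",
    class_pos: str = "B",
) -> QuadraticClassifier:
    """Design the optimal quadratic discriminant between two sample groups.

    Group statistics are taken in the lifted Z-space (population covariance);
    priors default to the empirical group fractions and must sum to 1. The
    returned classifier satisfies h >= 0 for the ``group_b`` side.
    """
    za = lift_to_z(np.atleast_2d(group_a))
    zb = lift_to_z(np.atleast_2d(group_b))
    if za.shape[0] < 6 or zb.shape[0] < 6:
        raise DegenerateClassError(
            "each group needs >= 6 samples to estimate the Z-space covariance"
        )
    if priors is None:
        total = za.shape[0] + zb.shape[0]
        p1, p2 = za.shape[0] / total, zb.shape[0] / total
    else:
        p1, p2 = priors
        if not np.isclose(p1 + p2, 1.0):
            raise ValueError(f"priors must sum to 1, got {p1 + p2}")
    m1, m2 = za.mean(axis=0), zb.mean(axis=0)
    s1 = np.cov(za, rowvar=False, bias=True)
    s2 = np.cov(zb, rowvar=False, bias=True)
    pooled = p1 * s1 + p2 * s2
    if np.linalg.cond(pooled) > _RIDGE_COND:
        pooled = pooled + _RIDGE_DELTA * np.trace(pooled) / 5.0 * np.eye(5)
        if np.linalg.cond(pooled) > 1 / np.finfo(float).eps:
            raise ConditioningError("pooled Z-space covariance singular beyond repair")
    vz = np.linalg.solve(pooled, m2 - m1)
    nu0 = float(-vz @ (p1 * m1 + p2 * m2))
    q11, q12, q22, nu1, nu2 = vz
    return QuadraticClassifier.from_coefficients(
        q11, q12, q22, nu1, nu2, nu0, class_neg=class_neg, class_pos=class_pos
    )


@dataclass
class PiecewiseQuadraticModel:
    """Two quadratic classifiers covering three classes in the same 2-D space.

    ``stage1`` separates its ``class_neg`` (healthy) from the pooled rest;
    points on the rest side fall through to ``stage2`` (interictal vs ictal).
    A boundary value h == 0 is assigned to the positive side.
    """

    stage1: QuadraticClassifier
    stage2: QuadraticClassifier
    reduction: ReductionMap | None = None

    def to_dict(self) -> dict:
        return {
            "stage1": self.stage1.to_dict(),
            "stage2": self.stage2.to_dict(),
            "reduction": None if self.reduction is None else self.reduction.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PiecewiseQuadraticModel":
        return cls(
            stage1=QuadraticClassifier.from_dict(d["stage1"]),
            stage2=QuadraticClassifier.from_dict(d["stage2"]),
            reduction=None
            if d.get("reduction") is None
            else ReductionMap.from_dict(d["reduction"]),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PiecewiseQuadraticModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def train_piecewise(
    reduced: np.ndarray,
    labels,
    stage1_class: str = "healthy",
    stage2_order: tuple[str, str] = ("interictal", "ictal"),
    priors: str = "empirical",
) -> PiecewiseQuadraticModel:
    """Design the two-stage piecewise quadratic model on reduced 2-D samples.

    Stage 1 pools the two non-``stage1_class`` classes into a single group
    (one mean and covariance in Z-space) and separates ``stage1_class`` from
    it; stage 2 is designed on the two remaining classes only. Priors are the
    empirical fractions within each stage.
    """
    y2 = np.atleast_2d(np.asarray(reduced, dtype=float))
    lab = np.asarray([str(v) for v in labels])
    classes = set(np.unique(lab))
    expected = {stage1_class, *stage2_order}
    if classes != expected:
        raise LabelError(f"expected classes {sorted(expected)}, got {sorted(classes)}")
    first = y2[lab == stage1_class]
    rest = y2[lab != stage1_class]
    stage1 = design_quadratic(first, rest, class_neg=stage1_class, class_pos="rest")
    a, b = stage2_order
    stage2 = design_quadratic(
        y2[lab == a], y2[lab == b], class_neg=a, class_pos=b
    )
    return PiecewiseQuadraticModel(stage1=stage1, stage2=stage2)


def piecewise_classify(model: PiecewiseQuadraticModel, y) -> str | np.ndarray:
    """Assign class labels to one or many reduced 2-D points."""
    y = np.asarray(y, dtype=float)
    single = y.ndim == 1
    y2 = np.atleast_2d(y)
    h1 = np.asarray(evaluate_h(model.stage1, y2))
    h2 = np.asarray(evaluate_h(model.stage2, y2))
    out = np.where(
        h1 < 0,
        model.stage1.class_neg,
        np.where(h2 < 0, model.stage2.class_neg, model.stage2.class_pos),
    )
    return str(out[0]) if single else out


def _round1(x: float) -> float:
    """Round half-up to one decimal (display convention for percent metrics)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class ClassificationReport:
    """Confusion matrix (rows true, columns predicted) and percent metrics.

    ``sensitivity[c]`` is the fraction of class-c segments classified as c;
    ``specificity[c]`` is the fraction of the other classes' segments *not*
    classified as c; ``accuracy`` is the overall correct fraction. All three
    are stored as raw percentages; ``rounded()`` applies the one-decimal
    half-up display convention.
    """

    labels: tuple[str, ...]
    confusion: np.ndarray
    sensitivity: dict[str, float]
    specificity: dict[str, float]
    accuracy: float

    def rounded(self) -> dict:
        return {
            "sensitivity": {c: _round1(v) for c, v in self.sensitivity.items()},
            "specificity": {c: _round1(v) for c, v in self.specificity.items()},
            "accuracy": _round1(self.accuracy),
        }

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "confusion": self.confusion.tolist(),
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "rounded": self.rounded(),
        }

    def __str__(self) -> str:
        r = self.rounded()
        lines = ["confusion (rows true / cols predicted):"]
        width = max(len(c) for c in self.labels)
        header = " " * (width + 2) + "  ".join(f"{c:>{width}}" for c in self.labels)
        lines.append(header)
        for c, row in zip(self.labels, self.confusion):
            lines.append(
                f"{c:>{width}}  " + "  ".join(f"{v:>{width}d}" for v in row)
            )
        for c in self.labels:
            lines.append(
                f"{c}: sensitivity {r['sensitivity'][c]}%  "
                f"specificity {r['specificity'][c]}%"
            )
        lines.append(f"accuracy: {r['accuracy']}%")
        return "\n".join(lines)


def performance_report(true_labels, predicted_labels, labels=None) -> ClassificationReport:
    """Confusion matrix plus per-class sensitivity/specificity and accuracy."""
    yt = np.asarray([str(v) for v in true_labels])
    yp = np.asarray([str(v) for v in predicted_labels])
    if yt.size != yp.size:
        raise ValueError("label sequences must have equal length")
    if labels is None:
        labels = tuple(str(c) for c in np.unique(yt))
    else:
        labels = tuple(labels)
    unseen = set(yp) - set(labels)
    if unseen or (set(yt) - set(labels)):
        raise LabelError(f"labels outside {labels}: {sorted(unseen | (set(yt) - set(labels)))}")
    k = len(labels)
    index = {c: i for i, c in enumerate(labels)}
    conf = np.zeros((k, k), dtype=int)
    for t, p in zip(yt, yp):
        conf[index[t], index[p]] += 1
    total = conf.sum()
    sens = {}
    spec = {}
    for c, i in index.items():
        row = conf[i].sum()
        sens[c] = float(100.0 * conf[i, i] / row) if row else float("nan")
        others = total - row
        false_in = conf[:, i].sum() - conf[i, i]
        spec[c] = float(100.0 * (others - false_in) / others) if others else float("nan")
    accuracy = float(100.0 * np.trace(conf) / total)
    return ClassificationReport(
        labels=labels,
        confusion=conf,
        sensitivity=sens,
        specificity=spec,
        accuracy=accuracy,
    )


def kfold_cv(
    reduced: np.ndarray,
    labels,
    k: int = 5,
    seed: int = 0,
    stage1_class: str = "healthy",
    stage2_order: tuple[str, str] = ("interictal", "ictal"),
) -> float:
    """Stratified k-fold cross-validation loss of the piecewise model.

    Both classifiers are re-designed on each fold's training part; the
    returned value is the out-of-fold error fraction. Shuffling is seeded so
    the loss is reproducible.
    """
    y2 = np.atleast_2d(np.asarray(reduced, dtype=float))
    lab = np.asarray([str(v) for v in labels])
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for c in np.unique(lab):
        idx = np.nonzero(lab == c)[0]
        if idx.size < k:
            raise StratificationError(
                f"class {c!r} has {idx.size} members, fewer than k={k}"
            )
        idx = rng.permutation(idx)
        for f in range(k):
            folds[f].extend(idx[f::k].tolist())
    errors = 0
    for f in range(k):
        test_idx = np.asarray(sorted(folds[f]))
        train_mask = np.ones(lab.size, dtype=bool)
        train_mask[test_idx] = False
        model = train_piecewise(
            y2[train_mask],
            lab[train_mask],
            stage1_class=stage1_class,
            stage2_order=stage2_order,
        )
        pred = piecewise_classify(model, y2[test_idx])
        errors += int(np.sum(pred != lab[test_idx]))
    return errors / lab.size
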