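"""End-to-end orchestration: preprocessing -> feature extraction ->
dimension reduction -> classification.

``run_pipeline`` executes the four-step flow on either a directory of
Bonn-style ASCII segments (class-named subdirectories) or on freshly
simulated data, designs the piecewise quadratic model on the first
``train_per_class`` segments of each class, evaluates on the remainder, and
optionally writes the feature table, model JSON, report and a reproducibility
manifest.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classifier import (
    PiecewiseQuadraticModel,
    kfold_cv,
    performance_report,
    piecewise_classify,
    train_piecewise,
)
from .linear_features import FEATURE_NAMES, FeatureConfig, assemble_feature_vector
from .preprocess import BONN_FS, EegSegment, normalize_segment, read_bonn_segment
from .reduction import apply_map, fit_reduction
from .simulate import generate_dataset

log = logging.getLogger("eegspike")


@dataclass
class PipelineConfig:
    """All tunable parameters of a run, with the reference protocol defaults.

    Feature extraction: db4 wavelet at 4 levels, Hamming window, clinical
    FFT bands, 16 MI bins, 5% Cao saturation threshold, 5% attractor radius.
    Reduction: scatter-matrix method to m=2 with per-feature standardization.
    Classification: first ``train_per_class`` segments per class design the
    classifiers, the rest test them; 5-fold cross-validation.
    """

    features: FeatureConfig = field(default_factory=FeatureConfig)
    reduction_method: str = "scatter"
    reduced_dim: int = 2
    standardize: bool = True
    stage1_class: str = "healthy"
    stage2_order: tuple[str, str] = ("interictal", "ictal")
    train_per_class: int = 50
    per_class: int = 100
    segment_length: int = 4096
    fs: float = BONN_FS
    cv_folds: int = 5
    seed: int = 0
    input_dir: str | None = None  # None -> simulate

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stage2_order"] = list(self.stage2_order)
        return d


@dataclass
class PipelineResult:
    features: pd.DataFrame
    reduced: pd.DataFrame
    model: PiecewiseQuadraticModel
    report: "object"  # ClassificationReport
    cv_loss: float | None


def load_directory(path: str | Path, fs: float = BONN_FS) -> list[EegSegment]:
    """Load Bonn-style ASCII segments from class-named subdirectories."""
    path = Path(path)
    segments: list[EegSegment] = []
    for sub in sorted(p for p in path.iterdir() if p.is_dir()):
        label = sub.name
        for f in sorted(sub.glob("*.txt")) + sorted(sub.glob("*.csv")):
            segments.append(read_bonn_segment(f, fs=fs, label=label))
    if not segments:
        raise FileNotFoundError(f"no segment files under {path}")
    return segments


def extract_features(
    segments: list[EegSegment], config: FeatureConfig | None = None
) -> pd.DataFrame:
    """Feature table: columns x1..x30 plus label and source_id."""
    cfg = config or FeatureConfig()
    rows = []
    for i, seg in enumerate(segments):
        if not seg.is_normalized(tol=1e-3):
            seg = normalize_segment(seg)
        fv = assemble_feature_vector(seg, cfg)
        row = fv.as_dict()
        row["label"] = fv.label
        row["source_id"] = fv.source_id
        rows.append(row)
        if (i + 1) % 50 == 0:
            log.info("extracted features for %d/%d segments", i + 1, len(segments))
    return pd.DataFrame(rows, columns=list(FEATURE_NAMES) + ["label", "source_id"])


def split_train_test(
    features: pd.DataFrame, train_per_class: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """First ``train_per_class`` rows of each class design, the rest test."""
    train_idx: list[int] = []
    for label in features["label"].unique():
        idx = features.index[features["label"] == label]
        if len(idx) <= train_per_class:
            raise ValueError(
                f"class {label!r} has {len(idx)} segments; need more than "
                f"train_per_class={train_per_class} to keep a test set"
            )
        train_idx.extend(idx[:train_per_class])
    mask = features.index.isin(train_idx)
    return features[mask], features[~mask]


def run_pipeline(
    config: PipelineConfig | None = None, outdir: str | Path | None = None
) -> PipelineResult:
    """Execute the full four-step flow and (optionally) persist the outputs."""
    cfg = config or PipelineConfig()
    if cfg.input_dir is not None:
        log.info("loading segments from %s", cfg.input_dir)
        segments = load_directory(cfg.input_dir, fs=cfg.fs)
    else:
        log.info(
            "simulating %d segments/class (n=%d, fs=%.2f, seed=%d)",
            cfg.per_class, cfg.segment_length, cfg.fs, cfg.seed,
        )
        segments = generate_dataset(
            per_class=cfg.per_class, n=cfg.segment_length, fs=cfg.fs, seed=cfg.seed
        )
    segments = [
        s if s.is_normalized(tol=1e-3) else normalize_segment(s) for s in segments
    ]
    log.info("extracting %d-feature vectors from %d segments",
             len(FEATURE_NAMES), len(segments))
    features = extract_features(segments, cfg.features)

    train, test = split_train_test(features, cfg.train_per_class)
    xcols = list(FEATURE_NAMES)
    log.info("fitting %s reduction to %d dimensions on %d training segments",
             cfg.reduction_method, cfg.reduced_dim, len(train))
    rmap = fit_reduction(
        train[xcols].to_numpy(),
        train["label"].to_numpy(),
        m=cfg.reduced_dim,
        method=cfg.reduction_method,
        standardize=cfg.standardize,
    )
    y_train = apply_map(rmap, train[xcols].to_numpy())
    y_test = apply_map(rmap, test[xcols].to_numpy())
    reduced = pd.DataFrame(
        np.vstack([y_train, y_test]),
        columns=[f"y{i + 1}" for i in range(cfg.reduced_dim)],
    )
    reduced["label"] = list(train["label"]) + list(test["label"])
    reduced["split"] = ["train"] * len(train) + ["test"] * len(test)

    log.info("designing piecewise quadratic classifier")
    model = train_piecewise(
        y_train,
        train["label"].to_numpy(),
        stage1_class=cfg.stage1_class,
        stage2_order=cfg.stage2_order,
    )
    model.reduction = rmap
    pred = piecewise_classify(model, y_test)
    report = performance_report(test["label"].to_numpy(), pred)
    cv_loss = None
    if cfg.cv_folds and cfg.cv_folds >= 2:
        cv_loss = kfold_cv(
            y_train,
            train["label"].to_numpy(),
            k=cfg.cv_folds,
            seed=cfg.seed,
            stage1_class=cfg.stage1_class,
            stage2_order=cfg.stage2_order,
        )
        log.info("%d-fold cross-validation loss on the design set: %.3f",
                 cfg.cv_folds, cv_loss)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        features.to_csv(outdir / "features.csv", index=False)
        reduced.to_csv(outdir / "reduced.csv", index=False)
        model.to_json(outdir / "model.json")
        report_d = report.to_dict()
        report_d["cv_loss"] = cv_loss
        (outdir / "report.json").write_text(json.dumps(report_d, indent=2))
        manifest = {
            "eegspike_version": __version__,
            "python": sys.version,
            "numpy": np.__version__,
            "config": cfg.to_dict(),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        log.info("wrote features.csv, reduced.csv, model.json, report.json, "
                 "manifest.json to %s", outdir)

    return PipelineResult(
        features=features, reduced=reduced, model=model, report=report, cv_loss=cv_loss
    )
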