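"""Time-, frequency- and wavelet-domain features, and the 30-entry feature vector.

The feature set per segment, in order:

======  =======================================================
x1-x5   total variation of the five DWT sub-band signals
x6-x10  FFT (periodogram) relative band power, clinical bands
x11-x15 standard deviation of DWT coefficients per sub-band
x16-x20 relative power of DWT coefficients per sub-band
x21-x25 correlation dimension of each sub-band signal
x26-x30 largest Lyapunov exponent of each sub-band signal
======  =======================================================

Band order within each block is delta, theta, alpha, beta, gamma.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pywt

from . import nonlinear_features as nl
from .exceptions import (
    DecompositionDepthError,
    DegenerateSignalError,
    EstimationError,
    SubsegmentError,
)
from .preprocess import (
    BAND_NAMES,
    BandSet,
    EegSegment,
    get_bands,
    subband_signals,
)

FEATURE_NAMES: tuple[str, ...] = tuple(f"x{i}" for i in range(1, 31))

#: Human-readable description of each feature.
FEATURE_DESCRIPTIONS: dict[str, str] = {}
for _i, _band in enumerate(BAND_NAMES):
    FEATURE_DESCRIPTIONS[f"x{1 + _i}"] = f"Total variation - {_band}"
    FEATURE_DESCRIPTIONS[f"x{6 + _i}"] = f"Relative power FFT - {_band}"
    FEATURE_DESCRIPTIONS[f"x{11 + _i}"] = f"St. dev. coeff. DWT - {_band}"
    FEATURE_DESCRIPTIONS[f"x{16 + _i}"] = f"Relative power DWT - {_band}"
    FEATURE_DESCRIPTIONS[f"x{21 + _i}"] = f"Correlation dimension - {_band}"
    FEATURE_DESCRIPTIONS[f"x{26 + _i}"] = f"Largest Lyapunov exp. - {_band}"


# ---------------------------------------------------------------------------
# Time domain
# ---------------------------------------------------------------------------

def total_variation(seg: EegSegment) -> float:
    """Normalized mean absolute first difference.

    v = (1/(N-1)) * sum_n |x[n] - x[n-1]| / (max - min).

    Bounded between 1/(N-1) (monotone ramp) and 1 (full-range alternation);
    invariant under affine amplitude maps a*x + b with a > 0.
    """
    x = seg.samples
    rng = float(np.max(x) - np.min(x))
    if rng == 0.0:
        raise DegenerateSignalError("total variation undefined for a constant signal")
    return float(np.sum(np.abs(np.diff(x))) / ((x.size - 1) * rng))


# ---------------------------------------------------------------------------
# Frequency domain
# ---------------------------------------------------------------------------

@dataclass
class PeriodogramEstimate:
    """Two-sided periodogram on the full digital frequency axis 0..fs.

    ``power[m]`` estimates the power carried by the bin at ``freqs[m]``; with
    a rectangular window and P=1, ``sum(power) == sum(x**2)`` (Parseval under
    the 1/N convention). ``n_subsegments > 1`` is the Welch-averaged variant.
    """

    freqs: np.ndarray
    power: np.ndarray
    fs: float
    normalized: bool = False
    window: str = "rectangular"
    n_subsegments: int = 1


def periodogram(
    seg: EegSegment,
    window: str = "hamming",
    P: int = 1,
    normalized: bool = False,
) -> PeriodogramEstimate:
    """Periodogram per[w] = (1/N)|fft[w]|^2, optionally Welch-averaged.

    With ``P > 1`` the segment is split into P sub-segments of N/P samples
    and the (1/P) sum of their (P/N)|fft_p|^2 spectra is returned: lower
    variance, coarser frequency resolution. ``normalized=True`` divides by
    total power so the bins sum to one.
    """
    x = seg.samples
    n = x.size
    if P < 1 or P > n // 2:
        raise SubsegmentError(f"sub-segment count P={P} invalid for n={n}")
    if n % P:
        warnings.warn(
            f"dropping {n % P} trailing samples so n is divisible by P={P}",
            stacklevel=2,
        )
        x = x[: n - (n % P)]
        n = x.size
    length = n // P
    if window == "hamming":
        w = np.hamming(length)
    elif window == "rectangular":
        w = np.ones(length)
    else:
        raise ValueError(f"unknown window {window!r}")
    parts = x.reshape(P, length) * w
    spectra = np.abs(np.fft.fft(parts, axis=1)) ** 2  # (P, length)
    power = spectra.mean(axis=0) / length  # (1/P) * sum (P/N)|fft_p|^2
    freqs = np.arange(length) * seg.fs / length
    if normalized:
        power = power / power.sum()
    return PeriodogramEstimate(
        freqs=freqs,
        power=power,
        fs=seg.fs,
        normalized=normalized,
        window=window,
        n_subsegments=P,
    )


def band_relative_power(
    p: PeriodogramEstimate, bandset: BandSet
) -> dict[str, float]:
    """Fraction of total power per band.

    The two-sided axis is folded onto 0..fs/2 (a bin at f and its mirror at
    fs-f carry the same physical frequency), then each band sums the bins with
    f_lo <= f < f_hi. Requires a normalized periodogram so the fractions are
    directly interpretable; they sum to at most 1.
    """
    if not p.normalized:
        raise ValueError("band_relative_power requires a normalized periodogram")
    f_eff = np.minimum(p.freqs, p.fs - p.freqs)
    nyq = p.fs / 2.0
    out: dict[str, float] = {}
    for name, lo, hi in bandset.bands:
        if lo >= nyq:
            warnings.warn(
                f"band {name} ({lo}-{hi} Hz) lies outside the 0-{nyq:.1f} Hz axis",
                stacklevel=2,
            )
        mask = (f_eff >= lo) & (f_eff < hi)
        out[name] = float(p.power[mask].sum())
    return out


# ---------------------------------------------------------------------------
# Time-frequency domain (DWT)
# ---------------------------------------------------------------------------

@dataclass
class WaveletDecomposition:
    """Multi-level DWT coefficients with clinical band labels.

    ``coeffs`` maps set names A{L}, D{L}..D1 to coefficient arrays;
    ``band_labels`` maps each set to its clinical band name and ``edges`` to
    the true dyadic frequency edges implied by the sampling rate (these only
    approximate the nominal clinical edges).
    """

    wavelet_name: str
    levels: int
    coeffs: dict[str, np.ndarray]
    band_labels: dict[str, str]
    edges: dict[str, tuple[float, float]]

    def sets_low_to_high(self) -> list[str]:
        return [f"A{self.levels}"] + [f"D{k}" for k in range(self.levels, 0, -1)]


def dwt_decompose(
    seg: EegSegment,
    wavelet: str = "db4",
    levels: int = 4,
    mode: str = "symmetric",
) -> WaveletDecomposition:
    """Dyadic discrete wavelet decomposition (default: 4-level db4).

    Four levels split the 0-60 Hz EEG band into five sub-bands that
    approximately correspond to the clinical delta..gamma division.
    """
    x = seg.samples
    if x.size < 2 ** levels:
        raise DecompositionDepthError(
            f"{x.size} samples cannot support a {levels}-level decomposition"
        )
    arrs = pywt.wavedec(x, wavelet, mode=mode, level=levels)
    names = [f"A{levels}"] + [f"D{k}" for k in range(levels, 0, -1)]
    coeffs = dict(zip(names, arrs))
    band_labels = dict(zip(names, BAND_NAMES[: levels + 1]))
    edges: dict[str, tuple[float, float]] = {
        f"A{levels}": (0.0, seg.fs / 2 ** (levels + 1))
    }
    for k in range(levels, 0, -1):
        edges[f"D{k}"] = (seg.fs / 2 ** (k + 1), seg.fs / 2 ** k)
    return WaveletDecomposition(
        wavelet_name=wavelet,
        levels=levels,
        coeffs=coeffs,
        band_labels=band_labels,
        edges=edges,
    )


def dwt_reconstruct(d: WaveletDecomposition, mode: str = "symmetric") -> np.ndarray:
    """Inverse transform of all coefficient sets (perfect reconstruction)."""
    arrs = [d.coeffs[name] for name in [f"A{d.levels}"] + [f"D{k}" for k in range(d.levels, 0, -1)]]
    return pywt.waverec(arrs, d.wavelet_name, mode=mode)


def dwt_band_features(
    d: WaveletDecomposition,
) -> tuple[dict[str, float], dict[str, float]]:
    """Per-band coefficient standard deviation and relative power.

    Standard deviation uses the population convention (divide by count).
    Relative power of a band is the band's sum of squared coefficients over
    the total across all bands, so the five values sum to one.
    """
    stds: dict[str, float] = {}
    powers: dict[str, float] = {}
    total = 0.0
    for name in d.sets_low_to_high():
        c = d.coeffs[name]
        band = d.band_labels[name]
        stds[band] = float(np.std(c))
        powers[band] = float(np.sum(c ** 2))
        total += powers[band]
    if total > 0:
        powers = {b: v / total for b, v in powers.items()}
    return stds, powers


# ---------------------------------------------------------------------------
# Full feature vector
# ---------------------------------------------------------------------------

@dataclass
class FeatureConfig:
    """Parameters of the feature-extraction stage.

    Defaults follow the reference analysis protocol: db4 wavelet at four
    levels, Hamming window, single-segment periodogram (P=1), clinical band
    edges for the FFT features, 5% attractor radius, 5% Cao saturation
    threshold. Nonlinear parameters (lag, embedding dimension) are
    re-estimated per sub-band signal.
    """

    wavelet: str = "db4"
    levels: int = 4
    fft_band_preset: str = "clinical"
    window: str = "hamming"
    welch_subsegments: int = 1
    mi_bins: int = 16
    max_lag: int = 40
    cao_dmax: int = 8
    cao_threshold: float = 0.05
    eps_fraction: float = 0.05
    k_steps: int = 12
    fit_lo: float = 0.1
    fit_hi: float = 0.4
    max_points: int = 1000
    seed: int = 0


@dataclass
class FeatureVector:
    """Ordered 30-entry feature set for one segment."""

    values: np.ndarray
    names: tuple[str, ...] = FEATURE_NAMES
    label: str = "unknown"
    source_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != len(self.names):
            raise ValueError(
                f"expected {len(self.names)} features, got {self.values.size}"
            )

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))


def _subband_nonlinear(
    branch: EegSegment, cfg: FeatureConfig
) -> tuple[float, float]:
    """Correlation dimension and largest Lyapunov exponent of one sub-band signal."""
    x = branch.samples
    lag = nl.optimal_lag(x, max_lag=cfg.max_lag, n_bins=cfg.mi_bins)
    e, _ = nl.cao_functions(
        x, lag=lag, d_max=cfg.cao_dmax, max_points=cfg.max_points, seed=cfg.seed
    )
    d_min = nl.min_embedding_dimension(e, threshold=cfg.cao_threshold)
    pts = nl.embed(x, lag=lag, dim=d_min)
    eps = nl.attractor_radius(
        pts, fraction=cfg.eps_fraction, sample_size=cfg.max_points, seed=cfg.seed
    )
    # High-dimensional noise-like branches can leave no pairs inside the
    # nominal radius; widen it geometrically (bounded by the diameter) so the
    # estimator always has support.
    diameter = eps / cfg.eps_fraction
    while True:
        try:
            d_corr = nl.correlation_dimension(
                pts, eps, max_points=cfg.max_points, seed=cfg.seed
            )
            break
        except EstimationError:
            if eps > diameter:
                raise
            eps *= 1.5
    curve = nl.divergence_curve(
        pts,
        k=cfg.k_steps,
        mode="sato",
        theiler=lag * d_min,
        max_points=cfg.max_points,
        seed=cfg.seed,
    )
    lam = nl.largest_lyapunov(
        curve, ts=1.0 / branch.fs, fit_lo=cfg.fit_lo, fit_hi=cfg.fit_hi
    )
    return d_corr, lam


def assemble_feature_vector(
    seg: EegSegment, config: FeatureConfig | None = None
) -> FeatureVector:
    """Compute the full ordered 30-entry feature vector for one segment.

    The segment must already be normalized (zero mean, unit variance).
    Sub-band errors are re-raised with the feature name as context.
    """
    cfg = config or FeatureConfig()
    if not seg.is_normalized(tol=1e-3):
        raise ValueError(
            f"segment {seg.source_id!r} must be normalized before feature "
            "extraction (see normalize_segment)"
        )
    values = np.empty(30)

    branches = subband_signals(seg, wavelet=cfg.wavelet, levels=cfg.levels)

    # x1-x5: total variation of sub-band signals
    for i, band in enumerate(BAND_NAMES):
        try:
            values[i] = total_variation(branches[band])
        except Exception as exc:  # add feature context
            raise type(exc)(f"x{1 + i} ({band}): {exc}") from exc

    # x6-x10: periodogram relative band power
    p = periodogram(seg, window=cfg.window, P=cfg.welch_subsegments, normalized=True)
    rel = band_relative_power(p, get_bands(cfg.fft_band_preset))
    for i, band in enumerate(BAND_NAMES):
        values[5 + i] = rel[band]

    # x11-x20: DWT coefficient std and relative power
    d = dwt_decompose(seg, wavelet=cfg.wavelet, levels=cfg.levels)
    stds, powers = dwt_band_features(d)
    for i, band in enumerate(BAND_NAMES):
        values[10 + i] = stds[band]
        values[15 + i] = powers[band]

    # x21-x30: nonlinear features of sub-band signals
    for i, band in enumerate(BAND_NAMES):
        try:
            d_corr, lam = _subband_nonlinear(branches[band], cfg)
        except Exception as exc:
            raise type(exc)(f"x{21 + i}/x{26 + i} ({band}): {exc}") from exc
        values[20 + i] = d_corr
        values[25 + i] = lam

    return FeatureVector(values, label=seg.label, source_id=seg.source_id)
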