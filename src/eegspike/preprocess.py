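"""Segment I/O, normalization, segment-start selection, and wavelet band splitting.

The file dialect is the Bonn-style single-channel EEG segment: one ASCII
number per line (integer ADC counts in the original recordings), 4096 samples
at 173.61 Hz. Segments are normalized to zero mean and unit *population*
variance before feature extraction so that the technique is independent of
amplifier gain, electrode and patient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pywt

from .exceptions import (
    DecompositionDepthError,
    DegenerateSignalError,
    SegmentFormatError,
    SegmentLengthError,
)

#: Sampling rate (Hz) and segment length of the Bonn recording specification.
BONN_FS = 173.61
BONN_N = 4096

LABELS = ("healthy", "interictal", "ictal", "unknown")

BAND_NAMES = ("delta", "theta", "alpha", "beta", "gamma")


@dataclass
class EegSegment:
    """One fixed-length single-channel EEG signal.

    Parameters
    ----------
    samples : array-like of float
        Amplitude values (arbitrary units after normalization).
    fs : float
        Sampling rate in Hz.
    label : str
        One of ``healthy``, ``interictal``, ``ictal``, ``unknown``.
    source_id : str
        Free-text provenance tag (file name, generator seed, ...).
    """

    samples: np.ndarray
    fs: float = BONN_FS
    label: str = "unknown"
    source_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise SegmentLengthError(
                f"segment must be a 1-D signal with at least 2 samples, "
                f"got shape {self.samples.shape}"
            )
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")

    @property
    def n(self) -> int:
        """Number of samples."""
        return self.samples.size

    @property
    def duration(self) -> float:
        """Segment duration in seconds."""
        return self.n / self.fs

    def is_normalized(self, tol: float = 1e-6) -> bool:
        m = float(np.mean(self.samples))
        v = float(np.var(self.samples))
        return abs(m) < tol and abs(v - 1.0) < tol


@dataclass(frozen=True)
class BandSet:
    """Ordered, non-overlapping frequency sub-bands (delta ... gamma).

    Two presets exist: ``dyadic`` matches the octave splitting of a dyadic
    wavelet filter bank (alpha 8-16, beta 16-32, gamma 32-64 Hz) and
    ``clinical`` the conventional EEG band edges (alpha 8-12, beta 12-30,
    gamma 30-60 Hz).
    """

    bands: tuple[tuple[str, float, float], ...]
    preset: str = "custom"

    def __post_init__(self) -> None:
        names = [b[0] for b in self.bands]
        if list(names) != list(BAND_NAMES):
            raise ValueError(f"bands must be named {BAND_NAMES} in order, got {names}")
        prev_hi = -np.inf
        for name, lo, hi in self.bands:
            if not lo < hi:
                raise ValueError(f"band {name}: need f_lo < f_hi, got ({lo}, {hi})")
            if lo < prev_hi:
                raise ValueError(f"band {name} overlaps its predecessor")
            prev_hi = hi

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(b[0] for b in self.bands)

    def edges(self) -> Mapping[str, tuple[float, float]]:
        return {name: (lo, hi) for name, lo, hi in self.bands}


def dyadic_bands() -> BandSet:
    """Octave band edges matching a 4-level dyadic wavelet split of 0-64 Hz."""
    return BandSet(
        bands=(
            ("delta", 0.0, 4.0),
            ("theta", 4.0, 8.0),
            ("alpha", 8.0, 16.0),
            ("beta", 16.0, 32.0),
            ("gamma", 32.0, 64.0),
        ),
        preset="dyadic",
    )


def clinical_bands() -> BandSet:
    """Conventional clinical EEG band edges (0-60 Hz)."""
    return BandSet(
        bands=(
            ("delta", 0.0, 4.0),
            ("theta", 4.0, 8.0),
            ("alpha", 8.0, 12.0),
            ("beta", 12.0, 30.0),
            ("gamma", 30.0, 60.0),
        ),
        preset="clinical",
    )


def get_bands(preset: str) -> BandSet:
    if preset == "dyadic":
        return dyadic_bands()
    if preset == "clinical":
        return clinical_bands()
    raise ValueError(f"unknown band preset {preset!r}")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_bonn_segment(
    path: str | Path, fs: float = BONN_FS, label: str = "unknown"
) -> EegSegment:
    """Read a Bonn-style ASCII segment file: one number per line.

    Accepts optional surrounding whitespace, Unix or Windows line endings,
    and a Unicode minus sign. Blank lines are skipped. A one-column CSV
    parses through the same path.
    """
    path = Path(path)
    values: list[float] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            token = line.strip().rstrip(",").replace("−", "-")
            if not token:
                continue
            try:
                values.append(float(token))
            except ValueError:
                raise SegmentFormatError(
                    f"{path}: cannot parse line {lineno}: {line.strip()!r}"
                ) from None
    if not values:
        raise SegmentFormatError(f"{path}: file contains no samples")
    return EegSegment(np.asarray(values), fs=fs, label=label, source_id=path.name)


def write_segment(seg: EegSegment, path: str | Path) -> None:
    """Write one sample per line; integral values are written as integers so
    integer round-trips are bit-exact."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for v in seg.samples:
            if float(v).is_integer():
                fh.write(f"{int(v)}\n")
            else:
                fh.write(f"{float(v)!r}\n")


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalize_segment(seg: EegSegment) -> EegSegment:
    """Return the segment scaled to zero mean, unit population variance.

    Population variance (divide by N) is used: the segment is the entire
    population of interest, so the unit-variance invariant is then exact.
    """
    x = seg.samples
    mu = float(np.mean(x))
    sd = float(np.std(x))  # population convention
    if sd == 0.0:
        raise DegenerateSignalError(
            f"segment {seg.source_id!r} is constant; cannot normalize"
        )
    return replace(seg, samples=(x - mu) / sd)


# ---------------------------------------------------------------------------
# Segment-start selection
# ---------------------------------------------------------------------------

def select_segment_start(recording: EegSegment, n: int) -> int:
    """Pick the earliest start of an ``n``-sample window minimizing edge effects.

    A start ``s`` qualifies when (a) the amplitude difference between the
    window's last and first samples lies within the range of consecutive-sample
    differences inside the window, and (b) the slope at the window start has
    the same sign as the slope at its end. These two conditions suppress the
    spectral leakage a wrap-around discontinuity would cause in the FFT.

    Returns the smallest qualifying start; if none qualifies, falls back to the
    start with the smallest end-start amplitude mismatch and emits a warning.
    """
    x = recording.samples
    if x.size < n + 2:
        raise SegmentLengthError(
            f"recording has {x.size} samples; need at least {n + 2}"
        )
    n_starts = x.size - n + 1
    absdiff = np.abs(np.diff(x))
    # max consecutive |delta| within each candidate window (n-1 diffs per window)
    win_max = np.max(
        np.lib.stride_tricks.sliding_window_view(absdiff, n - 1), axis=1
    )[:n_starts]
    edge_mismatch = np.abs(x[n - 1:][:n_starts] - x[:n_starts])
    first_slope = np.sign(x[1:][:n_starts] - x[:n_starts])
    last_slope = np.sign(x[n - 1:][:n_starts] - x[n - 2:][:n_starts])
    ok = (edge_mismatch <= win_max) & (first_slope == last_slope)
    hits = np.nonzero(ok)[0]
    if hits.size:
        return int(hits[0])
    warnings.warn(
        "no segment start satisfies both edge criteria; "
        "falling back to minimum end-start mismatch",
        stacklevel=2,
    )
    return int(np.argmin(edge_mismatch))


# ---------------------------------------------------------------------------
# Sub-band splitting
# ---------------------------------------------------------------------------

def subband_signals(
    seg: EegSegment,
    wavelet: str = "db4",
    levels: int = 4,
    mode: str = "symmetric",
) -> dict[str, EegSegment]:
    """Split a segment into five time-domain sub-band signals via the DWT.

    Each output is the single-branch inverse-DWT reconstruction of one
    decomposition level (D1..D4, A4 for ``levels=4``), so the five signals sum
    back to the input exactly (perfect-reconstruction filter bank) and, for an
    orthogonal wavelet, are mutually near-orthogonal. Branches are labelled
    with the clinical band names: A4 -> delta, D4 -> theta, D3 -> alpha,
    D2 -> beta, D1 -> gamma.
    """
    x = seg.samples
    if x.size < 2 ** levels:
        raise DecompositionDepthError(
            f"{x.size} samples cannot support a {levels}-level decomposition"
        )
    coeffs = pywt.wavedec(x, wavelet, mode=mode, level=levels)
    # coeffs = [A_L, D_L, D_{L-1}, ..., D_1]; band names from low to high freq
    names = list(BAND_NAMES[: levels + 1])
    out: dict[str, EegSegment] = {}
    for i, name in enumerate(names):
        branch = [np.zeros_like(c) for c in coeffs]
        branch[i] = coeffs[i]
        rec = pywt.waverec(branch, wavelet, mode=mode)[: x.size]
        out[name] = replace(seg, samples=rec, source_id=f"{seg.source_id}:{name}")
    return out
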