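"""Deterministic synthetic EEG-like segments and canonical validation signals.

Three class profiles emulate the study conditions of the single-channel
segment collections the detector is built for: scalp recordings from healthy
subjects (broadband spectrum with a mild alpha rhythm), interictal
intracranial recordings from within the seizure focus (delta-dominant, low
variability) and ictal recordings (a strong spike-and-wave rhythm around
3.5 Hz that concentrates power in the delta/theta bands, raises the
delta-band total variation and lowers the attractor complexity). Each
segment is band-shaped colored noise - independent white (or pink) noise
filtered into the five clinical bands and mixed by target power weights -
plus an optional rhythmic component, normalized to zero mean and unit
variance. No physiological realism is claimed beyond these spectral and
waveform contrasts.

``canonical_signal`` provides signals with known nonlinear ground truth
(logistic map, Henon map, sine, white noise) for estimator validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.signal

from .preprocess import BAND_NAMES, BONN_FS, BONN_N, EegSegment, clinical_bands, normalize_segment

__all__ = [
    "Rhythm",
    "ClassProfile",
    "default_profiles",
    "generate_segment",
    "generate_dataset",
    "canonical_signal",
    "write_dataset",
]


@dataclass(frozen=True)
class Rhythm:
    """A rhythmic component mixed into the noise background.

    ``amplitude`` is the fraction of total signal power carried by the
    rhythm (0 = none, 1 = pure rhythm).
    """

    freq_hz: float
    waveform: str = "sine"  # "sine" | "spike-wave"
    amplitude: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.amplitude <= 1.0:
            raise ValueError(f"amplitude fraction must be in [0, 1], got {self.amplitude}")
        if self.waveform not in ("sine", "spike-wave"):
            raise ValueError(f"unknown waveform {self.waveform!r}")


@dataclass(frozen=True)
class ClassProfile:
    """Spectral recipe for one segment class."""

    name: str
    band_weights: tuple[float, ...]  # delta..gamma, sums to 1
    rhythm: Rhythm = Rhythm(10.0, "sine", 0.0)
    noise_model: str = "white"  # "white" | "pink"

    def __post_init__(self) -> None:
        w = np.asarray(self.band_weights, dtype=float)
        if w.size != len(BAND_NAMES) or np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError(
                f"band_weights must be {len(BAND_NAMES)} non-negative values "
                f"summing to 1, got {self.band_weights}"
            )
        if self.noise_model not in ("white", "pink"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")


def default_profiles() -> tuple[ClassProfile, ClassProfile, ClassProfile]:
    """The three default class recipes (healthy, interictal, ictal)."""
    return (
        ClassProfile(
            name="healthy",
            band_weights=(0.30, 0.15, 0.25, 0.22, 0.08),
            rhythm=Rhythm(10.0, "sine", 0.10),
            noise_model="white",
        ),
        ClassProfile(
            name="interictal",
            band_weights=(0.63, 0.20, 0.08, 0.05, 0.04),
            rhythm=Rhythm(3.0, "sine", 0.05),
            noise_model="pink",
        ),
        ClassProfile(
            name="ictal",
            band_weights=(0.35, 0.35, 0.13, 0.12, 0.05),
            rhythm=Rhythm(3.5, "spike-wave", 0.45),
            noise_model="white",
        ),
    )


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.SeedSequence):
        return np.random.default_rng(seed)
    return np.random.default_rng(np.random.SeedSequence(int(seed)))


def _base_noise(rng: np.random.Generator, n: int, fs: float, model: str) -> np.ndarray:
    white = rng.standard_normal(n)
    if model == "white":
        return white
    # pink: 1/sqrt(f) spectral shaping, flat below 0.5 Hz
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    spec /= np.sqrt(np.maximum(f, 0.5))
    return np.fft.irfft(spec, n=n)


def _band_filter(x: np.ndarray, lo: float, hi: float, fs: float) -> np.ndarray:
    nyq = fs / 2.0
    hi = min(hi, 0.99 * nyq)
    if lo <= 0:
        sos = scipy.signal.butter(4, hi / nyq, btype="lowpass", output="sos")
    else:
        sos = scipy.signal.butter(4, [lo / nyq, hi / nyq], btype="bandpass", output="sos")
    return scipy.signal.sosfiltfilt(sos, x)


def _unit_var(x: np.ndarray) -> np.ndarray:
    sd = np.std(x)
    return x / sd if sd > 0 else x


def _rhythm_wave(rhythm: Rhythm, n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    t = np.arange(n) / fs
    phase0 = rng.uniform(0, 1)
    if rhythm.waveform == "sine":
        return np.sin(2 * np.pi * (rhythm.freq_hz * t + phase0))
    # spike-wave: asymmetric sawtooth plus a narrow spike once per period
    phase = (rhythm.freq_hz * t + phase0) % 1.0
    saw = scipy.signal.sawtooth(2 * np.pi * phase, width=0.15)
    spike = np.exp(-0.5 * ((phase - 0.5) / 0.03) ** 2)
    return saw + 2.5 * spike


def generate_segment(
    profile: ClassProfile,
    n: int = BONN_N,
    fs: float = BONN_FS,
    seed=0,
) -> EegSegment:
    """Generate one normalized segment from a class profile.

    Independent noise realizations are filtered into the five clinical bands,
    scaled to the target power weights and summed; the rhythmic component (if
    any) replaces its power fraction. Output is exactly zero-mean,
    unit-variance. Same seed, same segment, bit for bit.
    """
    if n < 64:
        raise ValueError(f"segment length must be >= 64, got {n}")
    rng = _rng(seed)
    bands = clinical_bands().bands
    x = np.zeros(n)
    for (name, lo, hi), w in zip(bands, profile.band_weights):
        if w == 0:
            continue
        noise = _base_noise(rng, n, fs, profile.noise_model)
        x += np.sqrt(w) * _unit_var(_band_filter(noise, lo, hi, fs))
    x = _unit_var(x)
    a = profile.rhythm.amplitude
    if a > 0:
        wave = _unit_var(_rhythm_wave(profile.rhythm, n, fs, rng))
        x = np.sqrt(1 - a) * x + np.sqrt(a) * wave
    seg = EegSegment(x, fs=fs, label=profile.name, source_id=f"sim:{profile.name}:{seed}")
    return normalize_segment(seg)


def generate_dataset(
    profiles: Sequence[ClassProfile] | None = None,
    per_class: int = 100,
    n: int = BONN_N,
    fs: float = BONN_FS,
    seed: int = 0,
) -> list[EegSegment]:
    """Generate ``per_class`` segments for each profile.

    Per-segment seeds derive from ``SeedSequence((seed, class_index, index))``,
    which is documented by NumPy to be stable across platforms, so disjoint
    (class, index) pairs never share a stream.
    """
    if per_class < 1:
        raise ValueError("per_class must be >= 1")
    profiles = tuple(profiles) if profiles is not None else default_profiles()
    out: list[EegSegment] = []
    for ci, prof in enumerate(profiles):
        for i in range(per_class):
            ss = np.random.SeedSequence((int(seed), ci, i))
            seg = generate_segment(prof, n=n, fs=fs, seed=ss)
            seg.source_id = f"sim:{prof.name}:{i:03d}"
            out.append(seg)
    return out


def write_dataset(segments: Sequence[EegSegment], outdir: str | Path) -> Path:
    """Write segments as Bonn-style ASCII files into class-named directories.

    Returns the path of the manifest CSV listing file, label and source_id.
    """
    from .preprocess import write_segment

    outdir = Path(outdir)
    rows = ["path,label,source_id"]
    counters: dict[str, int] = {}
    for seg in segments:
        sub = outdir / seg.label
        sub.mkdir(parents=True, exist_ok=True)
        i = counters.get(seg.label, 0)
        counters[seg.label] = i + 1
        fname = sub / f"{seg.label}_{i:03d}.txt"
        write_segment(seg, fname)
        rows.append(f"{fname.relative_to(outdir)},{seg.label},{seg.source_id}")
    manifest = outdir / "manifest.csv"
    manifest.write_text("\n".join(rows) + "\n")
    return manifest


# ---------------------------------------------------------------------------
# Canonical validation signals
# ---------------------------------------------------------------------------

def canonical_signal(
    kind: str,
    n: int = 4096,
    params: dict | None = None,
    seed: int = 0,
    fs: float = 1.0,
) -> EegSegment:
    """Deterministic signals with known properties for estimator validation.

    ``sine`` (param ``period`` in samples, default 100), ``white_noise``
    (seeded standard normal), ``logistic_map`` (params ``r`` in (0, 4],
    default 4, ``x0`` in (0, 1), default 0.2), ``henon_map`` (params ``a``
    default 1.4, ``b`` default 0.3; x-coordinate series after a 100-step
    transient).
    """
    if n < 64:
        raise ValueError(f"signal length must be >= 64, got {n}")
    p = dict(params or {})
    if kind == "sine":
        period = float(p.pop("period", 100.0))
        if period <= 0:
            raise ValueError("period must be positive")
        x = np.sin(2 * np.pi * np.arange(n) / period)
    elif kind == "white_noise":
        x = _rng(seed).standard_normal(n)
    elif kind == "logistic_map":
        r = float(p.pop("r", 4.0))
        x0 = float(p.pop("x0", 0.2))
        if not 0 < r <= 4 or not 0 < x0 < 1:
            raise ValueError(f"logistic map needs 0 < r <= 4 and 0 < x0 < 1")
        x = np.empty(n)
        x[0] = x0
        for i in range(1, n):
            x[i] = r * x[i - 1] * (1 - x[i - 1])
    elif kind == "henon_map":
        a = float(p.pop("a", 1.4))
        b = float(p.pop("b", 0.3))
        if not (0 < a < 2 and 0 <= b < 1):
            raise ValueError(f"Henon map parameters out of range: a={a}, b={b}")
        transient = int(p.pop("transient", 100))
        xs = np.empty(n + transient)
        xv, yv = 0.0, 0.0
        for i in range(n + transient):
            xv, yv = 1 - a * xv * xv + yv, b * xv
            xs[i] = xv
        x = xs[transient:]
    else:
        raise ValueError(f"unknown canonical signal kind {kind!r}")
    if p:
        raise ValueError(f"unused parameters for {kind!r}: {sorted(p)}")
    return EegSegment(x, fs=fs, label="unknown", source_id=f"canonical:{kind}")
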