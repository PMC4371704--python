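# Methods

## Scope and data model

The package operates on fixed-length, single-channel EEG segments
(`EegSegment`: samples, sampling rate, class label). The reference recording
protocol is 4096 samples at 173.61 Hz (≈23.6 s), stored as one ASCII number
per line; the reader accepts optional whitespace, Windows line endings and a
Unicode minus, and one-column CSV files parse through the same path. All
analysis assumes segments normalized to zero mean and unit variance.
Population variance (divide by N) is used throughout — for normalization,
DWT coefficient standard deviations, and all covariance estimates — because
each segment (or design set) is treated as the complete population of
interest, which makes the unit-variance invariant exact rather than
approximate.

Two band conventions coexist deliberately. The dyadic preset (alpha 8–16,
beta 16–32, gamma 32–64 Hz) matches the octave splitting of the wavelet
filter bank; the clinical preset (alpha 8–12, beta 12–30, gamma 30–60 Hz)
is the conventional EEG division and is the default for periodogram band
powers. Sub-band *signals* (and everything derived from them: total
variation, nonlinear features) come from the DWT branches, whose true edges
at 173.61 Hz are ≈5.4/10.9/21.7/43.4 Hz; branches carry clinical band names
for readability, but the decomposition metadata reports the true dyadic
edges.

## Preprocessing

- **Normalization**: exact zero mean, unit population variance; constant
  segments are rejected rather than silently zeroed.
- **Segment-start selection** (for cutting segments out of longer
  recordings): the earliest start whose end-to-start amplitude jump lies
  within the window's consecutive-sample differences and whose boundary
  slopes agree in sign — both conditions suppress the wrap-around
  discontinuity that leaks across the FFT spectrum. If no start qualifies,
  the start minimizing the end-start mismatch is used and a warning emitted.
- **Sub-band splitting**: four-level `db4` DWT with symmetric signal
  extension; each sub-band signal is the inverse transform of one
  coefficient set with the others zeroed. The five branches sum to the
  input exactly. Symmetric padding was chosen over periodization for its
  milder boundary artifacts on non-periodic signals; the cost is that
  branch orthogonality is only approximate near the edges (exact under
  `mode="periodization"`, which remains available). Signals shorter than
  2⁴ samples are rejected.

## Feature extraction (30 features)

Order: x1–x5 total variation per sub-band signal; x6–x10 periodogram
relative band power (clinical bands); x11–x15 DWT coefficient standard
deviation; x16–x20 DWT relative power; x21–x25 correlation dimension;
x26–x30 largest Lyapunov exponent — bands always delta, theta, alpha, beta,
gamma.

- **Total variation** is bounded in [1/(N−1), 1] and invariant to affine
  amplitude maps; it measures how often and how strongly the signal changes
  direction relative to its range.
- **Periodogram**: two-sided `|FFT|²/N` (Parseval-consistent under the 1/N
  convention), Hamming window by default (rectangular retained for
  Parseval checks), optional Welch averaging over P sub-segments (default
  P = 1; the averaged form trades frequency resolution for variance).
  Band powers fold the two-sided axis onto 0–Nyquist before summing bins,
  and are computed from the normalized periodogram so they are directly
  fractions of total power.
- **Wavelet features**: per-band coefficient standard deviation and the
  band's share of total squared-coefficient energy.

### Nonlinear features

Each sub-band signal is analyzed independently (lag and embedding dimension
re-estimated per band; a shared full-band embedding is a configuration away
but the per-band attractors differ enough that re-estimation is the
default).

- **Lag**: first local minimum of the mutual-information curve
  (equal-width amplitude bins, default 16 bins — a power of two that is
  stable at n ≈ 4096; the bin count is not critical). If the curve has no
  local minimum (strongly monotone MI, e.g. very smooth signals), the
  fallback is the first lag where MI drops below 1/e of its lag-1 value,
  else half the scan range, with a warning. Note that on *noiseless*
  periodic signals binned MI estimates are jagged and the first local
  minimum can appear before the quarter-period point; the quarter-period
  property shows up robustly as the curve's global minimum.
- **Embedding dimension**: Cao's method. Distances in the embedding-function
  ratios use the maximum (Chebyshev) norm of Cao's original formulation,
  under which the d- and (d+1)-dimensional distances nest; nearest
  neighbors exclude self with smallest-index tie-breaking, zero-distance
  denominators are skipped and the mean renormalized. d_min is the smallest
  d whose ratio e_{d+1}/e_d is within 5% of 1 (threshold configurable); the
  companion e* ratio staying at 1 for all d flags i.i.d. noise. If the
  function never saturates, d_max is used with a warning — for noise-like
  sub-bands this is expected, not an error.
- **Correlation dimension**: Takens maximum-likelihood estimator
  `d = −1/mean(ln(d_ij/ε))` over pairs with 0 < d_ij < ε, with
  ε = 5% of the attractor diameter (diameter from a seeded subsample, exact
  when the portrait is small). A literal variant without the inverse and
  the pair restriction is exposed for comparison (`mode="literal"`); it can
  go negative and the pipeline never uses it. In high-dimensional
  noise-like embeddings the nominal radius can trap no pairs; the feature
  assembler then widens ε geometrically (never past the diameter) so the
  estimator always has support.
- **Largest Lyapunov exponent**: Sato prediction error — for each reference
  point, the initial Euclidean nearest neighbor outside a Theiler window
  (default lag × dim, excluding trivially close temporal neighbors), then
  the mean log₂ distance ratio after k steps. λ is the least-squares slope
  of that curve against k·T_s over its middle part (k in [0.1K, 0.4K] by
  default), converted to nats/second (× ln 2). The Wolf mean-ratio variant
  of the divergence curve is also available.
- **Subsampling**: all neighbor searches are brute-force (O(M²), exactly
  reproducible, oracle-testable); portraits above `max_points` (default
  1000) are first reduced by a seeded random subsample. This caps the cost
  per segment at desk scale with a modest, documented accuracy cost, and
  seeded runs are bit-reproducible.

## Dimension reduction

Features are z-scored per feature over the design set before any reduction:
the blocks mix scales that differ by four orders of magnitude (relative
powers in [0,1] vs Lyapunov rates of tens per second), and without scale
handling the scatter solution is numerically dominated by the large-scale
block. The standardization is folded into the stored map, so applying a
trained `ReductionMap` to raw features is a single affine projection
`Y = Aᵀ((x − center)/scale)`.

The supervised map takes the m leading eigenvectors of `S_W⁻¹S_B`
(prior-weighted within-class and between-class scatter). Eigenvalues of
this problem are real and non-negative (it is similar to a symmetric PSD
problem) and at most L−1 are nonzero, so m = 2 preserves the full
separability index for three classes. Determinism: eigenpairs sorted by
eigenvalue then index, each eigenvector's largest-magnitude component made
positive. S_W receives a ridge `1e−8·tr(S_W)/n·I` only when its condition
number exceeds 1e12 (a 30-dimensional, 150-sample design can be
near-singular); truly irreparable matrices raise a conditioning error. The
KL expansion (principal axes of the overall covariance) is retained as the
unsupervised baseline it is: it keeps variance, not class separation.

## Classification

The quadratic discriminant is linear in the lifted coordinates
`Z = (y₁², 2y₁y₂, y₂², y₁, y₂)`, which reduces classifier design to a
generalized Fisher problem with the closed-form solution
`V_z = [P₁Σ₁+P₂Σ₂]⁻¹(M₂−M₁)`, `ν₀ = −V_zᵀ(P₁M₁+P₂M₂)` (the offset pins the
prior-weighted mean of h at zero; the criterion is unbounded if the offset
floats). Priors default to empirical group fractions; the pooled Z-space
covariance gets the same conditional ridge as S_W. Each group needs at
least 6 samples for the 5-dimensional Z covariance to be estimable.

Three classes are covered piecewise: stage 1 pools interictal and ictal
into a single "rest" group (one Z-space mean and covariance — the two-class
design formulas need a single second group) and separates healthy from it;
points on the rest side fall through to stage 2 (interictal vs ictal).
The boundary h = 0 is assigned to the positive side — a measure-zero event
that still needs a fixed rule.

Reports: 3×3 confusion matrix (rows true), per-class sensitivity
(true-positive rate) and specificity (fraction of other-class segments not
assigned to the class), overall accuracy. Raw percentages are kept
internally; display rounds half-up to one decimal. Cross-validation is
stratified k-fold (default 5) with seeded shuffling, re-designing both
classifiers per fold; the default train/test protocol uses the first 50
segments of each class for design and the rest for testing, mirroring the
reference protocol.

## Synthetic data

`simulate` generates the three-class study the detector is designed for.
Each segment is band-shaped colored noise — independent white (or
1/f-shaped pink) noise filtered into the five clinical bands
(4th-order Butterworth, zero-phase), each branch normalized to unit
variance and mixed by square-root weights so the band power fractions hit
the profile's targets — plus an optional rhythmic component taking a fixed
fraction of total power, then exact normalization. Default profiles:

| class | band weights (δ,θ,α,β,γ) | rhythm | noise |
|---|---|---|---|
| healthy | .30 .15 .25 .22 .08 | 10 Hz sine, 10% power | white |
| interictal | .63 .20 .08 .05 .04 | 3 Hz sine, 5% | pink |
| ictal | .35 .35 .13 .12 .05 | 3.5 Hz spike-wave, 45% | white |

The interictal delta weight (0.63 vs healthy 0.30) mirrors the reported
delta-power contrast between interictal and healthy recordings; the ictal
spike-wave (asymmetric sawtooth plus a narrow once-per-cycle spike) raises
the delta-band total variation and gives the class a low-dimensional
rhythmic attractor, the direction of the reported ictal contrasts. Band
weights are recovered by the periodogram within ±0.05 for rhythm-free
profiles, closing the loop between generator and extractor.

What the generator does **not** emulate: real EEG nonstationarity, artifact
contamination (eye blinks, EMG), patient-to-patient variability beyond
seeded noise, and the specific nonlinear-dynamical structure of cortical
recordings. Tests passing on this data therefore validate the machinery —
estimator correctness, reduction optimality, classifier design, end-to-end
plumbing — not clinical performance; headline accuracies on synthetic
classes this well separated are expected to be near 100% and say nothing
about accuracy on real recordings.

Per-segment seeds derive from `SeedSequence((master, class_index, index))`,
stable across platforms. `canonical_signal` supplies validation signals
with known ground truth: the r = 4 logistic map (λ = ln 2), the Hénon map
(embeds at d = 2), sines and seeded white noise.

## Problem sizes and defaults

The default synthetic study is 100 segments per class of 4096 samples —
the reference protocol's size — and runs the full pipeline in roughly two
to three minutes on one core; examples and most tests use smaller studies
(tens of segments, 512–4096 samples) chosen to exercise the same code paths
quickly. Estimator-validation fixtures use 2000–4000 points, enough for the
Takens and Sato estimators to sit well inside their quoted tolerances.

Key defaults in one place: db4 wavelet, 4 levels, symmetric extension;
Hamming window, P = 1; 16 MI bins, lag scan to 40; Cao scan to d = 8,
saturation threshold 5%; ε = 5% of attractor diameter; divergence horizon
12 steps, fit window [0.1, 0.4]; neighbor-search budget 1000 points;
reduction to m = 2 with standardization; 5-fold CV; 50/50 per-class
train/test split.

## Known limitations

- Nonlinear feature values depend on the neighbor-search budget and on the
  embedding parameters the per-band estimation picks; they are
  reproducible under a fixed seed but not comparable across different
  budgets.
- The Cao d_max cap (8) can truncate genuinely high-dimensional dynamics;
  noise-like bands legitimately hit the cap with a warning.
- The literal-form correlation estimator is provided for comparison only.
- The piecewise scheme is hard-wired to three classes with a fixed stage
  order (healthy first); it does not produce posterior probabilities.
- No artifact removal, no multi-channel support, no EDF/BDF readers.
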