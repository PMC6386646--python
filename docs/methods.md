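# Methods

## The model

A wearable session is a 6-channel time series (triaxial accelerometer +
triaxial gyroscope). The segmentation model assumes the series is piecewise
stationary: between breakpoints the samples are independent draws from a
multivariate normal with segment-specific mean and covariance. For
breakpoints b₀ = 0 < b₁ < … < b_K < b_{K+1} = T the fitted objective is

    Φ(b) = Σᵢ ψᵢ
    ψᵢ   = −(nᵢ/2) · (m ln 2π + ln det Σ̂ᵢ + tr(Σ̂ᵢ⁻¹ Sᵢ))
    Σ̂ᵢ  = Sᵢ + (λ/nᵢ)·I

where Sᵢ is the biased sample covariance of segment i, nᵢ its length,
m = 6, and λ ≥ 0 a regularisation weight that keeps near-singular segment
covariances (short segments, low-variance postures) from dominating the
likelihood. At λ = 0, tr(Σ̂ᵢ⁻¹Sᵢ) = m and ψᵢ is the maximised Gaussian
log-likelihood. The regularised covariance is pinned in one routine
(`_Cumulants.psi`) so the greedy search, the exhaustive test oracle, and the
reported parameters all share it.

### The greedy algorithm

*Addition (top-down)*: starting from no interior breakpoints, repeatedly
insert the single split — over all segments and all admissible positions —
with the largest Φ gain; stop early when the best gain is ≤ 0 unless a K is
forced. Ties go to the smallest index. *Adjustment (bottom-up)*: sweep the
breakpoints in order, moving each to the Φ-maximising position between its
two neighbours; repeat sweeps until one completes with no move. Φ strictly
increases on every accepted move and positions are finite, so termination is
guaranteed; a 1e-9 acceptance margin guards against floating-point
oscillation.

All segment statistics come from prefix sums of x and xxᵀ, so one candidate
costs O(m²) and split scans are vectorised (`numpy` batched `slogdet`/
`inv`); a 7 000-sample, 6-channel stream segments into ~70 breakpoints in
well under a second.

### Choosing K and λ

The Φ-versus-K curve recorded during addition flattens sharply at the true
bout count; the shipped elbow suggestion is the K maximising the negative
second difference of the curve. In the pipeline, prediction-time K is
`round(rate_per_minute × duration_minutes)` with `rate_per_minute` a profile
value calibrated on training streams and deliberately set *above* the
elbow — oversegmentation only splits pure segments, undersegmentation merges
activities. λ defaults to 1e-3 × the median channel variance of the stream
being segmented; results are insensitive to this within a couple of orders
of magnitude because the synthetic segments are well-conditioned.
`min_seg_len` defaults to 5 samples to keep segment covariances meaningful.

## Preprocessing

- Median filter, kernel 3, reflect padding: removes isolated spikes.
- Third-order low-pass Butterworth, applied forward–backward
  (`sosfiltfilt`): zero phase, so features and labels stay aligned; the
  effective stopband attenuation is the squared single-pass magnitude. The
  analytic response of this digital (bilinear-transform) filter is
  1/(1 + (tan(πf/fs)/tan(πfc/fs))^{2·order}) per pass, which the tests use
  as the oracle; near Nyquist this differs substantially from the
  continuous-time Butterworth formula.
- The cutoff is chosen by inspecting the Welch PSD (Hann, 50 % overlap,
  nperseg 256): 20 Hz for 50 Hz data, 8 Hz for the 20 Hz desk-scale
  profile (body motion lives below ~3 Hz). Order of operations: streams
  are aligned/resampled to the working rate *before* low-pass filtering,
  since a 20 Hz cutoff is meaningless at a 10 Hz native rate.

## Alignment and interpolation

Both sensors are snapped to an exact grid (integer-millisecond period,
anchored at the first sample's floor-to-grid time): each sample goes to its
nearest grid point (ties to the earlier point), collisions are averaged,
empty points are masked missing. The grid covers each sample's full nominal
period, so ideal r Hz input on a 50 Hz grid is missing exactly 1 − r/50 of
points. Missing points are filled by an ordinary least-squares line through
up to 5 non-missing neighbours on each side, evaluated at the missing
timestamp — a strict generalisation of two-point linear interpolation that
uses exactly the stated neighbourhoods; at stream edges only the available
side is used. Runs of all-channel-missing points strictly longer than 10 s
are cut out and the stream is split there. Per-channel gaps are
interpolated, not cut: truncation applies to dead *time periods*, not to a
single dropped channel.

## Features

Augmentation: 6 raw channels + 6 time derivatives (central differences,
one-sided at edges — "jerk") + 2 per-sensor Euclidean norms = 14 signals.
Per segment, 6 statistics (mean, SD, median absolute deviation about the
median (unscaled), min, max, entropy) on both the raw samples and the
one-sided magnitude spectrum of the mean-removed segment: 168 features.
Entropy is Shannon entropy (natural log) of |values| normalised to sum 1 —
spectral entropy in the frequency domain; this is an interpretation choice,
as "entropy" admits several definitions in the HAR feature tradition. A
window that is exactly constant has an all-zero spectrum; its entropy is
reported as 0 (the degenerate-distribution limit) so the feature matrix
stays finite. Segments of any length ≥ 2 are allowed; spectra are not
zero-padded because every statistic is a length-agnostic summary.

## Classification and evaluation

XGBoost multiclass (`multi:softprob`, 200 trees, learning rate 0.1, depth
2–3 by profile, histogram tree method, single thread). Training segments
take the majority ground-truth label (ties → the tied label occurring
earliest in the segment); fully unlabeled segments are dropped; purity is
kept for diagnostics. Training rows are canonically sorted before fitting
so the model is exactly invariant to row order. Evaluation broadcasts each
segment's prediction to its samples and scores per-sample, so every
windowing scheme shares the same denominator; unlabeled truth samples are
excluded and counted separately. Both per-class ratio families
(diagonal/row and diagonal/column) are reported under explicit names
because published tables are inconsistent about which is "recall".

## The synthetic generator

Each class is a stationary process x_t = µ_c + A_c sin(2πf_c t + φ) + ε_t,
ε_t ~ MVN(0, Σ_c), with a fresh uniform phase per bout. Static postures
(sit/stand/lie) have zero amplitude and differ in gravity orientation
across the accelerometer axes; the sit-vs-stand separation is deliberately
only ~0.8 noise-SD so that a sub-second window's sample mean is ambiguous
while a multi-second segment's is not. Dynamic classes (walk 1.6 Hz,
stairs 1.3 Hz, run 2.6 Hz) differ in oscillation frequency, amplitude and
noise level; walk vs stairs is intentionally subtle. The sinusoid violates
the within-segment i.i.d. assumption on purpose — real gait does too — and
the segmenter must still find boundaries from the induced mean/covariance
contrasts.

Shipped protocols: `breathe`-like (5 × 600 s + 300 s running at 10 Hz),
`harus`-like (twelve ~20 s bouts at 50 Hz), and `desk` (5 × 60 s + 30 s
running at 20 Hz), the scaled-down session used by the shipped experiments
and tests so that the full comparison — 12 training + 2 test streams, 200
trees, 10 replicate seeds — runs in minutes on one CPU. The bout shuffler
cuts each session at uniform-random interior points into 10 non-empty
subsessions (cut points drawn without replacement), shuffles all 60 and
concatenates; adjacent same-activity subsessions merge, so a shuffled
session typically has ~50 distinct bouts of wildly unequal length (mean
~6 s at desk scale). `degrade` splits a clean stream into per-sensor files
with Gaussian timestamp jitter, a constant inter-sensor offset, and
removed spans, for exercising the alignment path end to end.

What the generator does **not** emulate: biomechanical gait harmonics,
postural transitions, sensor saturation, orientation drift, heteroscedastic
noise within a bout. Passing tests therefore demonstrate that the
machinery behaves as designed under its own model assumptions — adaptive
windows beat fixed windows when bouts are unequal, match them when bouts
are equal — not that any particular accuracy carries over to real
recordings.

## Experiment profiles

| profile | sizes (s) | GGS rate/min | depth | cutoff |
|---|---|---|---|---|
| harus | 0.2, 0.8, 3, 8 | 7 | 2 | 20 Hz |
| breathe | 0.2, 0.8, 3, 8, 12, 40 | 2 | 3 | 20 Hz |
| desk_equal | 0.8, 3, 8, 30 | 4 | 3 | 8 Hz |
| desk_shuffled | 0.8, 3, 8, 30 | 12 | 3 | 8 Hz |

The desk GGS rates put K ≈ 22 (equal, 6 bouts) and K ≈ 66 (shuffled, ~50–60
bouts) for a 5.5-minute stream — both comfortably above the respective
elbows, mirroring the "conservatively above the inflection" practice.

## Numerical notes and limitations

- A segment whose regularised covariance is not positive definite gets
  ψ = −∞ and is never selected; at λ = 0 this means segments shorter than
  m+1 samples are effectively excluded by the likelihood itself.
- Greedy addition is not globally optimal for K ≥ 2 (only K = 1 is
  exhaustive); the adjustment phase repairs most misplacements but a
  pathological first split can persist.
- The greedy scan is O(T) candidate evaluations per added breakpoint;
  quadratic-and-worse exact dynamic programming is out of scope, as is
  streaming/online segmentation.
- `fixed_windows` keeps a final partial window of ≥ 2 samples and merges a
  1-sample remainder into the last full window, so windows always partition
  the stream exactly.
- Timestamps are integer milliseconds; grid rates must have integer-ms
  periods (50, 40, 25, 20, 10 Hz, …).
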