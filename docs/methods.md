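# Methods

## The model

Subcortical responses to continuous speech are modeled as a linear
convolution from a non-negative stimulus feature series (the *predictor*,
`x`) to single-channel EEG (`y`). To expose how the response changes with
presentation level, the predictor is partitioned into L intensity bins and
one impulse response — a temporal response function, TRF — is estimated per
bin in a *joint* regression:

    y[n] = Σ_l (h_l * x_l)[n] + noise,

where `x_l` equals `x` on the samples assigned to intensity bin `l` and is
zero elsewhere. Stacking lagged copies of all binned predictors into a
design matrix `X ∈ R^(N×KL)` (K lags per bin, zero-padded at the record
boundaries), the estimate is ordinary unregularized least squares,

    β = (XᵀX)⁻¹ Xᵀ y,

with `β` the concatenation of the L kernels. Joint estimation matters:
binned predictors are collinear at the lag scale (especially when bins
alternate quickly), and separate per-bin fits leak response energy across
levels — the test suite demonstrates this directly. No ridge penalty is
used; with 10–20 minutes of data per bin the unregularized solution is
stable, and a penalty would bias exactly the amplitude/latency comparisons
across levels that the analysis is for.

The implementation assembles `XᵀX` and `Xᵀy` from FFT cross-correlations of
the binned predictors plus explicit boundary-correction terms, which is
algebraically identical to building the dense lagged design (verified
against a brute-force dense solver to 1e-8 relative on random instances)
but runs in O(L²(N log N + K²)). A symmetric positive-definite solve is
attempted first; a singular Gram matrix falls back to a pseudoinverse with
a rank warning.

## Binning

Two binning modes are provided.

* **Scheduled ("ground-truth") bins** — each sample takes the level of the
  schedule segment it falls in; one bin per presented level (72/60/48/36 dB
  for speech). Crossfade-ramp samples belong to their segment's bin; they
  carry gains between the two adjacent levels, and at the quietest level
  they can dominate the bin's r.m.s. (a property inherited by anything
  computed from that bin's scale).
* **Inherent-intensity bins** — the predictor is smoothed with a 300 ms
  Hamming window as a running intensity measure and split at equal-count
  quantiles (default 8 bins). Equal counts equalize estimation SNR across
  bins; ties are broken by stable sample order, so counts are exactly equal
  up to one sample.

Unnormalized bins always sum back to the original predictor sample-exactly.
Before fitting, each binned predictor is scaled to unit r.m.s. over its
non-zero support so every level drives the regression equally; the scales
are recorded on the bin set (and on the fitted TRF set) so the partition and
the physical kernel units can be reconstructed. Normalization runs *after*
artifact zeroing, on the data actually entering the fit.

## Preprocessing

Cz referenced to the mastoid average; all filters are odd-length
linear-phase FIR kernels applied with centered convolution (zero-phase):

| step | default | contract |
|---|---|---|
| highpass | 1 Hz, Hamming windowed-sinc, transition 25% of cutoff | DC residual < −40 dB, passband ±1 dB |
| notch comb | 5 Hz-wide stops at every multiple of 50 Hz up to 1000 Hz, one multiband design | ≥30 dB at centers, ±1 dB midway |
| bandpass | 30–1000 Hz before TRF/ERP fitting | stopband ≥30 dB, passband ±1 dB |
| decimation | polyphase to the 4096 Hz analysis rate | anti-aliased |

Artifact rejection computes the mean and SD once over the whole recording,
and zeroes a ±0.5 s window around every sample beyond 5 SD — in the EEG and
in every predictor at identical sample indices; merged spans and the excluded
fraction are recorded. The analysis rate of 4096 Hz keeps content far above
the 1 kHz response band while halving the native 8192 Hz cost.

## Predictors

* **RS** — half-wave rectified speech, anti-alias resampled.
* **GT** — mean absolute value across a gammatone filterbank: 31 filters
  from 80 to 8000 Hz spaced 1 ERB-number apart
  (ERBn(f) = 21.4·log10(0.00437·f + 1)). Bands are 4th-order all-pole
  gammatone cascades (four 2nd-order resonators, unit gain at the center
  frequency); per-band "amplitude" is the rectified band signal, lowpass
  smoothing being subsumed by the anti-alias resampling. Band *magnitudes*
  (not powers) are averaged; either choice preserves the essential property
  that the predictor is 1-homogeneous — scaling the audio scales the
  predictor — which is what keeps level information available to the TRF.

Predictors from auditory periphery models with adaptation stages are not
reimplemented; `PredictorAdapter` accepts any external callable. Inherent
model lags are removed by per-trial cross-correlation against the RS
predictor within ±50 ms, taking the median lag over trials (robust to
occasional degenerate trials) and shifting once.

## Wave V metrics

TRF kernels (lag window −10..30 ms, matching the click-ERP epoch window and
covering the 4–10 ms wave V search region) are smoothed with a 4 ms Hamming
moving average before feature extraction; the same smoothing is applied to
click ERPs. Wave V is the largest *local* maximum between 4 and 10 ms; if a
kernel is monotone over the window the edge maximum is returned flagged as
`clear_peak=False` rather than silently accepted. SNR is
10·log10((S−N)/N) with S the mean power in a 5 ms window around the peak
and N the mean power over −10..0 ms, computed on the same smoothed
waveform used for detection; S ≤ N reports −inf, and the −5 dB display
floor exists only in reports, never in statistics. Level trends are OLS
fits of latency/amplitude against level in dB; across-measure comparisons
use Pearson correlations with Holm–Šidák step-down correction
(adjusted_i = 1 − (1 − p_i)^(m − i + 1), monotonized).

For morphology comparison with click ERPs, all TRFs can be rescaled by one
common factor equating grand-average TRF r.m.s. with grand-average click-ERP
r.m.s. (averaging across participants within level before taking the
r.m.s.); a single scalar cannot alter any level-dependent pattern.

## Synthetic sessions

The generator runs the model forward so every stage is testable without
recordings.

* **Predictor**: broadband magnitude noise, amplitude-modulated by a
  lognormal envelope driven by 3–6 Hz band noise (syllable-rate
  fluctuations, heavy-tailed so intensity octiles are non-degenerate), gated
  by ~10% pauses with 50 ms ramps, unit r.m.s. on its support.
* **Schedule**: as in the experiment — 1-min trials, either constant-level
  or hopping across {72, 60, 48, 36} dB every 5 s with 500 ms raised-cosine
  crossfades; levels balanced exactly in presented time.
* **Kernels**: wave-V-like 4th-order gammatone-envelope bumps (Gaussian
  optional), default latencies 7.5→5.7 ms and amplitudes 1→2.5 from 36 to
  72 dB, width 2 ms FWHM — generator defaults chosen to sit inside the
  plausible wave V range, not measured values. Ground-truth kernels are
  defined with respect to the *per-level unit-r.m.s.* predictors, mirroring
  the neural gain compression that keeps real responses in a similar
  amplitude range across a 36 dB stimulus span; the forward normalization
  scales are returned with the session so fitted kernels can be mapped into
  ground-truth units exactly.
* **Noise**: 1/f background (r.m.s. 35 against a clean-response r.m.s. of
  ~11, i.e. raw response-to-noise ≈ −10 dB) plus white sensor noise
  (r.m.s. 3.5), and sparse 200 ms biphasic artifacts (1.5/min at 15 SD),
  which the rejection stage excises at rates comparable to real sessions
  (~1–3% of data).

The forward convolution uses `scipy.signal.fftconvolve`; the estimator never
convolves at all (it assembles normal equations), so generator/estimator
agreement at zero noise (≤1e-6 relative; observed ~4e-9) is a genuine
cross-check of two independent code paths.

A toy **adaptive predictor** mimics periphery models with adaptation: each
level's samples are gain-equalized and delayed by that level's extra wave V
latency. Fitting against it moves the latency differences out of the EEG
model and into the predictor, so the fitted latency-vs-level slope collapses
into the permutation null band while the unmodified predictor preserves a
negative slope — the latency-flattening phenomenon that makes
adaptation-aware predictors unsuitable for level-dependence studies.

**What passing recovery shows, and what it does not.** The synthetic EEG is
exactly linear-in-the-predictor by construction, its noise is stationary
Gaussian 1/f and ~10 dB milder than typical scalp recordings, and artifacts
are isolated transients. Passing parameter recovery therefore demonstrates
the correctness and conditioning of the estimation machinery — not that
real recordings at clinical noise levels will yield 0.5 ms-accurate
latencies. Real data add nonlinear peripheral processing, non-stationary
noise, stimulus feedthrough and inter-participant variability that the
generator deliberately does not model.

## Problem sizes and numerical choices

* Parameter recovery runs 20 seeds of 40-min sessions (10 min per level) at
  4096 Hz; the adaptive-predictor contrast uses 12-min sessions (3 min per
  level), where the effect is already decisive. Unit tests use minutes-long
  sessions at 512–2048 Hz.
* Lags are integer samples; latencies are grid-quantized (0.24 ms at
  4096 Hz). Quantile bin edges use linear interpolation; degenerate
  (constant) predictors raise instead of producing empty bins.
* The smoother forces odd window lengths (zero phase); edge windows are
  truncated and renormalized so constants are preserved at the boundaries.
* Filters size themselves as 3.3·fs/transition-width taps (Hamming design),
  meeting the stated attenuation contracts; probe-tone tests enforce them.
* Reproducibility: every stochastic stage takes an explicit integer seed;
  derived seeds are drawn below 2³¹ from a seeded generator.

## Known limitations

* The periphery-model predictors (outer/inner hair cell and adaptation
  models) are adapter hooks only; the bundled adaptive transform is a
  caricature for testing the latency-flattening effect, not a model of the
  auditory periphery.
* Scheduled binning assigns crossfade-ramp samples to their segment's
  level; the quiet bins' normalization scale is therefore ramp-dominated.
  This matches the experimental bookkeeping but means "36 dB" kernels are
  estimated partly from louder-than-36 dB samples (~10% of short-trial
  time).
* Absolute dBA calibration, multi-channel analysis, ocular-artifact
  regression and earlier ABR waves (I–IV) are out of scope.
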