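# leveltrf

Level-dependent subcortical temporal response functions (TRFs) from
continuous-speech EEG.

## The problem

The auditory brainstem response (ABR) — in particular its wave V peak,
whose amplitude grows and latency shrinks with stimulus intensity — is the
workhorse of objective hearing assessment, but it is classically measured
by averaging thousands of responses to clicks. This package implements an
analysis that extracts the same level-dependent wave V information from EEG
recorded while a person listens to *natural continuous speech* presented at
stepped intensity levels, and, as a proof of concept, from the inherent
intensity fluctuations of speech itself. It is aimed at auditory
neuroscientists and audiology researchers working with single-channel
(Cz–mastoid) EEG at ABR-grade sampling rates.

## The method

A non-negative stimulus predictor `x` (half-wave rectified speech, or the
mean magnitude of a 31-channel, 1-ERB-spaced gammatone filterbank) is split
into L intensity bins — by the presentation schedule, or by equal-count
quantiles of the 300 ms-smoothed predictor — giving binned predictors `x_l`
that are zero outside their bin and are normalized to unit r.m.s. The EEG
is modeled as a sum of per-level convolutions,

    y = Σ_l h_l * x_l + n,

and all level-specific TRFs `h_l` (lags −10..30 ms) are estimated jointly
by unregularized least squares, `β = (XᵀX)⁻¹Xᵀy`, over a design matrix of
lagged binned predictors. Wave V is detected as the largest local maximum
of the 4 ms-smoothed kernel between 4 and 10 ms and scored as
`SNR = 10·log10((S−N)/N)` against the −10..0 ms baseline; latency and
amplitude trends across level are summarized by per-participant linear
fits, with Holm–Šidák-corrected Pearson correlations against click-ERP
features. A bundled synthetic-session generator (speech-like predictor,
scheduled level gains, known wave-V kernels, 1/f noise, artifacts) makes
the whole chain testable by parameter recovery. See `docs/methods.md` for
the full account.

## Worked example

Simulate an 8-minute session (2 min per level at 72/60/48/36 dB), fit
level-dependent TRFs, and extract wave V:

```
$ leveltrf simulate --out-dir session --seed 1 --minutes 8
wrote synthetic session (8 min, seed 1) to session
$ leveltrf trf --eeg session/eeg.h5 --predictor session/predictor.h5 \
      --schedule session/schedule.csv --out-dir results
{"fraction_excluded": 0.008336385091145834, "bin_labels": [36.0, 48.0, 60.0, 72.0]}
report bundle written to results
$ cat results/wave_v.csv
level,latency_ms,amplitude,snr_db,snr_display_db,clear_peak
36.0,7.8125,0.5856341569796899,14.862371332239423,14.862371332239423,True
48.0,7.080078125,0.9015595262798592,16.429428241288395,16.429428241288395,True
60.0,6.591796875,1.2357704389937765,16.31630326917312,16.31630326917312,True
72.0,5.859375,1.4805295440119413,17.42736036406954,17.42736036406954,True
$ cat results/trends.csv
metric,slope,intercept
latency,-0.052897135416666664,9.6923828125
amplitude,0.02515747561508893,-0.3076302666484856
```

Reading the tables: wave V latency falls (7.8 → 5.9 ms, −0.053 ms/dB) and
amplitude rises monotonically from 36 to 72 dB — the canonical wave V
intensity dependence — and every level's peak clears the 0 dB SNR threshold
for a meaningful peak. About 0.8% of the data was zeroed as artifacts. `results/` also
contains the fitted kernels (`trf.h5`, `trf_kernels.csv`), trend slopes
(`trends.csv`), diagnostic plots, and a `run_log.json` with the config
digest and excluded-data fraction. The same pipeline runs on real data by
pointing `--eeg` at a converted BDF recording (`leveltrf preprocess`) and
`--predictor` at a WAV-derived predictor (`leveltrf predictors`).

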