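"""Wave V feature extraction, SNR, level trends, and correlations.

Wave V is the dominant ABR peak (~5-8 ms); its amplitude grows and its
latency shrinks with stimulus intensity. This module extracts the peak from
smoothed TRF kernels or click ERPs, scores it with an SNR against the
pre-stimulus baseline, fits per-participant linear latency/amplitude vs
level trends, and correlates features across response types with Holm-Sidak
corrected Pearson tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .deconvolve import (
    ERP,
    LevelBinSet,
    TRFSet,
    bin_by_ground_truth,
    bin_by_inherent_intensity,
    estimate_trf,
    normalize_bins,
)
from .predictors import Predictor
from .preprocess import EEGRecording
from .stimuli import TrialSchedule
from .utils import hamming_smooth

__all__ = [
    "WaveVFeature",
    "LevelTrend",
    "smooth_waveform",
    "smooth_trfs",
    "smooth_erp",
    "scale_to_erp",
    "detect_wave_v",
    "compute_snr",
    "extract_wave_v",
    "fit_level_trend",
    "slope_permutation_p",
    "holm_sidak_correct",
    "correlate_features",
    "datalength_sweep",
]

SNR_DISPLAY_FLOOR = -5.0


@dataclass
class WaveVFeature:
    """Latency, amplitude and SNR of one wave V peak."""

    latency_ms: float
    amplitude: float
    snr: float = np.nan
    level: float | None = None
    clear_peak: bool = True

    @property
    def snr_display(self) -> float:
        """SNR floored at -5 dB, for plots only; statistics use ``snr``."""
        return max(self.snr, SNR_DISPLAY_FLOOR)


@dataclass
class LevelTrend:
    """Ordinary least-squares fit of a wave V metric against level (dB)."""

    metric: str
    slope: float
    intercept: float
    levels_used: tuple


def smooth_waveform(w: np.ndarray, window_width_ms: float, rate: float) -> np.ndarray:
    """Moving Hamming-weighted average (default pipeline width: 4 ms);
    length preserving, edge windows truncated and renormalized."""
    width = max(int(round(window_width_ms * rate / 1000.0)), 1)
    return hamming_smooth(np.asarray(w, dtype=float), width)


def smooth_trfs(trfs: TRFSet, window_width_ms: float = 4.0) -> TRFSet:
    kernels = np.stack([smooth_waveform(k, window_width_ms, trfs.rate) for k in trfs.kernels])
    return replace(trfs, kernels=kernels, smoothed=True)


def smooth_erp(erp: ERP, window_width_ms: float = 4.0, rate: float | None = None) -> ERP:
    if rate is None:
        dt = np.diff(erp.times_ms)
        rate = 1000.0 / dt[0]
    return ERP(erp.times_ms.copy(), smooth_waveform(erp.waveform, window_width_ms, rate),
               erp.level, erp.n_epochs)


def scale_to_erp(trf_sets: list[TRFSet], erps: list[ERP]) -> list[TRFSet]:
    """Scale every TRF by one common factor so the grand-average TRF r.m.s.
    matches the grand-average click-ERP r.m.s. (for morphology comparison;
    a single factor, so relative level effects are untouched)."""
    if not trf_sets or not erps:
        raise ValueError("need at least one TRF set and one ERP")
    mean_kernels = np.mean([t.kernels for t in trf_sets], axis=0)
    # grand average: across participants within each click level
    erp_levels = sorted({e.level for e in erps}, key=lambda v: (v is None, v))
    erp_means = [
        np.mean([e.waveform for e in erps if e.level == lvl], axis=0) for lvl in erp_levels
    ]
    rms_trf = float(np.sqrt(np.mean(mean_kernels**2)))
    rms_erp = float(np.sqrt(np.mean(np.stack(erp_means) ** 2)))
    if rms_trf == 0:
        raise ValueError("TRF r.m.s. is zero; cannot scale")
    factor = rms_erp / rms_trf
    return [
        replace(t, kernels=t.kernels * factor, scale_factor=t.scale_factor * factor)
        for t in trf_sets
    ]


def detect_wave_v(
    w: np.ndarray,
    lags_ms: np.ndarray,
    search: tuple[float, float] = (4.0, 10.0),
    level: float | None = None,
) -> WaveVFeature:
    """Largest local maximum in the search window (default 4-10 ms).

    If the window contains no local maximum (e.g. a monotone ramp), the
    window-edge maximum is returned with ``clear_peak=False``.
    """
    w = np.asarray(w, dtype=float)
    lags_ms = np.asarray(lags_ms, dtype=float)
    in_win = (lags_ms >= search[0]) & (lags_ms <= search[1])
    if not in_win.any():
        raise ValueError("lag axis does not cover the search window")
    interior = np.zeros(len(w), dtype=bool)
    interior[1:-1] = (w[1:-1] > w[:-2]) & (w[1:-1] >= w[2:])
    candidates = np.flatnonzero(interior & in_win)
    if candidates.size:
        best = candidates[np.argmax(w[candidates])]
        return WaveVFeature(float(lags_ms[best]), float(w[best]), level=level)
    win_idx = np.flatnonzero(in_win)
    best = win_idx[np.argmax(w[win_idx])]
    return WaveVFeature(float(lags_ms[best]), float(w[best]), level=level, clear_peak=False)


def compute_snr(
    w: np.ndarray,
    lags_ms: np.ndarray,
    peak_latency_ms: float,
    signal_halfwidth_ms: float = 2.5,
    noise_window: tuple[float, float] = (-10.0, 0.0),
) -> float:
    """Wave V SNR in dB: 10*log10((S - N) / N), with S the mean power in a
    5 ms window around the peak and N the mean power in the pre-stimulus
    baseline. Returns -inf when the signal window does not exceed the noise
    floor (reports floor the displayed value at -5 dB)."""
    w = np.asarray(w, dtype=float)
    lags_ms = np.asarray(lags_ms, dtype=float)
    sig = (lags_ms >= peak_latency_ms - signal_halfwidth_ms) & (
        lags_ms <= peak_latency_ms + signal_halfwidth_ms
    )
    noi = (lags_ms >= noise_window[0]) & (lags_ms < noise_window[1])
    if not sig.any() or not noi.any():
        raise ValueError("signal or noise window outside the lag axis")
    S = float(np.mean(w[sig] ** 2))
    N = float(np.mean(w[noi] ** 2))
    if N == 0:
        raise ValueError("noise window has zero power")
    if S <= N:
        return -np.inf
    return 10.0 * np.log10((S - N) / N)


def extract_wave_v(
    trfs: TRFSet,
    search: tuple[float, float] = (4.0, 10.0),
    smooth_ms: float | None = 4.0,
) -> list[WaveVFeature]:
    """Wave V features for every level of a TRF set. Peak detection and SNR
    are computed on the (optionally) smoothed kernels."""
    t = smooth_trfs(trfs, smooth_ms) if smooth_ms and not trfs.smoothed else trfs
    feats = []
    for kernel, label in zip(t.kernels, t.labels):
        f = detect_wave_v(kernel, t.lags_ms, search, level=float(label))
        f.snr = compute_snr(kernel, t.lags_ms, f.latency_ms)
        feats.append(f)
    return feats


def fit_level_trend(features: list[WaveVFeature], metric: str = "latency") -> LevelTrend:
    """OLS fit of latency (ms) or amplitude against level in dB."""
    attr = {"latency": "latency_ms", "amplitude": "amplitude"}[metric]
    levels = np.array([f.level for f in features], dtype=float)
    y = np.array([getattr(f, attr) for f in features], dtype=float)
    if len(np.unique(levels)) < 2:
        raise ValueError("need features at two or more levels")
    res = stats.linregress(levels, y)
    return LevelTrend(metric, float(res.slope), float(res.intercept), tuple(levels))


def slope_permutation_p(features: list[WaveVFeature], metric: str = "latency") -> float:
    """Two-sided permutation p-value for the level-trend slope, from the
    exhaustive permutation distribution of metric values over levels."""
    attr = {"latency": "latency_ms", "amplitude": "amplitude"}[metric]
    levels = np.array([f.level for f in features], dtype=float)
    y = np.array([getattr(f, attr) for f in features], dtype=float)
    obs = abs(stats.linregress(levels, y).slope)
    count = 0
    perms = list(itertools.permutations(range(len(y))))
    for p in perms:
        if abs(stats.linregress(levels, y[list(p)]).slope) >= obs - 1e-15:
            count += 1
    return count / len(perms)


def holm_sidak_correct(p_values) -> np.ndarray:
    """Holm-Sidak step-down adjusted p-values.

    Sorted ascending, adjusted_i = 1 - (1 - p_i)^(m - i + 1) (1-based rank),
    made monotone non-decreasing, then restored to the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj = np.maximum.accumulate(adj)
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def correlate_features(a: pd.DataFrame, b: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Pearson correlations between paired feature tables, Holm-Sidak
    corrected across the feature family."""
    if columns is None:
        columns = [c for c in a.columns if c in b.columns]
    if len(a) != len(b):
        raise ValueError("feature tables must be paired (same length)")
    if len(a) < 3:
        raise ValueError("need at least 3 paired observations")
    rows = []
    for col in columns:
        x = np.asarray(a[col], dtype=float)
        y = np.asarray(b[col], dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            raise ValueError(f"zero variance in feature {col!r}")
        r, p = stats.pearsonr(x, y)
        rows.append({"feature": col, "r": float(r), "p": float(p)})
    df = pd.DataFrame(rows)
    df["p_adj"] = holm_sidak_correct(df["p"].to_numpy())
    return df


def features_to_frame(features: list[WaveVFeature]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "level": [f.level for f in features],
            "latency_ms": [f.latency_ms for f in features],
            "amplitude": [f.amplitude for f in features],
            "snr_db": [f.snr for f in features],
            "snr_display_db": [f.snr_display for f in features],
            "clear_peak": [f.clear_peak for f in features],
        }
    )


def datalength_sweep(
    eeg: EEGRecording,
    pred: Predictor,
    schedule: TrialSchedule,
    increments_minutes: list[float],
    bin_mode: str = "ground_truth",
    n_bins: int = 8,
    lag_window: tuple[float, float] = (-10.0, 30.0),
    search: tuple[float, float] = (4.0, 10.0),
    smooth_ms: float = 4.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rerun binning + TRF estimation + wave V metrics on session prefixes of
    increasing length.

    Returns ``(features, trends)``: one row per (datalength, level) with
    wave V latency/amplitude/SNR, and one row per datalength with the fitted
    latency and amplitude slopes.
    """
    if max(increments_minutes) * 60 > len(pred) / pred.rate + 1e-9:
        raise ValueError("increment exceeds the session length")
    feat_rows = []
    trend_rows = []
    for minutes in increments_minutes:
        n = int(round(minutes * 60 * pred.rate))
        sub_pred = Predictor(pred.series[:n].copy(), pred.rate, pred.name, pred.applied_lag)
        sub_eeg = EEGRecording(eeg.series[:n].copy(), eeg.rate, reference=eeg.reference)
        if bin_mode == "ground_truth":
            bins = bin_by_ground_truth(sub_pred, schedule)
        elif bin_mode == "inherent":
            bins = bin_by_inherent_intensity(sub_pred, n_bins=n_bins)
        else:
            raise ValueError(f"unknown bin mode {bin_mode!r}")
        trfs = estimate_trf(sub_eeg, normalize_bins(bins), lag_window)
        feats = extract_wave_v(trfs, search, smooth_ms)
        for f in feats:
            feat_rows.append(
                {
                    "datalength_min": minutes,
                    "level": f.level,
                    "latency_ms": f.latency_ms,
                    "amplitude": f.amplitude,
                    "snr_db": f.snr,
                    "clear_peak": f.clear_peak,
                }
            )
        trend_rows.append(
            {
                "datalength_min": minutes,
                "latency_slope": fit_level_trend(feats, "latency").slope,
                "amplitude_slope": fit_level_trend(feats, "amplitude").slope,
            }
        )
    return pd.DataFrame(feat_rows), pd.DataFrame(trend_rows)
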