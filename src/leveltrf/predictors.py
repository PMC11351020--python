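"""Stimulus predictors for subcortical TRF estimation.

Two predictors are provided: the half-wave rectified speech waveform (RS) and
the average magnitude across a 1-ERB-spaced gammatone filterbank (GT). Both
are non-negative feature series resampled to the analysis rate, and both are
amplitude-linear — scaling the audio scales the predictor by the same factor,
which is the property that preserves stimulus level information in the
regression.

Predictors derived from auditory periphery models with adaptation are outside
the scope of this package; :class:`PredictorAdapter` is the hook for plugging
in any external callable that maps audio to a feature series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import signal

from .stimuli import AudioSignal
from .utils import resample_to

__all__ = [
    "Predictor",
    "FilterbankSpec",
    "PredictorAdapter",
    "rectified_speech",
    "erb_number",
    "erb_number_to_freq",
    "erb_center_frequencies",
    "gammatone_sos",
    "gammatone_predictor",
    "align_predictor",
]

DEFAULT_ANALYSIS_RATE = 4096.0


@dataclass
class Predictor:
    """Non-negative stimulus feature series at the analysis rate."""

    series: np.ndarray
    rate: float
    name: str = "custom"
    applied_lag: float = 0.0

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=float)
        if not np.all(np.isfinite(self.series)):
            raise ValueError("predictor contains non-finite values")
        if np.any(self.series < 0):
            raise ValueError("predictor must be non-negative")

    def __len__(self) -> int:
        return len(self.series)

    def copy(self) -> "Predictor":
        return Predictor(self.series.copy(), self.rate, self.name, self.applied_lag)


@dataclass(frozen=True)
class FilterbankSpec:
    """Gammatone filterbank layout: 1-ERB-spaced centers in [f_low, f_high]."""

    f_low: float = 80.0
    f_high: float = 8000.0
    spacing: float = 1.0  # ERB-number units

    def __post_init__(self) -> None:
        if self.f_low > self.f_high:
            raise ValueError("f_low must not exceed f_high")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")

    @property
    def n_filters(self) -> int:
        return len(self.center_frequencies())

    def center_frequencies(self) -> np.ndarray:
        return erb_center_frequencies(self.f_low, self.f_high, self.spacing)


def erb_number(f: np.ndarray | float) -> np.ndarray | float:
    """ERB-number scale: ERBn(f) = 21.4 * log10(0.00437 f + 1)."""
    return 21.4 * np.log10(0.00437 * np.asarray(f, dtype=float) + 1.0)


def erb_number_to_freq(erb: np.ndarray | float) -> np.ndarray | float:
    return (10.0 ** (np.asarray(erb, dtype=float) / 21.4) - 1.0) / 0.00437


def erb_center_frequencies(
    f_low: float = 80.0, f_high: float = 8000.0, spacing: float = 1.0
) -> np.ndarray:
    """Center frequencies spaced ``spacing`` ERB-numbers apart, starting at
    ``f_low`` and not exceeding ``f_high`` (80-8000 Hz gives 31 centers)."""
    if f_low > f_high:
        raise ValueError("f_low must not exceed f_high")
    e_lo = float(erb_number(f_low))
    e_hi = float(erb_number(f_high))
    n = int(np.floor((e_hi - e_lo) / spacing + 1e-9)) + 1
    return np.asarray(erb_number_to_freq(e_lo + spacing * np.arange(n)))


def gammatone_sos(fc: float, fs: float, order: int = 4) -> np.ndarray:
    """All-pole gammatone filter as ``order`` cascaded 2nd-order resonators.

    Each section has a complex-conjugate pole pair at the center frequency
    with radius set by the filter's equivalent rectangular bandwidth
    (b = 1.019 * ERB(fc)), normalized to unit gain at the center. The cascade
    is numerically stable at any center frequency, unlike the direct-form
    8-pole transfer function.
    """
    erb = 24.7 * (4.37 * fc / 1000.0 + 1.0)
    bw = 1.019 * erb
    r = np.exp(-2.0 * np.pi * bw / fs)
    theta = 2.0 * np.pi * fc / fs
    a1, a2 = -2.0 * r * np.cos(theta), r * r
    z = np.exp(-1j * theta)
    gain = np.abs(1.0 + a1 * z + a2 * z * z)  # per-section gain at fc
    section = [gain, 0.0, 0.0, 1.0, a1, a2]
    return np.array([section] * order)


def rectified_speech(audio: AudioSignal, rate: float = DEFAULT_ANALYSIS_RATE) -> Predictor:
    """Half-wave rectified speech (RS) predictor, resampled to ``rate``."""
    if len(audio.samples) == 0:
        raise ValueError("audio is empty")
    hw = np.maximum(audio.samples, 0.0)
    series = resample_to(hw, audio.sample_rate, rate)
    return Predictor(np.maximum(series, 0.0), rate, name="RS")


def gammatone_predictor(
    audio: AudioSignal,
    spec: FilterbankSpec = FilterbankSpec(),
    rate: float = DEFAULT_ANALYSIS_RATE,
) -> Predictor:
    """Gammatone (GT) predictor: average band magnitude of a 4th-order
    gammatone filterbank.

    Each band is the audio filtered by an IIR approximation of the 4th-order
    gammatone filter; the band "amplitude" is its absolute value. Band
    magnitudes are averaged and resampled (anti-aliased) to the analysis
    rate.
    """
    fs = audio.sample_rate
    if spec.f_high * 2 > fs:
        raise ValueError("f_high above Nyquist for this audio")
    if len(audio.samples) == 0:
        raise ValueError("audio is empty")
    centers = spec.center_frequencies()
    acc = np.zeros_like(audio.samples)
    for fc in centers:
        acc += np.abs(signal.sosfilt(gammatone_sos(fc, fs), audio.samples))
    acc /= len(centers)
    series = resample_to(acc, fs, rate)
    return Predictor(np.maximum(series, 0.0), rate, name="GT")


@dataclass
class PredictorAdapter:
    """Hook for external predictor generators (e.g. auditory periphery
    models). ``func`` maps an :class:`AudioSignal` to a 1-D feature series at
    the audio rate; the adapter rectifies and resamples it."""

    func: Callable[[AudioSignal], np.ndarray]
    name: str = "external"

    def __call__(self, audio: AudioSignal, rate: float = DEFAULT_ANALYSIS_RATE) -> Predictor:
        series = np.asarray(self.func(audio), dtype=float)
        series = resample_to(series, audio.sample_rate, rate)
        return Predictor(np.maximum(series, 0.0), rate, name=self.name)


def _trial_slices(trial_bounds: Sequence, rate: float, n: int) -> list[slice]:
    bounds = list(trial_bounds)
    if len(bounds) == 0:
        raise ValueError("at least one trial is required")
    if np.isscalar(bounds[0]):
        pairs = list(zip(bounds[:-1], bounds[1:]))
    else:
        pairs = [(a, b) for a, b in bounds]
    slices = []
    for a, b in pairs:
        i0, i1 = int(round(a * rate)), int(round(b * rate))
        slices.append(slice(max(i0, 0), min(i1, n)))
    return slices


def align_predictor(
    pred: Predictor,
    reference: Predictor,
    trial_bounds: Sequence,
    max_lag: float = 0.05,
) -> Predictor:
    """Remove a predictor's inherent lag relative to a reference predictor.

    For each trial the lag maximizing the cross-correlation with the
    reference is found within ``+/-max_lag``; the median lag across trials is
    then compensated by shifting the predictor. A positive recovered lag
    means the predictor is delayed relative to the reference; the shift
    advances it by that amount. The applied shift is recorded in
    ``applied_lag`` (seconds).

    All-zero trials are excluded from the median; if every trial is zero an
    error is raised.
    """
    if pred.rate != reference.rate or len(pred) != len(reference):
        raise ValueError("predictor and reference must share rate and length")
    n = len(pred)
    ml = int(round(max_lag * pred.rate))
    lags = []
    for sl in _trial_slices(trial_bounds, pred.rate, n):
        a = pred.series[sl]
        b = reference.series[sl]
        if not a.any() or not b.any():
            continue
        c = signal.correlate(a, b, mode="full")
        center = len(b) - 1
        lo, hi = center - ml, center + ml + 1
        window = c[max(lo, 0) : hi]
        lags.append(np.argmax(window) + max(lo, 0) - center)
    if not lags:
        raise ValueError("all trials are zero; cannot align")
    shift = int(round(np.median(lags)))  # samples; >0: pred lags reference
    out = np.zeros_like(pred.series)
    if shift > 0:
        out[:-shift] = pred.series[shift:]
    elif shift < 0:
        out[-shift:] = pred.series[:shift]
    else:
        out[:] = pred.series
    return Predictor(out, pred.rate, pred.name, applied_lag=pred.applied_lag + shift / pred.rate)
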