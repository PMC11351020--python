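"""EEG conditioning: referencing, zero-phase FIR filtering, artifact zeroing.

The analysis uses one channel — Cz referenced to the mastoid average, the
standard ABR derivation. All filters are odd-length linear-phase FIR kernels
applied with centered (delay-compensated) convolution, so filtering is
zero-phase. Filter orders are windowed-sinc (Hamming) designs sized to meet
the stopband/passband contracts stated in each function.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import reduce

import numpy as np
from scipy import signal

from .predictors import Predictor
from .utils import resample_to

__all__ = [
    "EEGRecording",
    "rereference",
    "filter_highpass",
    "notch_comb",
    "bandpass_subcortical",
    "reject_artifacts",
    "decimate_to",
    "read_bdf",
]

logger = logging.getLogger(__name__)


@dataclass
class EEGRecording:
    """Single-channel EEG (microvolts) with a record of zeroed spans."""

    series: np.ndarray
    rate: float
    zeroed_segments: list = field(default_factory=list)
    reference: str = "Cz-mastoids"

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=float)
        if not np.all(np.isfinite(self.series)):
            raise ValueError("EEG contains non-finite values")

    def __len__(self) -> int:
        return len(self.series)

    @property
    def duration(self) -> float:
        return len(self.series) / self.rate

    @property
    def fraction_zeroed(self) -> float:
        total = sum(e - s for s, e in self.zeroed_segments)
        return min(total / self.duration, 1.0) if len(self) else 0.0

    def _replace(self, series: np.ndarray) -> "EEGRecording":
        return EEGRecording(series, self.rate, list(self.zeroed_segments), self.reference)


def rereference(
    cz: np.ndarray, mastoid_left: np.ndarray, mastoid_right: np.ndarray, rate: float = 8192.0
) -> EEGRecording:
    """Cz referenced to the average of the two mastoids."""
    cz, ml, mr = (np.asarray(x, dtype=float) for x in (cz, mastoid_left, mastoid_right))
    if not (len(cz) == len(ml) == len(mr)):
        raise ValueError("channel lengths differ")
    return EEGRecording(cz - (ml + mr) / 2.0, rate, reference="Cz-avg(M1,M2)")


def _odd(n: int) -> int:
    n = int(np.ceil(n))
    return n if n % 2 else n + 1


def _zero_phase(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    # odd-length linear-phase kernel + centered convolution == zero phase
    return signal.oaconvolve(x, taps, mode="same")


def highpass_taps(cutoff: float, rate: float, transition: float | None = None) -> np.ndarray:
    if transition is None:
        transition = 0.25 * cutoff
    numtaps = _odd(3.3 * rate / transition)
    return signal.firwin(numtaps, cutoff, pass_zero=False, fs=rate)


def filter_highpass(
    eeg: EEGRecording, cutoff: float = 1.0, transition: float | None = None
) -> EEGRecording:
    """Zero-phase FIR highpass (default 1 Hz; stopband attenuation > 40 dB)."""
    if cutoff >= eeg.rate / 2:
        raise ValueError("cutoff must be below Nyquist")
    return eeg._replace(_zero_phase(eeg.series, highpass_taps(cutoff, eeg.rate, transition)))


def notch_taps(base: float, width: float, max_freq: float, rate: float) -> np.ndarray:
    """One multiband-stop FIR kernel with notches at every multiple of
    ``base`` up to ``max_freq``."""
    centers = np.arange(base, max_freq + 1e-9, base)
    edges = []
    for fc in centers:
        edges.extend([fc - width / 2.0, fc + width / 2.0])
    numtaps = _odd(3.3 * rate / (width / 2.0))
    return signal.firwin(numtaps, edges, pass_zero=True, fs=rate)


def notch_comb(
    eeg: EEGRecording, base: float = 50.0, width: float = 5.0, max_freq: float = 1000.0
) -> EEGRecording:
    """Comb of FIR notches at multiples of ``base`` (power-line harmonics).

    Contracts: >= 30 dB attenuation at every notch center; passband midway
    between notches within +/-1 dB.
    """
    if not (base <= max_freq < eeg.rate / 2):
        raise ValueError("need base <= max_freq < Nyquist")
    return eeg._replace(_zero_phase(eeg.series, notch_taps(base, width, max_freq, eeg.rate)))


def bandpass_taps(low: float, high: float, rate: float, transition: float | None = None) -> np.ndarray:
    if transition is None:
        transition = 0.25 * low
    numtaps = _odd(3.3 * rate / transition)
    return signal.firwin(numtaps, [low, high], pass_zero=False, fs=rate)


def bandpass_subcortical(
    eeg: EEGRecording, low: float = 30.0, high: float = 1000.0
) -> EEGRecording:
    """Zero-phase FIR bandpass (default 30-1000 Hz) isolating the subcortical
    response band."""
    if not (0 < low < high < eeg.rate / 2):
        raise ValueError("invalid band edges")
    return eeg._replace(_zero_phase(eeg.series, bandpass_taps(low, high, eeg.rate)))


def _merge_intervals(intervals: np.ndarray) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in intervals:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def reject_artifacts(
    eeg: EEGRecording,
    predictors: list[Predictor] | None = None,
    n_sd: float = 5.0,
    zero_halfwidth: float = 0.5,
) -> tuple[EEGRecording, list[Predictor], float]:
    """Zero 1 s sections around samples beyond ``n_sd`` SDs of the mean.

    The mean and SD are computed once over the whole recording. The same
    sample spans are zeroed in the EEG and in every predictor, and the merged
    spans are recorded on the returned recording. Returns
    ``(eeg, predictors, fraction_excluded)``.
    """
    predictors = predictors or []
    x = eeg.series
    n = len(x)
    for p in predictors:
        if len(p.series) != n or p.rate != eeg.rate:
            raise ValueError("predictors must match the EEG in rate and length")
    mu, sd = x.mean(), x.std()
    bad = np.flatnonzero(np.abs(x - mu) > n_sd * sd)
    if bad.size == 0:
        return eeg._replace(x.copy()), [p.copy() for p in predictors], 0.0
    hw = int(round(zero_halfwidth * eeg.rate))
    spans = np.stack([np.maximum(bad - hw, 0), np.minimum(bad + hw + 1, n)], axis=1)
    merged = _merge_intervals(spans)
    out = x.copy()
    new_preds = [p.copy() for p in predictors]
    zeroed = 0
    for s, e in merged:
        out[s:e] = 0.0
        for p in new_preds:
            p.series[s:e] = 0.0
        zeroed += e - s
    eeg_out = eeg._replace(out)
    eeg_out.zeroed_segments = eeg.zeroed_segments + [
        (s / eeg.rate, e / eeg.rate) for s, e in merged
    ]
    frac = zeroed / n
    logger.info("artifact rejection zeroed %.2f%% of the data", 100 * frac)
    return eeg_out, new_preds, frac


def decimate_to(eeg: EEGRecording, rate: float) -> EEGRecording:
    """Anti-aliased resampling to the analysis rate; previously zeroed spans
    are re-zeroed after resampling."""
    series = resample_to(eeg.series, eeg.rate, rate)
    out = EEGRecording(series, rate, list(eeg.zeroed_segments), eeg.reference)
    for s, e in out.zeroed_segments:
        out.series[int(round(s * rate)) : int(round(e * rate))] = 0.0
    return out


def read_bdf(path, cz: str = "Cz", mastoids: tuple[str, str] = ("M1", "M2")) -> EEGRecording:
    """Read a BioSemi BDF file and return the re-referenced Cz channel."""
    import mne

    raw = mne.io.read_raw_bdf(path, preload=True, verbose="error")
    picks = [cz, *mastoids]
    data = raw.get_data(picks=picks) * 1e6  # volts -> microvolts
    return rereference(data[0], data[1], data[2], rate=float(raw.info["sfreq"]))
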