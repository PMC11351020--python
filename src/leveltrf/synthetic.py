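"""Synthetic sessions with known wave-V kernels, for parameter recovery.

The generator runs the analysis model forward: a speech-like non-negative
predictor is built, scheduled level gains are applied, and the EEG is the sum
over levels of a level-specific wave-V-like kernel convolved with that
level's (per-level normalized) predictor, plus 1/f background noise and
sparse high-amplitude artifacts.

Ground-truth kernels are defined in the same units the analysis estimates:
the kernels that multiply the *unit-r.m.s.-per-level* predictors. This
mirrors real recordings, where neural gain compression keeps the response in
a similar amplitude range across presentation levels even though the
stimulus spans 36 dB, and it makes recovered and ground-truth kernels
directly comparable.

The forward convolution here (``scipy.signal.fftconvolve``) shares no code
with the estimator's normal-equations assembly, so generator/estimator
agreement at zero noise is a genuine cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .deconvolve import ERP, TRFSet
from .predictors import Predictor
from .preprocess import EEGRecording
from .stimuli import ClickTrain, TrialSchedule, gain_envelope, generate_click_train

__all__ = [
    "GroundTruthKernels",
    "NoiseSpec",
    "SimulatedSession",
    "default_ground_truth",
    "make_speech_like_predictor",
    "one_over_f_noise",
    "simulate_session",
    "make_adaptive_predictor",
    "simulate_click_session",
    "recover_wave_v",
]

#: Background noise r.m.s. under the default kernels and a unit-r.m.s.
#: predictor. The clean response r.m.s. is ~11 under the defaults, so this
#: puts the raw EEG at roughly -10 dB response-to-noise power — noisy enough
#: that single epochs show nothing, mild enough that deconvolution precision
#: (not detectability) is what gets tested. Real scalp recordings sit lower.
DEFAULT_BACKGROUND_RMS = 35.0


@dataclass
class GroundTruthKernels:
    """Per-level wave-V-like kernel parameters (the recovery target).

    Latencies decrease and amplitudes increase strictly with level — the
    canonical intensity dependence of wave V.
    """

    levels: tuple[float, ...]
    latencies_ms: tuple[float, ...]
    amplitudes: tuple[float, ...]
    width_ms: float = 2.0
    family: str = "gammatone"  # or "gaussian"

    def __post_init__(self) -> None:
        lat = np.asarray(self.latencies_ms, dtype=float)
        amp = np.asarray(self.amplitudes, dtype=float)
        lvl = np.asarray(self.levels, dtype=float)
        if not (len(lvl) == len(lat) == len(amp)):
            raise ValueError("levels, latencies and amplitudes differ in length")
        order = np.argsort(lvl)
        if not np.all(np.diff(lat[order]) < 0):
            raise ValueError("latency must strictly decrease with level")
        if not np.all(np.diff(amp[order]) > 0):
            raise ValueError("amplitude must strictly increase with level")
        if np.any(lat < 4.0) or np.any(lat > 10.0):
            raise ValueError("latencies must lie within 4-10 ms")

    def params(self, level: float) -> tuple[float, float]:
        idx = list(self.levels).index(level)
        return self.latencies_ms[idx], self.amplitudes[idx]

    def kernel_on_axis(self, level: float, lags_ms: np.ndarray) -> np.ndarray:
        """Kernel waveform evaluated on a lag axis in ms, peak == amplitude."""
        lat, amp = self.params(level)
        t = np.asarray(lags_ms, dtype=float)
        if self.family == "gammatone":
            # 4th-order gammatone envelope: (u/3)^3 exp(3 - u), peak at u = 3
            s = self.width_ms / 3.5  # FWHM of u^3 e^-u is ~3.5 scale units
            t0 = lat - 3.0 * s
            u = (t - t0) / s
            out = np.zeros_like(t)
            pos = u > 0
            out[pos] = amp * (u[pos] / 3.0) ** 3 * np.exp(3.0 - u[pos])
            return out
        if self.family == "gaussian":
            sigma = self.width_ms / 2.355  # FWHM -> sigma
            return amp * np.exp(-0.5 * ((t - lat) / sigma) ** 2)
        raise ValueError(f"unknown kernel family {self.family!r}")

    def sampled(self, level: float, rate: float, tail_ms: float = 15.0) -> np.ndarray:
        """Causal kernel sampled from lag 0, long enough to decay."""
        lat, _ = self.params(level)
        n = int(round((lat + tail_ms) * rate / 1000.0))
        lags_ms = np.arange(n) * 1000.0 / rate
        return self.kernel_on_axis(level, lags_ms)


def default_ground_truth(levels: tuple[float, ...] = (36.0, 48.0, 60.0, 72.0)) -> GroundTruthKernels:
    """Defaults spanning the plausible wave V range: latency 7.5 -> 5.7 ms
    and amplitude 1 -> 2.5 from the quietest to the loudest level."""
    L = len(levels)
    lat = tuple(np.linspace(7.5, 5.7, L))
    amp = tuple(np.linspace(1.0, 2.5, L))
    return GroundTruthKernels(tuple(float(v) for v in levels), lat, amp)


@dataclass
class NoiseSpec:
    """Background and artifact noise parameters."""

    alpha: float = 1.0  # 1/f^alpha spectral exponent
    background_rms: float = DEFAULT_BACKGROUND_RMS
    white_rms: float = 3.5  # broadband sensor noise
    artifact_rate_per_min: float = 1.5
    artifact_amplitude_sd: float = 15.0  # multiples of background SD
    artifact_width_s: float = 0.2

    def __post_init__(self) -> None:
        for name in ("alpha", "background_rms", "white_rms", "artifact_rate_per_min",
                     "artifact_amplitude_sd", "artifact_width_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _band_noise(n: int, rate: float, f_lo: float, f_hi: float, rng) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to [f_lo, f_hi] (FFT mask)."""
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n, 1.0 / rate)
    spec[(f < f_lo) | (f > f_hi)] = 0.0
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def one_over_f_noise(n: int, rate: float, alpha: float, rms: float, rng) -> np.ndarray:
    """Gaussian noise with a 1/f^alpha power spectrum (flat below 0.5 Hz),
    scaled to the requested r.m.s."""
    if rms == 0 or n == 0:
        return np.zeros(n)
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n, 1.0 / rate)
    shape = (np.maximum(f, 0.5)) ** (-alpha / 2.0)
    shape[0] = 0.0
    x = np.fft.irfft(spec * shape, n)
    return x * (rms / x.std())


def make_speech_like_predictor(
    duration: float,
    rate: float = 4096.0,
    seed: int = 0,
    pause_fraction: float = 0.1,
    syllable_band: tuple[float, float] = (3.0, 6.0),
) -> Predictor:
    """Speech-like non-negative predictor: broadband magnitude noise,
    amplitude-modulated at the syllable rate with a heavy-tailed (lognormal)
    envelope, gated by pauses. Normalized to unit r.m.s. over its non-zero
    support."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    carrier = np.abs(rng.standard_normal(n))
    syll = _band_noise(n, rate, syllable_band[0], syllable_band[1], rng)
    env = np.exp(0.7 * syll)  # lognormal: heavy-tailed intensity octiles
    pred = carrier * env
    if pause_fraction > 0:
        slow = _band_noise(n, rate, 0.1, 1.0, rng)
        gate = (slow > np.quantile(slow, pause_fraction)).astype(float)
        ramp = np.hamming(max(int(0.05 * rate), 3))
        gate = np.convolve(gate, ramp / ramp.sum(), mode="same")
        gate[gate < 1e-3] = 0.0
        pred = pred * gate
    nz = pred != 0
    pred = pred / np.sqrt(np.mean(pred[nz] ** 2))
    return Predictor(pred, rate, name="synthetic-speech")


def _per_level_normalized(pred: Predictor, schedule: TrialSchedule):
    """Split a predictor by scheduled level and normalize each part to unit
    r.m.s. over its non-zero support (the forward counterpart of the
    analysis-side bin normalization). Returns ``(parts, scales)`` where
    ``scales[level]`` is the multiplier that was applied."""
    lvl = schedule.level_at_samples(len(pred), pred.rate)
    parts = {}
    scales = {}
    for level in sorted(schedule.levels):
        x = np.where(lvl == level, pred.series, 0.0)
        nz = x != 0
        s = 1.0
        if nz.any():
            s = 1.0 / np.sqrt(np.mean(x[nz] ** 2))
            x = x * s
        parts[level] = x
        scales[level] = s
    return parts, scales


def _inject_artifacts(eeg: np.ndarray, rate: float, noise: NoiseSpec, rng) -> np.ndarray:
    n = len(eeg)
    minutes = n / rate / 60.0
    n_events = rng.poisson(noise.artifact_rate_per_min * minutes)
    if n_events == 0:
        return eeg
    width = max(int(round(noise.artifact_width_s * rate)), 4)
    t = np.arange(width) / width
    shape = np.sin(2 * np.pi * t) * np.hanning(width)  # biphasic transient
    amp = noise.artifact_amplitude_sd * noise.background_rms
    out = eeg.copy()
    for pos in rng.integers(0, max(n - width, 1), size=n_events):
        out[pos : pos + width] += rng.choice([-1.0, 1.0]) * amp * shape
    return out


@dataclass
class SimulatedSession:
    """A forward-simulated session and everything needed to score recovery.

    ``level_scales`` records the per-level normalization multiplier the
    forward model applied to the gained predictor. The analysis renormalizes
    its bins *after* artifact zeroing, so its scales can differ; fitted
    kernels are mapped into ground-truth units by multiplying level ``l`` by
    ``analysis_scale_l / level_scales[l]``.
    """

    eeg: EEGRecording
    predictor: Predictor
    kernels: GroundTruthKernels
    level_scales: dict

    def __iter__(self):
        return iter((self.eeg, self.predictor, self.kernels))


def simulate_session(
    schedule: TrialSchedule,
    kernels: GroundTruthKernels | None = None,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    rate: float = 4096.0,
    pause_fraction: float = 0.1,
) -> SimulatedSession:
    """Forward-simulate a speech session: EEG = sum_l kernel_l * x_l + noise.

    The returned predictor carries the scheduled level gains (what the
    analysis would compute from the audio); the kernels are the recovery
    targets. Unpacks as ``(eeg, predictor, kernels)``.
    """
    if kernels is None:
        kernels = default_ground_truth(tuple(sorted(schedule.levels)))
    if noise is None:
        noise = NoiseSpec()
    if tuple(sorted(kernels.levels)) != tuple(sorted(schedule.levels)):
        raise ValueError("kernel levels do not match the schedule levels")
    rng = np.random.default_rng(seed)
    base = make_speech_like_predictor(
        schedule.duration, rate, seed=int(rng.integers(2**31)), pause_fraction=pause_fraction
    )
    genv = gain_envelope(schedule, len(base), rate)
    pred = Predictor(base.series * genv, rate, name="synthetic-speech")

    n = len(pred)
    clean = np.zeros(n)
    parts, scales = _per_level_normalized(pred, schedule)
    for level, x in parts.items():
        k = kernels.sampled(level, rate)
        if len(k) * 1000.0 / rate > 45.0:
            import warnings

            warnings.warn("kernel longer than the usual lag window", RuntimeWarning)
        clean += signal.fftconvolve(x, k)[:n]

    eeg = clean.copy()
    if noise.background_rms > 0:
        eeg += one_over_f_noise(n, rate, noise.alpha, noise.background_rms, rng)
    if noise.white_rms > 0:
        eeg += noise.white_rms * rng.standard_normal(n)
    eeg = _inject_artifacts(eeg, rate, noise, rng)
    return SimulatedSession(EEGRecording(eeg, rate, reference="synthetic"), pred, kernels, scales)


def make_adaptive_predictor(
    pred: Predictor, schedule: TrialSchedule, kernels: GroundTruthKernels
) -> Predictor:
    """Toy stand-in for an adaptive periphery model (the latency-flattening
    behaviour of adaptation-stage predictors).

    Each level's samples are gain-equalized to the loudest level's r.m.s. and
    delayed by that level's extra wave V latency relative to the loudest
    level. A TRF fitted with this predictor sees all peaks at the reference
    latency, abolishing the latency-vs-level slope, while fits with the
    unmodified predictor preserve it.
    """
    ref_level = max(kernels.levels)
    lat_ref, _ = kernels.params(ref_level)
    lvl = schedule.level_at_samples(len(pred), pred.rate)
    ref_mask = lvl == ref_level
    ref_rms = np.sqrt(np.mean(pred.series[ref_mask & (pred.series != 0)] ** 2))
    out = np.zeros_like(pred.series)
    for level in sorted(schedule.levels):
        mask = lvl == level
        x = np.where(mask, pred.series, 0.0)
        nz = x != 0
        if not nz.any():
            continue
        x = x * (ref_rms / np.sqrt(np.mean(x[nz] ** 2)))
        lat, _ = kernels.params(level)
        shift = int(round((lat - lat_ref) * pred.rate / 1000.0))
        if shift > 0:
            out[shift:] += x[:-shift]
        else:
            out += x
    return Predictor(out, pred.rate, name="adaptive", applied_lag=pred.applied_lag)


def recover_wave_v(
    session: SimulatedSession,
    schedule: TrialSchedule,
    bandpass: tuple[float, float] | None = (30.0, 1000.0),
    lag_window: tuple[float, float] = (-10.0, 30.0),
    smooth_ms: float = 4.0,
):
    """Run the analysis pipeline on a simulated session and pair every
    fitted wave V feature with its ground-truth counterpart.

    The EEG is bandpass filtered and artifact-rejected, the predictor is
    level-binned, normalized and jointly deconvolved, and fitted kernels are
    mapped into ground-truth units using the recorded normalization scales.
    The reference features come from the ground-truth kernel passed through
    the *same* linear front-end (bandpass + smoothing), since any linear
    filter applied to the EEG is inherited by the kernel estimate.

    Returns ``(fitted, reference)``: two equally ordered WaveVFeature lists.
    """
    from scipy.signal import fftconvolve as _fftconv

    from . import preprocess, waves
    from .deconvolve import bin_by_ground_truth, estimate_trf, normalize_bins

    eeg = session.eeg
    taps = None
    if bandpass is not None:
        taps = preprocess.bandpass_taps(bandpass[0], bandpass[1], eeg.rate)
        eeg = preprocess.bandpass_subcortical(eeg, *bandpass)
    eeg, (pred,), _ = preprocess.reject_artifacts(eeg, [session.predictor])
    bins = normalize_bins(bin_by_ground_truth(pred, schedule))
    trfs = estimate_trf(eeg, bins, lag_window)
    # map into ground-truth units: analysis scale / forward scale per level
    unit = np.array([bins.norm_scales[l] / session.level_scales[lab]
                     for l, lab in enumerate(bins.labels)])
    trfs.kernels = trfs.kernels * unit[:, None]
    fitted = waves.extract_wave_v(trfs, smooth_ms=smooth_ms)

    reference = []
    for lab in bins.labels:
        k = session.kernels.kernel_on_axis(float(lab), trfs.lags_ms)
        if taps is not None:
            k = _fftconv(k, taps, mode="same")
        k = waves.smooth_waveform(k, smooth_ms, trfs.rate)
        reference.append(waves.detect_wave_v(k, trfs.lags_ms, level=float(lab)))
    return fitted, reference


def simulate_click_session(
    levels: tuple[float, ...],
    kernels: GroundTruthKernels | None = None,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    rate: float = 4096.0,
    block_duration: float = 120.0,
    click_rate: float = 44.0,
    gap: float = 5.0,
    feedthrough: float = 0.0,
) -> tuple[EEGRecording, list[ClickTrain]]:
    """Per-level click blocks: EEG = kernel conv unsigned click train + noise.

    The neural response is polarity-insensitive (the same kernel for
    rarefaction and condensation clicks); ``feedthrough`` optionally adds a
    signed stimulus artifact at lag zero, which cancels in the ERP average of
    an alternating train. Blocks are separated by ``gap`` seconds of silence.
    """
    if kernels is None:
        kernels = default_ground_truth(tuple(sorted(levels)))
    if noise is None:
        noise = NoiseSpec()
    rng = np.random.default_rng(seed)
    # recording starts one gap before the first block, as in a real session
    n_total = int(round(((len(levels) + 1) * gap + len(levels) * block_duration + 0.1) * rate))
    clean = np.zeros(n_total)
    trains = []
    for i, level in enumerate(sorted(levels, reverse=True)):  # decreasing intensity
        t0 = gap + i * (block_duration + gap)
        train = generate_click_train(
            block_duration, click_rate, sample_rate=rate, seed=int(rng.integers(2**31))
        )
        onsets = train.onset_times + t0
        trains.append(ClickTrain(onsets, train.polarities, train.click_duration, rate))
        idx = np.round(onsets * rate).astype(int)
        unsigned = np.zeros(n_total)
        unsigned[idx] = 1.0
        clean += signal.fftconvolve(unsigned, kernels.sampled(level, rate))[:n_total]
        if feedthrough:
            clean[idx] += feedthrough * train.polarities
    eeg = clean.copy()
    if noise.background_rms > 0:
        eeg += one_over_f_noise(n_total, rate, noise.alpha, noise.background_rms, rng)
    if noise.white_rms > 0:
        eeg += noise.white_rms * rng.standard_normal(n_total)
    eeg = _inject_artifacts(eeg, rate, noise, rng)
    return EEGRecording(eeg, rate, reference="synthetic"), trains
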