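"""Shared numeric helpers."""

from __future__ import annotations

from math import gcd

import numpy as np
from scipy import signal


def hamming_smooth(x: np.ndarray, width_samples: int) -> np.ndarray:
    """Moving Hamming-weighted average, length preserving.

    Edge windows are truncated and renormalized, so a constant input is
    returned unchanged everywhere (including at the edges).
    """
    x = np.asarray(x, dtype=float)
    n = int(width_samples)
    if n < 1:
        raise ValueError("window width must be at least one sample")
    if n >= len(x):
        raise ValueError("window must be shorter than the waveform")
    if n == 1:
        return x.copy()
    if n % 2 == 0:
        n += 1  # odd length keeps the smoother zero-phase
    win = np.hamming(n)
    win = win / win.sum()
    num = signal.fftconvolve(x, win, mode="same")
    den = signal.fftconvolve(np.ones_like(x), win, mode="same")
    return num / den


def support_rms(x: np.ndarray) -> float:
    """Root mean square over the non-zero samples of ``x``."""
    nz = x != 0
    if not nz.any():
        raise ValueError("signal has no non-zero support")
    return float(np.sqrt(np.mean(x[nz] ** 2)))


def resample_to(x: np.ndarray, rate_in: float, rate_out: float) -> np.ndarray:
    """Polyphase (anti-aliased) resampling between integer-ratio rates."""
    if rate_in == rate_out:
        return np.asarray(x, dtype=float).copy()
    ri, ro = int(round(rate_in)), int(round(rate_out))
    if abs(rate_in - ri) > 1e-6 or abs(rate_out - ro) > 1e-6:
        raise ValueError("resampling requires near-integer rates")
    g = gcd(ri, ro)
    return signal.resample_poly(np.asarray(x, dtype=float), ro // g, ri // g)
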