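"""Zero-phase FFT-based cosine filtering and fixed-window segmentation.

The band-pass has unity gain in the passband and raised-cosine flanks of
configurable width centred on the band edges; it is applied in the frequency
domain with a purely real transfer function, hence exactly zero-phase (no
group delay). Filtering is always applied to the full recording before
segmentation so that window boundaries carry no per-window edge artifacts.
"""

from __future__ import annotations

import numpy as np
from scipy.fft import irfft, next_fast_len, rfft, rfftfreq

from .types import ParameterError, Signal, WindowSet

__all__ = ["bandpass_cosine", "lowpass_cosine", "bandpass_beta",
           "segment", "cosine_band_response"]


def cosine_band_response(freqs: np.ndarray, lo: float, hi: float,
                         transition: float) -> np.ndarray:
    """Raised-cosine band-pass transfer function evaluated at ``freqs``.

    Unity between ``lo + transition/2`` and ``hi - transition/2``; zero
    outside ``[lo - transition/2, hi + transition/2]``; half-cosine flanks
    of width ``transition`` centred on ``lo`` and ``hi``.
    """
    h = np.zeros_like(freqs, dtype=float)
    t = transition
    lo0, lo1 = lo - t / 2.0, lo + t / 2.0
    hi0, hi1 = hi - t / 2.0, hi + t / 2.0
    h[(freqs >= lo1) & (freqs <= hi0)] = 1.0
    rise = (freqs > lo0) & (freqs < lo1)
    h[rise] = 0.5 * (1.0 - np.cos(np.pi * (freqs[rise] - lo0) / t))
    fall = (freqs > hi0) & (freqs < hi1)
    h[fall] = 0.5 * (1.0 + np.cos(np.pi * (freqs[fall] - hi0) / t))
    return h


def _apply_response(x: np.ndarray, fs: float, response,
                    pad_seconds: float = 1.0) -> np.ndarray:
    """Zero-phase frequency-domain filter with edge-reflection padding.

    The record is odd-reflection-padded out to the full FFT length (never
    zero-extended, which would smear a step into the edges): odd reflection
    keeps both the value and the first derivative continuous at the seams,
    so circular wrap-around leakage is negligible.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    pad = int(round(pad_seconds * fs))
    nfft = next_fast_len(n + 2 * pad)
    left = (nfft - n) // 2
    xp = np.pad(x, (left, nfft - n - left), mode="reflect",
                reflect_type="odd")
    h = response(rfftfreq(nfft, d=1.0 / fs))
    y = irfft(rfft(xp) * h, nfft)
    return y[left:left + n]


def bandpass_cosine(x: np.ndarray, fs: float, lo: float, hi: float,
                    transition: float = 2.0) -> np.ndarray:
    """Zero-phase raised-cosine band-pass on a raw sample array."""
    if not 0 < lo < hi:
        raise ParameterError(f"need 0 < lo < hi, got lo={lo}, hi={hi}")
    if hi + transition / 2.0 >= fs / 2.0:
        raise ParameterError(f"band edge {hi} Hz (+flank) exceeds Nyquist "
                             f"{fs / 2.0} Hz")
    return _apply_response(x, fs, lambda f: cosine_band_response(f, lo, hi,
                                                                 transition))


def lowpass_cosine(x: np.ndarray, fs: float, cutoff: float,
                   transition: float = 0.05) -> np.ndarray:
    """Zero-phase low-pass: unity below ``cutoff - transition/2``, cosine
    flank of width ``transition`` centred on ``cutoff``."""
    if not 0 < cutoff < fs / 2.0:
        raise ParameterError(f"cutoff must be in (0, Nyquist), got {cutoff}")

    def response(f):
        h = np.zeros_like(f)
        lo0, lo1 = cutoff - transition / 2.0, cutoff + transition / 2.0
        h[f <= lo0] = 1.0
        flank = (f > lo0) & (f < lo1)
        h[flank] = 0.5 * (1.0 + np.cos(np.pi * (f[flank] - lo0) / transition))
        return h

    # pad on the filter's own time scale: a 0.1 Hz low-pass needs far more
    # edge context than the 1 s that suffices for the beta band-pass
    return _apply_response(x, fs, response, pad_seconds=1.0 / cutoff)


def bandpass_beta(signal: Signal, lo: float = 13.0, hi: float = 30.0,
                  transition: float = 2.0) -> Signal:
    """Band-pass a signal to the beta range (13-30 Hz by default)."""
    return signal.copy_with(bandpass_cosine(signal.samples, signal.fs, lo, hi,
                                            transition))


def segment(signal: Signal, window_length: float = 10.0) -> WindowSet:
    """Cut a signal into contiguous non-overlapping windows.

    The trailing remainder shorter than one window is discarded; a signal
    shorter than one window is an error.
    """
    win = int(round(window_length * signal.fs))
    if win <= 0:
        raise ParameterError("window_length too short for this sampling rate")
    n_win = signal.n // win
    if n_win < 1:
        raise ParameterError(
            f"signal of {signal.n} samples is shorter than one "
            f"{window_length} s window ({win} samples)")
    windows = signal.samples[:n_win * win].reshape(n_win, win)
    return WindowSet(windows=windows, window_length=window_length, fs=signal.fs)
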