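"""Hilbert amplitude envelope, slow-drift normalization and burstiness.

The beta-band amplitude envelope is the modulus of the analytic signal.
Dividing it by a low-pass-filtered (0.1 Hz cutoff) version of itself
removes slow drifts and isolates relative amplitude fluctuations; the
coefficient of variation (CV = SD/mean) of this normalized envelope is the
burstiness statistic — higher CV means more transient, burst-like beta
activity. For an unmodulated Gaussian narrowband signal the envelope is
Rayleigh and the CV approaches sqrt(4/pi - 1) ~ 0.523.

Cross-modal similarity is the Pearson correlation between the normalized
envelopes of the two channels. The first and last 0.5 s are treated as a
Hilbert edge region and excluded from both statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert
from scipy.stats import pearsonr
from sklearn.base import BaseEstimator

from .preprocess import lowpass_cosine
from .types import EstimationError, ParameterError

__all__ = ["EnvelopeResult", "EnvelopeBurstiness", "hilbert_envelope",
           "normalize_envelope", "burstiness_cv", "envelope_correlation"]

#: CV of a Rayleigh-distributed envelope (unmodulated Gaussian narrowband noise)
RAYLEIGH_CV = float(np.sqrt(4.0 / np.pi - 1.0))


@dataclass
class EnvelopeResult:
    raw_envelope: np.ndarray
    normalized_envelope: np.ndarray
    cutoff: float
    cv: float


def hilbert_envelope(x: np.ndarray, fs: float) -> np.ndarray:
    """Modulus of the analytic signal of an (already band-passed) series."""
    x = np.asarray(x, dtype=float).ravel()
    if not np.any(x):
        raise EstimationError("all-zero input has no envelope")
    if fs <= 0:
        raise ParameterError("fs must be positive")
    return np.abs(hilbert(x))


def normalize_envelope(raw_envelope: np.ndarray, fs: float,
                       cutoff: float = 0.1,
                       transition: float = 0.05) -> np.ndarray:
    """Divide the envelope by its zero-phase low-passed version.

    Requires at least 3/cutoff seconds of data so the low-pass is
    meaningful; a non-positive low-passed envelope indicates pathological
    input and is an error.
    """
    env = np.asarray(raw_envelope, dtype=float).ravel()
    if env.size < 3.0 / cutoff * fs:
        raise ParameterError(
            f"record of {env.size / fs:.1f} s too short for a {cutoff} Hz "
            f"normalization low-pass (need >= {3.0 / cutoff:.0f} s)")
    slow = lowpass_cosine(env, fs, cutoff, transition)
    if np.any(slow <= 0):
        raise EstimationError("low-passed envelope non-positive; "
                              "pathological input")
    return env / slow


def _trim(x: np.ndarray, fs: float | None, edge: float) -> np.ndarray:
    if fs is None or edge <= 0:
        return x
    k = int(round(edge * fs))
    if 2 * k >= x.size:
        raise ParameterError("record shorter than twice the edge trim")
    return x[k:x.size - k]


def burstiness_cv(normalized_envelope: np.ndarray, fs: float | None = None,
                  edge: float = 0.5) -> float:
    """Coefficient of variation (SD/mean) of the normalized envelope."""
    env = _trim(np.asarray(normalized_envelope, float).ravel(), fs, edge)
    if env.size == 0:
        raise ParameterError("empty envelope")
    mean = env.mean()
    if mean == 0:
        raise EstimationError("zero-mean envelope: CV undefined")
    return float(env.std(ddof=1) / mean)


def envelope_correlation(env_a: np.ndarray, env_b: np.ndarray,
                         fs: float | None = None, edge: float = 0.5) -> float:
    """Pearson correlation between two time-aligned normalized envelopes."""
    a = np.asarray(env_a, float).ravel()
    b = np.asarray(env_b, float).ravel()
    if a.size != b.size:
        raise ParameterError(f"length mismatch: {a.size} vs {b.size}")
    a, b = _trim(a, fs, edge), _trim(b, fs, edge)
    if a.std() == 0 or b.std() == 0:
        raise EstimationError("zero-variance envelope: correlation undefined")
    return float(pearsonr(a, b).statistic)


class EnvelopeBurstiness(BaseEstimator):
    """Envelope extraction + normalization + CV as one fit-shaped step.

    ``fit`` expects a band-passed scalar series; fitted attributes expose
    the raw and normalized envelopes and the burstiness CV.
    """

    def __init__(self, fs: float = 1000.0, cutoff: float = 0.1,
                 transition: float = 0.05, edge: float = 0.5):
        self.fs = fs
        self.cutoff = cutoff
        self.transition = transition
        self.edge = edge

    def fit(self, X, y=None):
        raw = hilbert_envelope(X, self.fs)
        norm = normalize_envelope(raw, self.fs, self.cutoff, self.transition)
        self.raw_envelope_ = raw
        self.normalized_envelope_ = norm
        self.cv_ = burstiness_cv(norm, self.fs, self.edge)
        return self

    @property
    def result_(self) -> EnvelopeResult:
        return EnvelopeResult(raw_envelope=self.raw_envelope_,
                              normalized_envelope=self.normalized_envelope_,
                              cutoff=self.cutoff, cv=self.cv_)
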