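"""Core containers and exceptions shared across the pipeline.

The pipeline passes single-channel neurophysiological time series
(:class:`Signal`), fixed-length segmentations (:class:`WindowSet`),
delay-embedded state-space reconstructions (:class:`Trajectory`), and
per-window nonlinear feature values (:class:`FeatureValue`) between stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np


class ParameterError(ValueError):
    """An argument violates a documented precondition."""


class SignalLoadError(RuntimeError):
    """A signal file or manifest row could not be loaded."""


class EstimationError(RuntimeError):
    """A feature estimator could not produce a value (degenerate input)."""


@dataclass
class Signal:
    """A single-channel recording with its sampling rate and provenance.

    Parameters
    ----------
    samples : ndarray
        1-D real-valued samples, arbitrary units.
    fs : float
        Sampling rate in Hz; must be positive.
    subject_id, modality : str
        Provenance labels; ``modality`` is ``"MEG"`` or ``"EMG"`` for
        cohort data, free-form for synthetic fixtures.
    kind : str
        Generator kind for synthetic signals (empty for loaded data).
    seed : int or None
        Seed used to generate the signal, if synthetic.
    """

    samples: np.ndarray
    fs: float
    subject_id: str = ""
    modality: str = ""
    kind: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if not self.fs > 0:
            raise ParameterError(f"sampling rate must be positive, got {self.fs}")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n / self.fs

    def copy_with(self, samples: np.ndarray) -> "Signal":
        return Signal(samples=samples, fs=self.fs, subject_id=self.subject_id,
                      modality=self.modality, kind=self.kind, seed=self.seed)


@dataclass
class WindowSet:
    """Contiguous, non-overlapping equal-length windows of one signal."""

    windows: np.ndarray          # shape (n_windows, window_samples)
    window_length: float         # seconds
    fs: float

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]

    def __iter__(self):
        return iter(self.windows)


@dataclass
class EmbeddingSpec:
    """Delay-embedding parameters selected for one window, with diagnostics.

    ``tau`` comes from the first minimum of the average mutual information
    curve, ``m`` from the false-nearest-neighbour criterion.
    """

    tau: int
    m: int
    ami_curve: np.ndarray = field(default_factory=lambda: np.empty(0))
    fnn_fractions: np.ndarray = field(default_factory=lambda: np.empty(0))
    tau_fallback: bool = False
    m_saturated: bool = False

    def __post_init__(self) -> None:
        if self.tau < 1:
            raise ParameterError(f"tau must be >= 1, got {self.tau}")
        if self.m < 1:
            raise ParameterError(f"m must be >= 1, got {self.m}")


@dataclass
class Trajectory:
    """A delay-embedded trajectory: row i is (x[i], x[i+tau], ..., x[i+(m-1)tau])."""

    points: np.ndarray           # shape (N - (m-1)*tau, m)
    tau: int
    m: int
    fs: float

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


@dataclass
class FeatureValue:
    """One nonlinear feature evaluated on one window.

    ``name`` is ``"LE"`` (largest Lyapunov exponent, 1/s), ``"FD"``
    (Higuchi fractal dimension) or ``"CD"`` (correlation dimension);
    FD and CD are dimensionless. ``diagnostics`` always carries the fit
    range, fit R-squared and point count behind the estimate.
    """

    name: str
    value: float
    window_index: int = -1
    diagnostics: dict[str, Any] = field(default_factory=dict)


@dataclass
class SurrogateResult:
    """Original vs mean-over-surrogates feature value for one record."""

    subject_id: str
    modality: str
    feature: str
    original_value: float
    surrogate_values: np.ndarray
    flagged: bool = False

    @property
    def n_surrogates(self) -> int:
        return int(np.size(self.surrogate_values))

    @property
    def surrogate_mean(self) -> float:
        return float(np.mean(self.surrogate_values))


@dataclass
class GroupStatResult:
    """A t-type group comparison: statistic, df, two-sided p, effect size."""

    label: str
    t: float
    df: int
    p: float
    d: float | None = None
    power: float | None = None
    n: int = 0

    def as_dict(self) -> dict[str, Any]:
        return {"comparison": self.label, "t": self.t, "df": self.df,
                "p": self.p, "d": self.d, "power": self.power, "n": self.n}
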