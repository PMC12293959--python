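"""Synthetic test signals with known ground truth.

Two families of fixtures are generated here:

* canonical dynamical systems and stochastic processes whose invariants are
  known analytically or via independent numerics (Lorenz and Roessler flows,
  fractional Brownian motion, linear AR processes, sinusoids, white noise) —
  used to validate the Lyapunov, fractal-dimension and correlation-dimension
  estimators; and
* paired pseudo-MEG/EMG recordings (``bursty_beta``): beta-band (13-30 Hz)
  Gaussian carriers modulated by transient burst-like envelopes, with a
  controllable envelope component shared between the two channels. These
  stand in for sensorimotor MEG and surface EMG during steady isometric
  contraction, where beta activity appears as bursts of a few cycles
  separated by quieter periods.

All randomness flows from the single integer ``seed`` of a
:class:`SyntheticSpec` through ``numpy.random.SeedSequence`` children (one
per independent stream), so identical specs reproduce output bit-exactly
while paired channels remain independently seeded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .types import ParameterError, Signal

__all__ = [
    "SyntheticSpec", "generate", "gen_lorenz", "gen_rossler", "gen_fbm",
    "gen_ar_linear", "gen_sine", "gen_white_noise", "gen_bursty_beta",
    "lorenz_states", "fgn",
]

KINDS = ("lorenz", "rossler", "fbm", "ar_linear", "sine", "white_noise",
         "bursty_beta")

#: default parameters per generator kind
DEFAULTS: dict[str, dict[str, Any]] = {
    "lorenz": {"sigma": 10.0, "rho": 28.0, "beta": 8.0 / 3.0, "dt": 0.01,
               "transient": 10.0, "x0": (1.0, 1.0, 1.0)},
    "rossler": {"a": 0.2, "b": 0.2, "c": 5.7, "dt": 0.05, "transient": 50.0,
                "x0": (1.0, 1.0, 1.0)},
    "fbm": {"hurst": 0.5},
    "ar_linear": {"coeffs": None, "sigma_e": 1.0, "f0": 20.0, "r": 0.95},
    "sine": {"freq": 20.0, "amp": 1.0, "phase": 0.0},
    "white_noise": {"sd": 1.0},
    # burst_rate in bursts/s, burst_fwhm in s; amplitudes ~ Gamma(2, scale)
    "bursty_beta": {"burst_rate": 1.0, "burst_fwhm": 0.15,
                    "burst_amp_scale": 1.0, "shared_fraction": 0.3,
                    "noise_sd": 0.1, "band": (13.0, 30.0)},
}


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic signal (or channel pair for ``bursty_beta``)."""

    kind: str
    fs: float = 1000.0
    duration: float = 600.0
    seed: int = 0
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ParameterError(f"unknown kind {self.kind!r}; one of {KINDS}")
        if not self.fs > 0:
            raise ParameterError("fs must be positive")
        if not self.duration > 0:
            raise ParameterError("duration must be positive")
        merged = dict(DEFAULTS[self.kind])
        merged.update(self.params)
        self.params = merged

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration))


def _rng(seed_seq: np.random.SeedSequence) -> np.random.Generator:
    return np.random.default_rng(seed_seq)


def _children(spec: SyntheticSpec, n: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(spec.seed).spawn(n)


# ---------------------------------------------------------------------------
# deterministic flows

def _rk4(f, x: np.ndarray, dt: float, n_steps: int) -> np.ndarray:
    """Fixed-step 4th-order Runge-Kutta; returns the trajectory (n_steps, dim)."""
    out = np.empty((n_steps, x.size))
    for i in range(n_steps):
        k1 = f(x)
        k2 = f(x + 0.5 * dt * k1)
        k3 = f(x + 0.5 * dt * k2)
        k4 = f(x + dt * k3)
        x = x + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        out[i] = x
    return out


def lorenz_states(n_samples: int, sigma: float = 10.0, rho: float = 28.0,
                  beta: float = 8.0 / 3.0, dt: float = 0.01,
                  transient: float = 10.0,
                  x0: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> np.ndarray:
    """Full 3-D Lorenz trajectory after discarding the transient.

    Fixed-step RK4 keeps the output reproducible across platforms. The
    default ``transient`` of 10 model-time units (1000 steps at dt=0.01)
    lets the orbit settle onto the attractor.
    """
    if dt <= 0:
        raise ParameterError("dt must be positive")

    def f(s):
        x, y, z = s
        return np.array([sigma * (y - x), x * (rho - z) - y, x * y - beta * z])

    n_trans = max(int(round(transient / dt)), 0)
    full = _rk4(f, np.asarray(x0, float), dt, n_trans + n_samples)
    return full[n_trans:]


def gen_lorenz(spec: SyntheticSpec) -> Signal:
    """x-coordinate of the Lorenz flow; ``fs`` is interpreted as 1/dt."""
    p = spec.params
    states = lorenz_states(spec.n_samples, p["sigma"], p["rho"], p["beta"],
                           p["dt"], p["transient"], tuple(p["x0"]))
    return Signal(states[:, 0], fs=1.0 / p["dt"], kind="lorenz", seed=spec.seed)


def gen_rossler(spec: SyntheticSpec) -> Signal:
    p = spec.params
    if p["dt"] <= 0:
        raise ParameterError("dt must be positive")
    a, b, c = p["a"], p["b"], p["c"]

    def f(s):
        x, y, z = s
        return np.array([-y - z, x + a * y, b + z * (x - c)])

    n_trans = max(int(round(p["transient"] / p["dt"])), 0)
    full = _rk4(f, np.asarray(p["x0"], float), p["dt"], n_trans + spec.n_samples)
    return Signal(full[n_trans:, 0], fs=1.0 / p["dt"], kind="rossler",
                  seed=spec.seed)


# ---------------------------------------------------------------------------
# stochastic processes

def fgn(n: int, hurst: float, rng: np.random.Generator) -> np.ndarray:
    """Exact-covariance fractional Gaussian noise via circulant embedding.

    The autocovariance gamma(k) = (|k+1|^2H - 2|k|^2H + |k-1|^2H)/2 is
    embedded in a circulant matrix of order 2(n-1) whose eigenvalues are the
    FFT of the first row; sampling is then a filtered complex normal draw
    (Davies-Harte). Eigenvalues are non-negative for all H in (0,1) up to
    roundoff, which is clipped.
    """
    if not 0.0 < hurst < 1.0:
        raise ParameterError(f"hurst must be in (0, 1), got {hurst}")
    k = np.arange(n)
    gamma = 0.5 * (np.abs(k + 1) ** (2 * hurst) - 2 * np.abs(k) ** (2 * hurst)
                   + np.abs(k - 1) ** (2 * hurst))
    row = np.concatenate([gamma, gamma[-2:0:-1]])          # length 2n-2
    eig = np.fft.fft(row).real
    eig = np.clip(eig, 0.0, None)
    m = row.size
    z = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    w = np.fft.fft(np.sqrt(eig / (2.0 * m)) * z)
    return w.real[:n]


def gen_fbm(spec: SyntheticSpec) -> Signal:
    """Fractional Brownian motion: cumulative sum of exact-covariance fGn."""
    hurst = spec.params["hurst"]
    rng = _rng(_children(spec, 1)[0])
    increments = fgn(spec.n_samples, hurst, rng)
    return Signal(np.cumsum(increments), fs=spec.fs, kind="fbm", seed=spec.seed)


def _ar2_coeffs(f0: float, r: float, fs: float) -> tuple[float, float]:
    """AR(2) coefficients for complex poles r*exp(+-2*pi*i*f0/fs)."""
    w = 2.0 * np.pi * f0 / fs
    return 2.0 * r * np.cos(w), -(r * r)


def gen_ar_linear(spec: SyntheticSpec) -> Signal:
    """Stationary Gaussian AR process (linear null for surrogate testing).

    Defaults to an AR(2) with complex poles giving a resonance near
    ``f0`` = 20 Hz at the spec's sampling rate, i.e. beta-band-like linear
    dynamics with no nonlinear structure.
    """
    p = spec.params
    coeffs = p["coeffs"]
    if coeffs is None:
        coeffs = _ar2_coeffs(p["f0"], p["r"], spec.fs)
    coeffs = np.atleast_1d(np.asarray(coeffs, float))
    poles = np.roots(np.concatenate([[1.0], -coeffs]))
    if coeffs.any() and np.max(np.abs(poles)) >= 1.0:
        raise ParameterError(f"unstable AR coefficients {coeffs.tolist()}")
    rng = _rng(_children(spec, 1)[0])
    burn = max(10 * coeffs.size, 200)
    e = rng.standard_normal(spec.n_samples + burn) * p["sigma_e"]
    from scipy.signal import lfilter
    x = lfilter([1.0], np.concatenate([[1.0], -coeffs]), e)
    return Signal(x[burn:], fs=spec.fs, kind="ar_linear", seed=spec.seed)


def gen_sine(spec: SyntheticSpec) -> Signal:
    p = spec.params
    t = np.arange(spec.n_samples) / spec.fs
    x = p["amp"] * np.sin(2.0 * np.pi * p["freq"] * t + p["phase"])
    return Signal(x, fs=spec.fs, kind="sine", seed=spec.seed)


def gen_white_noise(spec: SyntheticSpec) -> Signal:
    rng = _rng(_children(spec, 1)[0])
    x = rng.standard_normal(spec.n_samples) * spec.params["sd"]
    return Signal(x, fs=spec.fs, kind="white_noise", seed=spec.seed)


# ---------------------------------------------------------------------------
# paired pseudo-MEG/EMG

def _burst_envelope(n: int, fs: float, rate: float, fwhm: float,
                    amp_scale: float, rng: np.random.Generator) -> np.ndarray:
    """1 + sum of Gaussian bumps at Poisson times, Gamma(2, amp_scale) heights."""
    env = np.ones(n)
    if amp_scale <= 0 or rate <= 0:
        return env
    duration = n / fs
    n_bursts = rng.poisson(rate * duration)
    times = rng.uniform(0.0, duration, n_bursts)
    amps = rng.gamma(2.0, amp_scale, n_bursts)
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    half = int(np.ceil(4.0 * sigma * fs))
    kernel_t = np.arange(-half, half + 1) / fs
    kernel = np.exp(-0.5 * (kernel_t / sigma) ** 2)
    for t0, a in zip(times, amps):
        c = int(round(t0 * fs))
        lo, hi = max(c - half, 0), min(c + half + 1, n)
        env[lo:hi] += a * kernel[lo - (c - half): hi - (c - half)]
    return env


def _beta_carrier(n: int, fs: float, band: tuple[float, float],
                  rng: np.random.Generator) -> np.ndarray:
    from .preprocess import bandpass_cosine
    c = bandpass_cosine(rng.standard_normal(n), fs, band[0], band[1], 2.0)
    sd = c.std()
    if sd > 0:
        c = c / sd
    return c


def gen_bursty_beta(spec: SyntheticSpec) -> tuple[Signal, Signal]:
    """Paired pseudo-MEG / pseudo-EMG beta-band recordings.

    Each channel is a unit-variance 13-30 Hz Gaussian carrier multiplied by
    a burst envelope ``e_ch = (1 - rho_sh) * e_indep + rho_sh * e_shared``,
    plus additive white noise. ``shared_fraction`` (rho_sh) controls how
    much amplitude modulation the channels share, mimicking the weak
    envelope coupling between sensorimotor MEG and EMG; ``burst_amp_scale``
    controls burstiness (envelope CV).
    """
    p = spec.params
    rho = float(p["shared_fraction"])
    if not 0.0 <= rho <= 1.0:
        raise ParameterError(f"shared_fraction must be in [0, 1], got {rho}")
    n = spec.n_samples
    ss = _children(spec, 7)
    e_shared = _burst_envelope(n, spec.fs, p["burst_rate"], p["burst_fwhm"],
                               p["burst_amp_scale"], _rng(ss[0]))
    signals = []
    for ch, (ss_env, ss_car, ss_noise) in zip(
            ("MEG", "EMG"), ((ss[1], ss[2], ss[3]), (ss[4], ss[5], ss[6]))):
        e_indep = _burst_envelope(n, spec.fs, p["burst_rate"], p["burst_fwhm"],
                                  p["burst_amp_scale"], _rng(ss_env))
        env = (1.0 - rho) * e_indep + rho * e_shared
        carrier = _beta_carrier(n, spec.fs, tuple(p["band"]), _rng(ss_car))
        noise = p["noise_sd"] * _rng(ss_noise).standard_normal(n)
        signals.append(Signal(env * carrier + noise, fs=spec.fs, modality=ch,
                              kind="bursty_beta", seed=spec.seed))
    return signals[0], signals[1]


_DISPATCH = {
    "lorenz": gen_lorenz, "rossler": gen_rossler, "fbm": gen_fbm,
    "ar_linear": gen_ar_linear, "sine": gen_sine,
    "white_noise": gen_white_noise, "bursty_beta": gen_bursty_beta,
}


def generate(spec: SyntheticSpec):
    """Dispatch on ``spec.kind``; ``bursty_beta`` returns a (MEG, EMG) pair."""
    return _DISPATCH[spec.kind](spec)
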