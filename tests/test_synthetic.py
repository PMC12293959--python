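"""Synthetic generators: determinism, known invariants, parameter errors."""

import numpy as np
import pytest

from betadyn.envelope import RAYLEIGH_CV, burstiness_cv, hilbert_envelope, \
    normalize_envelope
from betadyn.synthetic import (SyntheticSpec, gen_ar_linear, gen_bursty_beta,
                               gen_fbm, gen_lorenz, gen_white_noise, generate)
from betadyn.types import ParameterError


def _spec(kind, **kw):
    return SyntheticSpec(kind=kind, **kw)


@pytest.mark.parametrize("kind,params", [
    ("lorenz", {}),
    ("fbm", {"hurst": 0.7}),
    ("ar_linear", {}),
    ("white_noise", {}),
])
def test_identical_spec_reproduces_bit_identical_output(kind, params):
    a = generate(_spec(kind, fs=200.0, duration=5.0, seed=42, params=params))
    b = generate(_spec(kind, fs=200.0, duration=5.0, seed=42, params=params))
    np.testing.assert_array_equal(a.samples, b.samples)


def test_bursty_beta_pair_reproducible_and_distinct():
    spec = _spec("bursty_beta", duration=40.0, seed=9)
    meg1, emg1 = gen_bursty_beta(spec)
    meg2, emg2 = gen_bursty_beta(_spec("bursty_beta", duration=40.0, seed=9))
    np.testing.assert_array_equal(meg1.samples, meg2.samples)
    np.testing.assert_array_equal(emg1.samples, emg2.samples)
    # paired channels use independent seed streams
    assert not np.array_equal(meg1.samples, emg1.samples)


def test_lorenz_trajectory_bounded_for_standard_parameters():
    sig = gen_lorenz(_spec("lorenz", fs=100.0, duration=100.0))
    assert np.all(np.abs(sig.samples) < 25.0)


def test_lorenz_stable_regime_converges_to_fixed_point():
    # rho < 1: the origin is globally stable, so the late trajectory contracts
    sig = gen_lorenz(_spec("lorenz", fs=100.0, duration=50.0,
                           params={"rho": 0.5}))
    tail = np.abs(sig.samples[-500:])
    head = np.abs(sig.samples[:500])
    assert tail.max() < 1e-3
    assert tail.max() < head.max()


def test_lorenz_nonpositive_dt_rejected():
    with pytest.raises(ParameterError):
        gen_lorenz(_spec("lorenz", duration=1.0, params={"dt": 0.0}))


@pytest.mark.parametrize("hurst", [-0.1, 0.0, 1.0, 1.3])
def test_fbm_hurst_outside_unit_interval_rejected(hurst):
    with pytest.raises(ParameterError):
        gen_fbm(_spec("fbm", fs=100.0, duration=1.0,
                      params={"hurst": hurst}))


def test_fbm_h05_increments_uncorrelated():
    # H = 0.5 is ordinary Brownian motion: increments are white
    sig = gen_fbm(_spec("fbm", fs=1000.0, duration=20.0, seed=3,
                        params={"hurst": 0.5}))
    inc = np.diff(sig.samples)
    n = inc.size
    for lag in (1, 2, 5):
        r = np.corrcoef(inc[:-lag], inc[lag:])[0, 1]
        assert abs(r) < 4.0 / np.sqrt(n)


def test_fbm_hurst_controls_increment_correlation_sign():
    # persistent (H>0.5) fGn has positive lag-1 autocorrelation, antipersistent negative
    def lag1(h):
        inc = np.diff(gen_fbm(_spec("fbm", fs=1000.0, duration=20.0, seed=5,
                                    params={"hurst": h})).samples)
        return np.corrcoef(inc[:-1], inc[1:])[0, 1]

    assert lag1(0.8) > 0.1
    assert lag1(0.2) < -0.1


def test_ar2_sample_variance_matches_closed_form():
    # stationary AR(2) variance: s2_e*(1-a2) / ((1+a2)*((1-a2)^2 - a1^2))
    f0, r, fs = 20.0, 0.95, 1000.0
    w = 2 * np.pi * f0 / fs
    a1, a2 = 2 * r * np.cos(w), -r * r
    analytic = (1 - a2) / ((1 + a2) * ((1 - a2) ** 2 - a1 ** 2))
    sig = gen_ar_linear(_spec("ar_linear", fs=fs, duration=40.0, seed=8))
    assert sig.samples.var() == pytest.approx(analytic, rel=0.10)


def test_ar2_spectral_peak_near_analytic_resonance():
    fs = 1000.0
    sig = gen_ar_linear(_spec("ar_linear", fs=fs, duration=40.0, seed=2))
    freqs = np.fft.rfftfreq(sig.n, 1 / fs)
    pxx = np.abs(np.fft.rfft(sig.samples)) ** 2
    # smooth the periodogram so the argmax is stable
    kernel = np.ones(41) / 41
    peak = freqs[np.argmax(np.convolve(pxx, kernel, mode="same"))]
    w = 2 * np.pi * 20.0 / fs
    a1, a2 = 2 * 0.95 * np.cos(w), -0.95 ** 2
    grid = np.linspace(1, 100, 2000)
    h = 1.0 / np.abs(1 - a1 * np.exp(-2j * np.pi * grid / fs)
                     - a2 * np.exp(-4j * np.pi * grid / fs)) ** 2
    analytic_peak = grid[np.argmax(h)]
    assert peak == pytest.approx(analytic_peak, abs=2.0)


def test_zero_coefficient_ar_is_white():
    sig = gen_ar_linear(_spec("ar_linear", fs=1000.0, duration=20.0, seed=4,
                              params={"coeffs": [0.0]}))
    x = sig.samples
    assert abs(np.corrcoef(x[:-1], x[1:])[0, 1]) < 4.0 / np.sqrt(x.size)


def test_unstable_ar_rejected():
    with pytest.raises(ParameterError):
        gen_ar_linear(_spec("ar_linear", duration=1.0,
                            params={"coeffs": [1.2, 0.3]}))


def test_bursty_beta_power_concentrated_in_band():
    meg, emg = gen_bursty_beta(_spec("bursty_beta", duration=30.0, seed=6))
    for sig in (meg, emg):
        freqs = np.fft.rfftfreq(sig.n, 1 / sig.fs)
        pxx = np.abs(np.fft.rfft(sig.samples)) ** 2
        in_band = pxx[(freqs >= 13) & (freqs <= 30)].sum()
        assert in_band / pxx.sum() > 0.8


def test_bursty_beta_shared_fraction_out_of_range_rejected():
    with pytest.raises(ParameterError):
        gen_bursty_beta(_spec("bursty_beta", duration=5.0,
                              params={"shared_fraction": 1.5}))


def test_unmodulated_carrier_envelope_cv_is_rayleigh():
    # burst_amp_scale = 0: constant envelope, pure narrowband Gaussian carrier
    meg, _ = gen_bursty_beta(_spec("bursty_beta", duration=120.0, seed=12,
                                   params={"burst_amp_scale": 0.0,
                                           "noise_sd": 0.0}))
    env = normalize_envelope(hilbert_envelope(meg.samples, meg.fs), meg.fs)
    cv = burstiness_cv(env, meg.fs)
    assert cv == pytest.approx(RAYLEIGH_CV, abs=0.03)


def test_white_noise_sd_parameter():
    sig = gen_white_noise(_spec("white_noise", fs=1000.0, duration=20.0,
                                seed=1, params={"sd": 2.5}))
    assert sig.samples.std() == pytest.approx(2.5, rel=0.05)


def test_rossler_bounded_and_oscillatory():
    sig = generate(_spec("rossler", fs=20.0, duration=200.0))
    assert np.all(np.abs(sig.samples) < 30.0)
    # the x-coordinate oscillates around 0 on the standard attractor
    assert (np.diff(np.signbit(sig.samples)) != 0).sum() > 20


def test_unknown_kind_rejected():
    with pytest.raises(ParameterError):
        SyntheticSpec(kind="pink_noise")
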