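"""Delay and dimension selection (AMI / FNN) and the embedding itself."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from betadyn.embedding import (DelayEmbedding, average_mutual_information,
                               delay_embed, false_nearest_neighbors,
                               select_delay, select_dimension)
from betadyn.preprocess import bandpass_cosine
from betadyn.types import EstimationError, ParameterError


def _sine(period_samples, n=5000):
    return np.sin(2 * np.pi * np.arange(n) / period_samples)


class TestAMI:
    def test_sinusoid_minimum_in_quarter_period_valley(self):
        # the histogram AMI of a sinusoid has a broad valley around the
        # quarter period (lag 25 here); binning ripple makes the exact
        # first minimum jitter inside it, hence the smoothed detection
        ami = average_mutual_information(_sine(100), max_lag=60)
        tau = select_delay(ami, smooth_window=5)
        assert 10 <= tau <= 35
        # the selected lag sits near the bottom of the valley
        assert ami[tau] < ami[5] and ami[tau] < np.max(ami[45:])

    def test_iid_noise_ami_near_zero_for_positive_lags(self, rng):
        x = rng.standard_normal(20000)
        ami = average_mutual_information(x, max_lag=20, n_bins=16)
        # histogram-MI bias bound ~ n_bins^2 / (2 N ln 2)
        bias = 16 ** 2 / (2 * x.size * np.log(2)) * 4
        assert np.all(ami[1:] < ami[0])
        assert np.all(ami[1:] < 0.05 + bias)

    def test_lag_zero_is_marginal_entropy_and_maximal(self, rng):
        x = rng.standard_normal(5000)
        ami = average_mutual_information(x, max_lag=30)
        assert np.all(ami[0] >= ami[1:])
        assert ami[0] > 1.0  # entropy of a 16-bin Gaussian histogram

    def test_constant_signal_rejected(self):
        with pytest.raises(EstimationError):
            average_mutual_information(np.ones(1000), max_lag=10)

    def test_permuting_the_signal_destroys_lag_structure(self, rng):
        x = _sine(100, 8000)
        ami = average_mutual_information(x, max_lag=30)
        perm = rng.permutation(x)
        ami_perm = average_mutual_information(perm, max_lag=30)
        assert ami[10] > 0.5
        assert np.all(ami_perm[1:] < 0.05)

    def test_narrowband_beta_delay_near_quarter_period(self, rng):
        # 13-30 Hz noise at 1 kHz: mean frequency ~20 Hz, quarter period ~12
        x = bandpass_cosine(rng.standard_normal(20000), 1000.0, 13.0, 30.0)
        tau = select_delay(average_mutual_information(x, max_lag=50))
        assert 10 <= tau <= 15


class TestSelectDelay:
    def test_first_local_minimum_wins(self):
        curve = np.array([3.0, 2.0, 1.0, 1.5, 0.2, 0.1])
        assert select_delay(curve) == 2

    def test_one_over_e_fallback_on_monotone_curve(self):
        curve = 3.0 * 0.9 ** np.arange(30)  # monotone decreasing
        tau, fallback = select_delay(curve, return_info=True)
        assert fallback
        assert curve[tau] < curve[0] / np.e
        assert curve[tau - 1] >= curve[0] / np.e

    def test_max_lag_fallback_when_curve_never_drops(self):
        curve = np.linspace(3.0, 2.9, 20)
        tau, fallback = select_delay(curve, return_info=True)
        assert fallback and tau == 19


class TestFNN:
    def test_sinusoid_embeds_in_two_dimensions(self):
        # incommensurate period: the sampled orbit fills the closed curve
        # densely, so neighbour distances are genuine curve distances
        x = np.sin(2 * np.pi * np.arange(4000) / 99.7)
        fr = false_nearest_neighbors(x, tau=25, m_max=4)
        assert fr[1] < 0.01  # m = 2

    def test_lorenz_needs_three_dimensions(self, lorenz_signal):
        fr = false_nearest_neighbors(lorenz_signal.samples, tau=17, m_max=5)
        m = select_dimension(fr)
        assert m == 3

    def test_iid_noise_fnn_stays_high(self, rng):
        x = rng.standard_normal(3000)
        fr = false_nearest_neighbors(x, tau=1, m_max=5, max_anchors=1000)
        m, saturated = select_dimension(fr, return_info=True)
        assert saturated and m == 5

    def test_time_reversed_signal_has_similar_fnn(self):
        # a sampled closed orbit is invariant under time reversal, so the
        # FNN fractions must agree up to neighbour-tie resolution
        x = np.sin(2 * np.pi * np.arange(4000) / 99.7)
        fr_fwd = false_nearest_neighbors(x, tau=25, m_max=4)
        fr_rev = false_nearest_neighbors(x[::-1].copy(), tau=25, m_max=4)
        np.testing.assert_allclose(fr_fwd, fr_rev, atol=0.03)

    def test_too_short_series_rejected(self):
        with pytest.raises(EstimationError):
            false_nearest_neighbors(np.sin(np.arange(30.0)), tau=5, m_max=5)


class TestSelectDimension:
    @pytest.mark.parametrize("fractions,expected", [
        ([0.6, 0.005, 0.001], 2),
        ([0.0, 0.0, 0.0], 1),
    ])
    def test_smallest_dimension_below_threshold(self, fractions, expected):
        assert select_dimension(np.array(fractions)) == expected

    def test_saturation_returns_m_max_with_flag(self):
        m, saturated = select_dimension(np.full(8, 0.5), return_info=True)
        assert m == 8 and saturated


class TestDelayEmbed:
    @given(n=st.integers(50, 300), m=st.integers(1, 5), tau=st.integers(1, 10))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_shape_and_content_invariant(self, n, m, tau):
        x = np.arange(float(n))
        if n - (m - 1) * tau <= 0:
            with pytest.raises(ParameterError):
                delay_embed(x, tau, m)
            return
        traj = delay_embed(x, tau, m)
        assert traj.points.shape == (n - (m - 1) * tau, m)
        # component j of point i equals x[i + j*tau]
        i, j = traj.points.shape[0] // 2, m - 1
        assert traj.points[i, j] == x[i + j * tau]

    def test_m_one_is_the_signal_as_column(self):
        x = np.arange(10.0)
        np.testing.assert_array_equal(delay_embed(x, 5, 1).points.ravel(), x)

    def test_insufficient_length_rejected(self):
        with pytest.raises(ParameterError):
            delay_embed(np.arange(10.0), tau=5, m=3)


class TestDelayEmbeddingEstimator:
    def test_fit_then_transform_on_lorenz(self, lorenz_signal):
        est = DelayEmbedding(max_lag=100, m_max=5).fit(lorenz_signal.samples)
        assert 10 <= est.tau_ <= 30
        assert est.m_ == 3
        pts = est.transform(lorenz_signal.samples)
        assert pts.shape[1] == est.m_

    def test_sklearn_param_interface(self):
        est = DelayEmbedding(m_max=6)
        assert est.get_params()["m_max"] == 6
        clone = est.set_params(tau=12, m=3)
        assert clone.fit(np.sin(np.arange(2000) / 7.0)).tau_ == 12
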