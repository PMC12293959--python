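"""Zero-phase cosine filter, segmentation, and signal/manifest round trips."""

import numpy as np
import pandas as pd
import pytest

from betadyn.io import load_manifest, read_signal, write_manifest, write_signal
from betadyn.preprocess import (bandpass_beta, bandpass_cosine,
                                cosine_band_response, lowpass_cosine, segment)
from betadyn.types import ParameterError, Signal, SignalLoadError


def _tone(freq, fs=1000.0, duration=10.0, amp=1.0):
    t = np.arange(int(fs * duration)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


class TestBandpass:
    def test_passband_tone_preserved(self):
        x = _tone(20.0)
        y = bandpass_cosine(x, 1000.0, 13.0, 30.0)
        # compare RMS away from the edges
        sl = slice(1000, -1000)
        assert np.sqrt(np.mean(y[sl] ** 2)) == pytest.approx(
            np.sqrt(np.mean(x[sl] ** 2)), rel=0.01)

    def test_stopband_tone_suppressed(self):
        x = _tone(5.0)
        y = bandpass_cosine(x, 1000.0, 13.0, 30.0)
        assert np.sqrt(np.mean(y ** 2)) < 0.01 * np.sqrt(np.mean(x ** 2))

    def test_zero_phase_no_lag(self):
        # cross-correlation between a band-limited input and its filtered
        # copy peaks at lag zero
        rng = np.random.default_rng(0)
        x = bandpass_cosine(rng.standard_normal(5000), 1000.0, 13.0, 30.0)
        y = bandpass_cosine(x, 1000.0, 13.0, 30.0)
        lags = np.arange(-20, 21)
        xc = [np.dot(x[20:-20], y[20 + l:y.size - 20 + l]) for l in lags]
        assert lags[int(np.argmax(xc))] == 0

    def test_response_flanks_are_raised_cosine(self):
        f = np.linspace(0, 50, 5001)
        h = cosine_band_response(f, 13.0, 30.0, 2.0)
        assert h[f <= 12.0].max() == 0.0
        assert np.all(h[(f >= 14.0) & (f <= 29.0)] == 1.0)
        # half-gain exactly at the band edges
        assert np.interp(13.0, f, h) == pytest.approx(0.5, abs=1e-6)
        assert np.interp(30.0, f, h) == pytest.approx(0.5, abs=1e-6)

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ParameterError):
            bandpass_cosine(np.zeros(1000), 50.0, 13.0, 30.0)

    def test_lowpass_passes_dc_blocks_fast(self):
        fs = 100.0
        t = np.arange(int(fs * 200)) / fs
        x = 3.0 + np.sin(2 * np.pi * 1.0 * t)
        y = lowpass_cosine(x, fs, cutoff=0.1)
        assert y.mean() == pytest.approx(3.0, rel=1e-3)
        assert (y - y.mean()).std() < 0.05


class TestSegment:
    def test_600s_at_1khz_gives_60_windows(self):
        sig = Signal(np.zeros(600_000), fs=1000.0)
        ws = segment(sig, 10.0)
        assert ws.n_windows == 60
        assert ws.windows.shape == (60, 10_000)

    def test_trailing_remainder_discarded(self):
        ws = segment(Signal(np.arange(25_000.0), fs=1000.0), 10.0)
        assert ws.n_windows == 2
        # order preserved, contiguous
        np.testing.assert_array_equal(ws.windows[1][:3],
                                      [10_000.0, 10_001.0, 10_002.0])

    def test_signal_shorter_than_window_rejected(self):
        with pytest.raises(ParameterError):
            segment(Signal(np.zeros(9_000), fs=1000.0), 10.0)

    def test_filter_commutes_with_segmentation(self):
        # filtering the full record then slicing equals slicing the
        # filtered record: filtering is never applied per window
        rng = np.random.default_rng(1)
        sig = Signal(rng.standard_normal(30_000), fs=1000.0)
        filtered = bandpass_beta(sig)
        ws = segment(filtered, 10.0)
        np.testing.assert_array_equal(
            np.concatenate(list(ws)), filtered.samples[:30_000])


class TestIO:
    def test_signal_round_trip_bit_exact(self, tmp_path, rng):
        sig = Signal(rng.standard_normal(500), fs=1000.0, subject_id="S01",
                     modality="MEG", kind="bursty_beta", seed=7)
        path = write_signal(sig, tmp_path / "s.txt")
        back = read_signal(path)
        np.testing.assert_array_equal(back.samples, sig.samples)
        assert (back.fs, back.subject_id, back.modality, back.seed) == \
            (1000.0, "S01", "MEG", 7)

    def test_manifest_with_17_subjects_loads_34_signals(self, tmp_path, rng):
        rows = []
        for i in range(17):
            for mod in ("MEG", "EMG"):
                sig = Signal(rng.standard_normal(100), fs=1000.0)
                fname = f"S{i:02d}_{mod}.txt"
                write_signal(sig, tmp_path / fname)
                rows.append({"subject_id": f"S{i:02d}", "modality": mod,
                             "path": fname})
        manifest = write_manifest(rows, tmp_path / "manifest.csv")
        signals = load_manifest(manifest)
        assert len(signals) == 34
        assert {s.modality for s in signals} == {"MEG", "EMG"}

    def test_empty_manifest_gives_empty_list(self, tmp_path):
        manifest = write_manifest([], tmp_path / "manifest.csv")
        assert load_manifest(manifest) == []

    def test_missing_file_error_names_the_path(self, tmp_path):
        manifest = write_manifest(
            [{"subject_id": "S1", "modality": "MEG", "path": "absent.txt"}],
            tmp_path / "manifest.csv")
        with pytest.raises(SignalLoadError, match="absent.txt"):
            load_manifest(manifest)

    def test_duplicate_subject_modality_rejected(self, tmp_path, rng):
        sig = Signal(rng.standard_normal(50), fs=1000.0)
        write_signal(sig, tmp_path / "a.txt")
        manifest = write_manifest(
            [{"subject_id": "S1", "modality": "MEG", "path": "a.txt"},
             {"subject_id": "S1", "modality": "MEG", "path": "a.txt"}],
            tmp_path / "manifest.csv")
        with pytest.raises(SignalLoadError, match="duplicate"):
            load_manifest(manifest)

    def test_non_finite_samples_rejected(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("# fs=1000.0\n1.0\nnan\n2.0\n")
        with pytest.raises(SignalLoadError, match="non-finite"):
            read_signal(path)
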