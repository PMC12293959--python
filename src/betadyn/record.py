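"""Full-record analysis: preprocess once, then per-window features.

The recording is band-passed as a whole (never per window), segmented into
fixed windows, and each window is run through the nonlinear feature chain.
Windows on which an estimator degenerates (e.g. constant data) are excluded
and counted, never silently filled with NaN.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import RunConfig
from .embedding import DelayEmbedding
from .envelope import burstiness_cv, hilbert_envelope, normalize_envelope
from .features import features_for_window
from .preprocess import bandpass_cosine, segment
from .types import EstimationError, Signal

__all__ = ["analyze_record", "window_feature_means", "envelope_of_record"]

log = logging.getLogger(__name__)


def _make_embedder(cfg: RunConfig) -> DelayEmbedding:
    return DelayEmbedding(max_lag=cfg.max_lag, n_bins=cfg.n_bins,
                          m_max=cfg.m_max, r_tol=cfg.r_tol, a_tol=cfg.a_tol,
                          fnn_threshold=cfg.fnn_threshold)


def analyze_record(samples: np.ndarray, fs: float,
                   cfg: RunConfig) -> pd.DataFrame:
    """Band-pass, segment, and compute per-window nonlinear features.

    Returns a tidy frame with columns ``window_index, feature, value,
    fit_r2``; the number of failed windows is stored in
    ``df.attrs["n_failed_windows"]`` (and the window count in
    ``df.attrs["n_windows"]``).
    """
    filtered = bandpass_cosine(np.asarray(samples, float).ravel(), fs,
                               cfg.band_lo, cfg.band_hi, cfg.band_transition)
    windows = segment(Signal(filtered, fs), cfg.window_length)
    shared_embedder = None
    if not cfg.per_window_embedding:
        shared_embedder = _make_embedder(cfg).fit(windows.windows[0])
    rows, n_failed = [], 0
    for w_idx, window in enumerate(windows):
        embedder = shared_embedder if shared_embedder is not None \
            else _make_embedder(cfg)
        try:
            feats = features_for_window(
                window, fs, features=cfg.features, embedder=embedder,
                k_max=cfg.k_max, n_radii=cfg.n_radii,
                max_points=cfg.max_points, window_index=w_idx)
        except EstimationError as exc:
            n_failed += 1
            log.warning("window %d excluded: %s", w_idx, exc)
            continue
        for name, fv in feats.items():
            rows.append({"window_index": w_idx, "feature": name,
                         "value": fv.value,
                         "fit_r2": fv.diagnostics.get("fit_r2", np.nan)})
    df = pd.DataFrame(rows, columns=["window_index", "feature", "value",
                                     "fit_r2"])
    df.attrs["n_windows"] = windows.n_windows
    df.attrs["n_failed_windows"] = n_failed
    return df


def window_feature_means(df: pd.DataFrame) -> dict[str, float]:
    """Mean over windows per feature (the per-record reduction)."""
    if df.empty:
        return {}
    return df.groupby("feature")["value"].mean().to_dict()


def envelope_of_record(samples: np.ndarray, fs: float,
                       cfg: RunConfig) -> tuple[np.ndarray, float]:
    """Band-pass, Hilbert envelope, slow normalization, burstiness CV.

    Returns the normalized envelope (full length; callers trim edges) and
    the CV computed with the configured edge trim.
    """
    filtered = bandpass_cosine(np.asarray(samples, float).ravel(), fs,
                               cfg.band_lo, cfg.band_hi, cfg.band_transition)
    raw = hilbert_envelope(filtered, fs)
    norm = normalize_envelope(raw, fs, cfg.env_cutoff, cfg.env_transition)
    cv = burstiness_cv(norm, fs, cfg.edge_trim)
    return norm, cv
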