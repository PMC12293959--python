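"""Phase-randomized surrogate testing for nonlinearity.

A surrogate keeps the discrete-Fourier amplitude spectrum of the original
recording exactly but draws the positive-frequency phases iid uniform (DC
and Nyquist bins are untouched so the output stays real with the original
mean). This destroys any nonlinear temporal structure — e.g. burst
clustering — while preserving the linear (spectral) properties, so a
feature that differs between originals and surrogates reflects structure
beyond a linear-Gaussian process.

Surrogates are generated from the full raw recording and pushed through
the identical preprocessing + feature pipeline as the real data; each
record's surrogate score is the mean over windows, then over realizations.
"""

from __future__ import annotations

import logging

import numpy as np

from .config import RunConfig
from .record import analyze_record, window_feature_means
from .types import Signal, SurrogateResult

__all__ = ["phase_randomize", "surrogate_features"]

log = logging.getLogger(__name__)


def phase_randomize(x: np.ndarray,
                    rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Return a surrogate with the same amplitude spectrum as ``x``.

    Positive-frequency phases are iid uniform on [0, 2pi); the DC bin and,
    for even length, the Nyquist bin keep their original (real) values, so
    the mean is preserved to machine precision.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 samples")
    spec = np.fft.rfft(x)
    amp = np.abs(spec)
    phases = rng.uniform(0.0, 2.0 * np.pi, spec.size)
    out_spec = amp * np.exp(1j * phases)
    out_spec[0] = spec[0]
    if n % 2 == 0:
        out_spec[-1] = spec[-1]
    return np.fft.irfft(out_spec, n)


def surrogate_features(signal: Signal, cfg: RunConfig,
                       n: int | None = None,
                       seed: int | np.random.SeedSequence | None = None
                       ) -> dict[str, SurrogateResult]:
    """Original vs surrogate feature values for one recording.

    Each of the ``n`` surrogates (default ``cfg.n_surrogates``) is
    band-passed, segmented and run through the same feature chain as the
    original; the per-surrogate value is the mean over its windows. A
    feature whose estimators fail on more than 10% of surrogate windows is
    flagged in the result.
    """
    n = cfg.n_surrogates if n is None else int(n)
    if not isinstance(seed, np.random.SeedSequence):
        seed = np.random.SeedSequence(cfg.master_seed if seed is None else seed)
    child_rngs = [np.random.default_rng(s) for s in seed.spawn(n)]

    orig_df = analyze_record(signal.samples, signal.fs, cfg)
    orig_means = window_feature_means(orig_df)

    per_feature: dict[str, list[float]] = {f: [] for f in cfg.features}
    total_windows = 0
    failed_windows = 0
    for rng in child_rngs:
        xs = phase_randomize(signal.samples, rng)
        df = analyze_record(xs, signal.fs, cfg)
        total_windows += df.attrs["n_windows"]
        failed_windows += df.attrs["n_failed_windows"]
        means = window_feature_means(df)
        for f in cfg.features:
            if f in means:
                per_feature[f].append(means[f])
    flagged = total_windows > 0 and failed_windows > 0.1 * total_windows
    if flagged:
        log.warning("%s/%s: %d of %d surrogate windows failed",
                    signal.subject_id, signal.modality, failed_windows,
                    total_windows)
    out = {}
    for f in cfg.features:
        if f not in orig_means or not per_feature[f]:
            continue
        out[f] = SurrogateResult(
            subject_id=signal.subject_id, modality=signal.modality,
            feature=f, original_value=float(orig_means[f]),
            surrogate_values=np.asarray(per_feature[f]), flagged=flagged)
    return out
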