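"""Per-window nonlinear features: largest Lyapunov exponent (Rosenstein),
Higuchi fractal dimension, and Grassberger-Procaccia correlation dimension.

Each estimator is a scikit-learn style class (``fit`` + trailing-underscore
attributes) with a functional wrapper returning a :class:`FeatureValue`
that carries fit diagnostics (scaling region, fit R-squared, points used).

Units: the Lyapunov exponent is the log-distance divergence slope per
sample multiplied by the sampling rate, i.e. 1/s (or 1/model-time-unit
when ``fs`` = 1/dt for an integrated flow). FD and CD are dimensionless.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator

from .embedding import DelayEmbedding
from .types import EstimationError, FeatureValue, ParameterError, Trajectory

__all__ = [
    "RosensteinLyapunov", "HiguchiFractalDimension", "GrassbergerProcaccia",
    "rosenstein_le", "higuchi_fd", "grassberger_procaccia_cd",
    "features_for_window", "mean_period_samples", "correlation_sum",
]

FEATURE_NAMES = ("LE", "FD", "CD")


def mean_period_samples(x: np.ndarray, fs: float = 1.0) -> int:
    """Mean period of a series in samples: fs / power-weighted mean frequency.

    Used as the Theiler window and as the default divergence fit span for
    the Lyapunov estimator, following Rosenstein's recommendation.
    """
    x = np.asarray(x, dtype=float).ravel()
    spec = np.abs(np.fft.rfft(x - x.mean())) ** 2
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fs)
    power = spec[1:].sum()
    if power <= 0:
        raise EstimationError("constant signal has no mean period")
    mean_freq = float((freqs[1:] * spec[1:]).sum() / power)
    return max(int(round(fs / mean_freq)), 1)


def _linfit(k: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares slope, intercept and R^2."""
    slope, intercept = np.polyfit(k, y, 1)
    resid = y - (slope * k + intercept)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid ** 2) / ss_tot if ss_tot > 0 else 0.0
    return float(slope), float(intercept), float(r2)


def _best_linear_region(xs: np.ndarray, ys: np.ndarray,
                        min_frac: float = 1.0 / 3.0) -> tuple[int, int]:
    """Bounds (a, b) of the most scaling-like contiguous span of a curve.

    Scaling regions are plateaus of the local slope, so among all spans of
    at least ``min_frac`` of the points the one with the smallest standard
    deviation of local (finite-difference) slopes is chosen; ties go to the
    longer span, then to the one at smaller abscissae. This favours the
    true power-law region over smoothly curving shoulders, which can have
    deceptively high linear-fit R^2.
    """
    n = xs.size
    min_len = max(int(np.ceil(min_frac * n)), 4)
    if n < min_len:
        raise EstimationError(f"curve of {n} points too short for a "
                              f"{min_len}-point scaling region")
    local = np.diff(ys) / np.diff(xs)
    best = None
    for a in range(0, n - min_len + 1):
        for b in range(a + min_len, n + 1):
            spread = float(np.std(local[a:b - 1]))
            key = (spread, -(b - a), a)
            if best is None or key < best[0]:
                best = (key, a, b)
    return best[1], best[2]


# ---------------------------------------------------------------------------
# Rosenstein largest Lyapunov exponent

class RosensteinLyapunov(BaseEstimator):
    """Largest Lyapunov exponent from nearest-neighbour divergence.

    For every trajectory point the nearest neighbour outside a Theiler
    window of ``mean_period`` samples is found; the mean log distance
    between the pair after k steps defines the divergence curve. Its slope
    over the most linear contiguous region within the first ``fit_span``
    steps (least squares; the region is where the local slope is most
    constant, skipping the initial neighbour-realignment transient) times
    the sampling rate is the exponent in 1/s.

    Attributes
    ----------
    exponent_ : float
        Largest Lyapunov exponent (1/s).
    divergence_curve_ : ndarray
        Mean log-distance at steps 0..fit_span.
    fit_r2_ : float
        R-squared of the linear fit; low values flag poor exponential
        scaling (e.g. pure noise).
    n_pairs_ : int
        Neighbour pairs entering the average.
    """

    def __init__(self, fs: float | None = None, mean_period: int | None = None,
                 fit_span: int | None = None, min_points: int = 500,
                 max_pairs: int | None = 2000):
        self.fs = fs
        self.mean_period = mean_period
        self.fit_span = fit_span
        self.min_points = min_points
        self.max_pairs = max_pairs

    def fit(self, traj: Trajectory, y=None):
        points, fs = _as_points(traj, self.fs)
        n = points.shape[0]
        if n < self.min_points:
            raise EstimationError(f"trajectory has {n} points; "
                                  f"need >= {self.min_points}")
        mp = self.mean_period
        if mp is None:
            mp = mean_period_samples(points[:, 0], 1.0)  # in samples
        if mp < 1:
            raise ParameterError("mean_period must be >= 1")
        span = self.fit_span if self.fit_span is not None else mp
        span = int(min(span, n - 2))
        if self.max_pairs is not None and n > self.max_pairs:
            anchors = np.arange(0, n, int(np.ceil(n / self.max_pairs)))
        else:
            anchors = np.arange(n)
        nbr, _ = _nearest_theiler(points, mp, anchors)
        # keep pairs that can be followed for the whole fit span
        valid = nbr >= 0
        i = anchors[valid]
        j = nbr[valid]
        keep = np.maximum(i, j) + span < n
        i, j = i[keep], j[keep]
        if i.size == 0:
            raise EstimationError("no neighbour pairs admissible for the "
                                  "requested Theiler window and fit span")
        curve = np.empty(span + 1)
        for k in range(span + 1):
            d = np.linalg.norm(points[i + k] - points[j + k], axis=1)
            d = d[d > 0]
            if d.size == 0:
                raise EstimationError(f"all pair distances collapsed to zero "
                                      f"at step {k}")
            curve[k] = np.mean(np.log(d))
        if not np.all(np.isfinite(curve)):
            raise EstimationError("non-finite divergence curve")
        ks = np.arange(span + 1, dtype=float)
        a, b = _best_linear_region(ks, curve)
        slope, _, r2 = _linfit(ks[a:b], curve[a:b])
        self.divergence_curve_ = curve
        self.exponent_ = slope * fs
        self.fit_r2_ = r2
        self.fit_region_ = (int(a), int(b - 1))
        self.n_pairs_ = int(i.size)
        self.mean_period_ = int(mp)
        self.fit_span_ = span
        return self


def _as_points(traj, fs):
    if isinstance(traj, Trajectory):
        return np.asarray(traj.points, float), (fs if fs is not None else traj.fs)
    pts = np.asarray(traj, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    return pts, (fs if fs is not None else 1.0)


def _nearest_theiler(points: np.ndarray, theiler: int,
                     anchors: np.ndarray | None = None):
    n = points.shape[0]
    if anchors is None:
        anchors = np.arange(n)
    k = min(2 * theiler + 2, n)
    dist, idx = cKDTree(points).query(points[anchors], k=k)
    if k == 1:
        dist, idx = dist[:, None], idx[:, None]
    admissible = np.abs(idx - anchors[:, None]) > theiler
    first = admissible.argmax(axis=1)
    rows = np.arange(anchors.size)
    found = admissible[rows, first]
    return (np.where(found, idx[rows, first], -1),
            np.where(found, dist[rows, first], np.nan))


def rosenstein_le(traj: Trajectory, mean_period: int | None = None,
                  fit_span: int | None = None, window_index: int = -1,
                  fs: float | None = None) -> FeatureValue:
    est = RosensteinLyapunov(fs=fs, mean_period=mean_period,
                             fit_span=fit_span).fit(traj)
    return FeatureValue(
        name="LE", value=est.exponent_, window_index=window_index,
        diagnostics={"fit_r2": est.fit_r2_, "fit_span": est.fit_span_,
                     "mean_period": est.mean_period_,
                     "n_points": est.n_pairs_})


# ---------------------------------------------------------------------------
# Higuchi fractal dimension

class HiguchiFractalDimension(BaseEstimator):
    """Higuchi's curve-length fractal dimension of a scalar series.

    For each scale k the mean normalized curve length L(k) is computed over
    the k possible offsets; the slope of log L(k) versus log(1/k) is the
    fractal dimension, which lies in [1, 2] for a scalar curve (values
    outside are kept but flagged in the diagnostics).
    """

    def __init__(self, k_max: int = 16):
        self.k_max = k_max

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float).ravel()
        n = x.size
        if n < 10 * self.k_max:
            raise EstimationError(f"need >= {10 * self.k_max} samples for "
                                  f"k_max={self.k_max}, got {n}")
        lengths = np.empty(self.k_max)
        for k in range(1, self.k_max + 1):
            lm = []
            for m in range(k):
                idx = np.arange(m, n, k)
                if idx.size < 2:
                    continue
                dist = np.abs(np.diff(x[idx])).sum()
                norm = (n - 1) / ((idx.size - 1) * k)
                lm.append(dist * norm / k)
            lengths[k - 1] = np.mean(lm)
        if np.any(lengths <= 0):
            raise EstimationError("constant signal: zero curve length")
        ks = np.arange(1, self.k_max + 1)
        slope, _, r2 = _linfit(np.log(1.0 / ks), np.log(lengths))
        self.fd_ = float(slope)
        self.lengths_ = lengths
        self.fit_r2_ = r2
        return self


def higuchi_fd(x: np.ndarray, k_max: int = 16,
               window_index: int = -1) -> FeatureValue:
    est = HiguchiFractalDimension(k_max=k_max).fit(x)
    in_range = 1.0 <= est.fd_ <= 2.0
    return FeatureValue(
        name="FD", value=est.fd_, window_index=window_index,
        diagnostics={"fit_r2": est.fit_r2_, "k_max": k_max,
                     "n_points": int(np.size(x)), "in_range": bool(in_range)})


# ---------------------------------------------------------------------------
# Grassberger-Procaccia correlation dimension

def correlation_sum(points: np.ndarray, radii: np.ndarray,
                    theiler: int = 0,
                    time_index: np.ndarray | None = None) -> np.ndarray:
    """C(r): fraction of admissible point pairs within distance r.

    Pairs closer than ``theiler`` samples in time (per ``time_index``,
    default the row number) are excluded to avoid autocorrelation bias.
    Vectorized over the full distance set; exact, no binning.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    n = pts.shape[0]
    if time_index is None:
        time_index = np.arange(n)
    iu, ju = np.triu_indices(n, k=1)
    admissible = np.abs(time_index[iu] - time_index[ju]) > theiler
    if not np.any(admissible):
        raise EstimationError("all pairs excluded by the Theiler window")
    d = pdist(pts)[admissible]
    return np.searchsorted(np.sort(d), np.asarray(radii),
                           side="right") / d.size


class GrassbergerProcaccia(BaseEstimator):
    """Correlation dimension from the scaling of the correlation sum.

    C(r) is evaluated on ``n_radii`` log-spaced radii between the
    ``r_lo_pct`` and ``r_hi_pct`` percentiles of admissible pairwise
    distances (defaults 0.1 and 20: the power law holds at radii well
    below the attractor diameter, and pair counts there are still in the
    thousands); the dimension is the
    log-log slope over the contiguous span of at least ``region_fraction``
    of the radii where the local slope is most constant (the scaling
    plateau — large radii curve over as r approaches the attractor size
    and would bias a fit chosen by R-squared alone). Trajectories
    longer than ``max_points`` are subsampled with an even stride (original
    time indices are kept for the Theiler exclusion), bounding the O(N^2)
    pair cost.
    """

    def __init__(self, n_radii: int = 24, theiler: int | None = None,
                 max_points: int = 2000, region_fraction: float = 1.0 / 3.0,
                 min_points: int = 200, r_lo_pct: float = 0.1,
                 r_hi_pct: float = 20.0):
        self.n_radii = n_radii
        self.theiler = theiler
        self.max_points = max_points
        self.region_fraction = region_fraction
        self.min_points = min_points
        self.r_lo_pct = r_lo_pct
        self.r_hi_pct = r_hi_pct

    def fit(self, traj: Trajectory, y=None):
        points, _ = _as_points(traj, None)
        n = points.shape[0]
        if n < self.min_points:
            raise EstimationError(f"trajectory has {n} points; "
                                  f"need >= {self.min_points}")
        theiler = self.theiler
        if theiler is None:
            theiler = traj.tau if isinstance(traj, Trajectory) else 0
        if n > self.max_points:
            stride = int(np.ceil(n / self.max_points))
            keep = np.arange(0, n, stride)
            points, tindex = points[keep], keep
        else:
            tindex = np.arange(n)
        iu, ju = np.triu_indices(points.shape[0], k=1)
        adm = np.abs(tindex[iu] - tindex[ju]) > theiler
        if not np.any(adm):
            raise EstimationError("all pairs excluded by the Theiler window")
        d = np.sort(pdist(points)[adm])
        r_lo = max(np.percentile(d, self.r_lo_pct), np.finfo(float).tiny)
        r_hi = np.percentile(d, self.r_hi_pct)
        if not r_hi > r_lo:
            raise EstimationError("degenerate pairwise-distance distribution")
        radii = np.geomspace(r_lo, r_hi, self.n_radii)
        csum = np.searchsorted(d, radii, side="right") / d.size
        ok = csum > 0
        log_r, log_c = np.log(radii[ok]), np.log(csum[ok])
        a, b = _best_linear_region(log_r, log_c, self.region_fraction)
        slope, _, r2 = _linfit(log_r[a:b], log_c[a:b])
        self.dimension_ = float(slope)
        self.radii_ = radii
        self.corr_sum_ = csum
        self.scaling_region_ = (float(radii[ok][a]), float(radii[ok][b - 1]))
        self.fit_r2_ = float(r2)
        self.n_points_ = int(points.shape[0])
        return self


def grassberger_procaccia_cd(traj: Trajectory, n_radii: int = 24,
                             theiler: int | None = None,
                             max_points: int = 2000,
                             window_index: int = -1) -> FeatureValue:
    est = GrassbergerProcaccia(n_radii=n_radii, theiler=theiler,
                               max_points=max_points).fit(traj)
    return FeatureValue(
        name="CD", value=est.dimension_, window_index=window_index,
        diagnostics={"fit_r2": est.fit_r2_,
                     "scaling_region": est.scaling_region_,
                     "n_points": est.n_points_})


# ---------------------------------------------------------------------------
# per-window driver

def features_for_window(window: np.ndarray, fs: float,
                        features: tuple[str, ...] = FEATURE_NAMES,
                        embedder: DelayEmbedding | None = None,
                        k_max: int = 16, n_radii: int = 24,
                        max_points: int = 2000,
                        window_index: int = -1) -> dict[str, FeatureValue]:
    """Compute the requested features on one window.

    LE and CD share a single delay embedding (AMI delay, FNN dimension,
    estimated on this window unless a pre-fitted ``embedder`` is supplied);
    FD operates on the scalar window directly. The spectral mean period of
    the window serves as the Theiler window for both LE and CD and as the
    LE divergence fit span.
    """
    window = np.asarray(window, dtype=float).ravel()
    out: dict[str, FeatureValue] = {}
    if "FD" in features:
        out["FD"] = higuchi_fd(window, k_max=k_max, window_index=window_index)
    if "LE" in features or "CD" in features:
        if embedder is None:
            embedder = DelayEmbedding()
        try:
            from sklearn.utils.validation import check_is_fitted
            check_is_fitted(embedder)
        except Exception:
            embedder.fit(window)
        traj = embedder.embed(window, fs=fs)
        mp = mean_period_samples(window, 1.0)
        if "LE" in features:
            out["LE"] = rosenstein_le(traj, mean_period=mp, fit_span=mp,
                                      window_index=window_index, fs=fs)
            out["LE"].diagnostics.update(tau=embedder.tau_, m=embedder.m_)
        if "CD" in features:
            out["CD"] = grassberger_procaccia_cd(
                traj, n_radii=n_radii, theiler=mp, max_points=max_points,
                window_index=window_index)
            out["CD"].diagnostics.update(tau=embedder.tau_, m=embedder.m_)
    return out
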