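"""Phase-space reconstruction by time-delay embedding.

The delay ``tau`` is taken at the first minimum of the average mutual
information (AMI) between the series and its lagged copy, and the embedding
dimension ``m`` at the smallest dimension whose false-nearest-neighbour
(FNN) fraction drops below a threshold — the standard Fraser-Swinney /
Kennel recipe. Narrowband beta signals may lack a clean AMI minimum, so
delay selection falls back to the first lag where AMI drops below
``AMI(0)/e``, and finally to ``max_lag`` with a warning flag.

:class:`DelayEmbedding` bundles both selections as a scikit-learn style
transformer: ``fit`` estimates ``tau_`` and ``m_`` from a scalar series,
``transform`` returns the embedded trajectory matrix.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator, TransformerMixin

from .types import EmbeddingSpec, EstimationError, ParameterError, Trajectory

__all__ = ["DelayEmbedding", "average_mutual_information", "select_delay",
           "false_nearest_neighbors", "select_dimension", "delay_embed"]

log = logging.getLogger(__name__)


def average_mutual_information(x: np.ndarray, max_lag: int = 100,
                               n_bins: int = 16) -> np.ndarray:
    """Histogram-based AMI (in bits) between ``x(t)`` and ``x(t+k)``.

    Equal-width bins spanning the full signal range are shared by every lag
    so the curve is comparable across lags; lag 0 equals the marginal
    entropy of the binned signal.
    """
    x = np.asarray(x, dtype=float).ravel()
    if n_bins < 4:
        raise ParameterError(f"n_bins must be >= 4, got {n_bins}")
    if max_lag >= x.size / 4:
        raise ParameterError(f"max_lag {max_lag} too large for {x.size} samples")
    lo, hi = x.min(), x.max()
    if hi <= lo:
        raise EstimationError("constant signal has zero entropy; AMI undefined")
    edges = np.linspace(lo, hi, n_bins + 1)
    edges[-1] += 1e-12 * (hi - lo)      # include the maximum in the last bin
    idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, n_bins - 1)
    ami = np.empty(max_lag + 1)
    for k in range(max_lag + 1):
        a = idx[:x.size - k] if k else idx
        b = idx[k:]
        joint = np.zeros((n_bins, n_bins))
        np.add.at(joint, (a, b), 1.0)
        joint /= joint.sum()
        pa, pb = joint.sum(axis=1), joint.sum(axis=0)
        nz = joint > 0
        ami[k] = float(np.sum(joint[nz] * np.log2(
            joint[nz] / (pa[:, None] * pb[None, :])[nz])))
    return ami


def select_delay(ami_curve: np.ndarray, return_info: bool = False,
                 smooth_window: int = 1):
    """First strict local minimum of the AMI curve; 1/e drop as fallback.

    ``smooth_window`` > 1 applies a centred moving average before minimum
    detection (the raw curve still sets the 1/e fallback threshold):
    histogram AMI of strongly periodic signals ripples from binning
    artifacts, and smoothing suppresses spurious early minima.
    """
    ami = np.asarray(ami_curve, dtype=float)
    if ami.size < 3:
        raise ParameterError("AMI curve needs at least 3 lags")
    det = ami
    if smooth_window > 1:
        pad = smooth_window // 2
        det = np.convolve(np.pad(ami, pad, mode="edge"),
                          np.ones(smooth_window) / smooth_window,
                          mode="valid")
    tau, fallback = None, False
    interior = np.nonzero((det[1:-1] < det[:-2]) & (det[1:-1] < det[2:]))[0]
    if interior.size:
        tau = int(interior[0] + 1)
    else:
        below = np.nonzero(ami[1:] < ami[0] / np.e)[0]
        fallback = True
        if below.size:
            tau = int(below[0] + 1)
        else:
            tau = ami.size - 1
            log.warning("AMI has no minimum and never drops below AMI(0)/e; "
                        "using max_lag=%d as delay", tau)
    return (tau, fallback) if return_info else tau


def delay_embed(x: np.ndarray, tau: int, m: int, fs: float = 1.0) -> Trajectory:
    """Embed ``x`` into m dimensions: row i = (x[i], x[i+tau], ..., x[i+(m-1)tau])."""
    x = np.asarray(x, dtype=float).ravel()
    if tau < 1 or m < 1:
        raise ParameterError(f"need tau >= 1 and m >= 1, got tau={tau}, m={m}")
    n_points = x.size - (m - 1) * tau
    if n_points <= 0:
        raise ParameterError(f"series of {x.size} samples too short for "
                             f"m={m}, tau={tau}")
    points = np.column_stack([x[j * tau: j * tau + n_points] for j in range(m)])
    return Trajectory(points=points, tau=tau, m=m, fs=fs)


def _nearest_with_theiler(points: np.ndarray, theiler: int,
                          anchors: np.ndarray | None = None
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Index and distance of each anchor point's nearest neighbour with
    temporally close pairs (|i-j| <= theiler) excluded.

    The tree holds every point; only the query set may be thinned
    (``anchors``), which keeps the neighbour structure exact while
    bounding the query cost.
    """
    n = points.shape[0]
    if anchors is None:
        anchors = np.arange(n)
    k = min(2 * theiler + 2, n)
    tree = cKDTree(points)
    dist, idx = tree.query(points[anchors], k=k)
    if k == 1:
        dist, idx = dist[:, None], idx[:, None]
    admissible = np.abs(idx - anchors[:, None]) > theiler
    first = admissible.argmax(axis=1)
    rows = np.arange(anchors.size)
    found = admissible[rows, first]
    return (np.where(found, idx[rows, first], -1),
            np.where(found, dist[rows, first], np.nan))


def _strided_anchors(n: int, max_anchors: int | None) -> np.ndarray | None:
    if max_anchors is None or n <= max_anchors:
        return None
    return np.arange(0, n, int(np.ceil(n / max_anchors)))


def false_nearest_neighbors(x: np.ndarray, tau: int, m_max: int = 10,
                            r_tol: float = 15.0, a_tol: float = 2.0,
                            theiler: int | None = None,
                            max_anchors: int | None = 2000) -> np.ndarray:
    """Fraction of false nearest neighbours for m = 1 .. m_max.

    A neighbour pair found in dimension m is false when adding the
    (m+1)-th delay coordinate stretches it by more than ``r_tol`` relative
    to its m-dimensional distance, or beyond ``a_tol`` times the signal SD
    (Kennel's two criteria). Temporal neighbours within the Theiler window
    (default ``tau``) are excluded from the search. For long series the
    fraction is estimated from ``max_anchors`` evenly strided reference
    points (the neighbour search itself always covers every point).
    """
    x = np.asarray(x, dtype=float).ravel()
    if m_max < 2:
        raise ParameterError("m_max must be >= 2")
    if theiler is None:
        theiler = tau
    sd = x.std()
    if sd == 0:
        raise EstimationError("constant signal: FNN undefined")
    fractions = np.empty(m_max)
    for m in range(1, m_max + 1):
        n_pts = x.size - m * tau          # points with the next coordinate available
        if n_pts < 10:
            raise EstimationError(f"fewer than 10 usable points at m={m} "
                                  f"(tau={tau}, N={x.size})")
        emb = delay_embed(x[:n_pts + (m - 1) * tau], tau, m).points
        anchors = _strided_anchors(n_pts, max_anchors)
        nbr, dist = _nearest_with_theiler(emb, theiler, anchors)
        queried = anchors if anchors is not None else np.arange(n_pts)
        valid = nbr >= 0
        i = queried[valid]
        j = nbr[valid]
        r_m = dist[valid]
        extra = np.abs(x[i + m * tau] - x[j + m * tau])
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(r_m > 0, extra / r_m, np.where(extra > 0, np.inf, 0.0))
        false = (ratio > r_tol) | (np.hypot(r_m, extra) > a_tol * sd)
        if i.size == 0:
            raise EstimationError(f"no admissible neighbour pairs at m={m}")
        fractions[m - 1] = false.mean()
    return fractions


def select_dimension(fnn_fractions: np.ndarray, threshold: float = 0.01,
                     return_info: bool = False):
    """Smallest m whose FNN fraction is <= threshold; else m_max with warning."""
    fr = np.asarray(fnn_fractions, dtype=float)
    if fr.size == 0:
        raise ParameterError("empty FNN fractions")
    below = np.nonzero(fr <= threshold)[0]
    if below.size:
        m, saturated = int(below[0] + 1), False
    else:
        m, saturated = fr.size, True
        log.warning("FNN fraction never dropped below %.3g; using m_max=%d",
                    threshold, m)
    return (m, saturated) if return_info else m


class DelayEmbedding(BaseEstimator, TransformerMixin):
    """Select delay and dimension from a scalar series, then embed it.

    Parameters
    ----------
    max_lag : int
        Longest lag scanned for the AMI minimum (samples).
    n_bins : int
        Histogram bins for the AMI estimator.
    m_max : int
        Largest candidate embedding dimension.
    r_tol, a_tol : float
        Kennel FNN tolerances (distance-ratio and attractor-size tests).
    fnn_threshold : float
        FNN fraction below which a dimension is accepted.
    theiler : int or None
        Temporal exclusion for the FNN neighbour search; defaults to the
        selected delay.
    tau, m : int or None
        Fix either parameter instead of estimating it.

    Attributes
    ----------
    tau_, m_ : int
        Selected delay (samples) and dimension.
    ami_curve_, fnn_fractions_ : ndarray
        Selection diagnostics.
    tau_fallback_, m_saturated_ : bool
        True when the 1/e fallback (resp. the m_max cap) was used.
    """

    def __init__(self, max_lag: int = 100, n_bins: int = 16, m_max: int = 10,
                 r_tol: float = 15.0, a_tol: float = 2.0,
                 fnn_threshold: float = 0.01, theiler: int | None = None,
                 tau: int | None = None, m: int | None = None,
                 max_anchors: int | None = 2000, ami_smooth: int = 5):
        self.max_lag = max_lag
        self.n_bins = n_bins
        self.m_max = m_max
        self.r_tol = r_tol
        self.a_tol = a_tol
        self.fnn_threshold = fnn_threshold
        self.theiler = theiler
        self.tau = tau
        self.m = m
        self.max_anchors = max_anchors
        self.ami_smooth = ami_smooth

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float).ravel()
        if self.tau is not None:
            self.ami_curve_ = np.empty(0)
            self.tau_, self.tau_fallback_ = int(self.tau), False
        else:
            self.ami_curve_ = average_mutual_information(x, self.max_lag,
                                                         self.n_bins)
            self.tau_, self.tau_fallback_ = select_delay(
                self.ami_curve_, return_info=True,
                smooth_window=self.ami_smooth)
        if self.m is not None:
            self.fnn_fractions_ = np.empty(0)
            self.m_, self.m_saturated_ = int(self.m), False
        else:
            self.fnn_fractions_ = false_nearest_neighbors(
                x, self.tau_, self.m_max, self.r_tol, self.a_tol,
                self.theiler, self.max_anchors)
            self.m_, self.m_saturated_ = select_dimension(
                self.fnn_fractions_, self.fnn_threshold, return_info=True)
        return self

    def transform(self, X) -> np.ndarray:
        return delay_embed(np.asarray(X, dtype=float).ravel(),
                           self.tau_, self.m_).points

    def embed(self, X, fs: float = 1.0) -> Trajectory:
        """Like :meth:`transform` but returns a full :class:`Trajectory`."""
        return delay_embed(np.asarray(X, dtype=float).ravel(),
                           self.tau_, self.m_, fs=fs)

    @property
    def embedding_spec_(self) -> EmbeddingSpec:
        return EmbeddingSpec(tau=self.tau_, m=self.m_,
                             ami_curve=self.ami_curve_,
                             fnn_fractions=self.fnn_fractions_,
                             tau_fallback=self.tau_fallback_,
                             m_saturated=self.m_saturated_)
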