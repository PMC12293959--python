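"""Group-level statistics: paired and one-sample t-tests, across-subject
Pearson correlations, Cohen's d, exact noncentral-t post hoc power, and
per-subject stability summaries.

All tests are two-sided; p-values are raw (no multiple-testing correction
by default, matching the analysis design; a Holm option is available).
For a paired test, |t| = |d| * sqrt(n) with d = mean(diff)/sd(diff), an
identity used as an internal consistency check.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import EstimationError, GroupStatResult

__all__ = ["paired_t", "one_sample_t", "pearson_across_subjects",
           "cohens_d_paired", "posthoc_power_paired", "stability_summary",
           "holm_correction"]

log = logging.getLogger(__name__)


def _check_nonzero_variance(x: np.ndarray, what: str) -> None:
    if np.std(x, ddof=1) == 0:
        raise EstimationError(f"zero variance in {what}: t undefined")


def cohens_d_paired(x: np.ndarray, y: np.ndarray) -> float:
    """Cohen's d for paired samples: mean difference over SD of differences."""
    diff = np.asarray(x, float) - np.asarray(y, float)
    _check_nonzero_variance(diff, "paired differences")
    return float(diff.mean() / diff.std(ddof=1))


def posthoc_power_paired(d: float, n: int, alpha: float = 0.05,
                         two_sided: bool = True) -> float:
    """Achieved power of a paired/one-sample t-test at effect size ``d``.

    Exact noncentral-t computation: with df = n-1 and noncentrality
    |d|*sqrt(n), power = P(|T'| > t_crit) at the two-sided critical value.
    Equals alpha when d = 0.
    """
    if n < 2:
        raise EstimationError("power undefined for n < 2")
    df = n - 1
    ncp = abs(d) * np.sqrt(n)
    if two_sided:
        tcrit = sps.t.ppf(1.0 - alpha / 2.0, df)
        return float(sps.nct.sf(tcrit, df, ncp) + sps.nct.cdf(-tcrit, df, ncp))
    tcrit = sps.t.ppf(1.0 - alpha, df)
    return float(sps.nct.sf(tcrit, df, ncp))


def paired_t(x: np.ndarray, y: np.ndarray, label: str = "paired",
             with_power: bool = True, alpha: float = 0.05) -> GroupStatResult:
    """Two-sided paired-sample t-test across subjects."""
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if x.size != y.size or x.size < 3:
        raise EstimationError("paired test needs equal-length samples, n >= 3")
    diff = x - y
    _check_nonzero_variance(diff, "paired differences")
    res = sps.ttest_rel(x, y)
    d = cohens_d_paired(x, y)
    power = posthoc_power_paired(d, x.size, alpha) if with_power else None
    return GroupStatResult(label=label, t=float(res.statistic),
                           df=int(res.df), p=float(res.pvalue), d=d,
                           power=power, n=x.size)


def one_sample_t(x: np.ndarray, mu0: float = 0.0,
                 label: str = "one-sample") -> GroupStatResult:
    """Two-sided one-sample t-test against ``mu0``."""
    x = np.asarray(x, float).ravel()
    if x.size < 3:
        raise EstimationError("one-sample test needs n >= 3")
    _check_nonzero_variance(x, "sample")
    res = sps.ttest_1samp(x, mu0)
    d = float((x.mean() - mu0) / x.std(ddof=1))
    return GroupStatResult(label=label, t=float(res.statistic),
                           df=int(res.df), p=float(res.pvalue), d=d,
                           n=x.size)


def pearson_across_subjects(a: np.ndarray, b: np.ndarray
                            ) -> tuple[float, float]:
    """Product-moment r across subjects with its t-transform p (df = n-2)."""
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    if a.size != b.size or a.size < 4:
        raise EstimationError("correlation needs equal-length samples, n >= 4")
    if np.std(a) == 0 or np.std(b) == 0:
        raise EstimationError("zero variance: correlation undefined")
    res = sps.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue)


def holm_correction(pvals: list[float]) -> list[float]:
    """Holm step-down adjusted p-values (optional; off by default upstream)."""
    p = np.asarray(pvals, float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj.tolist()


def stability_summary(feature_table: pd.DataFrame
                      ) -> tuple[pd.DataFrame, dict[str, GroupStatResult | str]]:
    """Per-subject mean and SD over windows, plus a cross-modal SD test.

    ``feature_table`` is tidy: columns ``subject_id, modality, window_index,
    feature, value``. Subjects with a single window are excluded (SD over
    windows undefined) with a warning. For each feature present in both
    modalities, the per-subject SDs are compared between modalities with a
    paired t-test; a zero-variance degenerate case is reported as
    ``"no difference"`` rather than raised.
    """
    counts = feature_table.groupby(
        ["subject_id", "modality", "feature"])["value"].transform("size")
    dropped = feature_table[counts < 2]
    if not dropped.empty:
        log.warning("excluding %d single-window rows from stability summary",
                    len(dropped))
    ft = feature_table[counts >= 2]
    per = (ft.groupby(["subject_id", "modality", "feature"])["value"]
             .agg(per_subject_mean="mean",
                  per_subject_sd=lambda v: v.std(ddof=1))
             .reset_index())
    grp = (per.groupby(["modality", "feature"])
              .agg(group_mean=("per_subject_mean", "mean"),
                   group_sd=("per_subject_mean", lambda v: v.std(ddof=1)))
              .reset_index())
    summary = per.merge(grp, on=["modality", "feature"])

    sd_tests: dict[str, GroupStatResult | str] = {}
    for feat in sorted(per["feature"].unique()):
        wide = per[per["feature"] == feat].pivot(
            index="subject_id", columns="modality", values="per_subject_sd")
        if {"MEG", "EMG"} <= set(wide.columns):
            wide = wide.dropna()
            if len(wide) >= 3:
                try:
                    sd_tests[feat] = paired_t(
                        wide["MEG"].to_numpy(), wide["EMG"].to_numpy(),
                        label=f"{feat} window-SD MEG vs EMG",
                        with_power=False)
                except EstimationError:
                    sd_tests[feat] = "no difference"
    return summary, sd_tests
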