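"""End-to-end study flow: simulate -> preprocess -> features -> envelope ->
surrogates -> group statistics.

Outputs are tidy TSV tables plus a JSON stats report. Every stage writes a
sidecar ``.hash`` carrying the configuration digest; a stage whose output
already matches the digest is not recomputed. A single master seed drives
the synthetic cohort and the surrogate branch through documented
``SeedSequence`` derivations, so a full rerun is byte-identical.
"""

from __future__ import annotations

import json
import logging
import platform
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .io import load_manifest, write_manifest, write_signal
from .record import analyze_record, envelope_of_record
from .stats import (one_sample_t, paired_t, pearson_across_subjects,
                    stability_summary)
from .surrogates import surrogate_features
from .synthetic import SyntheticSpec, gen_bursty_beta
from .types import EstimationError, GroupStatResult, Signal

__all__ = ["make_demo_cohort", "run_study", "group_stats_from_tables"]

log = logging.getLogger(__name__)

_FLOAT_FMT = "%.17g"


def make_demo_cohort(out_dir: str | Path, n_subjects: int = 17, seed: int = 0,
                     duration: float = 600.0, fs: float = 1000.0,
                     shared_fraction: float = 0.3,
                     burst_amp_scale: float | None = None) -> Path:
    """Write a synthetic cohort of paired pseudo-MEG/EMG recordings.

    Burst rate and amplitude scale vary across subjects (drawn from
    subject-level seeds) so the cohort has realistic between-subject
    heterogeneity; the planted shared-envelope fraction is common to all
    subjects. Returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    master = np.random.SeedSequence(seed)
    rows = []
    for s_idx, child in enumerate(master.spawn(n_subjects)):
        rng = np.random.default_rng(child)
        params = {
            "burst_rate": float(rng.uniform(0.6, 1.4)),
            "burst_amp_scale": (float(rng.uniform(0.5, 1.5))
                                if burst_amp_scale is None
                                else float(burst_amp_scale)),
            "shared_fraction": shared_fraction,
        }
        spec = SyntheticSpec(kind="bursty_beta", fs=fs, duration=duration,
                             seed=int(rng.integers(2 ** 31)), params=params)
        meg, emg = gen_bursty_beta(spec)
        subject = f"S{s_idx + 1:02d}"
        for sig in (meg, emg):
            sig.subject_id = subject
            fname = f"{subject}_{sig.modality}.txt"
            write_signal(sig, out_dir / fname)
            rows.append({"subject_id": subject, "modality": sig.modality,
                         "path": fname})
    return write_manifest(rows, out_dir / "manifest.csv")


# ---------------------------------------------------------------------------
# stage helpers

def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def _stage_fresh(path: Path, digest: str) -> bool:
    side = path.with_suffix(path.suffix + ".hash")
    return path.is_file() and side.is_file() and side.read_text() == digest


def _stage_done(path: Path, digest: str) -> None:
    path.with_suffix(path.suffix + ".hash").write_text(digest)


def _features_stage(signals: list[Signal], cfg: RunConfig) -> pd.DataFrame:
    frames = []
    for sig in signals:
        df = analyze_record(sig.samples, sig.fs, cfg)
        df.insert(0, "modality", sig.modality)
        df.insert(0, "subject_id", sig.subject_id)
        frames.append(df)
        log.info("features %s/%s: %d windows (%d failed)", sig.subject_id,
                 sig.modality, df.attrs["n_windows"],
                 df.attrs["n_failed_windows"])
    return pd.concat(frames, ignore_index=True)


def _envelope_stage(signals: list[Signal], cfg: RunConfig
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    burst_rows, envelopes = [], {}
    for sig in signals:
        norm, cv = envelope_of_record(sig.samples, sig.fs, cfg)
        burst_rows.append({"subject_id": sig.subject_id,
                           "modality": sig.modality, "cv": cv})
        envelopes[(sig.subject_id, sig.modality)] = (norm, sig.fs)
    corr_rows = []
    for subject in sorted({s for s, _ in envelopes}):
        if (subject, "MEG") in envelopes and (subject, "EMG") in envelopes:
            from .envelope import envelope_correlation
            (meg, fs), (emg, _) = envelopes[(subject, "MEG")], \
                envelopes[(subject, "EMG")]
            corr_rows.append({"subject_id": subject,
                              "envelope_r": envelope_correlation(
                                  meg, emg, fs, cfg.edge_trim)})
    return pd.DataFrame(burst_rows), pd.DataFrame(corr_rows)


def _surrogate_stage(signals: list[Signal], cfg: RunConfig) -> pd.DataFrame:
    master = np.random.SeedSequence(cfg.master_seed).spawn(1)[0]
    order = sorted(range(len(signals)),
                   key=lambda i: (signals[i].subject_id, signals[i].modality))
    children = master.spawn(len(signals))
    rows = []
    for child, idx in zip(children, order):
        sig = signals[idx]
        results = surrogate_features(sig, cfg, seed=child)
        for feat, res in results.items():
            rows.append({"subject_id": res.subject_id,
                         "modality": res.modality, "feature": feat,
                         "original_value": res.original_value,
                         "surrogate_mean": res.surrogate_mean,
                         "n_surrogates": res.n_surrogates,
                         "flagged": res.flagged})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# statistics over the output tables

def _result_or_note(fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs).as_dict()
    except EstimationError as exc:
        return {"note": str(exc)}


def group_stats_from_tables(features: pd.DataFrame,
                            burstiness: pd.DataFrame,
                            envelope_r: pd.DataFrame,
                            surrogates: pd.DataFrame | None = None) -> dict:
    """The full statistics layer, recomputable from the stage TSVs.

    Covers: paired MEG-vs-EMG tests per feature (with Cohen's d and post
    hoc power), the one-sample test of envelope correlations against zero,
    per-subject cross-modal correlation of window-wise feature courses,
    burstiness-feature correlations across subjects, original-vs-surrogate
    paired tests, and window-stability summaries.
    """
    out: dict = {"n_subjects": int(features["subject_id"].nunique())}

    per_subject = (features.groupby(["subject_id", "modality", "feature"])
                   ["value"].mean().reset_index())
    # paired MEG vs EMG on per-subject means
    cross: dict = {}
    for feat in sorted(features["feature"].unique()):
        wide = per_subject[per_subject["feature"] == feat].pivot(
            index="subject_id", columns="modality", values="value").dropna()
        if {"MEG", "EMG"} <= set(wide.columns) and len(wide) >= 3:
            cross[feat] = _result_or_note(
                paired_t, wide["MEG"].to_numpy(), wide["EMG"].to_numpy(),
                label=f"{feat} MEG vs EMG")
            cross[feat].update(
                meg_mean=float(wide["MEG"].mean()),
                meg_sd=float(wide["MEG"].std(ddof=1)),
                emg_mean=float(wide["EMG"].mean()),
                emg_sd=float(wide["EMG"].std(ddof=1)))
    out["meg_vs_emg"] = cross

    # envelope correlation against zero
    if not envelope_r.empty and len(envelope_r) >= 3:
        r = envelope_r["envelope_r"].to_numpy()
        res = _result_or_note(one_sample_t, r, 0.0, label="envelope r vs 0")
        res.update(mean_r=float(r.mean()), sd_r=float(r.std(ddof=1)))
        out["envelope_correlation"] = res

    # cross-modal correlation of per-window feature courses, per subject
    feat_corr: dict = {}
    for feat in sorted(features["feature"].unique()):
        sub_rs = []
        for subject, g in features[features["feature"] == feat].groupby(
                "subject_id"):
            wide = g.pivot_table(index="window_index", columns="modality",
                                 values="value").dropna()
            if {"MEG", "EMG"} <= set(wide.columns) and len(wide) >= 4:
                if wide["MEG"].std() > 0 and wide["EMG"].std() > 0:
                    sub_rs.append(float(np.corrcoef(wide["MEG"],
                                                    wide["EMG"])[0, 1]))
        if len(sub_rs) >= 3:
            res = _result_or_note(one_sample_t, np.asarray(sub_rs), 0.0,
                                  label=f"{feat} cross-modal r vs 0")
            res.update(mean_r=float(np.mean(sub_rs)),
                       sd_r=float(np.std(sub_rs, ddof=1)))
            feat_corr[feat] = res
    out["feature_cross_modal_correlation"] = feat_corr

    # burstiness vs features across subjects, per modality
    bf: dict = {}
    for modality in sorted(burstiness["modality"].unique()):
        cv = burstiness[burstiness["modality"] == modality].set_index(
            "subject_id")["cv"]
        for feat in sorted(features["feature"].unique()):
            vals = per_subject[(per_subject["modality"] == modality)
                               & (per_subject["feature"] == feat)].set_index(
                "subject_id")["value"]
            joined = pd.concat([cv, vals], axis=1, join="inner").dropna()
            if len(joined) >= 4:
                try:
                    r, p = pearson_across_subjects(joined.iloc[:, 0],
                                                   joined.iloc[:, 1])
                    bf[f"{modality}_{feat}"] = {"r": r, "p": p,
                                                "n": len(joined)}
                except EstimationError as exc:
                    bf[f"{modality}_{feat}"] = {"note": str(exc)}
    out["burstiness_vs_features"] = bf

    # original vs surrogate, paired across subjects
    if surrogates is not None and not surrogates.empty:
        sur: dict = {}
        for (modality, feat), g in surrogates.groupby(["modality", "feature"]):
            if len(g) >= 3:
                sur[f"{modality}_{feat}"] = _result_or_note(
                    paired_t, g["original_value"].to_numpy(),
                    g["surrogate_mean"].to_numpy(),
                    label=f"{feat} original vs surrogate ({modality})")
        out["original_vs_surrogate"] = sur

    # stability of features over windows
    summary, sd_tests = stability_summary(features)
    out["stability"] = {
        "group": summary.groupby(["modality", "feature"])
        [["per_subject_mean", "per_subject_sd"]].mean().reset_index()
        .to_dict(orient="records"),
        "sd_meg_vs_emg": {k: (v.as_dict() if isinstance(v, GroupStatResult)
                              else v) for k, v in sd_tests.items()},
    }
    return out


# ---------------------------------------------------------------------------
# orchestration

def run_study(manifest: str | Path, cfg: RunConfig,
              out_dir: str | Path) -> dict:
    """Run the full pipeline on a cohort manifest; returns output paths.

    Emits ``features.tsv``, ``burstiness.tsv``, ``envelope_r.tsv``,
    ``surrogates.tsv``, ``stats.json``, a serialized config copy and a run
    log. Any hard stage error propagates with subject/window context.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.monotonic()
    digest = cfg.content_hash() + ":" + str(Path(manifest).resolve())
    cfg.to_yaml(out_dir / "config.yaml")
    timings: dict[str, float] = {}

    signals = load_manifest(manifest)
    timings["load"] = time.monotonic() - t0

    paths = {name: out_dir / f"{name}.tsv"
             for name in ("features", "burstiness", "envelope_r",
                          "surrogates")}
    paths["stats"] = out_dir / "stats.json"

    t = time.monotonic()
    if _stage_fresh(paths["features"], digest):
        features = pd.read_csv(paths["features"], sep="\t")
    else:
        features = _features_stage(signals, cfg)
        _write_tsv(features, paths["features"])
        _stage_done(paths["features"], digest)
    timings["features"] = time.monotonic() - t

    t = time.monotonic()
    if _stage_fresh(paths["burstiness"], digest) and \
            _stage_fresh(paths["envelope_r"], digest):
        burst = pd.read_csv(paths["burstiness"], sep="\t")
        env_r = pd.read_csv(paths["envelope_r"], sep="\t")
    else:
        burst, env_r = _envelope_stage(signals, cfg)
        _write_tsv(burst, paths["burstiness"])
        _write_tsv(env_r, paths["envelope_r"])
        _stage_done(paths["burstiness"], digest)
        _stage_done(paths["envelope_r"], digest)
    timings["envelope"] = time.monotonic() - t

    t = time.monotonic()
    if _stage_fresh(paths["surrogates"], digest):
        surr = pd.read_csv(paths["surrogates"], sep="\t")
    else:
        surr = _surrogate_stage(signals, cfg)
        _write_tsv(surr, paths["surrogates"])
        _stage_done(paths["surrogates"], digest)
    timings["surrogates"] = time.monotonic() - t

    t = time.monotonic()
    stats = group_stats_from_tables(features, burst, env_r, surr)
    paths["stats"].write_text(json.dumps(stats, indent=2, sort_keys=True))
    timings["stats"] = time.monotonic() - t

    (out_dir / "run.log").write_text(
        f"betadyn {__version__} | python {platform.python_version()} | "
        f"numpy {np.__version__}\nmaster_seed={cfg.master_seed}\n"
        f"config_hash={cfg.content_hash()}\n"
        + "".join(f"{k}: {v:.2f} s\n" for k, v in timings.items()))
    return {"paths": {k: str(v) for k, v in paths.items()}, "stats": stats,
            "timings": timings}
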