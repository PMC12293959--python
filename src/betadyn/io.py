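"""Delimited-text signal files and cohort manifests.

A signal file is plain text: ``#``-prefixed header lines carrying the
sampling rate and provenance, then one sample per row at full double
precision (``%.17g``, bit-exact round trip). A manifest is a CSV with
columns ``subject_id, modality, path``; relative paths are resolved
against the manifest's directory.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .types import Signal, SignalLoadError

__all__ = ["write_signal", "read_signal", "write_manifest", "load_manifest"]

log = logging.getLogger(__name__)

MANIFEST_COLUMNS = ["subject_id", "modality", "path"]


def write_signal(signal: Signal, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = (f"fs={signal.fs!r}\nkind={signal.kind}\nseed={signal.seed}\n"
              f"subject_id={signal.subject_id}\nmodality={signal.modality}")
    np.savetxt(path, signal.samples, fmt="%.17g", header=header)
    return path


def read_signal(path: str | Path) -> Signal:
    path = Path(path)
    if not path.is_file():
        raise SignalLoadError(f"signal file not found: {path}")
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
    try:
        samples = np.loadtxt(path, comments="#")
    except ValueError as exc:
        raise SignalLoadError(f"could not parse samples in {path}: {exc}") from exc
    if samples.ndim != 1:
        raise SignalLoadError(f"{path}: expected one sample per row")
    if not np.all(np.isfinite(samples)):
        raise SignalLoadError(f"{path}: non-finite samples present")
    fs = float(meta.get("fs", "nan"))
    if not np.isfinite(fs) or fs <= 0:
        raise SignalLoadError(f"{path}: missing or invalid fs header")
    seed = meta.get("seed")
    return Signal(samples=samples, fs=fs, kind=meta.get("kind", ""),
                  subject_id=meta.get("subject_id", ""),
                  modality=meta.get("modality", ""),
                  seed=None if seed in (None, "", "None") else int(seed))


def write_manifest(rows: list[dict], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)
    return path


def load_manifest(path: str | Path) -> list[Signal]:
    """Load every signal referenced by a manifest CSV.

    Raises :class:`SignalLoadError` naming the offending row for missing
    files, duplicate (subject, modality) pairs, or non-finite samples. An
    empty manifest yields an empty list with a logged warning.
    """
    path = Path(path)
    if not path.is_file():
        raise SignalLoadError(f"manifest not found: {path}")
    df = pd.read_csv(path)
    missing_cols = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing_cols:
        raise SignalLoadError(f"manifest {path} missing columns {missing_cols}")
    if df.empty:
        log.warning("manifest %s is empty", path)
        return []
    dup = df.duplicated(subset=["subject_id", "modality"])
    if dup.any():
        row = df[dup].iloc[0]
        raise SignalLoadError(
            f"duplicate (subject, modality) pair in manifest: "
            f"({row.subject_id}, {row.modality})")
    signals = []
    for idx, row in df.iterrows():
        fpath = Path(row["path"])
        if not fpath.is_absolute():
            fpath = path.parent / fpath
        try:
            sig = read_signal(fpath)
        except SignalLoadError as exc:
            raise SignalLoadError(f"manifest row {idx} "
                                  f"({row.subject_id}/{row.modality}): {exc}") from exc
        sig.subject_id = str(row["subject_id"])
        sig.modality = str(row["modality"])
        log.info("loaded %s/%s: %d samples at %g Hz", sig.subject_id,
                 sig.modality, sig.n, sig.fs)
        signals.append(sig)
    return signals
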