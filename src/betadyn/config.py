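"""Run configuration: band edges, windowing, embedding and feature
parameters, surrogate count and master seed, with YAML round-trip."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .types import ParameterError

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All tunable parameters of the analysis pipeline.

    Defaults follow the study conditions: 13-30 Hz beta band with 2 Hz
    raised-cosine flanks, 10 s windows, AMI/FNN embedding with canonical
    Kennel tolerances, 100 phase-randomized surrogates, and a 0.1 Hz
    envelope-normalization cutoff.
    """

    # band-pass
    band_lo: float = 13.0
    band_hi: float = 30.0
    band_transition: float = 2.0
    # segmentation
    window_length: float = 10.0
    # embedding
    max_lag: int = 100
    n_bins: int = 16
    m_max: int = 10
    r_tol: float = 15.0
    a_tol: float = 2.0
    fnn_threshold: float = 0.01
    per_window_embedding: bool = True
    # features
    features: tuple[str, ...] = ("LE", "FD", "CD")
    k_max: int = 16
    n_radii: int = 24
    max_points: int = 2000
    # envelope / burstiness
    env_cutoff: float = 0.1
    env_transition: float = 0.05
    edge_trim: float = 0.5
    # surrogates
    n_surrogates: int = 100
    # seeding
    master_seed: int = 0

    def __post_init__(self) -> None:
        self.features = tuple(self.features)
        self.validate()

    def validate(self) -> None:
        if not 0 < self.band_lo < self.band_hi:
            raise ParameterError("need 0 < band_lo < band_hi")
        if self.window_length <= 0:
            raise ParameterError("window_length must be positive")
        if self.n_surrogates < 1:
            raise ParameterError("n_surrogates must be >= 1")
        unknown = set(self.features) - {"LE", "FD", "CD"}
        if unknown:
            raise ParameterError(f"unknown features {sorted(unknown)}")
        if not 0 < self.env_cutoff:
            raise ParameterError("env_cutoff must be positive")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["features"] = list(self.features)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def content_hash(self) -> str:
        """Short digest of the full parameter set, for stage caching."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
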