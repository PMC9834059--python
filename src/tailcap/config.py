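"""Run configuration: validated defaults, YAML round-trip, config hashing."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """All pipeline thresholds plus paths, serializable to YAML.

    Defaults follow the documented chemistry conventions: +/-10 nt
    assignment window, >80% A-content filter, last-30 classification and
    last-20 profile windows, >10 reads per unit, 0.1 mismatch mask, 50%
    adapter end identity with no extra trim, alpha 0.05.
    """

    window: int = 10
    a_content_threshold: float = 80.0
    last_n_class: int = 30
    last_n_profile: int = 20
    min_reads: int = 10
    mask_threshold: float = 0.1
    end_threshold: float = 50.0
    extra_end_trim: int = 0
    alpha: float = 0.05
    seed: int = 0
    dwell_mean: float = 10.0
    noise_sd: float = 0.3
    n_reads: int = 200
    inputs: dict[str, str] = field(default_factory=dict)
    output_dir: str = "out"

    def __post_init__(self) -> None:
        if self.window < 0:
            raise ValueError("window must be >= 0")
        if not 0 <= self.a_content_threshold <= 100:
            raise ValueError("a_content_threshold must be in [0, 100]")
        if self.last_n_class < 1 or self.last_n_profile < 1:
            raise ValueError("classification/profile windows must be >= 1")
        if self.min_reads < 0:
            raise ValueError("min_reads must be >= 0")
        if not 0 <= self.mask_threshold <= 1:
            raise ValueError("mask_threshold must be in [0, 1]")
        if not 0 <= self.end_threshold <= 100:
            raise ValueError("end_threshold must be in [0, 100]")
        if self.extra_end_trim < 0:
            raise ValueError("extra_end_trim must be >= 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 <= self.seed < 2**31:
            raise ValueError("seed must be in [0, 2^31)")
        if self.dwell_mean <= 2 or self.noise_sd < 0 or self.n_reads < 1:
            raise ValueError("invalid simulation parameters")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        """Short stable digest embedded in output headers for provenance."""
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
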