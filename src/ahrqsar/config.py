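"""Run configuration: every tunable threshold with its standard default.

The configuration round-trips losslessly through YAML, and its content
hash is stamped into every written artifact so a run can be reproduced
from its outputs alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields

import yaml

from .mixture import TCDD_EC25_DEFAULT_UM

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    scheme: str = "4cat"
    seed: int = 0
    # curation thresholds
    purity_min_pct: float = 90.0
    cytotox_factor: float = 3.0
    inactive_cytotox_limit_uM: float = 100.0
    # predictor filtering / reselection
    min_variability: float = 0.01
    importance_threshold: float = 0.05
    # mixture accounting
    tcdd_ec25_uM: float = TCDD_EC25_DEFAULT_UM
    # paths (optional, CLI-facing)
    out_dir: str = "."
    extra: dict = field(default_factory=dict)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def content_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
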