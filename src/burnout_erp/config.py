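"""Run configuration: one YAML-serialisable object covering every stage."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml


@dataclass
class RunConfig:
    """Parameters for a full simulate -> extract -> analyze run.

    Defaults mirror the study conditions: an 18 + 17 ERP-eligible cohort,
    0.1-40 Hz band, 80 μV rejection threshold, and a 50-epoch eligibility
    minimum.
    """

    seed: int = 0
    n_burnout: int = 18
    n_non_burnout: int = 17
    dispersed: bool = True
    low_hz: float = 0.1
    high_hz: float = 40.0
    threshold_uv: float = 80.0
    min_epochs: int = 50
    out_dir: str = "results/run"

    def __post_init__(self):
        if not (0 < self.low_hz < self.high_hz < 250.0):
            raise ValueError("band edges must satisfy 0 < low < high < 250 Hz")
        if self.threshold_uv <= 0:
            raise ValueError("rejection threshold must be positive")
        if self.min_epochs < 1:
            raise ValueError("min_epochs must be >= 1")
        if self.n_burnout < 0 or self.n_non_burnout < 0:
            raise ValueError("cohort sizes must be non-negative")

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(asdict(self), f, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as f:
            return cls(**yaml.safe_load(f))

    def digest(self) -> str:
        """Short stable hash of the scientific configuration (the output
        location does not participate)."""
        d = asdict(self)
        d.pop("out_dir")
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
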