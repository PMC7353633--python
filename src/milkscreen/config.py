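"""Run configuration for the screening pipeline."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

from .adulteration import DEFAULT_DOSES


@dataclass
class RunConfig:
    """All tunables of the pipeline, with the study defaults.

    Defaults: 0.5/99.5 percentile boundaries, variance factor 2, KNN k=3,
    1% significance, leave-30%-out with 100 repetitions, 3-of-4 consensus.
    """

    seed: int = 0
    lower_pct: float = 0.5
    upper_pct: float = 99.5
    variance_factor: float = 2.0
    alpha: float = 0.01
    holdout_fraction: float = 0.30
    repetitions: int = 100
    knn_k: int = 3
    simca_factors: int = 3
    svm_gamma: float = 0.1
    min_votes: int = 3
    n_controls: int = 15
    doses: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_DOSES.items()})

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 1 <= self.min_votes <= 4:
            raise ValueError("min_votes must lie in 1..4")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        """Stable hash of the configuration, for run logs."""
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
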