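"""Analysis configuration.

Defaults reproduce the published case study when run on the fixture trials:
95% level with the exact normal quantile, 60% preservation, uniform
Beta prior for the posterior-predictive simulations, continuous expected
responder counts in the deterministic sweeps, and DerSimonian–Laird
random-effects pooling when several trials inform one comparison.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ValidationError

POOLING_MODELS = ("random_dl", "common_iv", "common_mh")
SWEEP_MODES = ("continuous", "integer")
PRIORS = ("uniform", "jeffreys")


@dataclass
class AnalysisConfig:
    confidence_level: float = 0.95
    z_multiplier: float | None = None  # None -> exact quantile for the level
    preservation: float = 0.60
    n_reps: int = 1000
    seed: int | None = None  # required for simulate commands
    prior: str = "uniform"
    sweep_mode: str = "continuous"
    pooling_model: str = "random_dl"

    def __post_init__(self) -> None:
        if not 0.0 < self.confidence_level < 1.0:
            raise ValidationError(f"confidence_level must be in (0,1), got {self.confidence_level}")
        if not 0.0 <= self.preservation <= 1.0:
            raise ValidationError(f"preservation must be in [0,1], got {self.preservation}")
        if self.n_reps < 1:
            raise ValidationError(f"n_reps must be >= 1, got {self.n_reps}")
        if self.prior not in PRIORS:
            raise ValidationError(f"prior must be one of {PRIORS}, got {self.prior!r}")
        if self.sweep_mode not in SWEEP_MODES:
            raise ValidationError(f"sweep_mode must be one of {SWEEP_MODES}, got {self.sweep_mode!r}")
        if self.pooling_model not in POOLING_MODELS:
            raise ValidationError(
                f"pooling_model must be one of {POOLING_MODELS}, got {self.pooling_model!r}"
            )

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        """Load from a YAML or JSON mapping of field names to values."""
        text = Path(path).read_text()
        data = json.loads(text) if str(path).lower().endswith(".json") else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValidationError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"{path}: unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**data)

    def replace(self, **kwargs) -> "AnalysisConfig":
        provided = {k: v for k, v in kwargs.items() if v is not None}
        return dataclasses.replace(self, **provided)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
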