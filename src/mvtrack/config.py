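"""Pipeline hyperparameters.

Defaults are the deployed operating point: 5 prongs spanning a 40-degree
cone, a bottom-right search box covering 60% of each dimension, a minimum
contour span of 10% of the box, a threshold step of 0.005 on the unit
intensity scale, prong length 25% of the atrial bounding-box height, an 85%
open/closed dominance cut-off and a rapid-transition budget of 5% of the
frame count.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

__all__ = ["Config"]


@dataclass(frozen=True)
class Config:
    prong_count: int = 5
    cone_deg: float = 40.0
    box_frac: float = 0.6
    contour_frac: float = 0.1
    step: float = 0.005
    prong_len_frac: float = 0.25
    open_close_frac: float = 0.85
    transition_frac: float = 0.05

    def __post_init__(self) -> None:
        if self.prong_count < 1 or self.prong_count % 2 == 0:
            raise ValueError("Config: prong_count must be odd and >= 1")
        if not (0.0 < self.cone_deg < 180.0):
            raise ValueError("Config: cone_deg must lie in (0, 180)")
        for name in ("box_frac", "contour_frac", "prong_len_frac",
                     "open_close_frac", "transition_frac"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"Config: {name} must lie in (0, 1]")
        if self.step <= 0.0:
            raise ValueError("Config: step must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "Config":
        """Load a YAML mapping of config keys; keyword overrides win."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"Config: unknown keys {sorted(unknown)}")
        data.update(overrides)
        return cls(**data)
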