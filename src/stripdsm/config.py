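"""Pipeline configuration: the survey-design and modelling constants.

Defaults mirror the motivating aerial-survey analysis: 1400 m strip
bandwidth (700 m per side, certain detection), 1.96 km^2 segments and
prediction cells, the 95 % forest-cover exclusion, the |r| >= 0.4
collinearity rule, basis dimensions within k = 4-20, Tweedie power 1.5
and the 15 % residual-autocorrelation trigger.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    bandwidth: float = 1400.0          # m; strip width, also segment length
    min_fraction: float = 0.5          # keep terminal remainder >= this x bandwidth
    forest_threshold: float = 0.95     # exclusion rule for segments and cells
    collinearity_threshold: float = 0.4
    k_min: int = 4
    k_max: int = 20
    k_default: int = 10
    k_grid: list[int] | None = None    # basis-dimension search grid (None = fixed)
    tweedie_p: float = 1.5
    profile_p: bool = False            # profile p over a 0.1 grid in (1, 2)
    acf_threshold: float = 0.15
    cell_area_km2: float = 1.96
    seed: int = 0
    candidates: list[str] = field(default_factory=lambda: [
        "AA+GL", "DC+GL", "GL", "AA", "DC", "AA:GL", "DC:GL"])
    include_joint: bool = True         # keep the AA:GL / DC:GL joint smooths
    outputs: str = "outputs"

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        if not (0.0 <= self.min_fraction <= 1.0):
            raise ValueError("min_fraction must lie in [0, 1]")
        if not (0.0 < self.forest_threshold <= 1.0):
            raise ValueError("forest threshold must lie in (0, 1]")
        if not (0.0 <= self.collinearity_threshold <= 1.0):
            raise ValueError("collinearity threshold must lie in [0, 1]")
        if not (4 <= self.k_min <= self.k_max <= 20):
            raise ValueError("basis dimensions must satisfy 4 <= k_min <= k_max <= 20")
        if not (self.k_min <= self.k_default <= self.k_max):
            raise ValueError("k_default must lie within [k_min, k_max]")
        if not (1.0 < self.tweedie_p < 2.0):
            raise ValueError("Tweedie power must lie strictly inside (1, 2)")
        if not (0.0 <= self.acf_threshold <= 1.0):
            raise ValueError("acf threshold must lie in [0, 1]")
        if self.cell_area_km2 <= 0:
            raise ValueError("cell area must be positive")

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "PipelineConfig":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        return cls(**json.loads(text))
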