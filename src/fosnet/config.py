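"""Run configuration: defaults, YAML loading and validation.

All analysis constants (thresholds 0.79/0.83/0.87, negative cutoff 0.83,
80th hub percentile, 0.70 tree-cut fraction, alpha 0.05) live here as
config defaults — stage logic never hard-codes them.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import yaml

from .hierarchy import DEFAULT_CUT_FRACTION, DEFAULT_CUT_GRID
from .networks import DEFAULT_THRESHOLDS

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    input_paths: tuple[str, ...] = ()
    synthetic: bool = True
    n_regions: int = 60
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    hub_percentile: float = 80.0
    require_all_levels: bool = True
    sign_policy: str = "positive_only"
    cut_fraction: float = DEFAULT_CUT_FRACTION
    cut_fractions: tuple = tuple(DEFAULT_CUT_GRID)
    include_diagonal: bool = True
    alpha: float = 0.05
    run_anova: bool = True
    seed: int = 0
    output_dir: str = "fosnet_run"

    def __post_init__(self) -> None:
        t = self.thresholds
        for key in ("low", "primary", "high", "negative"):
            if key not in t:
                raise ValueError(f"thresholds missing {key!r}")
        if not (t["low"] < t["primary"] < t["high"]):
            raise ValueError("thresholds must satisfy low < primary < high")
        if not 0 < self.hub_percentile < 100:
            raise ValueError("hub_percentile must lie in (0, 100)")
        if not 0 < self.cut_fraction <= 1:
            raise ValueError("cut_fraction must lie in (0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.sign_policy not in ("positive_only", "signed"):
            raise ValueError(f"unknown sign_policy {self.sign_policy!r}")
        self.cut_fractions = tuple(float(f) for f in self.cut_fractions)
        self.input_paths = tuple(str(p) for p in self.input_paths)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["thresholds"] = dict(self.thresholds)
        d["cut_fractions"] = list(self.cut_fractions)
        d["input_paths"] = list(self.input_paths)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a YAML config (flat keys) with keyword overrides on top."""
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        data.update(loaded)
    data.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**data)
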