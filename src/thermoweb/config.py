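"""Scenario configuration: YAML/JSON parsing, validation, grid specs.

A scenario bundles everything a run needs: a community source (either the
synthetic generator or paths to trait tables — exactly one of the two), the
temperature-size rule, an optional thermal-performance model, the
temperature grid, and robustness settings.  Grids may be given as an
explicit list or as an inclusive ``"start:stop:step"`` string.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import yaml

from .biomech import TemperatureSizeRule, ThermalPerformanceModel
from .community import SyntheticConfig

__all__ = ["ScenarioConfig", "parse_t_grid", "load_scenario"]

_GRID_TOL = 1e-9


def parse_t_grid(spec: Union[str, list, tuple, np.ndarray]) -> np.ndarray:
    """Parse a temperature grid.

    Accepts an explicit sequence of temperatures or a ``"start:stop:step"``
    string inclusive of both endpoints (within a 1e-9 floating tolerance),
    e.g. ``"20:30:0.5"`` yields 21 points.
    """
    if isinstance(spec, str):
        parts = spec.split(":")
        if len(parts) != 3:
            raise ValueError(
                f"grid spec must be 'start:stop:step', got {spec!r}"
            )
        start, stop, step = (float(p) for p in parts)
        if step <= 0:
            raise ValueError(f"grid step must be positive, got {step!r}")
        if stop < start:
            raise ValueError(f"grid stop must be >= start in {spec!r}")
        n = int(np.floor((stop - start) / step + _GRID_TOL)) + 1
        grid = start + step * np.arange(n)
        return grid
    grid = np.asarray(spec, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise ValueError("grid must be a non-empty 1-D sequence of temperatures")
    return grid


@dataclass
class ScenarioConfig:
    """Validated configuration of a full pipeline run."""

    synthetic: Optional[SyntheticConfig] = None
    consumer_table: Optional[Path] = None
    resource_table: Optional[Path] = None
    rule: TemperatureSizeRule = field(
        default_factory=lambda: TemperatureSizeRule(alpha=0.98, reference_temperature=20.0)
    )
    thermal: Optional[ThermalPerformanceModel] = None
    t_grid: np.ndarray = field(default_factory=lambda: parse_t_grid("20:30:0.5"))
    robustness_strategy: str = "random"
    robustness_replicates: int = 100
    robustness_seed: Optional[int] = None
    output_dir: Path = Path("thermoweb_out")
    graphml: bool = False

    def validate(self, check_paths: bool = True) -> None:
        has_tables = self.consumer_table is not None or self.resource_table is not None
        if self.synthetic is not None and has_tables:
            raise ValueError(
                "supply either a synthetic community or trait-table paths, not both"
            )
        if self.synthetic is None and not (
            self.consumer_table is not None and self.resource_table is not None
        ):
            raise ValueError(
                "a community source is required: synthetic config, or both "
                "consumer_table and resource_table"
            )
        if self.synthetic is not None:
            self.synthetic.validate()
        if check_paths and has_tables:
            for path in (self.consumer_table, self.resource_table):
                if not Path(path).exists():
                    raise FileNotFoundError(f"trait table not found: {path}")

    def to_dict(self) -> dict:
        return {
            "synthetic": self.synthetic.to_dict() if self.synthetic else None,
            "consumer_table": str(self.consumer_table) if self.consumer_table else None,
            "resource_table": str(self.resource_table) if self.resource_table else None,
            "rule": {
                "alpha": self.rule.alpha,
                "reference_temperature": self.rule.reference_temperature,
            },
            "thermal": (
                {
                    "q10": self.thermal.q10,
                    "reference_temperature": self.thermal.reference_temperature,
                    "plateau_temperature": self.thermal.plateau_temperature,
                }
                if self.thermal
                else None
            ),
            "t_grid": [float(t) for t in self.t_grid],
            "robustness": {
                "strategy": self.robustness_strategy,
                "n_replicates": self.robustness_replicates,
                "seed": self.robustness_seed,
            },
            "output_dir": str(self.output_dir),
            "graphml": self.graphml,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ScenarioConfig":
        kwargs: dict = {}
        if data.get("synthetic"):
            kwargs["synthetic"] = SyntheticConfig.from_dict(dict(data["synthetic"]))
        for key in ("consumer_table", "resource_table"):
            if data.get(key):
                kwargs[key] = Path(data[key])
        if data.get("rule"):
            kwargs["rule"] = TemperatureSizeRule(**data["rule"])
        if data.get("thermal"):
            kwargs["thermal"] = ThermalPerformanceModel(**data["thermal"])
        if data.get("t_grid") is not None:
            kwargs["t_grid"] = parse_t_grid(data["t_grid"])
        rob = data.get("robustness") or {}
        if "strategy" in rob:
            kwargs["robustness_strategy"] = rob["strategy"]
        if "n_replicates" in rob:
            kwargs["robustness_replicates"] = int(rob["n_replicates"])
        if rob.get("seed") is not None:
            kwargs["robustness_seed"] = int(rob["seed"])
        if data.get("output_dir"):
            kwargs["output_dir"] = Path(data["output_dir"])
        if data.get("graphml") is not None:
            kwargs["graphml"] = bool(data["graphml"])
        return cls(**kwargs)


def load_scenario(path: str | Path) -> ScenarioConfig:
    """Load a scenario from a YAML (or JSON — a YAML subset) file."""
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ValueError(f"cannot parse config {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must contain a mapping at the top level")
    config = ScenarioConfig.from_dict(data)
    config.validate(check_paths=False)
    return config


def dump_scenario(config: ScenarioConfig, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(config.to_dict(), indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
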