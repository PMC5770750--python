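"""Declarative run configuration: defaults, validation, YAML round-trip.

A :class:`RunConfig` gathers every knob of the pipeline — arm parameters,
estimator weights, cost weights, optimizer budget, task layout, controller
size and the master seed — with defaults equal to the model's published
operating point.  An empty config file therefore reproduces the default
campaign; any override is carried verbatim into the run archive so that a
stored campaign is bit-reproducible from its config and seed alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .arm import ArmParams
from .estimator import EstimatorConfig
from .optimize import OptimizerConfig
from .task import ANGULAR_SPAN_DEG, ARC_FRACTIONS, POINTS_PER_ARC, WALL_Y, CostConfig

__all__ = ["LayoutSpec", "RunConfig", "load_config", "save_config"]

#: The four target widths of the reaching study (m).
DEFAULT_TARGET_WIDTHS = (0.005, 0.01, 0.02, 0.04)


@dataclass
class LayoutSpec:
    """Task-geometry part of the run configuration."""

    target_widths: tuple = DEFAULT_TARGET_WIDTHS
    wall_y: float = WALL_Y
    target_center_x: float = 0.0
    arc_fractions: tuple = ARC_FRACTIONS
    points_per_arc: tuple = POINTS_PER_ARC
    angular_span_deg: float = ANGULAR_SPAN_DEG
    eval_rollouts: int = 100  #: evaluation rollouts per (width, start)

    def __post_init__(self) -> None:
        self.target_widths = tuple(float(w) for w in self.target_widths)
        self.arc_fractions = tuple(float(f) for f in self.arc_fractions)
        self.points_per_arc = tuple(int(n) for n in self.points_per_arc)
        if any(w <= 0 for w in self.target_widths):
            raise ValueError("LayoutSpec.target_widths must be strictly positive")
        if len(self.arc_fractions) != len(self.points_per_arc):
            raise ValueError("LayoutSpec arcs and point counts must align")
        if self.eval_rollouts < 1:
            raise ValueError("LayoutSpec.eval_rollouts must be >= 1")


@dataclass
class RunConfig:
    """Complete, validated configuration of one campaign."""

    arm: ArmParams = field(default_factory=ArmParams)
    estimator: EstimatorConfig = field(default_factory=EstimatorConfig)
    cost: CostConfig = field(default_factory=CostConfig)
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    layout: LayoutSpec = field(default_factory=LayoutSpec)
    n_hidden: int = 10
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.n_hidden < 1:
            raise ValueError("RunConfig.n_hidden must be >= 1")


_SECTIONS = {
    "arm": ArmParams,
    "estimator": EstimatorConfig,
    "cost": CostConfig,
    "optimizer": OptimizerConfig,
    "layout": LayoutSpec,
}
_SCALARS = {"n_hidden", "seed", "out_dir"}


def _build_section(cls, data: dict, section: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(
            f"unknown key(s) in config section '{section}': {sorted(unknown)}"
        )
    return cls(**data)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    An empty file yields the full default configuration.  Unknown keys are
    rejected with the offending name; every sub-config re-runs its own
    invariant checks.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError("config file must contain a YAML mapping")
    unknown = set(data) - set(_SECTIONS) - _SCALARS
    if unknown:
        raise ValueError(f"unknown top-level config key(s): {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        section = data.get(name, {})
        if not isinstance(section, dict):
            raise ValueError(f"config section '{name}' must be a mapping")
        kwargs[name] = _build_section(cls, section, name)
    for name in _SCALARS:
        if name in data:
            kwargs[name] = data[name]
    return RunConfig(**kwargs)


def _to_plain(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if dataclasses.is_dataclass(obj):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    return obj


def save_config(cfg: RunConfig, path) -> None:
    """Write a configuration to YAML such that ``load_config`` round-trips."""
    data = {name: _to_plain(getattr(cfg, name)) for name in _SECTIONS}
    for name in _SCALARS:
        data[name] = _to_plain(getattr(cfg, name))
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
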