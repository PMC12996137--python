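"""Run configuration: nested YAML blocks with presets and strict validation.

A run config has optional blocks ``phantom``, ``augment``, ``network``,
``loss``, ``train`` and ``evaluate`` plus a ``preset`` ("paper" or "tiny"),
a global ``seed`` and a ``log_level``.  Presets expand to fully resolved
configs: "paper" carries the published training protocol (13×13 kernels,
stage widths 32–256, 1000 epochs at batch 2, lr warmup 1e-7 → 1e-4), while
"tiny" is the desk-scale profile that trains on 64×64 phantom slices in
minutes on a CPU.  Unknown keys are rejected with the offending name.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields, replace
from typing import Any, Optional

import yaml

from .loss import LossConfig
from .network import NetworkConfig, TINY
from .phantom import PhantomSpec
from .preprocess import AugmentConfig
from .train import TINY_TRAIN, TrainConfig


@dataclass(frozen=True)
class EvalConfig:
    prob_threshold: float = 0.5
    match_radius: float = 4.0
    min_lesion_size: int = 2
    component_mode: str = "3d"
    small_lesion_max_mm: float = 3.0


@dataclass(frozen=True)
class RunConfig:
    preset: str = "paper"
    seed: int = 0
    log_level: str = "info"
    resolution: int = 512
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    evaluate: EvalConfig = field(default_factory=EvalConfig)


_BLOCKS = {
    "phantom": PhantomSpec,
    "augment": AugmentConfig,
    "network": NetworkConfig,
    "loss": LossConfig,
    "train": TrainConfig,
    "evaluate": EvalConfig,
}

_TUPLE_KEYS = {
    "volume_shape", "voxel_size", "cmb_diameter_range", "stage_channels",
    "blocks_per_stage", "droppath_rates", "lambdas",
}


def _preset_defaults(preset: str) -> RunConfig:
    if preset == "paper":
        return RunConfig(preset="paper")
    if preset == "tiny":
        return RunConfig(
            preset="tiny",
            resolution=64,
            network=TINY,
            train=TINY_TRAIN,
            phantom=PhantomSpec(
                volume_shape=(10, 64, 64),
                cmb_diameter_range=(2.5, 4.5),
                n_cmb=2,
                n_vessels=3,
                n_calcifications=2,
            ),
        )
    raise ValueError(f"unknown preset {preset!r} (expected 'paper' or 'tiny')")


def _build_block(cls, base, data: dict, path: str):
    valid = {f.name for f in fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in valid:
            raise ValueError(f"unknown config key {path}.{key!r}")
        if key in _TUPLE_KEYS and isinstance(value, list):
            value = tuple(value)
        if key == "cbam_enabled_skips" and isinstance(value, list):
            value = frozenset(value)
        kwargs[key] = value
    return replace(base, **kwargs)


def parse_config(data: Optional[dict]) -> RunConfig:
    """Build a :class:`RunConfig` from a parsed YAML/JSON mapping."""
    data = dict(data or {})
    preset = data.pop("preset", "paper")
    base = _preset_defaults(preset)
    top_scalars = {"seed", "log_level", "resolution"}
    updates: dict[str, Any] = {}
    for key, value in data.items():
        if key in top_scalars:
            updates[key] = value
        elif key in _BLOCKS:
            if not isinstance(value, dict):
                raise ValueError(f"config block {key!r} must be a mapping")
            updates[key] = _build_block(_BLOCKS[key], getattr(base, key), value, key)
        else:
            raise ValueError(f"unknown config key {key!r}")
    return replace(base, **updates)


def load_config(path: str) -> RunConfig:
    """Load and validate a YAML (or JSON) run configuration file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is not None and not isinstance(data, dict):
        raise ValueError(f"{path}: config root must be a mapping")
    return parse_config(data)


def dump_config(cfg: RunConfig) -> str:
    """Serialize a RunConfig to YAML; ``parse_config(yaml.safe_load(...))``
    round-trips to an identical config."""
    out: dict[str, Any] = {
        "preset": cfg.preset,
        "seed": cfg.seed,
        "log_level": cfg.log_level,
        "resolution": cfg.resolution,
    }
    for name, cls in _BLOCKS.items():
        block = dataclasses.asdict(getattr(cfg, name))
        for k, v in block.items():
            if isinstance(v, tuple):
                block[k] = list(v)
            elif isinstance(v, frozenset):
                block[k] = sorted(v)
        out[name] = block
    return yaml.safe_dump(out, sort_keys=False)
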