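"""Merged run configuration with YAML round-trip and seed propagation.

A :class:`RunConfig` bundles the per-stage configs (phantom, sampler,
augmentation, network, training) so one YAML file drives the whole
pipeline. A single global seed deterministically derives independent
per-stage seeds, so every stochastic stage is reproducible from one
integer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .augment import AugmentConfig
from .nn.network import UNetConfig
from .nn.train import TrainConfig
from .phantom import PhantomConfig
from .sampling import SamplerConfig

_STAGES = ("phantom", "sampler", "augment", "network", "train")


def derive_seeds(global_seed: int, n: int = len(_STAGES)) -> list[int]:
    """Derive ``n`` independent per-stage seeds (< 2**31) from one seed."""
    ss = np.random.SeedSequence(global_seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


@dataclass(frozen=True)
class RunConfig:
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    network: UNetConfig = field(default_factory=UNetConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    seed: int = 0

    def with_seed(self, seed: int) -> "RunConfig":
        """Propagate a global seed to every stage config."""
        s = derive_seeds(seed)
        return replace(
            self,
            seed=seed,
            phantom=replace(self.phantom, seed=s[0]),
            sampler=replace(self.sampler, seed=s[1]),
            augment=replace(self.augment, seed=s[2]),
            network=replace(self.network, seed=s[3]),
            train=replace(self.train, seed=s[4]),
        )


_FACTORIES = {
    "phantom": PhantomConfig,
    "sampler": SamplerConfig,
    "augment": AugmentConfig,
    "network": UNetConfig,
    "train": TrainConfig,
}

# tuple-valued fields arrive from YAML as lists
_TUPLE_FIELDS = {
    "tube_radius",
    "elastic_alpha",
    "elastic_sigma",
    "intensity_scale_range",
    "intensity_offset_range",
}


def _coerce(section: dict[str, Any]) -> dict[str, Any]:
    return {
        k: tuple(v) if k in _TUPLE_FIELDS and isinstance(v, list) else v
        for k, v in section.items()
    }


def load_run_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from YAML; absent sections keep their defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs: dict[str, Any] = {}
    for name, factory in _FACTORIES.items():
        section = raw.get(name, {})
        if not isinstance(section, dict):
            raise ValueError(f"YAML section {name!r} must be a mapping")
        section = _coerce(section)
        if name == "train" and isinstance(section.get("class_weights"), dict):
            from .labels import ClassWeights

            section["class_weights"] = ClassWeights(**section["class_weights"])
        kwargs[name] = factory(**section)
    cfg = RunConfig(**kwargs, seed=int(raw.get("seed", 0)))
    if "seed" in raw:
        cfg = cfg.with_seed(int(raw["seed"]))
    return cfg


def dump_run_config(config: RunConfig, path: str | Path) -> None:
    """Write the resolved config snapshot next to a run's outputs."""
    out: dict[str, Any] = {"seed": config.seed}
    for name in _STAGES:
        stage = getattr(config, name)
        out[name] = {
            f.name: _to_plain(getattr(stage, f.name)) for f in fields(stage)
        }
    Path(path).write_text(yaml.safe_dump(out, sort_keys=False))


def _to_plain(value: Any) -> Any:
    if isinstance(value, tuple):
        return list(value)
    if hasattr(value, "__dataclass_fields__"):  # nested config (class weights)
        return {f.name: getattr(value, f.name) for f in fields(value)}
    return value
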