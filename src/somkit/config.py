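"""TOML configuration loading and CLI-flag merging.

Config files carry sections ``[featurization] [model] [evaluate]
[reliability] [logging]``.  Command-line flags always override file
values; the fully resolved configuration is embedded into every output
artifact as provenance.
"""

from __future__ import annotations

import logging
import tomllib
from dataclasses import asdict, dataclass, field
from typing import Any, Optional

from . import descriptors as desc
from .chem_core import SomkitError
from .reliability import ReliabilityConfig
from .som_model import TrainingConfig


class ConfigError(SomkitError):
    pass


@dataclass
class RunConfig:
    radius: int = 5
    fingerprint_kind: str = "fame_binary"
    descriptor_slots: tuple[str, ...] = desc.PHYSCHEM_SLOTS
    n_trees: int = 250
    max_features: str = "sqrt"
    class_weight: str = "balanced"
    threshold: float = 0.3
    reliability_k: int = 3
    seed: int = 0
    log_level: str = "INFO"

    def training(self) -> TrainingConfig:
        return TrainingConfig(
            radius=self.radius,
            fingerprint_kind=self.fingerprint_kind,
            n_trees=self.n_trees,
            max_features=self.max_features,
            class_weight=self.class_weight,
            threshold=self.threshold,
            seed=self.seed,
            descriptor_slots=tuple(self.descriptor_slots),
        )

    def reliability(self) -> ReliabilityConfig:
        return ReliabilityConfig(k=self.reliability_k)

    def provenance(self) -> dict[str, Any]:
        d = asdict(self)
        d["descriptor_slots"] = list(self.descriptor_slots)
        return d


_SECTION_KEYS = {
    "featurization": {"radius", "fingerprint_kind", "descriptor_slots"},
    "model": {"n_trees", "max_features", "class_weight", "threshold", "seed"},
    "evaluate": {"threshold"},
    "reliability": {"k"},
    "logging": {"level"},
}

_RENAMES = {("reliability", "k"): "reliability_k", ("logging", "level"): "log_level"}


def load_config(path: Optional[str] = None, **overrides: Any) -> RunConfig:
    """Build a :class:`RunConfig` from an optional TOML file plus overrides.

    ``overrides`` with value ``None`` are ignored (unset CLI flags).
    """
    values: dict[str, Any] = {}
    if path is not None:
        with open(path, "rb") as fh:
            doc = tomllib.load(fh)
        for section, keys in _SECTION_KEYS.items():
            for key, val in doc.get(section, {}).items():
                if key not in keys:
                    raise ConfigError(f"unknown key {key!r} in section [{section}]")
                values[_RENAMES.get((section, key), key)] = val
        unknown = set(doc) - set(_SECTION_KEYS)
        if unknown:
            raise ConfigError(f"unknown config sections: {sorted(unknown)}")
    for key, val in overrides.items():
        if val is not None:
            values[key] = val
    if "descriptor_slots" in values:
        values["descriptor_slots"] = tuple(values["descriptor_slots"])
    try:
        cfg = RunConfig(**values)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    return cfg
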