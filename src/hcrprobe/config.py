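"""Configuration loading: amplifier definitions and pipeline parameters.

Precedence is CLI flag > user config file > built-in defaults; the effective
values are echoed into every design report.
"""

from __future__ import annotations

from dataclasses import fields as dataclass_fields
from importlib import resources
from pathlib import Path
from typing import Any, Dict, Optional

import yaml

from .pairing import Amplifier
from .sequences import (
    ConfigError,
    DesignParameters,
    HybridizationConditions,
    Region,
)


def _default_config_text() -> str:
    return (
        resources.files("hcrprobe").joinpath("data/default_config.yaml").read_text()
    )


def load_config(path: Optional[str | Path] = None) -> Dict[str, Any]:
    """Merged raw config dict: built-in defaults overlaid with a user file."""
    config = yaml.safe_load(_default_config_text())
    if path is not None:
        with open(path) as handle:
            user = yaml.safe_load(handle) or {}
        for key, value in user.items():
            if isinstance(value, dict) and isinstance(config.get(key), dict):
                config[key].update(value)
            else:
                config[key] = value
    return config


def amplifiers_from_config(config: Dict[str, Any]) -> Dict[str, Amplifier]:
    block = config.get("amplifiers") or {}
    if not block:
        raise ConfigError("config defines no amplifiers")
    up = str(config.get("arm_spacer_up", "AA"))
    down = str(config.get("arm_spacer_down", "AA"))
    out: Dict[str, Amplifier] = {}
    for name, arms in block.items():
        out[name] = Amplifier(
            name=name,
            initiator_up=str(arms["initiator_up"]),
            initiator_down=str(arms["initiator_down"]),
            arm_spacer_up=str(arms.get("arm_spacer_up", up)),
            arm_spacer_down=str(arms.get("arm_spacer_down", down)),
        )
    return out


def get_amplifier(config: Dict[str, Any], name: str) -> Amplifier:
    amps = amplifiers_from_config(config)
    if name not in amps:
        raise ConfigError(
            f"unknown amplifier {name!r}; available: {', '.join(sorted(amps))}"
        )
    return amps[name]


def conditions_from_config(
    config: Dict[str, Any], **overrides: float
) -> HybridizationConditions:
    block = dict(config.get("conditions") or {})
    block.update({k: v for k, v in overrides.items() if v is not None})
    return HybridizationConditions(**block)


def parameters_from_config(
    config: Dict[str, Any], **overrides: Any
) -> DesignParameters:
    block = dict(config.get("parameters") or {})
    block.update({k: v for k, v in overrides.items() if v is not None})
    if "region_priority" in block:
        block["region_priority"] = tuple(
            r if isinstance(r, Region) else Region[str(r).upper()]
            for r in block["region_priority"]
        )
    known = {f.name for f in dataclass_fields(DesignParameters)}
    unknown = set(block) - known
    if unknown:
        raise ConfigError(f"unknown parameter(s) in config: {sorted(unknown)}")
    return DesignParameters(**block)
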