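"""Flat key/value configuration for the task, network and plasticity constants.

A config file is plain YAML with dotted flat keys, e.g.::

    arena.well_radius: 0.3
    protocol.days_reversal: 12
    action.a0: 0.08
    plasticity.eta_ach: 0.000345
    lateral.normalised: true

Unknown keys raise.  Every analysis script accepts ``--config FILE``; values
not present keep their defaults.
"""

from __future__ import annotations

import dataclasses

import yaml

from .action_ring import ActionLayerParams
from .arena import ArenaSpec, ProtocolSpec
from .plasticity import PlasticityParams

__all__ = ["load_config", "build_components"]

_SECTIONS = {
    "arena": ArenaSpec,
    "protocol": ProtocolSpec,
    "action": ActionLayerParams,
    "plasticity": PlasticityParams,
}


def load_config(path: str | None) -> dict:
    """Read a flat-key YAML file; ``None`` gives an empty override set."""
    if path is None:
        return {}
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a flat mapping of key: value")
    for key in cfg:
        section, _, name = key.partition(".")
        if section == "lateral" and name == "normalised":
            continue
        cls = _SECTIONS.get(section)
        if cls is None or name not in {f.name for f in dataclasses.fields(cls)}:
            raise KeyError(f"unknown config key {key!r}")
    return cfg


def build_components(cfg: dict) -> dict:
    """Instantiate the arena/protocol/network/plasticity specs from overrides.

    Returns a dict with keys ``arena``, ``protocol``, ``action``,
    ``plasticity`` and ``lateral_normalised``.
    """
    out = {}
    for section, cls in _SECTIONS.items():
        kwargs = {
            key.split(".", 1)[1]: val
            for key, val in cfg.items()
            if key.startswith(section + ".")
        }
        out[section] = cls(**kwargs)
    out["lateral_normalised"] = bool(cfg.get("lateral.normalised", True))
    return out
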