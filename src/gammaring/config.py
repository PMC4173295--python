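"""YAML round-trip for run configurations.

One human-readable file holds every model constant: cell geometry and
channel densities, both synapse blocks, ring topology, drive frequency,
the optional perturbation protocol, and integration settings.  Defaults
are the calibrated baseline; any subset of keys may appear in a file and
overrides the defaults.
"""

from __future__ import annotations

from dataclasses import asdict, fields, replace
from pathlib import Path

import yaml

from .cell import CellParams
from .drive import DriveConfig
from .network import TopologyConfig
from .perturbation import Protocol
from .simulator import RunConfig
from .synapses import SynapseParams

__all__ = ["to_dict", "from_dict", "save_config", "load_config"]

_SECTIONS = {
    "cell": CellParams,
    "gaba": SynapseParams,
    "topology": TopologyConfig,
    "drive": DriveConfig,
    "protocol": Protocol,
}


def to_dict(config: RunConfig) -> dict:
    return asdict(config)


def _build(cls, data: dict):
    names = {f.name for f in fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = dict(data)
    if cls is DriveConfig and "epsc_params" in kwargs and kwargs["epsc_params"] is not None:
        kwargs["epsc_params"] = _build(SynapseParams, kwargs["epsc_params"])
    if cls is Protocol and "window" in kwargs:
        kwargs["window"] = tuple(kwargs["window"])
    return cls(**kwargs)


def from_dict(data: dict) -> RunConfig:
    kwargs = dict(data)
    for key, cls in _SECTIONS.items():
        if key in kwargs and kwargs[key] is not None:
            kwargs[key] = _build(cls, kwargs[key])
    return _build(RunConfig, kwargs)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(to_dict(config), sort_keys=False))


def load_config(path: str | Path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return from_dict(data)
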