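"""Configuration I/O and packaged fixtures.

Model configurations are plain YAML mirroring the dataclass registry in
:mod:`cryonet.params`; an empty file (or ``load_config(None)``) yields the
packaged defaults, which reproduce the reference oocyte parameter tables
verbatim.  Unknown keys are rejected with their full field path so typos
cannot silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .params import ConfigurationError, ModelConfig

__all__ = ["load_config", "save_config", "config_to_dict", "make_fixture"]


def _apply(obj, data: dict, path: str):
    names = {f.name for f in dataclasses.fields(obj)}
    for key, value in data.items():
        if key not in names:
            raise ConfigurationError(f"unknown config key: {path}{key}")
        current = getattr(obj, key)
        if dataclasses.is_dataclass(current) and isinstance(value, dict):
            _apply(current, value, f"{path}{key}.")
        else:
            setattr(obj, key, value)


def load_config(path=None) -> ModelConfig:
    """Load and validate a YAML config; missing fields take table defaults."""
    cfg = ModelConfig()
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ConfigurationError("config root must be a mapping")
        _apply(cfg, data, "")
    return cfg.validate()


def config_to_dict(cfg: ModelConfig) -> dict:
    d = dataclasses.asdict(cfg)

    def clean(x):
        if isinstance(x, dict):
            return {k: clean(v) for k, v in x.items()}
        if isinstance(x, (list, tuple)):
            return [clean(v) for v in x]
        return x

    return clean(d)


def save_config(cfg: ModelConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=False))


def make_fixture(kind: str) -> ModelConfig:
    """Small, fast configurations for tests and benchmarks.

    - ``sphere_cell``: spherical cell without nucleus, for analytic oracles.
    - ``coarse_oocyte``: the full reference oocyte geometry at coarse resolution.
    - ``no_nucleus``: the homogeneous "ideal solution" variant of the
      oocyte (no nucleus, no envelope), all cytoplasm properties.
    """
    cfg = ModelConfig()
    cfg.numerics.n_r = cfg.numerics.n_theta = 12
    cfg.numerics.frame_stride = 50
    if kind == "sphere_cell":
        cfg.geometry.l_maj = cfg.geometry.l_min = 20.0
        cfg.geometry.has_nucleus = False
        cfg.network_enabled = False
        cfg.ae_mode = "none"
    elif kind == "coarse_oocyte":
        cfg.protocol.dT_max = 0.02
        cfg.protocol.T_stop = 243.15
    elif kind == "no_nucleus":
        cfg.geometry.has_nucleus = False
        cfg.network_enabled = False
        cfg.ae_mode = "none"
    else:
        raise ConfigurationError(f"unknown fixture kind {kind!r}")
    return cfg.validate()
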