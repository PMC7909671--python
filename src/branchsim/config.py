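"""TOML configuration loading for the command-line interface.

A configuration file holds optional ``[model]``, ``[ibs]``, ``[oss]``,
``[pde]`` and ``[experiment]`` tables.  All model defaults equal the reference
parameterization a = 1, b = 1.05, c = 0.9, d = 1.65, alpha = 0.5, k = 2.

Example::

    [model]
    a = 1.0
    b = 1.05
    c = 0.9
    d = 1.65
    alpha = 0.5

    [ibs]
    n = 1000
    sigma = 5e-4
    mu = 1e-2
"""

from __future__ import annotations

import tomllib
from dataclasses import fields

from .games import GameParams, ModelConfig
from .ibs import IbsConfig
from .oss import OssConfig
from .pde import PdeConfig


def _dataclass_from(table: dict, cls):
    names = {f.name for f in fields(cls)}
    unknown = set(table) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {k: (tuple(v) if isinstance(v, list) else v) for k, v in table.items()}
    return cls(**kwargs)


def model_from_table(table: dict) -> ModelConfig:
    alpha = table.pop("alpha", 0.5)
    k = table.pop("k", 2)
    if "games" in table:
        games = tuple(_dataclass_from(g, GameParams) for g in table.pop("games"))
        weights = tuple(table.pop("weights")) if "weights" in table else None
        return ModelConfig(games=games, weights=weights)
    game = _dataclass_from(table, GameParams)
    if k == 2:
        return ModelConfig.asymmetric(alpha, game, game)
    return ModelConfig.symmetric(game, k=k)


def load_config(path) -> dict:
    """Parse a TOML file into model/engine configuration objects."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    out = {"model": model_from_table(dict(raw.get("model", {})))}
    if "ibs" in raw:
        out["ibs"] = _dataclass_from(raw["ibs"], IbsConfig)
    if "oss" in raw:
        out["oss"] = _dataclass_from(raw["oss"], OssConfig)
    if "pde" in raw:
        out["pde"] = _dataclass_from(raw["pde"], PdeConfig)
    if "experiment" in raw:
        out["experiment"] = dict(raw["experiment"])
    return out
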