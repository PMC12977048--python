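"""Hierarchical run configuration.

A :class:`RunConfig` is a nested mapping with the groups
``{data, split, representation, transform, model, routine, trainer, seed}``.
A resolved config fully determines a run; the trainer echoes the resolved copy
into the run directory so any run can be reproduced from it alone.  Dot-path
overrides (``model.width=128``) mirror command-line usage.
"""

from __future__ import annotations

import copy
from typing import Any, Optional

import yaml

from ..errors import ConfigError

DEFAULTS: dict = {
    "seed": 0,
    "data": {
        "path": None,
        "rxn_column": "rxn_smiles",
        "target_column": "target",
        "skip_invalid": False,
        "geometry_dir": None,
    },
    "split": {
        "strategy": "random",
        "ratios": [0.8, 0.1, 0.1],
        "seed": None,            # falls back to the global seed
        "path": None,            # load a saved split instead of computing one
        "subsample_fraction": 1.0,
        "subsample_seed": None,
    },
    "representation": {
        "name": "cgr",           # drfp | tokens | cgr | geometry
        "radius": 3,
        "n_bits": 2048,
        "fp_seed": 0,
        "transforms": [],        # e.g. [{name: virtual_node}, {name: rwse, k: 8}]
    },
    "model": {
        "architecture": "dmpnn",
        "width": 64,
        "depth": 3,
        "dropout": 0.0,
        "normalization": "none",
        "pooling": None,         # default: sum for graphs, mean for 3D
        "head_depth": 1,
        "activation": None,
        "cutoff": 5.0,
        "n_rbf": 8,
        "n_blocks": 3,
        "n_angular": 6,
        "embedding_dim": 64,
        "molecule_encoder": "gru",
    },
    "routine": {
        "task": "regression",    # regression | classification
        "scale_targets": True,
        "n_classes": 2,
        "lr": 1e-3,
        "weight_decay": 0.0,
        "batch_size": 64,
        "warmup_steps": 10,
        "clip_norm": 1.0,
        "max_epochs": 100,
        "patience": 30,
        "min_delta": 0.01,
    },
    "trainer": {
        "run_dir": None,
        "log_epochs": True,
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


class RunConfig:
    def __init__(self, overrides: Optional[dict] = None):
        self._d = _merge(DEFAULTS, overrides or {})

    # -- access --------------------------------------------------------------

    def __getitem__(self, group: str) -> Any:
        return self._d[group]

    def get(self, path: str, default: Any = ConfigError) -> Any:
        node: Any = self._d
        for part in path.split("."):
            if not isinstance(node, dict) or part not in node:
                if default is ConfigError:
                    raise ConfigError(f"no config entry at path {path!r}")
                return default
            node = node[part]
        return node

    def set(self, path: str, value: Any) -> None:
        parts = path.split(".")
        node = self._d
        for part in parts[:-1]:
            if part not in node or not isinstance(node[part], dict):
                raise ConfigError(f"no config group at path {path!r}")
            node = node[part]
        if parts[-1] not in node:
            raise ConfigError(f"unknown config key {path!r}")
        node[parts[-1]] = value

    def has_path(self, path: str) -> bool:
        try:
            self.get(path)
            return True
        except ConfigError:
            return False

    def copy(self) -> "RunConfig":
        return RunConfig(copy.deepcopy(self._d))

    def to_dict(self) -> dict:
        return copy.deepcopy(self._d)

    # -- (de)serialization -----------------------------------------------------

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self._d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh) or {})

    def apply_overrides(self, overrides: list[str]) -> "RunConfig":
        """Apply ``group.key=value`` strings; values parse as YAML scalars."""
        for ov in overrides:
            if "=" not in ov:
                raise ConfigError(f"override must look like group.key=value, got {ov!r}")
            path, raw = ov.split("=", 1)
            self.set(path.strip(), yaml.safe_load(raw))
        return self

    def resolved_seed(self, group: str, key: str = "seed") -> int:
        value = self._d[group].get(key)
        return int(self._d["seed"] if value is None else value)
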