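"""Hyperparameter sweeps: random search with successive halving.

All sampled trials train for the minimum epoch budget; the top ``1/eta`` by
validation loss advance with the epoch budget multiplied by ``eta`` (trials
are re-run from scratch at the larger budget, so every rung is reproducible
from its config alone), repeated until a single trial remains or the run
budget is exhausted.  Non-integer rung sizes round down with a floor of one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from ..core_data import DatasetTable
from ..errors import ConfigError
from .config import RunConfig
from .trainer import fit


def sample_parameter(rng: np.random.Generator, dist: dict):
    kind = dist.get("type", "choice")
    if kind == "choice":
        values = dist["values"]
        return values[int(rng.integers(len(values)))]
    if kind == "uniform":
        return float(rng.uniform(dist["low"], dist["high"]))
    if kind == "loguniform":
        return float(np.exp(rng.uniform(np.log(dist["low"]), np.log(dist["high"]))))
    if kind == "randint":
        return int(rng.integers(dist["low"], dist["high"] + 1))
    raise ConfigError(f"unknown distribution type {kind!r}")


@dataclass
class SweepResult:
    best_config: RunConfig
    best_val_loss: float
    trials: pd.DataFrame


def load_space(path: str) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def sweep(space: dict, budget: int, eta: float, min_epochs: int,
          base_config: RunConfig, master_seed: int = 0,
          table: Optional[DatasetTable] = None, geoms=None) -> SweepResult:
    """Run a successive-halving sweep over ``space`` (dot-path -> distribution).

    ``budget`` is the number of sampled configurations; with ``budget`` 1 the
    single trial is trained at ``min_epochs`` and returned as best.
    """
    if budget < 1:
        raise ConfigError(f"budget must be >= 1, got {budget}")
    if eta <= 1:
        raise ConfigError(f"halving factor eta must exceed 1, got {eta}")
    for path in space:
        if not base_config.has_path(path):
            raise ConfigError(f"sweep path {path!r} is not a RunConfig entry")

    rng = np.random.default_rng(master_seed)
    trials = []
    for t in range(budget):
        params = {p: sample_parameter(rng, d) for p, d in space.items()}
        trials.append({"trial": t, "params": params})

    rows = []
    surviving = list(range(budget))
    epochs = int(min_epochs)
    rung = 0
    while True:
        scores = {}
        for t in surviving:
            cfg = base_config.copy()
            for p, v in trials[t]["params"].items():
                cfg.set(p, v)
            cfg.set("routine.max_epochs", epochs)
            result = fit(cfg, table=table, geoms=geoms)
            val = float(result.metrics["best_val_loss"])
            scores[t] = val
            rows.append({"trial": t, "rung": rung, "epochs": epochs,
                         "val_loss": val, "test_mae": result.metrics.get("test_mae"),
                         **{f"param.{p}": v for p, v in trials[t]["params"].items()}})
        if len(surviving) <= 1:
            break
        keep = max(1, int(len(surviving) / eta))
        surviving = sorted(sorted(scores, key=lambda t: (scores[t], t))[:keep])
        epochs = int(round(epochs * eta))
        rung += 1

    best_trial = min(scores, key=lambda t: (scores[t], t))
    best_cfg = base_config.copy()
    for p, v in trials[best_trial]["params"].items():
        best_cfg.set(p, v)
    best_cfg.set("routine.max_epochs", epochs)
    return SweepResult(best_cfg, scores[best_trial], pd.DataFrame(rows))


def rung_schedule(budget: int, eta: float, min_epochs: int) -> list[tuple[int, int]]:
    """(rung size, epoch budget) pairs of the successive-halving schedule."""
    out = []
    n, epochs = budget, int(min_epochs)
    while True:
        out.append((n, epochs))
        if n <= 1:
            break
        n = max(1, int(n / eta))
        epochs = int(round(epochs * eta))
    return out
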