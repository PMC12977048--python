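"""Task-level training utilities: target scaling, the learning-rate schedule,
error metrics, seed aggregation and the relative-performance normalizations
used to compare models across splits."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ..errors import ConfigError, RxnForgeError


@dataclass
class TargetScaler:
    """Standardize regression targets with training-set statistics
    (sample standard deviation, n-1 denominator)."""

    mean: float
    std: float

    def scale(self, y: np.ndarray) -> np.ndarray:
        return (np.asarray(y, dtype=float) - self.mean) / self.std

    def unscale(self, y: np.ndarray) -> np.ndarray:
        return np.asarray(y, dtype=float) * self.std + self.mean


def scale_targets(y: Sequence[float]) -> tuple[TargetScaler, np.ndarray]:
    y = np.asarray(y, dtype=float)
    if y.size < 2:
        raise RxnForgeError(f"need >= 2 training targets to fit a scaler, got {y.size}")
    mu = float(y.mean())
    sigma = float(y.std(ddof=1))
    if sigma == 0.0:
        raise RxnForgeError("degenerate targets: zero variance in the training split")
    scaler = TargetScaler(mu, sigma)
    return scaler, scaler.scale(y)


def cosine_warmup_lr(step: int, total_steps: int, base_lr: float,
                     warmup: int = 10) -> float:
    """Linear ramp 0 -> base_lr over ``warmup`` steps, then a half-cosine decay
    to zero at ``total_steps``."""
    if total_steps <= warmup:
        raise ConfigError(
            f"total_steps ({total_steps}) must exceed warmup ({warmup})")
    if step <= warmup:
        return base_lr * step / warmup
    progress = (step - warmup) / (total_steps - warmup)
    return base_lr * 0.5 * (1.0 + np.cos(np.pi * progress))


def compute_metrics(pred: Sequence[float], true: Sequence[float]) -> tuple[float, float]:
    """(MAE, RMSE) in the units of the inputs."""
    pred = np.asarray(pred, dtype=float)
    true = np.asarray(true, dtype=float)
    if pred.shape != true.shape or pred.size == 0:
        raise RxnForgeError(
            f"prediction/target length mismatch: {pred.shape} vs {true.shape}")
    err = pred - true
    return float(np.abs(err).mean()), float(np.sqrt((err ** 2).mean()))


@dataclass
class MetricsReport:
    """Per-seed and aggregate errors for one model on one split."""

    per_seed: list[tuple[float, float]]            # (MAE, RMSE) per seed
    mae_mean: float
    mae_std: float
    rmse_mean: float
    rmse_std: float
    seeds: list[int] = field(default_factory=list)
    excluded: dict[int, str] = field(default_factory=dict)
    split: str = ""
    model: str = ""

    def __post_init__(self) -> None:
        for mae, rmse in self.per_seed:
            if not (rmse >= mae >= 0):
                raise RxnForgeError(
                    f"invalid metrics: need RMSE >= MAE >= 0, got ({mae}, {rmse})")


def aggregate_seeds(per_seed: Sequence[tuple[float, float]],
                    seeds: Optional[Sequence[int]] = None,
                    excluded: Optional[dict[int, str]] = None,
                    split: str = "", model: str = "") -> MetricsReport:
    """Mean and sample standard deviation of MAE/RMSE across seed replicates;
    excluded seeds are recorded with their reason but do not enter the stats."""
    per_seed = [tuple(map(float, p)) for p in per_seed]
    if len(per_seed) < 2:
        raise RxnForgeError("seed aggregation needs >= 2 replicates")
    seeds = list(seeds) if seeds is not None else list(range(len(per_seed)))
    if len(set(seeds)) != len(seeds):
        raise RxnForgeError(f"duplicate seed ids: {seeds}")
    maes = np.array([p[0] for p in per_seed])
    rmses = np.array([p[1] for p in per_seed])
    return MetricsReport(per_seed, float(maes.mean()), float(maes.std(ddof=1)),
                         float(rmses.mean()), float(rmses.std(ddof=1)),
                         seeds=seeds, excluded=dict(excluded or {}),
                         split=split, model=model)


def relative_performance(mae_table: pd.DataFrame,
                         random_split: str = "random") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalize a (model x split) MAE table two ways.

    (a) per split: each model's MAE divided by the best (lowest) MAE on that
    split; (b) per model: each split's MAE divided by the same model's MAE on
    the random split.  Both are returned as DataFrames ready for plotting.
    """
    if mae_table.isna().any().any():
        raise RxnForgeError("MAE table has missing entries; complete it first")
    by_best = mae_table / mae_table.min(axis=0)
    if random_split not in mae_table.columns:
        raise RxnForgeError(
            f"normalization by the random split needs a {random_split!r} column; "
            f"have {list(mae_table.columns)}")
    by_random = mae_table.div(mae_table[random_split], axis=0)
    return by_best, by_random


def subsample_train(indices: Sequence[int], fraction: float, seed: int = 0) -> list[int]:
    """Seeded uniform subsample (without replacement) of the training indices;
    implemented as a shuffle + prefix so samples nest across fractions."""
    if not 0.0 < fraction <= 1.0:
        raise ConfigError(f"subsample fraction must be in (0, 1], got {fraction}")
    indices = list(indices)
    if not indices:
        raise ConfigError("cannot subsample an empty training partition")
    if fraction == 1.0:
        return indices
    order = np.random.default_rng(seed).permutation(len(indices))
    size = round(fraction * len(indices))
    return [indices[i] for i in order[:size]]
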