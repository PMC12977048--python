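"""Reference benchmarks on the synthetic reaction fixtures.

Two standing experiments anchor the test suite and the reproduction script:

* **parameter recovery** — on a noiseless fixture dataset (the target is an
  exact function of bond changes and ring core atoms), a CGR/D-MPNN should
  drive the test error to near zero, while the fingerprint/MLP cannot fully
  recover the mechanism from hashed environment differences and lands
  strictly higher; this reproduces the modality ranking on real barrier data.
* **OOD degradation** — on target-ascending splits (test reactions have
  targets above every training target), every modality's test MAE exceeds its
  random-split MAE, the extrapolation failure that motivates OOD-aware
  benchmarking.

Problem sizes (n=2000 for recovery, n=600 for the cross-modality OOD grid)
and the small widths used here keep a full run on one CPU core in the
minutes range; see docs/methods.md.
"""

from __future__ import annotations

import warnings
from typing import Optional

from .core_data import DatasetTable
from .fixtures import FixtureSpec, generate_dataset
from .representations import GeometryPair
from .training import RunConfig, fit

#: per-modality run settings used by the fixture benchmarks (small widths)
MODALITY_CONFIGS: dict[str, dict] = {
    "dmpnn": {"representation": {"name": "cgr"},
              "model": {"architecture": "dmpnn", "width": 64, "depth": 1},
              "routine": {"lr": 5e-3, "weight_decay": 1e-4, "batch_size": 32}},
    "gcn": {"representation": {"name": "cgr"},
            "model": {"architecture": "gcn", "width": 48, "depth": 2},
            "routine": {"lr": 3e-3, "batch_size": 64}},
    "mlp": {"representation": {"name": "drfp", "n_bits": 2048, "radius": 3},
            "model": {"architecture": "mlp", "width": 128, "depth": 2},
            "routine": {"lr": 1e-3, "batch_size": 64}},
    "han": {"representation": {"name": "tokens"},
            "model": {"architecture": "han", "width": 24, "embedding_dim": 24},
            "routine": {"lr": 3e-3, "batch_size": 64}},
    "dimereaction": {"representation": {"name": "geometry"},
                     "model": {"architecture": "dimereaction", "width": 32,
                               "n_blocks": 1, "cutoff": 4.0},
                     "routine": {"lr": 3e-3, "batch_size": 64}},
}


def _run(modality: str, strategy: str, table: DatasetTable,
         geoms: Optional[dict[str, GeometryPair]], seed: int,
         max_epochs: int) -> dict:
    cfg = RunConfig(MODALITY_CONFIGS[modality])
    cfg.set("seed", int(seed))
    cfg.set("split.strategy", strategy)
    cfg.set("routine.max_epochs", int(max_epochs))
    cfg.set("routine.min_delta", 0.0)
    cfg.set("routine.patience", max(30, max_epochs))
    result = fit(cfg, table=table, geoms=geoms)
    return result.metrics


def parameter_recovery(seed: int = 0, n: int = 2000,
                       max_epochs: int = 300, mlp_epochs: int = 60) -> dict:
    """Noiseless-fixture recovery: returns test MAEs for CGR/D-MPNN and
    DRFP/MLP on the same random split of the same dataset."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table, _ = generate_dataset(FixtureSpec(n=n, seed=seed, sigma_eps=0.0))
        dmpnn = _run("dmpnn", "random", table, None, seed, max_epochs)
        mlp = _run("mlp", "random", table, None, seed, mlp_epochs)
    return {"dmpnn_test_mae": dmpnn["test_mae"], "dmpnn_test_rmse": dmpnn["test_rmse"],
            "mlp_test_mae": mlp["test_mae"], "mlp_test_rmse": mlp["test_rmse"],
            "n": n}


def ood_degradation(seed: int = 0, n: int = 600, max_epochs: int = 25,
                    modalities: tuple[str, ...] = ("mlp", "han", "dmpnn",
                                                   "gcn", "dimereaction")) -> dict:
    """Random-split vs target-ascending test MAE for each modality on one
    fixture dataset (with toy geometries for the 3D model)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table, geoms = generate_dataset(FixtureSpec(n=n, seed=seed, geometry=True))
        out: dict = {"n": n}
        for mod in modalities:
            rand = _run(mod, "random", table, geoms, seed, max_epochs)
            asc = _run(mod, "target_asc", table, geoms, seed, max_epochs)
            out[mod] = {"random_mae": rand["test_mae"],
                        "target_asc_mae": asc["test_mae"],
                        "degradation_ratio": asc["test_mae"] / rand["test_mae"]}
    return out
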