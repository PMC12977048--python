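"""End-to-end run orchestration.

``fit`` executes one resolved :class:`RunConfig`: load data -> split (or load
a saved split) -> build the configured representation -> initialize the model
from the seed -> minibatch training with AdamW, cosine warmup schedule,
gradient-norm clipping and early stopping on validation loss -> restore the
best-validation parameters -> report test metrics in original target units.
Runs with identical configs and seeds are bit-identical.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from ..core_data import DatasetTable, load_dataset
from ..errors import ConfigError, RxnForgeError
from ..models import ModelConfig, ReactionModel, build_model
from ..nn import AdamW, clip_grad_norm, cross_entropy_loss, mse_loss
from ..representations import (GeometryPair, apply_transforms, build_cgr,
                               drfp_fingerprint, load_geometry_pair,
                               tokenize_smiles, Vocabulary)
from ..splitters import SplitIndices, load_split, save_split, split_dataset
from .config import RunConfig
from .routine import (TargetScaler, compute_metrics, cosine_warmup_lr,
                      scale_targets, subsample_train)

GRAPH_ARCHS = ("dmpnn", "gcn")


@dataclass
class FitResult:
    model: ReactionModel
    metrics: dict
    run_dir: Optional[str]
    split: SplitIndices
    history: list[dict] = field(default_factory=list)
    scaler: Optional[TargetScaler] = None


def _model_config(run: RunConfig) -> ModelConfig:
    m = run["model"]
    pooling = m.get("pooling")
    if pooling is None:
        pooling = "mean" if m["architecture"] == "dimereaction" else "sum"
    return ModelConfig(
        architecture=m["architecture"], width=int(m["width"]), depth=int(m["depth"]),
        dropout=float(m["dropout"]), normalization=m["normalization"],
        pooling=pooling, head_depth=int(m["head_depth"]), activation=m.get("activation"),
        cutoff=float(m["cutoff"]), n_rbf=int(m["n_rbf"]), n_blocks=int(m["n_blocks"]),
        n_angular=int(m["n_angular"]), embedding_dim=int(m["embedding_dim"]),
        molecule_encoder=m.get("molecule_encoder", "gru"))


def build_representation(run: RunConfig, table: DatasetTable,
                         train_idx: list[int],
                         geoms: Optional[dict[str, GeometryPair]] = None
                         ) -> tuple[Callable, dict]:
    """Return ``(batch_fn, meta)``: ``batch_fn(indices)`` yields the model input
    for those records; ``meta`` carries the input dimensions the model needs.

    Fitted pieces (the token vocabulary) only ever see the training indices.
    """
    rep = run["representation"]
    name = rep["name"]
    if name == "drfp":
        x = np.stack([drfp_fingerprint(r, radius=int(rep["radius"]),
                                       n_bits=int(rep["n_bits"]),
                                       seed=int(rep["fp_seed"])).bits
                      for r in table.records]).astype(float)
        return (lambda idx: x[np.asarray(idx, dtype=int)]), {"n_bits": x.shape[1]}
    if name == "tokens":
        seqs = [tokenize_smiles(r.to_smiles()) for r in table.records]
        vocab = Vocabulary().fit([seqs[i] for i in train_idx])
        seqs = [vocab.encode(s) for s in seqs]
        return (lambda idx: [seqs[i] for i in idx]), {"vocab_size": vocab.size}
    if name == "cgr":
        graphs = [apply_transforms(build_cgr(r), rep["transforms"] or [])
                  for r in table.records]
        meta = {"d_node": graphs[0].node_features.shape[1],
                "d_edge": graphs[0].edge_features.shape[1]}
        return (lambda idx: [graphs[i] for i in idx]), meta
    if name == "geometry":
        pairs = _resolve_geometries(run, table, geoms)
        return (lambda idx: [pairs[i] for i in idx]), {}
    raise ConfigError(f"unknown representation {name!r}")


def _resolve_geometries(run: RunConfig, table: DatasetTable,
                        geoms: Optional[dict[str, GeometryPair]]) -> list[GeometryPair]:
    if geoms is not None:
        missing = [r.identifier for r in table.records if r.identifier not in geoms]
        if missing:
            raise ConfigError(f"no geometry for records {missing[:5]}...")
        return [geoms[r.identifier] for r in table.records]
    gdir = run.get("data.geometry_dir")
    if not gdir:
        raise ConfigError("geometry representation needs data.geometry_dir "
                          "or in-memory geometries")
    return [load_geometry_pair(os.path.join(gdir, f"{r.identifier}_r.xyz"),
                               os.path.join(gdir, f"{r.identifier}_ts.xyz"))
            for r in table.records]


def _meta_kwargs(arch: str, meta: dict, n_outputs: int) -> dict:
    out = {"n_outputs": n_outputs}
    if arch == "mlp":
        out["n_bits"] = meta["n_bits"]
    elif arch == "han":
        out["vocab_size"] = meta["vocab_size"]
    elif arch in GRAPH_ARCHS:
        out["d_node"] = meta["d_node"]
        out["d_edge"] = meta["d_edge"]
    return out


def _predict(model: ReactionModel, batch_fn: Callable, indices: list[int],
             batch_size: int) -> np.ndarray:
    model.eval()
    preds = []
    for lo in range(0, len(indices), batch_size):
        chunk = indices[lo:lo + batch_size]
        preds.append(model(batch_fn(chunk)).data)
    model.train()
    return np.concatenate(preds) if preds else np.zeros(0)


def fit(run: RunConfig, table: Optional[DatasetTable] = None,
        geoms: Optional[dict[str, GeometryPair]] = None) -> FitResult:
    """Execute one run end to end; see the module docstring."""
    seed = int(run.get("seed"))
    routine = run["routine"]
    task = routine["task"]
    if task not in ("regression", "classification"):
        raise ConfigError(f"routine.task must be regression|classification, got {task!r}")

    if table is None:
        path = run.get("data.path")
        if not path:
            raise ConfigError("data.path is required when no table is passed in")
        table = load_dataset(path, {"rxn_smiles": run.get("data.rxn_column"),
                                    "target": run.get("data.target_column")},
                             skip_invalid=bool(run.get("data.skip_invalid")))

    split_path = run.get("split.path")
    if split_path:
        split = load_split(split_path, n=len(table))
    else:
        split = split_dataset(table, run.get("split.strategy"),
                              run.get("split.ratios"),
                              run.resolved_seed("split"))
    train_idx = list(split.train)
    frac = float(run.get("split.subsample_fraction"))
    if frac < 1.0:
        sub_seed = run["split"].get("subsample_seed")
        train_idx = subsample_train(train_idx, frac,
                                    seed if sub_seed is None else int(sub_seed))

    batch_fn, meta = build_representation(run, table, train_idx, geoms)
    y = table.targets()

    scaler: Optional[TargetScaler] = None
    y_fit = y.copy()
    if task == "regression" and routine["scale_targets"]:
        scaler, _ = scale_targets(y[train_idx])
        y_fit = scaler.scale(y)
    elif task == "classification":
        y_fit = y.astype(int)

    cfg = _model_config(run)
    n_outputs = int(routine["n_classes"]) if task == "classification" else 1
    model = build_model(cfg, seed=seed, **_meta_kwargs(cfg.architecture, meta, n_outputs))

    batch_size = int(routine["batch_size"])
    max_epochs = int(routine["max_epochs"])
    n_batches = max(1, int(np.ceil(len(train_idx) / batch_size)))
    total_steps = max_epochs * n_batches
    warmup = int(routine["warmup_steps"])
    if total_steps <= warmup:
        warnings.warn(f"run too short for {warmup} warmup steps; clamping")
        warmup = max(total_steps - 1, 1)

    opt = AdamW(model.parameters(), lr=float(routine["lr"]),
                weight_decay=float(routine["weight_decay"]))
    shuffle_rng = np.random.default_rng(np.random.SeedSequence([seed, 7919]))
    loss_fn = mse_loss if task == "regression" else cross_entropy_loss

    best_val = np.inf
    best_state = model.state_dict()
    best_epoch = 0
    since_improve = 0
    step = 0
    history: list[dict] = []
    patience = int(routine["patience"])
    min_delta = float(routine["min_delta"])
    clip = float(routine["clip_norm"])

    for epoch in range(1, max_epochs + 1):
        order = shuffle_rng.permutation(len(train_idx))
        epoch_loss = 0.0
        for lo in range(0, len(train_idx), batch_size):
            idx = [train_idx[i] for i in order[lo:lo + batch_size]]
            step += 1
            opt.lr = cosine_warmup_lr(step, total_steps, float(routine["lr"]), warmup)
            model.zero_grad()
            pred = model(batch_fn(idx))
            loss = loss_fn(pred, y_fit[idx])
            value = loss.item()
            if not np.isfinite(value):
                raise RxnForgeError(
                    f"non-finite training loss at epoch {epoch}, step {step}")
            loss.backward()
            clip_grad_norm(model.parameters(), clip)
            opt.step()
            epoch_loss += value * len(idx)
        epoch_loss /= len(train_idx)

        if split.val:
            val_pred = _predict(model, batch_fn, list(split.val), batch_size)
            val_loss = float(np.mean((val_pred - y_fit[list(split.val)]) ** 2)) \
                if task == "regression" else \
                float(cross_entropy_loss(model(batch_fn(list(split.val))),
                                         y_fit[list(split.val)]).item())
        else:
            val_loss = epoch_loss
        history.append({"epoch": epoch, "train_loss": epoch_loss,
                        "val_loss": val_loss, "lr": opt.lr})
        if best_val - val_loss > min_delta:
            best_val = val_loss
            best_state = model.state_dict()
            best_epoch = epoch
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= patience:
                break

    model.load_state_dict(best_state)
    metrics: dict = {"best_epoch": best_epoch, "best_val_loss": float(best_val),
                     "epochs_run": len(history)}
    test_idx = list(split.test)
    if test_idx:
        pred = _predict(model, batch_fn, test_idx, batch_size)
        if task == "regression":
            pred_units = scaler.unscale(pred) if scaler is not None else pred
            mae, rmse = compute_metrics(pred_units, y[test_idx])
            metrics.update({"test_mae": mae, "test_rmse": rmse})
        else:
            labels = pred.argmax(axis=1) if pred.ndim == 2 else pred
            metrics["test_accuracy"] = float((labels == y_fit[test_idx]).mean())

    run_dir = run.get("trainer.run_dir")
    if run_dir:
        os.makedirs(run_dir, exist_ok=True)
        run.to_yaml(os.path.join(run_dir, "config.resolved.yaml"))
        save_split(split, os.path.join(run_dir, "split.json"))
        with open(os.path.join(run_dir, "metrics.json"), "w") as fh:
            json.dump(metrics, fh, indent=2)
        if run.get("trainer.log_epochs"):
            with open(os.path.join(run_dir, "epochs.csv"), "w") as fh:
                fh.write("epoch,train_loss,val_loss,lr\n")
                for h in history:
                    fh.write(f"{h['epoch']},{h['train_loss']:.10g},"
                             f"{h['val_loss']:.10g},{h['lr']:.10g}\n")
    return FitResult(model, metrics, run_dir, split, history, scaler)


def evaluate(result: FitResult, run: RunConfig, table: DatasetTable,
             indices: list[int],
             geoms: Optional[dict[str, GeometryPair]] = None) -> dict:
    """Metrics of a fitted model on an arbitrary index set, in original units."""
    batch_fn, _ = build_representation(run, table, list(result.split.train), geoms)
    pred = _predict(result.model, batch_fn, indices,
                    int(run.get("routine.batch_size")))
    if result.scaler is not None:
        pred = result.scaler.unscale(pred)
    mae, rmse = compute_metrics(pred, table.targets()[indices])
    return {"mae": mae, "rmse": rmse, "n": len(indices)}
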