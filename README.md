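# rxnforge

Modular pipelines for predicting scalar properties of chemical reactions —
activation barrier heights above all — from atom-mapped reaction SMILES, with
chemically informed in- and out-of-distribution data splitting.

Quantum-chemical barrier heights are expensive (a transition-state search can
take hours per reaction), so surrogate models are trained on reaction
databases and queried in milliseconds. How well such a model works depends
jointly on the *representation* of the reaction and the *architecture* paired
with it, and reported accuracies are notoriously sensitive to how the data
were split. `rxnforge` puts the common choices behind one interface so they
can be compared fairly:

| representation | architecture |
| --- | --- |
| differential reaction fingerprint (DRFP): hashed symmetric difference of reactant/product circular substructure sets | multilayer perceptron (MLP) |
| tokenized SMILES (token → molecule hierarchy) | hierarchical attention network (HAN): BiGRU + additive attention at both levels |
| condensed graph of reaction (CGR): one graph over the mapped atoms carrying reactant *and* product bond states | directed message passing network (D-MPNN, hidden states on directed edges with the reverse edge excluded), plus a degree-normalized GCN as the pluggable reference |
| reactant + transition-state 3D geometries | an E(3)-invariant directional message-passing encoder; the head consumes `embedding(TS) − embedding(R)` |

Every stage — data, split, representation, transform, model, routine,
trainer — is a config-selected component: switching from fingerprint/MLP to
CGR/D-MPNN is a configuration change, not a code change. Models train on a
small NumPy reverse-mode autodiff engine included in the package
(`rxnforge.nn`), so runs are dependency-light, CPU-friendly and bit-level
reproducible from a seed.

## Splitters

`random`, `size_asc`/`size_desc` (ordered by reactant heavy-atom count),
`target_asc`/`target_desc` (ordered by the target, probing extrapolation
beyond the observed range), `core` (grouped by the reaction core — the
minimal subgraph of bonds broken, formed or changed in order, so test
mechanisms are unseen) and `scaffold` (grouped by Bemis–Murcko scaffold of
the largest reactant). Splits are saved as JSON with full provenance and
reloaded for reproducible evaluation.

## Worked example

The synthetic-reaction generator produces valence-legal atom-mapped reactions
whose target is a known function of the reaction mechanism
(`w_b`·bond-changes + `w_r`·ring-core-atoms + noise), so a pipeline can be
validated against ground truth:

```python
from rxnforge import FixtureSpec, generate_dataset, parse_reaction_smiles, reaction_core
from rxnforge.training import RunConfig, fit

r = parse_reaction_smiles("[CH3:1][Br:2].[OH-:3]>>[CH3:1][OH:3].[Br-:2]")
core = reaction_core(r)
print("core atoms:", sorted(core.core_atoms))          # [1, 2, 3]
print("broken:", sorted(b[0] for b in core.broken))    # [(1, 2)]
print("formed:", sorted(f[0] for f in core.formed))    # [(1, 3)]
print("canonical key:", core.canonical_key)            # CBr.[OH-]>>CO.[Br-]

table, _ = generate_dataset(FixtureSpec(n=500, seed=0, sigma_eps=0.0))
cfg = RunConfig({
    "representation": {"name": "cgr"},
    "model": {"architecture": "dmpnn", "width": 64, "depth": 1},
    "routine": {"max_epochs": 80, "batch_size": 32, "lr": 5e-3,
                "weight_decay": 1e-4, "min_delta": 0.0, "patience": 80},
})
result = fit(cfg, table=table)
print(f"test MAE  = {result.metrics['test_mae']:.3f} kcal/mol")
print(f"test RMSE = {result.metrics['test_rmse']:.3f} kcal/mol")
```

```
test MAE  = 0.393 kcal/mol
test RMSE = 0.626 kcal/mol
```

On 500 noiseless reactions the CGR/D-MPNN already recovers the
target-generating mechanism to a fraction of a kcal/mol; at n = 2000 the
test MAE drops below 0.05 (see the reproduction script below). A
fingerprint/MLP on the same data plateaus around 4 kcal/mol because the
hashed environment differences do not identify the mechanism — the same
modality ranking seen on real barrier-height data.

The same pipelines run from the shell:

```bash
rxnforge fixtures --n 2000 --seed 0 --out data/fix --geometry
rxnforge split --data data/fix/reactions.csv --strategy core --seed 0 --out split.json
rxnforge train data.path=data/fix/reactions.csv split.path=split.json \
    representation.name=cgr model.architecture=dmpnn routine.max_epochs=50
rxnforge sweep --space sweep.yaml --budget 9 --eta 1.5 --min-epochs 30 \
    data.path=data/fix/reactions.csv
```

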