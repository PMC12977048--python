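# Methods

This note records the modeling assumptions, defaults and numerical choices
behind `rxnforge`, in the order a pipeline executes them.

## Reaction records

Reactions are parsed from atom-mapped reaction SMILES with RDKit. Internal
atom indices are 0-based; atom-map labels are the 1-based integers written in
the SMILES. Hydrogens are implicit: heavy-atom graphs feed all graph
representations, and each heavy atom's total hydrogen count is an atom
feature. The agents field of `reactants>agents>products` is parsed and
discarded with a warning, since no in-scope representation consumes it. When
every heavy atom carries a map label, atom conservation (equal label
multisets on both sides) is enforced at parse time; violations raise a
mapping error listing the offending labels. Duplicate reaction SMILES are
kept as-is so splitter studies see the file unchanged.

## Splitters

All splitters return disjoint, exhaustive partitions with sizes
`round(n·r_train)`, `round(n·r_val)` and the remainder. Ordered splits sort
by the key with the original index as tie-break; ascending order puts the
largest keys in the test set. Grouped splits (reaction core, scaffold)
shuffle the sorted group keys with the seed and assign groups whole — train
fills until it reaches its quota (overshooting by at most one group), then
validation, remainder to test. This greedy rule was an open choice; it is
deterministic, testable, and recorded in the split-file metadata.

The reaction core treats a bond-order change as simultaneously broken and
formed, following the condensed-graph convention that an order change is a
bond-state change. The canonical core key is the map-stripped canonical
fragment SMILES of the core-induced subgraphs, `reactant-core>>product-core`,
and is therefore invariant to atom-map permutation. Bemis–Murcko scaffolds
are computed on the largest reactant fragment (ties broken by
canonical-SMILES order); all acyclic molecules share the empty scaffold `""`
and hence one group.

## Representations

**DRFP.** Shingles are canonical SMILES of the circular environment of every
heavy atom at radii 0..3 (default), collected per side with maps stripped;
bits are set for the symmetric difference, hashed with BLAKE2b (64-bit,
seeded) modulo `n_bits` (default 2048, must be a power of two). The hash
function is pinned for reproducibility. By construction the fingerprint is
invariant to atom maps and molecule order, and symmetric in reaction
direction.

**Tokens.** The standard SMILES token grammar (bracket atoms, two-letter
elements, `%nn` ring closures, `>>`), with the invariant that concatenating
tokens reproduces the input. The vocabulary is fitted on the training split
only; unseen tokens map to a reserved UNK id, preventing leakage.

**CGR.** One node per mapped heavy atom, ordered by map label; the edge set
is the union of reactant and product bonds, materialized as directed edge
pairs. Node features are the element one-hot over {H, C, N, O, F, S, Cl, Br,
other} plus reactant-state (degree, formal charge, aromatic flag, H count,
in-ring flag) and product-minus-reactant differences of the same five. Edge
features are one-hot reactant and product bond orders with "absent" as its
own category, plus a dynamic-bond flag marking edges whose order differs
between sides. The in-ring and dynamic-bond entries go beyond the minimal
feature set; both are standard in CGR-style encodings and make mechanistic
structure directly visible to shallow models. Aromatic bonds are their own
order category rather than order 1.5, keeping the encoding categorical.

**Transforms.** A virtual node (flagged, bidirectionally connected) and
random-walk structural encodings (k return probabilities of the
degree-normalized walk; isolated nodes get zeros) can be chained onto any
graph via config.

**Geometries.** Standard XYZ files in Å; reactant and TS files must agree in
atom count and element order.

## Models

All models train on the package's reverse-mode autodiff engine over float64
NumPy arrays. Weights are fan-in uniform from an explicit seeded generator,
so every run is bit-reproducible. Parameter counts are exact sums over
registered tensors.

* **MLP** — fully connected stack with ReLU, optional dropout/normalization,
  linear head; input is the fingerprint.
* **HAN** — token-level BiGRU with additive attention pooled per molecule,
  then a molecule-level BiGRU (or identity, for an order-insensitive
  variant) with a second attention pooled per reaction.
* **D-MPNN** — hidden states on directed edges; the update of edge `v→w`
  sums states of incoming edges `u→v` with `u ≠ w` (reverse excluded), adds
  the initial edge state, and applies a shared linear map with ReLU. Atom
  states aggregate incoming edge states; pooling is sum by default (size
  information is informative for CGRs).
* **GCN** — `h_v' = act(W_self h_v + W_nbr Σ_u h_u /√(d_u d_v))`; the
  reference implementation of the encoder/layers/pooling/head composition
  that further variants (registry stubs) plug into.
* **3D encoder** — radius graph under a cutoff (default 5 Å), sinusoidal
  (spherical-Bessel l=0) radial basis of distances, cosine basis of angles
  between incident edges, directional interaction blocks over edge triplets,
  SiLU activations, mean pooling. Only distances and angles enter, so the
  embedding is invariant under rotations, translations and reflections; the
  prediction is `head(embedding(TS) − embedding(R))`, so identical pairs
  collapse to `head(0)`. The exact basis family was an open choice — the
  binding contracts are E(3) invariance and the difference head. Atoms with
  no neighbor inside the cutoff are permitted (warned) and contribute
  through their element embedding only.

## Training routine

AdamW (β₁ = 0.9, β₂ = 0.999), cosine learning-rate schedule with 10 warmup
steps (clamped with a warning for runs shorter than the warmup), MSE loss
for regression (cross-entropy for classification), global gradient-norm
clipping at 1.0. Targets are standardized with training-split mean and
sample standard deviation (n−1), and predictions are unscaled before any
metric is computed — metrics are always in original units (kcal/mol). Early
stopping monitors the *scaled* validation loss (the training objective, an
open choice recorded in config) with patience 30 and minimum improvement
Δ = 0.01 by default; "improvement" means `best − current > Δ`. The best
validation checkpoint is restored before testing. Seed replicates aggregate
as mean ± sample standard deviation, with excluded seeds recorded alongside
their reason.

Sweeps are random search plus successive halving: all sampled trials run the
minimum epoch budget, the top `1/η` (floored, minimum one) re-run from
scratch at `η×` the budget, until one trial remains. Re-running from scratch
(rather than warm-starting) keeps every rung reproducible from its config
alone. A Bayesian proposal step is deliberately out of scope.

## Synthetic data generator

The generator emulates unimolecular organic reactions: a random connected
C/N/O heavy-atom graph (3–8 atoms, valences 4/3/2, optional ring closure and
double bond), 1–3 bond edits (break, form, order change) on distinct atom
pairs that keep both sides valence-legal, atom-map labels assigned by a
random permutation, and the target

    y = w_b · (#changed bonds) + w_r · (#core atoms in reactant rings) + ε

with defaults w_b = 5 kcal/mol, w_r = 2 kcal/mol, ε ~ N(0, 1 kcal/mol),
giving targets spanning roughly 5–30 kcal/mol — comparable in spread to real
barrier-height data. Records whose RDKit-parsed bond sets differ from the
sampled edit (aromatic re-perception) are resampled, so the target model
holds exactly for every emitted record. Toy geometries are a deterministic
force layout (springs to 1.5 Å on bonds, soft repulsion) with the TS as the
midpoint of reactant and product layouts plus 0.05 Å seeded jitter.

What this does and does not show: generated reactions exercise parsing,
atom-map bookkeeping, splitting, every representation and model, and give
OOD splits a real signal (targets correlate with core size by construction).
They are *not* thermochemically meaningful — the geometries are not
conformers and the targets are not energies — so passing tests demonstrate
pipeline correctness and learnability of a known mechanism-level signal, not
accuracy on real chemistry.

## Benchmark problem sizes

The standing benchmarks (`rxnforge.benchmarks`) use n = 2000 noiseless
reactions for parameter recovery — D-MPNN width 64, depth 1, batch 32,
lr 5·10⁻³, weight decay 10⁻⁴, 300 epochs; depth 1 with weight decay
generalizes the purely local target best, while deeper/wider settings
memorize the training set without improving test error — and n = 600 (25
epochs, small widths) for the five-modality OOD grid, where the
extrapolation failure on target-ascending splits appears long before
convergence. Both complete in minutes on one CPU core.

## Known limitations

* No automatic atom mapping; inputs must arrive mapped.
* Batch normalization uses batch statistics at evaluation time as well (no
  running averages); layer normalization is the safer default for small
  batches.
* The HAN pads token and molecule sequences per batch; extremely long
  SMILES inflate memory linearly.
* Registry entries for further GNN variants (GAT, GINE, GraphGPS, …) are
  stubs awaiting contribution.
* Classification support is minimal (cross-entropy, accuracy); the
  regression routine is the primary path.
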