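# Methods

## Model

The network predicts logS (log₁₀ aqueous solubility in mol/L) from a
molecular graph of heavy atoms. Hydrogens are implicit: they enter only
through each atom's attached-H count feature. Atom vectors are 39-dim
(element one-hot over B, C, N, O, F, Si, P, S, Cl, As, Se, Br, Te, I,
At plus a catch-all "metal" bin; heavy-atom degree 0–5; formal charge;
radical electrons; hybridization sp/sp²/sp³/sp³d/sp³d²/other;
aromaticity; 0–4 attached hydrogens; chiral-center flag; CIP R/S
one-hot). Bond vectors are 10-dim (single/double/triple/aromatic;
conjugation; ring membership; stereo none/any/Z/E). Degree and H count
clip at the last bin; elements outside the named fifteen fall into the
"metal" bin; an unassigned stereocenter sets the chirality flag with an
all-zero R/S block.

Message passing runs κ layers of neighbor attention
(LeakyReLU-activated linear logit on the concatenated pair of hidden
states, softmax over the bonded neighborhood, ELU context vector
through a value matrix) followed by a GRU state update. A per-layer
readout uses a virtual super node connected to every atom: its state is
initialized to the sum of atom states and refined τ times by the same
attention + GRU cycle, with the final refinement's attention over atoms
retained as that layer's atom-importance vector. The κ per-layer graph
embeddings are fused by scaled dot-product attention
(A = softmax(𝒢𝒢ᵀ/√d_𝒢)) and a linear head with bias maps the fused
embedding to the prediction.

## Design choices where the architecture was genuinely open

- **Initial atom state.** A LeakyReLU-activated linear projection of
  the 39-dim features into d_𝒢, matching the attentive-fingerprint
  lineage this feature scheme comes from.
- **Bond features** enter only the first layer's attention logit,
  concatenated to the neighbor term ([h_v; h_n; b_vn]); later layers
  use node states alone. After one update the states already carry
  bond information, and this keeps all later layers shape-uniform.
- **Fusion to a single embedding.** Row-wise softmax of 𝒢𝒢ᵀ/√d_𝒢
  yields a κ×κ matrix; we take the mean over the rows of A𝒢. This
  treats all neighboring orders symmetrically and reduces exactly to
  the identity at κ = 1 (a single-order model: one readout, fusion a
  no-op — the structural degeneration the tests assert). The
  alternative of using only the last row as a query is not taken
  because it would reintroduce the last-layer bias the multi-order
  design exists to remove.
- **Atom importance** combines layers with weights w_k = column-mean of
  A (how much all queries attend to layer k): score(atom) =
  Σ_k w_k a_k(atom), normalized to sum to one. Using a single layer's
  a_k instead is a defensible alternative; the per-layer vectors are
  retained on the result object so either view is available.
- **Super-node parameters** are shared across the τ refinements within
  a layer but distinct between layers; τ therefore adds computation,
  not parameters (asserted in the tests).
- **Single-atom molecules** have an empty bonded neighborhood, where
  the attention softmax is undefined; the neighborhood is defined as
  the atom itself (self-loop), making featurization and the forward
  pass total.
- **Dropout placement**: on the context vectors (atom- and super-level)
  and on the fused embedding before the head; never inside the GRU
  gates; disabled at inference.
- **No bias terms** in the attention or GRU maps — the update equations
  are pure linear maps of concatenated states; only the output head
  carries a bias.

## Numerical implementation

Parameters live in a nested dict of float64 NumPy arrays and the
forward pass is written against `autograd.numpy`, so gradients come
from reverse-mode AD rather than hand-derived backprop. Molecules are
padded into dense batch tensors; masked attention adds −10³⁰ to
disallowed logits before a max-subtracted softmax, which makes
off-neighborhood weights exactly zero in float64. Padded atoms
self-attend in their own rows (keeping every softmax defined) and are
masked out of all readouts. A per-molecule `forward` (batch of one)
returns the full layer trace — node states, contexts, edge attention,
super-node attention, fusion matrix — used by the attribution code. A
straight-line per-atom loop implementation of the same equations lives
in the test suite as an independent oracle; the batched path agrees
with it to ~10⁻¹⁶ and the tests require 10⁻⁷.

Initialization is Glorot-uniform (fan-based limits), seeded. Training
minimizes mean squared error with Adam (β₁ = 0.9, β₂ = 0.999) plus ℓ2
weight decay added to the gradient, keeping the parameters with the
best validation RMSE. Non-finite loss aborts with a diagnostic rather
than continuing. Mini-batches have fixed, seeded composition; their
order is reshuffled each epoch.

## Hyperparameters

| name | meaning | default | grid |
|---|---|---|---|
| κ | node-embedding layers (neighboring orders) | 2 | 1–6 |
| τ | super-node refinements per layer | 2 | 1–6 |
| d_𝒢 | embedding dimension | 200 | 100–400 step 50 |
| dropout | rate on contexts and fused embedding | 0.2 | 0.1–0.5 |
| learning rate | Adam step size | 0.01 | 10⁻¹–10⁻⁴ |
| weight decay | ℓ2 coefficient | 10⁻⁵ | — |
| epochs | maximum training epochs | 300 | — |

Defaults are the optimum of a random search over the grid; weight
decay and the epoch cap are conventional values exposed as
configuration, not tuned claims. `random_search` samples the grid
uniformly and ranks configurations by validation RMSE.

## Evaluation protocol

Datasets split 80/10/10 at random (sizes floor(0.8n), floor(0.1n),
remainder — n = 1128 gives 902/112/114), repeated five times by
default with the arithmetic mean reported. Metrics are RMSE and
R² = 1 − SS_res/SS_tot (undefined, reported as NaN with a warning,
when the test targets have zero variance). Residuals are
predicted − experimental, so a positive location parameter means
overprediction. The residual distribution is summarized by a
maximum-likelihood fit of the symmetric generalized Gaussian
f(x) = β/(2αΓ(1/β))·exp(−(|x−μ|/α)^β), optimized over (μ, log α,
log β) by Nelder–Mead from a moment-matching start (μ̂ = mean, β = 2,
α² = 2·variance). β = 2 recovers the Gaussian (σ² = α²/2), β = 1 the
Laplace. Zero-spread residuals are rejected as degenerate (α → 0).

## Synthetic benchmark

The generator emulates a group-contribution model of solubility:
random valence-respecting trees (optionally closed into one ring, 30%
of molecules) over C/N/O/S, 3–12 heavy atoms, with target = Σ
per-element contributions + Gaussian noise. Default contributions
(C −0.34, N +0.80, O +1.09, S −1.00) echo the relative ordering of
published group-contribution tables — amine and hydroxyl groups raise
logS, hydrocarbon and divalent-sulfur fragments lower it — and the
default noise sd of 0.3 logS units approximates the reproducibility of
experimental solubility data. Contributions are per element rather
than per functional group so the attribution ground truth is exact and
unambiguous.

What the benchmark exercises: end-to-end learning of an additive
structure from graphs, the direction and rough magnitude of
substitution effects, and calibration of the evaluation stack. What it
does not: aromaticity-dependent targets, charged species, stereo
effects on the label, long-range intramolecular interactions, and the
property distribution of any experimental dataset — passing it shows
the machinery learns and attributes correctly, not that real-data
accuracy is guaranteed. Real datasets in `smiles,logS` CSV form run
through the identical pipeline via `read_dataset`.

Problem sizes used by the test suite and `scripts/acceptance.py`: 600
molecules, three seeds, 30 training epochs at batch size 128 with the
default hyperparameters. Thirty epochs is past the point where
validation RMSE plateaus near the noise floor on this benchmark
(roughly epoch 15–20); the 300-epoch default remains for real
datasets.

## Known limitations

- Molecule-at-a-time inference contract; the batched path exists for
  training throughput, not GPU-scale screening.
- One attention head per mechanism; no multi-head variant.
- Attribution scores are attention weights, not causal effects;
  substitution experiments are the stronger, intervention-based check.
- The GRU and attention carry no bias terms, which slightly restricts
  the function class relative to common GRU parameterizations.
- Random search re-trains from scratch per configuration; there is no
  early stopping across trials or successive halving.
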