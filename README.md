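# mogat

A multi-order graph attention network (MoGAT) for predicting the aqueous
solubility of small molecules (logS, log₁₀ mol/L) from SMILES strings,
with atom-level attribution of each prediction.

Solubility drives formulation, dosing and bioavailability decisions in
drug discovery, but measuring it is slow and models that merely predict
a number are hard to trust. This package targets both problems at once:
a message-passing network whose attention weights *are* the
explanation — every prediction comes with a normalized importance score
per atom, and substitution experiments let you ask "what happens to
solubility if this NH becomes a CH₂?".

## The model

A molecule is a graph of heavy atoms (39 features each: element,
degree, charge, radicals, hybridization, aromaticity, H count,
chirality) and bonds (10 features: type, conjugation, ring membership,
stereo). The network runs κ node-embedding layers. In layer *k*, each
atom *v* attends over its bonded neighbors *n* ∈ 𝒩(v):

    e_vn = LeakyReLU(W · [h_v ; h_n])          (bond features join h_n in layer 1)
    s_vn = softmax_{n∈𝒩(v)}(e_vn)
    c_v  = ELU(Σ_n s_vn · V · h_n)
    h_v  ← GRU(h_v, c_v)

After **every** layer a virtual super node connected to all atoms reads
out a graph embedding: initialized to Σ_v h_v, refined τ times by the
same attention + GRU cycle over all atoms. The κ per-layer graph
embeddings — each summarizing a different neighboring order — are
stacked into 𝒢 and fused with scaled dot-product attention,

    A = softmax(𝒢𝒢ᵀ / √d_𝒢),   final embedding = mean of rows of A𝒢,

and a one-layer FC head maps the fused embedding to logS. The fusion
weights (columns of A) times each layer's super-node attention over
atoms give the per-atom importance scores.

Reference hyperparameters: κ = 2, τ = 2, d_𝒢 = 200, dropout 0.2,
learning rate 0.01 (Adam, ℓ2 weight decay 10⁻⁵, best-on-validation
selection). The model is pure NumPy, differentiated with `autograd`.

## Worked example

Train on a synthetic group-contribution benchmark (600 random
tree-shaped molecules over C/N/O/S; the target is the sum of
per-element contributions — C −0.34, N +0.80, O +1.09, S −1.00 —
plus Gaussian noise, sd 0.3):

```python
from mogat import (SyntheticSpec, SplitSpec, HyperParams, generate_dataset,
                   split_dataset, train, evaluate, fit_ged, build_graph,
                   forward, atom_importance, substitution_experiment)

dataset = generate_dataset(SyntheticSpec(n_molecules=600, seed=0))
graphs = dataset.graphs()
tr, va, te = split_dataset(len(graphs), SplitSpec(n_repeats=1, seed=0))
hyper = HyperParams(epochs=30, seed=0)
result = train([graphs[i] for i in tr], [graphs[i] for i in va], hyper,
               batch_size=128)
ev = evaluate(result.params, hyper, [graphs[i] for i in te])
print(f"test RMSE {ev.metrics.rmse:.3f}   R^2 {ev.metrics.r_squared:.3f}")
ged = fit_ged(ev.residuals)
print(f"residual GED: mu={ged.mu:.3f}  alpha={ged.alpha:.3f}  beta={ged.beta:.3f}")

g = build_graph("CNN")                      # methyl hydrazine
res = forward(g, result.params, hyper)
imp = atom_importance(res.trace)
print(f"prediction for CNN: {res.prediction:.3f}")
for i, (sym, score) in enumerate(zip(g.atom_symbols(), imp.scores)):
    print(f"  atom {i} ({sym}): importance {score:.3f}")

rep = substitution_experiment(result.params, hyper, g, 1, "C")
print(f"replace N1 -> C: {rep.original_prediction:.3f} -> "
      f"{rep.modified_prediction:.3f} (delta {rep.delta:+.3f})")
```

Output:

```
test RMSE 0.400   R^2 0.951
residual GED: mu=0.022  alpha=0.327  beta=1.093
prediction for CNN: 1.721
  atom 0 (C): importance 0.378
  atom 1 (N): importance 0.261
  atom 2 (N): importance 0.361
replace N1 -> C: 1.721 -> 0.006 (delta -1.715)
```

The test RMSE (0.40) sits near the injected noise floor (0.3), i.e. the
network recovered most of the learnable signal. The residuals' fitted
generalized error distribution is nearly unbiased (μ ≈ 0) with
heavier-than-Gaussian tails (β ≈ 1.1). In the ground-truth table
nitrogen contributes +0.80 and carbon −0.34, so swapping the central N
of methyl hydrazine for C should lower the target by ≈ 1.1 — the
trained model predicts a drop of 1.7, the right direction and scale.

Real data work the same way through `read_dataset("esol.csv")` for any
ESOL-shaped `smiles,logS` CSV, or through the CLI:

```bash
mogat simulate --n 600 --seed 7 --noise 0.3 --out synth.csv
mogat train --data synth.csv --out model.npz --seed 1
mogat explain --ckpt model.npz --smiles "CNN"
mogat substitute --ckpt model.npz --smiles "CNN" --atom 1 --to C
```

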