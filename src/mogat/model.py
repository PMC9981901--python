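"""The multi-order graph attention network (MoGAT).

Forward pass, per molecule:

1. Project the 39-dim atom features to the embedding dimension d_G
   (LeakyReLU-activated linear map).
2. Run kappa node-embedding layers.  Each layer scores every bonded
   neighbor with attention (the first layer's neighbor term additionally
   carries the 10-dim bond features), builds an ELU context vector, and
   updates the atom state with a GRU.
3. After EVERY layer, read out a graph embedding through a virtual
   super node connected to all atoms: its state starts as the sum of
   atom states and is refined tau times by attention over the atoms
   followed by a GRU update.  The last update's attention weights are
   that layer's per-atom importance.
4. Stack the kappa graph embeddings, fuse them with scaled dot-product
   attention, and map the fused embedding to the logS prediction with a
   one-layer fully connected head.

Parameters live in a nested dict of numpy arrays (an autograd pytree),
so the whole forward pass is differentiable with ``autograd``.

The internal computation is batched over molecules with padding; the
public :func:`forward` runs a single molecule and returns the full
:class:`LayerTrace` used for atom attribution.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Optional, Sequence

import autograd.numpy as anp
import numpy as np

from .attention import elu, leaky_relu, softmax
from .mol_graph import ATOM_DIM, BOND_DIM, MolecularGraph

#: Hyperparameter search grid for random search.
SEARCH_SPACE = {
    "kappa": [1, 2, 3, 4, 5, 6],
    "tau": [1, 2, 3, 4, 5, 6],
    "d_g": [100, 150, 200, 250, 300, 350, 400],
    "dropout_rate": [0.1, 0.2, 0.3, 0.4, 0.5],
    "learning_rate": [0.1, 0.01, 0.001, 0.0001],
}


@dataclass
class HyperParams:
    """Model and training hyperparameters.

    Defaults are the reference optimum from the search grid
    (kappa=2, tau=2, d_G=200, dropout 0.2, learning rate 0.01).
    kappa counts node-embedding updates (message-passing layers), tau
    counts graph-embedding (super node) updates per layer, and d_G is
    the shared embedding dimension.
    """

    kappa: int = 2
    tau: int = 2
    d_g: int = 200
    dropout_rate: float = 0.2
    learning_rate: float = 0.01
    weight_decay: float = 1e-5
    epochs: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kappa < 1 or self.tau < 1:
            raise ValueError("kappa and tau must be >= 1")
        if self.d_g < 1:
            raise ValueError("d_g must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "HyperParams":
        return cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})


@dataclass
class GRUParams:
    """Gate matrices; each maps [state; context] (reset-gated for W_h)."""

    W_r: np.ndarray
    W_z: np.ndarray
    W_h: np.ndarray


@dataclass
class GRUState:
    r: np.ndarray
    z: np.ndarray
    h_candidate: np.ndarray
    h_new: np.ndarray


def sigmoid(x):
    return 0.5 * (anp.tanh(0.5 * x) + 1.0)


def gru_update(h_prev, c, params: GRUParams) -> GRUState:
    """One GRU step: reset/update gates on [h; c], candidate on [r*h; c].

    h_new = (1 - z) * h_candidate + z * h_prev.
    """
    h_prev = anp.asarray(h_prev)
    c = anp.asarray(c)
    d = h_prev.shape[-1]
    if params.W_r.shape[-1] != d + c.shape[-1]:
        raise ValueError(
            f"GRU gate maps dimension {params.W_r.shape[-1]} but "
            f"[h; c] has {d + c.shape[-1]}"
        )
    hc = anp.concatenate([h_prev, c], axis=-1)
    r = sigmoid(anp.dot(params.W_r, hc))
    z = sigmoid(anp.dot(params.W_z, hc))
    hcand = anp.tanh(anp.dot(params.W_h, anp.concatenate([r * h_prev, c], axis=-1)))
    h_new = (1.0 - z) * hcand + z * h_prev
    return GRUState(r=r, z=z, h_candidate=hcand, h_new=h_new)


# ---------------------------------------------------------------------------
# parameter initialization

def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_out, fan_in = (shape if len(shape) == 2 else (1, shape[0]))
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _gru_block(rng: np.random.Generator, d: int) -> dict:
    return {
        "W_r": _glorot(rng, (d, 2 * d)),
        "W_z": _glorot(rng, (d, 2 * d)),
        "W_h": _glorot(rng, (d, 2 * d)),
    }


def init_params(hyper: HyperParams, seed: Optional[int] = None) -> dict:
    """Glorot-uniform initialization of all learnable matrices.

    Layout::

        proj          (d, 39)   input projection
        atom_layers   kappa dicts: w_self (d,), w_nbr (d,), V (d, d),
                      gru {W_r, W_z, W_h: (d, 2d)};
                      layer 0 additionally w_bond (10,)
        super_layers  kappa dicts: w_self, w_nbr, V, gru (shared across
                      the tau updates within a layer)
        fc            w (d,), b ()

    The attention logit W of the pair [h_v; h_n(; b_vn)] is stored split
    as w_self / w_nbr / w_bond; bond features enter only the first
    layer's neighbor term.
    """
    rng = np.random.default_rng(hyper.seed if seed is None else seed)
    d = hyper.d_g
    params: dict = {"proj": _glorot(rng, (d, ATOM_DIM))}
    atom_layers = []
    super_layers = []
    for k in range(hyper.kappa):
        layer = {
            "w_self": _glorot(rng, (d,)),
            "w_nbr": _glorot(rng, (d,)),
            "V": _glorot(rng, (d, d)),
            "gru": _gru_block(rng, d),
        }
        if k == 0:
            layer["w_bond"] = _glorot(rng, (BOND_DIM,))
        atom_layers.append(layer)
        super_layers.append({
            "w_self": _glorot(rng, (d,)),
            "w_nbr": _glorot(rng, (d,)),
            "V": _glorot(rng, (d, d)),
            "gru": _gru_block(rng, d),
        })
    params["atom_layers"] = atom_layers
    params["super_layers"] = super_layers
    params["fc"] = {"w": _glorot(rng, (d,)), "b": np.zeros(())}
    return params


def count_params(params: dict) -> int:
    n = 0
    stack = [params]
    while stack:
        obj = stack.pop()
        if isinstance(obj, dict):
            stack.extend(obj.values())
        elif isinstance(obj, (list, tuple)):
            stack.extend(obj)
        else:
            n += np.size(obj)
    return n


def init_node_states(graph: MolecularGraph, params: dict) -> np.ndarray:
    """Initial atom states: LeakyReLU(projection @ features), (n, d)."""
    return np.asarray(leaky_relu(graph.atom_matrix() @ params["proj"].T))


# ---------------------------------------------------------------------------
# batching

_NEG = -1e30  # additive mask: exp underflows to exactly 0 after max-subtraction


@dataclass
class GraphBatch:
    """Padded arrays for a batch of molecules."""

    X: np.ndarray          # (B, N, 39) atom features, zero-padded
    atom_mask: np.ndarray  # (B, N) 1 for real atoms
    nbr_mask: np.ndarray   # (B, N, N) 1 where attention (v <- n) is allowed
    bond: np.ndarray       # (B, N, N, 10) bond features, zero where no bond
    n_atoms: np.ndarray    # (B,) true atom counts
    targets: Optional[np.ndarray] = None  # (B,) when all graphs carry targets


def pack_graphs(graphs: Sequence[MolecularGraph]) -> GraphBatch:
    """Pad a list of molecules into dense batch arrays."""
    B = len(graphs)
    sizes = np.array([g.n_atoms for g in graphs])
    N = int(sizes.max())
    X = np.zeros((B, N, ATOM_DIM))
    atom_mask = np.zeros((B, N))
    nbr_mask = np.zeros((B, N, N))
    bond = np.zeros((B, N, N, BOND_DIM))
    for b, g in enumerate(graphs):
        n = g.n_atoms
        X[b, :n] = g.atom_matrix()
        atom_mask[b, :n] = 1.0
        nbr_mask[b, :n, :n] = g.neighbor_mask()
        bond[b, :n, :n] = g.bond_tensor()
        # padded rows attend to themselves so their softmax is defined;
        # their states are zero and they are masked out of every readout
        for v in range(n, N):
            nbr_mask[b, v, v] = 1.0
    targets = None
    if all(g.target is not None for g in graphs):
        targets = np.array([g.target for g in graphs], dtype=float)
    return GraphBatch(X=X, atom_mask=atom_mask, nbr_mask=nbr_mask,
                      bond=bond, n_atoms=sizes, targets=targets)


# ---------------------------------------------------------------------------
# forward pass

@dataclass
class LayerTrace:
    """Everything the forward pass saw, retained for attribution."""

    node_states: list        # per layer: (n, d) updated atom states
    contexts: list           # per layer: (n, d) context vectors
    edge_attention: list     # per layer: (n, n) weights, zero off-neighborhood
    super_states: list       # per layer: (d,) super-node state after tau updates
    atom_attention: list     # per layer: (n,) super-node weights over atoms
    layer_weights: np.ndarray  # (kappa, kappa) fusion matrix A
    final_embedding: np.ndarray  # (d,)
    prediction: float


@dataclass
class PredictionResult:
    prediction: float
    trace: LayerTrace


def _dropout(x, rate: float, rng: Optional[np.random.Generator], training: bool):
    if not training or rate <= 0.0 or rng is None:
        return x
    keep = (rng.random(np.shape(x)) >= rate) / (1.0 - rate)
    return x * keep


def forward_batch(
    params: dict,
    hyper: HyperParams,
    batch: GraphBatch,
    training: bool = False,
    rng: Optional[np.random.Generator] = None,
    collect_trace: bool = False,
):
    """Batched forward pass.

    Returns ``(predictions, extras)`` where predictions is (B,) and
    extras is a dict of intermediate arrays when ``collect_trace``.
    """
    X, atom_mask, nbr_mask, bond = batch.X, batch.atom_mask, batch.nbr_mask, batch.bond
    B, N = X.shape[0], X.shape[1]
    d = hyper.d_g
    rate = hyper.dropout_rate

    # all contractions are phrased as 2-D BLAS matmuls around reshapes
    def _map(x3, M_T):  # (B, N, a) x (a, b) -> (B, N, b)
        a, b = M_T.shape
        return anp.reshape(anp.dot(anp.reshape(x3, (B * N, a)), M_T), (B, N, b))

    H = leaky_relu(_map(X, anp.transpose(params["proj"])))
    H = H * atom_mask[:, :, None]

    embeddings = []
    trace: dict = {"node_states": [], "contexts": [], "edge_attention": [],
                   "super_states": [], "atom_attention": []}

    for k in range(hyper.kappa):
        layer = params["atom_layers"][k]
        # attention logit for the pair (v <- n) splits into a query term
        # on h_v, a key term on h_n, and (first layer) a bond term
        e = anp.dot(H, layer["w_self"])[:, :, None] + anp.dot(H, layer["w_nbr"])[:, None, :]
        if k == 0:
            e = e + anp.dot(bond, layer["w_bond"])
        e = leaky_relu(e)
        e = e + (1.0 - nbr_mask) * _NEG
        S = softmax(e, axis=2)
        HV = _map(H, anp.transpose(layer["V"]))
        C = elu(anp.matmul(S, HV))
        C = _dropout(C, rate, rng, training)

        hc = anp.concatenate([H, C], axis=2)
        gru = layer["gru"]
        r = sigmoid(_map(hc, anp.transpose(gru["W_r"])))
        z = sigmoid(_map(hc, anp.transpose(gru["W_z"])))
        hc2 = anp.concatenate([r * H, C], axis=2)
        hcand = anp.tanh(_map(hc2, anp.transpose(gru["W_h"])))
        H = ((1.0 - z) * hcand + z * H) * atom_mask[:, :, None]

        # super-node readout for this layer
        sl = params["super_layers"][k]
        g = anp.sum(H * atom_mask[:, :, None], axis=1)
        keys = anp.dot(H, sl["w_nbr"])
        HVs = _map(H, anp.transpose(sl["V"]))
        a = None
        for _ in range(hyper.tau):
            logits = leaky_relu(anp.dot(g, sl["w_self"])[:, None] + keys)
            logits = logits + (1.0 - atom_mask) * _NEG
            a = softmax(logits, axis=1)
            c = elu(anp.matmul(a[:, None, :], HVs)[:, 0, :])
            c = _dropout(c, rate, rng, training)
            hcs = anp.concatenate([g, c], axis=1)
            sg = sl["gru"]
            rs = sigmoid(anp.dot(hcs, anp.transpose(sg["W_r"])))
            zs = sigmoid(anp.dot(hcs, anp.transpose(sg["W_z"])))
            gc = anp.tanh(anp.dot(anp.concatenate([rs * g, c], axis=1),
                                  anp.transpose(sg["W_h"])))
            g = (1.0 - zs) * gc + zs * g
        embeddings.append(g)

        if collect_trace:
            trace["node_states"].append(H)
            trace["contexts"].append(C)
            trace["edge_attention"].append(S * nbr_mask)
            trace["super_states"].append(g)
            trace["atom_attention"].append(a)

    G = anp.stack(embeddings, axis=1)  # (B, kappa, d)
    scores = anp.matmul(G, anp.swapaxes(G, 1, 2)) / anp.sqrt(float(d))
    A = softmax(scores, axis=2)
    fused = anp.mean(anp.matmul(A, G), axis=1)
    fused = _dropout(fused, rate, rng, training)
    preds = anp.dot(fused, params["fc"]["w"]) + params["fc"]["b"]

    if collect_trace:
        trace["layer_weights"] = A
        trace["final_embedding"] = fused
        return preds, trace
    return preds, None


def forward(
    graph: MolecularGraph,
    params: dict,
    hyper: HyperParams,
    training: bool = False,
    rng: Optional[np.random.Generator] = None,
) -> PredictionResult:
    """Run one molecule through the network and keep the full trace."""
    batch = pack_graphs([graph])
    preds, tr = forward_batch(params, hyper, batch, training=training,
                              rng=rng, collect_trace=True)
    n = graph.n_atoms
    trace = LayerTrace(
        node_states=[np.asarray(h)[0, :n] for h in tr["node_states"]],
        contexts=[np.asarray(c)[0, :n] for c in tr["contexts"]],
        edge_attention=[np.asarray(s)[0, :n, :n] for s in tr["edge_attention"]],
        super_states=[np.asarray(g)[0] for g in tr["super_states"]],
        atom_attention=[np.asarray(a)[0, :n] for a in tr["atom_attention"]],
        layer_weights=np.asarray(tr["layer_weights"])[0],
        final_embedding=np.asarray(tr["final_embedding"])[0],
        prediction=float(np.asarray(preds)[0]),
    )
    return PredictionResult(prediction=trace.prediction, trace=trace)


def predict(graphs: Sequence[MolecularGraph], params: dict, hyper: HyperParams,
            batch_size: int = 128) -> np.ndarray:
    """Deterministic predictions (dropout off) for a list of molecules."""
    out = []
    for i in range(0, len(graphs), batch_size):
        chunk = list(graphs[i:i + batch_size])
        preds, _ = forward_batch(params, hyper, pack_graphs(chunk))
        out.append(np.asarray(preds))
    return np.concatenate(out) if out else np.array([])


# ---------------------------------------------------------------------------
# checkpointing

_CHECKPOINT_VERSION = 1


def _flatten_tree(obj, prefix: str, out: dict) -> None:
    if isinstance(obj, dict):
        for k, v in obj.items():
            _flatten_tree(v, f"{prefix}{k}/", out)
    elif isinstance(obj, (list, tuple)):
        for i, v in enumerate(obj):
            _flatten_tree(v, f"{prefix}{i}/", out)
    else:
        out[prefix.rstrip("/")] = np.asarray(obj)


def save_checkpoint(path, params: dict, hyper: HyperParams,
                    metadata: Optional[dict] = None) -> None:
    """Serialize parameters + hyperparameters (+ training metadata)."""
    flat: dict = {}
    _flatten_tree(params, "p/", flat)
    header = {
        "version": _CHECKPOINT_VERSION,
        "hyper": hyper.to_dict(),
        "metadata": metadata or {},
    }
    flat["__header__"] = np.frombuffer(
        json.dumps(header).encode("utf-8"), dtype=np.uint8
    )
    np.savez(path, **flat)


def load_checkpoint(path) -> tuple[dict, HyperParams, dict]:
    """Load a checkpoint and validate parameter shapes against its hyperparameters."""
    with np.load(path) as npz:
        flat = {k: npz[k] for k in npz.files}
    header = json.loads(bytes(flat.pop("__header__")).decode("utf-8"))
    hyper = HyperParams.from_dict(header["hyper"])
    reference = init_params(hyper, seed=0)
    expected: dict = {}
    _flatten_tree(reference, "p/", expected)
    if set(expected) != set(flat):
        missing = set(expected) ^ set(flat)
        raise ValueError(f"checkpoint structure mismatch: {sorted(missing)[:5]}")
    params = _unflatten_like(reference, flat)
    for key in expected:
        if expected[key].shape != flat[key].shape:
            raise ValueError(
                f"checkpoint shape mismatch at {key}: "
                f"{flat[key].shape} vs expected {expected[key].shape}"
            )
    return params, hyper, header.get("metadata", {})


def _unflatten_like(template, flat: dict, prefix: str = "p/"):
    if isinstance(template, dict):
        return {k: _unflatten_like(v, flat, f"{prefix}{k}/") for k, v in template.items()}
    if isinstance(template, (list, tuple)):
        return [_unflatten_like(v, flat, f"{prefix}{i}/") for i, v in enumerate(template)]
    return flat[prefix.rstrip("/")]
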