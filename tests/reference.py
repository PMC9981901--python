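"""Independent straight-line reference implementation of the network.

Deliberately written as explicit per-atom loops over the defining
equations (neighbor attention -> context -> GRU; per-layer super-node
readout; scaled dot-product fusion; linear head), sharing no code with
``mogat.model``.  Used as the oracle for forward-pass equivalence
tests.
"""

import math

import numpy as np


def _lrelu(x):
    return np.where(np.asarray(x) >= 0, x, 0.01 * np.asarray(x))


def _elu(x):
    x = np.asarray(x, dtype=float)
    return np.where(x > 0, x, np.exp(np.minimum(x, 0.0)) - 1.0)


def _softmax_list(logits):
    e = [math.exp(l - max(logits)) for l in logits]
    tot = sum(e)
    return [v / tot for v in e]


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def _gru(h, c, gp):
    hc = np.concatenate([h, c])
    r = _sigmoid(gp["W_r"] @ hc)
    z = _sigmoid(gp["W_z"] @ hc)
    hcand = np.tanh(gp["W_h"] @ np.concatenate([r * h, c]))
    return (1.0 - z) * hcand + z * h


def reference_forward(graph, params, hyper):
    """Compute the scalar prediction (and per-layer atom attention)
    for one molecule by direct evaluation of the model equations."""
    X = graph.atom_matrix()
    n = graph.n_atoms
    d = hyper.d_g

    bond_vec = {}
    for i, j, bf in graph.bonds:
        v = bf.vector()
        bond_vec[(i, j)] = v
        bond_vec[(j, i)] = v

    neighborhoods = [list(nb) if nb else [v] for v, nb in enumerate(graph.neighbors)]

    H = [_lrelu(params["proj"] @ X[v]) for v in range(n)]

    graph_embeddings = []
    atom_attentions = []
    for k in range(hyper.kappa):
        layer = params["atom_layers"][k]
        new_H = []
        for v in range(n):
            logits = []
            for nb in neighborhoods[v]:
                t = float(layer["w_self"] @ H[v]) + float(layer["w_nbr"] @ H[nb])
                if k == 0:
                    b = bond_vec.get((v, nb), np.zeros(10))
                    t += float(layer["w_bond"] @ b)
                logits.append(float(_lrelu(t)))
            s = _softmax_list(logits)
            acc = np.zeros(d)
            for w, nb in zip(s, neighborhoods[v]):
                acc = acc + w * (layer["V"] @ H[nb])
            c_v = _elu(acc)
            new_H.append(_gru(H[v], c_v, layer["gru"]))
        H = new_H

        sl = params["super_layers"][k]
        g = np.zeros(d)
        for v in range(n):
            g = g + H[v]
        a = None
        for _ in range(hyper.tau):
            logits = [float(_lrelu(float(sl["w_self"] @ g) + float(sl["w_nbr"] @ H[v])))
                      for v in range(n)]
            a = _softmax_list(logits)
            acc = np.zeros(d)
            for w, v in zip(a, range(n)):
                acc = acc + w * (sl["V"] @ H[v])
            c = _elu(acc)
            g = _gru(g, c, sl["gru"])
        graph_embeddings.append(g)
        atom_attentions.append(np.array(a))

    G = np.stack(graph_embeddings)            # (kappa, d)
    scores = (G @ G.T) / math.sqrt(d)
    A = np.stack([_softmax_list(list(row)) for row in scores])
    fused = np.mean(A @ G, axis=0)
    pred = float(params["fc"]["w"] @ fused) + float(params["fc"]["b"])
    return {
        "prediction": pred,
        "atom_attention": atom_attentions,
        "layer_weights": A,
        "final_embedding": fused,
    }
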