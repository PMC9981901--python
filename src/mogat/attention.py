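"""Attention primitives: neighbor-level soft attention and layer-level
scaled dot-product fusion.

The neighbor-level path scores each neighbor n of a node v with a
LeakyReLU-activated linear form on the concatenated hidden states,
normalizes the scores with a softmax over the neighborhood, and builds
an ELU-activated context vector from the value-projected neighbor
states.  The layer-level path fuses a stack of per-layer graph
embeddings with scaled dot-product attention.

All functions are pure and written against ``autograd.numpy`` so they
can sit on a differentiation path; with plain ndarrays they behave like
ordinary NumPy.
"""

from __future__ import annotations

from dataclasses import dataclass

import autograd.numpy as anp
import numpy as np


def leaky_relu(x, slope: float = 0.01):
    """x for x >= 0, ``slope * x`` otherwise (elementwise)."""
    return anp.where(x >= 0, x, slope * x)


def elu(x):
    """x for x > 0, ``exp(x) - 1`` otherwise (elementwise)."""
    # clip the negative branch's argument so exp never overflows; the
    # clipped region is only reached where the other branch is selected
    return anp.where(x > 0, x, anp.exp(anp.minimum(x, 0.0)) - 1.0)


def softmax(x, axis: int = -1):
    """Numerically stable softmax (max-subtracted)."""
    shifted = x - anp.max(x, axis=axis, keepdims=True)
    e = anp.exp(shifted)
    return e / anp.sum(e, axis=axis, keepdims=True)


@dataclass
class AttentionParams:
    """Parameters of one attention block.

    ``W`` maps a concatenated pair of states to a scalar logit; ``V``
    projects a state into the context space (square in the state dim).
    """

    W: np.ndarray
    V: np.ndarray


def neighbor_logit(h_v, h_n, params: AttentionParams):
    """Unnormalized attention logit e_vn = LeakyReLU(W . [h_v; h_n])."""
    pair = anp.concatenate([h_v, h_n])
    W = params.W
    if W.shape[-1] != pair.shape[0]:
        raise ValueError(
            f"W maps dimension {W.shape[-1]} but [h_v; h_n] has {pair.shape[0]}"
        )
    return leaky_relu(anp.dot(W, pair))


def neighbor_weights(logits):
    """Softmax over a node's neighborhood; logits must be non-empty."""
    logits = anp.asarray(logits)
    if logits.shape[-1] == 0:
        raise ValueError(
            "empty neighbor set: apply the self-loop fallback before the softmax"
        )
    return softmax(logits, axis=-1)


def context_vector(weights, neighbor_states, params: AttentionParams):
    """Context c_v = ELU(sum_n s_vn V h_n) for stacked neighbor states (m, d)."""
    neighbor_states = anp.asarray(neighbor_states)
    if params.V.shape[-1] != neighbor_states.shape[-1]:
        raise ValueError(
            f"V maps dimension {params.V.shape[-1]} but states have "
            f"{neighbor_states.shape[-1]}"
        )
    projected = anp.dot(neighbor_states, params.V.T)  # (m, d)
    return elu(anp.dot(weights, projected))


def layer_attention(G, d_g: float | None = None):
    """Row-stochastic fusion weights A = softmax(G G^T / sqrt(d_G)).

    ``G`` stacks k per-layer graph embeddings as rows (k, d_G).
    """
    G = anp.asarray(G)
    if d_g is None:
        d_g = G.shape[-1]
    scores = anp.dot(G, G.T) / anp.sqrt(float(d_g))
    return softmax(scores, axis=-1)


def fuse_embeddings(G, A):
    """Final graph embedding: mean over the k rows of A G.

    Each row of A G is a convex combination of the per-layer embeddings;
    averaging the rows treats every neighboring order symmetrically and
    reduces to the identity when k = 1.
    """
    return anp.mean(anp.dot(A, G), axis=0)
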