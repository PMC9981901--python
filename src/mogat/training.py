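"""Training loop, splitting protocol, random hyperparameter search, and
evaluation metrics.

The protocol: random 80/10/10 train/validation/test splits, repeated
(five times by default) with the reported metric being the arithmetic
mean over repeats.  Training minimizes mean squared error with l2
weight decay using Adam, keeping the parameters with the best
validation RMSE seen during training.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import autograd.numpy as anp
import numpy as np
from autograd import value_and_grad
from autograd.misc.flatten import flatten

from .ged import GEDParams, fit_ged  # noqa: F401  (re-exported)
from .model import (
    SEARCH_SPACE,
    GraphBatch,
    HyperParams,
    forward_batch,
    init_params,
    pack_graphs,
    predict,
)
from .mol_graph import MolecularGraph

logger = logging.getLogger(__name__)


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass
class SplitSpec:
    """Random split protocol: fractions, number of repeats, seed."""

    train_fraction: float = 0.8
    val_fraction: float = 0.1
    test_fraction: float = 0.1
    n_repeats: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        total = self.train_fraction + self.val_fraction + self.test_fraction
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {total}")


def split_dataset(n_or_graphs, spec: SplitSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint, exhaustive (train, val, test) index partition.

    Sizes are floor(train_fraction * n), floor(val_fraction * n), and
    the remainder, drawn from a seeded shuffle.
    """
    n = n_or_graphs if isinstance(n_or_graphs, int) else len(n_or_graphs)
    if n < 3:
        raise ValueError(f"need at least 3 items to split, got {n}")
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(n)
    n_train = int(np.floor(spec.train_fraction * n))
    n_val = int(np.floor(spec.val_fraction * n))
    return (order[:n_train], order[n_train:n_train + n_val],
            order[n_train + n_val:])


@dataclass
class Metrics:
    """RMSE and R-squared; r_squared is NaN for single-element test sets."""

    rmse: float
    r_squared: float


@dataclass
class EvalResult:
    metrics: Metrics
    predictions: np.ndarray
    residuals: np.ndarray  # predicted - experimental


@dataclass
class TrainResult:
    params: dict
    history: dict
    best_epoch: int


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i:i + batch_size]


def train(
    train_graphs: Sequence[MolecularGraph],
    val_graphs: Sequence[MolecularGraph],
    hyper: HyperParams,
    batch_size: int = 64,
    init: Optional[dict] = None,
    log_every: int = 10,
) -> TrainResult:
    """Fit model parameters by Adam on MSE + l2 weight decay.

    Keeps the parameters with the best validation RMSE (early
    selection).  ``hyper.epochs == 0`` returns the initialization
    unchanged.  Raises :class:`TrainingDivergedError` on non-finite
    loss.
    """
    if len(train_graphs) == 0 or len(val_graphs) == 0:
        raise ValueError("train and validation sets must be nonempty")
    params = init if init is not None else init_params(hyper)
    rng = np.random.default_rng(np.random.SeedSequence([hyper.seed, 0xA11]))

    # pre-pack per-batch groups once per epoch is wasteful; instead pack
    # fixed batches once and shuffle which batch comes first each epoch
    train_list = list(train_graphs)
    y_train = np.array([g.target for g in train_list], dtype=float)
    val_list = list(val_graphs)
    y_val = np.array([g.target for g in val_list], dtype=float)

    def loss(p, batch: GraphBatch, y, drop_rng):
        preds, _ = forward_batch(p, hyper, batch, training=True, rng=drop_rng)
        return anp.mean((preds - y) ** 2)

    loss_and_grad = value_and_grad(loss)

    flat, unflatten = flatten(params)
    m = np.zeros_like(flat)
    v = np.zeros_like(flat)
    b1, b2, eps = 0.9, 0.999, 1e-8
    step = 0

    best_flat = flat.copy()
    best_val = np.inf
    best_epoch = 0
    history = {"train_loss": [], "val_rmse": []}

    # fixed batch composition, seeded; epoch order reshuffled
    n = len(train_list)
    batch_rng = np.random.default_rng(np.random.SeedSequence([hyper.seed, 0xB5]))
    batch_idx = list(_batches(n, batch_size, batch_rng))
    packed = [(pack_graphs([train_list[i] for i in idx]), y_train[idx])
              for idx in batch_idx]

    for epoch in range(hyper.epochs):
        epoch_losses = []
        for bi in rng.permutation(len(packed)):
            batch, y = packed[bi]
            params = unflatten(flat)
            batch_loss, g_tree = loss_and_grad(params, batch, y, rng)
            g, _ = flatten(g_tree)
            g = g + hyper.weight_decay * flat
            step += 1
            m = b1 * m + (1 - b1) * g
            v = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1 ** step)
            vhat = v / (1 - b2 ** step)
            flat = flat - hyper.learning_rate * mhat / (np.sqrt(vhat) + eps)
            epoch_losses.append(float(batch_loss))
        train_loss = float(np.mean(epoch_losses))
        if not np.isfinite(train_loss) or not np.all(np.isfinite(flat)):
            raise TrainingDivergedError(
                f"non-finite loss at epoch {epoch}: {train_loss} "
                f"(lr={hyper.learning_rate})"
            )
        params = unflatten(flat)
        val_pred = predict(val_list, params, hyper)
        val_rmse = float(np.sqrt(np.mean((val_pred - y_val) ** 2)))
        history["train_loss"].append(train_loss)
        history["val_rmse"].append(val_rmse)
        if val_rmse < best_val:
            best_val = val_rmse
            best_flat = flat.copy()
            best_epoch = epoch
        if log_every and epoch % log_every == 0:
            logger.info("epoch %d train_mse=%.4f val_rmse=%.4f",
                        epoch, train_loss, val_rmse)

    return TrainResult(params=unflatten(best_flat), history=history,
                       best_epoch=best_epoch)


def compute_metrics(predictions, targets) -> Metrics:
    """RMSE and R^2 = 1 - SS_res/SS_tot; R^2 is NaN when SS_tot = 0."""
    preds = np.asarray(predictions, dtype=float)
    y = np.asarray(targets, dtype=float)
    rmse = float(np.sqrt(np.mean((preds - y) ** 2)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        warnings.warn("R^2 undefined: targets have zero variance")
        r2 = float("nan")
    else:
        r2 = 1.0 - float(np.sum((preds - y) ** 2)) / ss_tot
    return Metrics(rmse=rmse, r_squared=r2)


def evaluate(params: dict, hyper: HyperParams,
             test_graphs: Sequence[MolecularGraph]) -> EvalResult:
    """RMSE, R-squared and residuals (predicted - experimental) on a test set."""
    test_list = list(test_graphs)
    if len(test_list) == 0:
        raise ValueError("empty test set")
    y = np.array([g.target for g in test_list], dtype=float)
    preds = predict(test_list, params, hyper)
    return EvalResult(metrics=compute_metrics(preds, y),
                      predictions=preds, residuals=preds - y)


@dataclass
class RepeatedMetrics:
    """Per-repeat metrics plus their arithmetic mean."""

    per_repeat: list[Metrics]
    mean_rmse: float
    mean_r_squared: float


def repeated_evaluation(
    graphs: Sequence[MolecularGraph],
    hyper: HyperParams,
    split: SplitSpec,
    batch_size: int = 64,
) -> tuple[RepeatedMetrics, list[TrainResult]]:
    """Full protocol: repeat the random split, train, evaluate; average."""
    graphs = list(graphs)
    per_repeat: list[Metrics] = []
    results: list[TrainResult] = []
    for rep in range(split.n_repeats):
        rep_spec = SplitSpec(split.train_fraction, split.val_fraction,
                             split.test_fraction, 1, seed=split.seed + rep)
        tr_idx, va_idx, te_idx = split_dataset(len(graphs), rep_spec)
        rep_hyper = HyperParams.from_dict({**hyper.to_dict(),
                                           "seed": hyper.seed + rep})
        result = train([graphs[i] for i in tr_idx], [graphs[i] for i in va_idx],
                       rep_hyper, batch_size=batch_size)
        ev = evaluate(result.params, rep_hyper, [graphs[i] for i in te_idx])
        per_repeat.append(ev.metrics)
        results.append(result)
        logger.info("repeat %d rmse=%.4f r2=%.4f", rep, ev.metrics.rmse,
                    ev.metrics.r_squared)
    return (
        RepeatedMetrics(
            per_repeat=per_repeat,
            mean_rmse=float(np.mean([m.rmse for m in per_repeat])),
            mean_r_squared=float(np.mean([m.r_squared for m in per_repeat])),
        ),
        results,
    )


@dataclass
class SearchEntry:
    hyper: HyperParams
    val_rmse: float


def sample_hyperparams(rng: np.random.Generator, base: HyperParams,
                       space: dict = SEARCH_SPACE) -> HyperParams:
    """Draw one configuration uniformly from the search grid."""
    choice = {k: vals[rng.integers(len(vals))] for k, vals in space.items()}
    return HyperParams.from_dict({**base.to_dict(), **choice})


def random_search(
    train_graphs: Sequence[MolecularGraph],
    val_graphs: Sequence[MolecularGraph],
    budget: int,
    seed: int = 0,
    base: Optional[HyperParams] = None,
    space: dict = SEARCH_SPACE,
    batch_size: int = 64,
) -> tuple[HyperParams, list[SearchEntry]]:
    """Uniform random search over the hyperparameter grid.

    Each sampled configuration is trained and scored by validation
    RMSE; returns the argmin plus the full leaderboard (sorted best
    first).
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    base = base if base is not None else HyperParams()
    rng = np.random.default_rng(seed)
    leaderboard: list[SearchEntry] = []
    for trial in range(budget):
        hyper = sample_hyperparams(rng, base, space)
        hyper = HyperParams.from_dict({**hyper.to_dict(), "seed": seed + trial})
        try:
            result = train(train_graphs, val_graphs, hyper, batch_size=batch_size)
            val_rmse = float(np.min(result.history["val_rmse"])) \
                if result.history["val_rmse"] else float("inf")
        except TrainingDivergedError:
            val_rmse = float("inf")
        leaderboard.append(SearchEntry(hyper=hyper, val_rmse=val_rmse))
        logger.info("trial %d val_rmse=%.4f %s", trial, val_rmse, hyper)
    leaderboard.sort(key=lambda e: e.val_rmse)
    return leaderboard[0].hyper, leaderboard
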