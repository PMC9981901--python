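"""Atom-level importance scores and atom-substitution experiments.

The model's readout attaches an attention weight to every atom at every
node-embedding layer (the super node's weights), and the multi-order
fusion attaches a weight to every layer.  Combining the two gives a
per-atom importance score for the prediction: atoms the readout leans
on, in the layers the fusion leans on, score high.

Substitution experiments replace one atom's element, re-derive the
molecule (hydrogen counts, hybridization and aromaticity are
recomputed by the parser), and compare predictions and importances
before and after.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from rdkit import Chem

from .model import HyperParams, LayerTrace, forward
from .mol_graph import MolecularGraph, SmilesParseError, build_graph


@dataclass
class AtomImportance:
    """Normalized per-atom importance scores (sum to 1, nonnegative)."""

    scores: np.ndarray               # (n_atoms,)
    per_layer: np.ndarray            # (kappa, n_atoms) raw attention weights
    layer_weights: np.ndarray        # (kappa,) fusion weight of each layer

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)


def atom_importance(trace: LayerTrace) -> AtomImportance:
    """Fuse per-layer atom attention into one score per atom.

    score(atom) = sum_k w_k * a_k(atom), where a_k is layer k's
    super-node attention over atoms and w_k is the column-mean of the
    layer-fusion matrix A (how much all queries attend to layer k);
    the result is normalized to sum to 1.
    """
    per_layer = np.stack(trace.atom_attention)          # (kappa, n)
    w = np.asarray(trace.layer_weights).mean(axis=0)    # column-mean, (kappa,)
    scores = w @ per_layer
    scores = scores / scores.sum()
    return AtomImportance(scores=scores, per_layer=per_layer, layer_weights=w)


class SubstitutionError(ValueError):
    """Raised when an element replacement is chemically invalid."""


def substitute_atom(graph: MolecularGraph, atom_index: int,
                    new_symbol: str) -> MolecularGraph:
    """Replace one atom's element and re-featurize the molecule.

    Bonds are preserved; implicit hydrogens and hybridization are
    recomputed.  A replacement that violates valence rules raises
    :class:`SubstitutionError`.
    """
    if not 0 <= atom_index < graph.n_atoms:
        raise IndexError(f"atom index {atom_index} out of range "
                         f"for {graph.n_atoms} atoms")
    mol = Chem.MolFromSmiles(graph.smiles)
    if mol is None:  # graph.smiles came from build_graph, so this is unexpected
        raise SmilesParseError(f"could not re-parse SMILES: {graph.smiles!r}")
    rw = Chem.RWMol(mol)
    atom = rw.GetAtomWithIdx(atom_index)
    new_num = Chem.GetPeriodicTable().GetAtomicNumber(new_symbol)
    atom.SetAtomicNum(new_num)
    atom.SetNoImplicit(False)
    atom.SetNumExplicitHs(0)
    try:
        Chem.SanitizeMol(rw)
    except Exception as exc:
        raise SubstitutionError(
            f"replacing atom {atom_index} of {graph.smiles!r} with "
            f"{new_symbol!r} is not chemically valid: {exc}"
        ) from exc
    new_smiles = Chem.MolToSmiles(rw.GetMol())
    return build_graph(new_smiles)


@dataclass
class SubstitutionReport:
    """Before/after comparison for one element replacement."""

    original_prediction: float
    modified_prediction: float
    delta: float                      # modified - original
    original_importance: AtomImportance
    modified_importance: AtomImportance
    atom_index: int
    old_symbol: str
    new_symbol: str
    original_smiles: str
    modified_smiles: str


def substitution_experiment(params: dict, hyper: HyperParams,
                            graph: MolecularGraph, atom_index: int,
                            new_symbol: str) -> SubstitutionReport:
    """Predict and attribute before and after replacing one atom."""
    modified = substitute_atom(graph, atom_index, new_symbol)
    orig = forward(graph, params, hyper)
    mod = forward(modified, params, hyper)
    return SubstitutionReport(
        original_prediction=orig.prediction,
        modified_prediction=mod.prediction,
        delta=mod.prediction - orig.prediction,
        original_importance=atom_importance(orig.trace),
        modified_importance=atom_importance(mod.trace),
        atom_index=atom_index,
        old_symbol=graph.atoms[atom_index].symbol,
        new_symbol=new_symbol,
        original_smiles=graph.smiles,
        modified_smiles=modified.smiles,
    )


_EXPORT_FIELDS = ("smiles", "atom_index", "symbol", "score")


def export_importance(items: Iterable[tuple[MolecularGraph, AtomImportance]],
                      path) -> None:
    """Write per-atom importance records as CSV (one row per atom).

    Columns: smiles, atom_index, symbol, score.  Scores are written in
    full precision so the file round-trips losslessly.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_EXPORT_FIELDS)
        for graph, imp in items:
            for i, (sym, score) in enumerate(
                    zip(graph.atom_symbols(), imp.scores)):
                writer.writerow([graph.smiles, i, sym, repr(float(score))])


def import_importance(path) -> dict[str, list[tuple[int, str, float]]]:
    """Read an export back: smiles -> [(atom_index, symbol, score)]."""
    out: dict[str, list[tuple[int, str, float]]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or tuple(reader.fieldnames) != _EXPORT_FIELDS:
            raise ValueError(f"unexpected header in {path}: {reader.fieldnames}")
        for row in reader:
            out.setdefault(row["smiles"], []).append(
                (int(row["atom_index"]), row["symbol"], float(row["score"])))
    for rows in out.values():
        rows.sort(key=lambda r: r[0])
    return out
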