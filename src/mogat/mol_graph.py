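"""SMILES to featurized molecular graphs.

Atoms are encoded as 39-dimensional vectors and bonds as 10-dimensional
vectors following the AttentiveFP feature scheme: one-hot element symbol
(15 named elements plus a catch-all "metal" bin), heavy-atom degree,
formal charge, radical electron count, hybridization, aromaticity,
attached-hydrogen count, and chirality.  Hydrogens are implicit: only
heavy atoms become graph nodes, and H counts enter through the
``hydrogens`` one-hot block.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.error")

logger = logging.getLogger(__name__)

#: Named element categories; anything else falls into the trailing "metal" bin.
ATOM_SYMBOLS = (
    "B", "C", "N", "O", "F", "Si", "P", "S",
    "Cl", "As", "Se", "Br", "Te", "I", "At",
)
METAL_INDEX = len(ATOM_SYMBOLS)  # 15
N_SYMBOL = 16
N_DEGREE = 6
N_HYBRID = 6
N_HYDROGEN = 5
ATOM_DIM = N_SYMBOL + N_DEGREE + 1 + 1 + N_HYBRID + 1 + N_HYDROGEN + 1 + 2  # 39

N_BOND_TYPE = 4
N_STEREO = 4
BOND_DIM = N_BOND_TYPE + 1 + 1 + N_STEREO  # 10

_HYBRIDIZATION_INDEX = {
    Chem.HybridizationType.SP: 0,
    Chem.HybridizationType.SP2: 1,
    Chem.HybridizationType.SP3: 2,
    Chem.HybridizationType.SP3D: 3,
    Chem.HybridizationType.SP3D2: 4,
}
_OTHER_HYBRID = 5

_BOND_TYPE_INDEX = {
    Chem.BondType.SINGLE: 0,
    Chem.BondType.DOUBLE: 1,
    Chem.BondType.TRIPLE: 2,
    Chem.BondType.AROMATIC: 3,
}

# STEREOCIS/STEREOTRANS are geometrically identical to Z/E; anything else
# (and anything unrecognized) maps to StereoNone.
_STEREO_INDEX = {
    Chem.BondStereo.STEREONONE: 0,
    Chem.BondStereo.STEREOANY: 1,
    Chem.BondStereo.STEREOZ: 2,
    Chem.BondStereo.STEREOE: 3,
    Chem.BondStereo.STEREOCIS: 2,
    Chem.BondStereo.STEREOTRANS: 3,
}


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""


def _onehot(index: int, size: int) -> np.ndarray:
    v = np.zeros(size)
    v[index] = 1.0
    return v


@dataclass
class AtomFeatures:
    """Featurized heavy atom.  ``vector()`` concatenates to length 39."""

    symbol_onehot: np.ndarray
    degree_onehot: np.ndarray
    formal_charge: int
    radical_electrons: int
    hybridization_onehot: np.ndarray
    aromaticity: int
    hydrogens_onehot: np.ndarray
    chirality: int
    chirality_type_onehot: np.ndarray
    symbol: str = ""

    def vector(self) -> np.ndarray:
        return np.concatenate([
            self.symbol_onehot,
            self.degree_onehot,
            [float(self.formal_charge)],
            [float(self.radical_electrons)],
            self.hybridization_onehot,
            [float(self.aromaticity)],
            self.hydrogens_onehot,
            [float(self.chirality)],
            self.chirality_type_onehot,
        ])


@dataclass
class BondFeatures:
    """Featurized bond.  ``vector()`` concatenates to length 10."""

    bond_type_onehot: np.ndarray
    conjugation: int
    in_ring: int
    stereo_onehot: np.ndarray

    def vector(self) -> np.ndarray:
        return np.concatenate([
            self.bond_type_onehot,
            [float(self.conjugation)],
            [float(self.in_ring)],
            self.stereo_onehot,
        ])


def featurize_atom(atom: Chem.Atom, chiral_tag: Optional[str] = None) -> AtomFeatures:
    """Encode one RDKit atom.

    ``chiral_tag`` is the CIP label from ``FindMolChiralCenters``
    (``"R"``, ``"S"``, ``"?"`` for an unassigned stereocenter, or None
    for a non-stereocenter).  Unknown element symbols fall into the
    "metal" bin; degree clips at 5 and hydrogen count at 4.
    """
    symbol = atom.GetSymbol()
    sym_idx = ATOM_SYMBOLS.index(symbol) if symbol in ATOM_SYMBOLS else METAL_INDEX
    degree = min(atom.GetDegree(), N_DEGREE - 1)
    hyb = _HYBRIDIZATION_INDEX.get(atom.GetHybridization(), _OTHER_HYBRID)
    n_h = min(atom.GetTotalNumHs(), N_HYDROGEN - 1)

    chirality = int(chiral_tag is not None)
    chir_type = np.zeros(2)
    if chiral_tag == "R":
        chir_type[0] = 1.0
    elif chiral_tag == "S":
        chir_type[1] = 1.0

    return AtomFeatures(
        symbol_onehot=_onehot(sym_idx, N_SYMBOL),
        degree_onehot=_onehot(degree, N_DEGREE),
        formal_charge=atom.GetFormalCharge(),
        radical_electrons=atom.GetNumRadicalElectrons(),
        hybridization_onehot=_onehot(hyb, N_HYBRID),
        aromaticity=int(atom.GetIsAromatic()),
        hydrogens_onehot=_onehot(n_h, N_HYDROGEN),
        chirality=chirality,
        chirality_type_onehot=chir_type,
        symbol=symbol,
    )


def featurize_bond(bond: Chem.Bond) -> BondFeatures:
    """Encode one RDKit bond; unrecognized bond types count as single."""
    bt = _BOND_TYPE_INDEX.get(bond.GetBondType(), 0)
    stereo = _STEREO_INDEX.get(bond.GetStereo(), 0)
    return BondFeatures(
        bond_type_onehot=_onehot(bt, N_BOND_TYPE),
        conjugation=int(bond.GetIsConjugated()),
        in_ring=int(bond.IsInRing()),
        stereo_onehot=_onehot(stereo, N_STEREO),
    )


@dataclass
class MolecularGraph:
    """A featurized molecule: the universal model input.

    ``bonds`` stores each undirected bond once as ``(i, j, BondFeatures)``;
    ``neighbors`` expands them to symmetric adjacency lists.
    """

    atoms: list[AtomFeatures]
    bonds: list[tuple[int, int, BondFeatures]]
    smiles: str
    target: Optional[float] = None
    neighbors: list[list[int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.neighbors:
            nbrs: list[list[int]] = [[] for _ in self.atoms]
            for i, j, _ in self.bonds:
                nbrs[i].append(j)
                nbrs[j].append(i)
            self.neighbors = nbrs

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def atom_matrix(self) -> np.ndarray:
        """(n_atoms, 39) feature matrix."""
        return np.stack([a.vector() for a in self.atoms])

    def neighbor_mask(self) -> np.ndarray:
        """(n, n) boolean attention mask.

        Entry (v, n) is True when n is bonded to v.  An atom with no
        neighbors (single-atom molecule) gets a self-loop so the softmax
        over its neighborhood is defined.
        """
        n = self.n_atoms
        mask = np.zeros((n, n), dtype=bool)
        for i, j, _ in self.bonds:
            mask[i, j] = True
            mask[j, i] = True
        for v in range(n):
            if not mask[v].any():
                mask[v, v] = True
        return mask

    def bond_tensor(self) -> np.ndarray:
        """(n, n, 10) bond-feature tensor, zero where no bond exists."""
        n = self.n_atoms
        t = np.zeros((n, n, BOND_DIM))
        for i, j, bf in self.bonds:
            v = bf.vector()
            t[i, j] = v
            t[j, i] = v
        return t

    def atom_symbols(self) -> list[str]:
        return [a.symbol for a in self.atoms]


def build_graph(smiles: str, target: Optional[float] = None) -> MolecularGraph:
    """Parse a SMILES string into a featurized :class:`MolecularGraph`.

    Raises :class:`SmilesParseError` if the string is not valid SMILES.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"could not parse SMILES: {smiles!r}")
    Chem.AssignStereochemistry(mol, cleanIt=True, force=True)
    centers = dict(
        Chem.FindMolChiralCenters(
            mol, includeUnassigned=True, useLegacyImplementation=False
        )
    )
    atoms = [featurize_atom(a, centers.get(a.GetIdx())) for a in mol.GetAtoms()]
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), featurize_bond(b))
        for b in mol.GetBonds()
    ]
    return MolecularGraph(atoms=atoms, bonds=bonds, smiles=smiles, target=target)


DEFAULT_SMILES_COLUMN = "smiles"
DEFAULT_TARGET_COLUMN = "measured log solubility in mols per litre"


@dataclass
class Dataset:
    """Graphs loaded from a CSV, with a count of unparseable rows."""

    graphs: list[MolecularGraph]
    n_skipped: int = 0

    def __len__(self) -> int:
        return len(self.graphs)

    def __iter__(self) -> Iterator[MolecularGraph]:
        return iter(self.graphs)

    def __getitem__(self, i):
        return self.graphs[i]

    def targets(self) -> np.ndarray:
        return np.array([g.target for g in self.graphs], dtype=float)


def read_dataset(
    path,
    smiles_col: str = DEFAULT_SMILES_COLUMN,
    target_col: str = DEFAULT_TARGET_COLUMN,
) -> Dataset:
    """Read a ``smiles,target`` CSV into featurized graphs.

    Rows whose SMILES do not parse are skipped with a logged warning and
    counted in ``Dataset.n_skipped``.
    """
    df = pd.read_csv(path)
    for col in (smiles_col, target_col):
        if col not in df.columns:
            raise ValueError(
                f"column {col!r} not found in {path}; available: {list(df.columns)}"
            )
    graphs: list[MolecularGraph] = []
    n_skipped = 0
    for _, row in df.iterrows():
        try:
            graphs.append(build_graph(str(row[smiles_col]), float(row[target_col])))
        except SmilesParseError as exc:
            logger.warning("skipping row: %s", exc)
            n_skipped += 1
    return Dataset(graphs=graphs, n_skipped=n_skipped)


def write_dataset(records: Sequence[tuple[str, float]], path,
                  smiles_col: str = DEFAULT_SMILES_COLUMN,
                  target_col: str = DEFAULT_TARGET_COLUMN) -> None:
    """Write ``(smiles, target)`` records in the CSV dialect read_dataset consumes."""
    pd.DataFrame(records, columns=[smiles_col, target_col]).to_csv(path, index=False)
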