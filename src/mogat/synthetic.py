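"""Synthetic molecule datasets with a known additive ground truth.

Emulates a Klopman-style group-contribution model of aqueous
solubility: every atom of element E contributes a fixed value c_E and a
molecule's target is the sum of its atomic contributions plus Gaussian
noise.  Molecules are random valence-respecting trees over a small
element alphabet, optionally closed into a single ring, emitted as
canonical SMILES.  Contributions are per element (not per functional
group) so the ground truth for atom-attribution tests is unambiguous.

Default conditions: 600 molecules of 3-12 heavy atoms over C/N/O/S
with contributions echoing the relative ordering of published
group-contribution tables (N and O strongly positive, C mildly
negative, divalent S negative) and noise standard deviation 0.3 logS
units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
from rdkit import Chem

from .mol_graph import (
    MolecularGraph,
    build_graph,
    featurize_atom,
    featurize_bond,
    write_dataset,
)

#: Maximum bonds to heavy atoms per element in generated molecules.
VALENCES = {"C": 4, "N": 3, "O": 2, "S": 2, "P": 3, "F": 1, "Cl": 1, "Br": 1}

#: Default per-element solubility contributions (logS units).
DEFAULT_CONTRIBUTIONS = {"C": -0.34, "N": 0.80, "O": 1.09, "S": -1.00}


@dataclass
class ContributionTable:
    """Per-element additive contributions plus the target noise level."""

    values: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONTRIBUTIONS))
    noise_sd: float = 0.3

    def __post_init__(self) -> None:
        if len(self.values) < 2:
            raise ValueError("need at least 2 distinct element contributions")
        if not all(np.isfinite(v) for v in self.values.values()):
            raise ValueError("contributions must be finite")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        unknown = set(self.values) - set(VALENCES)
        if unknown:
            raise ValueError(f"no valence rule for elements: {sorted(unknown)}")


@dataclass
class SyntheticSpec:
    """Generation conditions for one dataset."""

    n_molecules: int = 600
    size_min: int = 3
    size_max: int = 12
    topology: str = "tree_ring"  # "tree" or "tree_ring"
    seed: int = 0
    table: ContributionTable = field(default_factory=ContributionTable)
    ring_probability: float = 0.3

    def __post_init__(self) -> None:
        if self.size_min < 1 or self.size_max < self.size_min:
            raise ValueError("need 1 <= size_min <= size_max")
        if self.topology not in ("tree", "tree_ring"):
            raise ValueError(f"unknown topology {self.topology!r}")


@dataclass
class SyntheticMolecule:
    smiles: str
    target: float
    noise_free_target: float
    #: per-atom contributions in canonical (build_graph) atom order
    atom_contributions: list[float]


@dataclass
class SyntheticDataset:
    molecules: list[SyntheticMolecule]
    spec: SyntheticSpec

    def __len__(self) -> int:
        return len(self.molecules)

    def records(self) -> list[tuple[str, float]]:
        return [(m.smiles, m.target) for m in self.molecules]

    def to_csv(self, path) -> None:
        write_dataset(self.records(), path)

    def graphs(self) -> list[MolecularGraph]:
        return [build_graph(m.smiles, m.target) for m in self.molecules]


def _random_molecule(rng: np.random.Generator, spec: SyntheticSpec) -> Chem.Mol:
    symbols = sorted(spec.table.values)
    n = int(rng.integers(spec.size_min, spec.size_max + 1))
    mol = Chem.RWMol()
    free: list[int] = []  # remaining valence per atom
    first = symbols[rng.integers(len(symbols))]
    mol.AddAtom(Chem.Atom(first))
    free.append(VALENCES[first])
    for _ in range(n - 1):
        hosts = [i for i, f in enumerate(free) if f > 0]
        if not hosts:
            break  # all valences saturated (e.g. halogen-only alphabets)
        host = hosts[rng.integers(len(hosts))]
        sym = symbols[rng.integers(len(symbols))]
        idx = mol.AddAtom(Chem.Atom(sym))
        mol.AddBond(host, idx, Chem.BondType.SINGLE)
        free[host] -= 1
        free.append(VALENCES[sym] - 1)
    if spec.topology == "tree_ring" and rng.random() < spec.ring_probability:
        open_atoms = [i for i, f in enumerate(free) if f > 0]
        rng.shuffle(open_atoms)
        done = False
        for a in open_atoms:
            if done:
                break
            for b in open_atoms:
                if b <= a or mol.GetBondBetweenAtoms(a, b) is not None:
                    continue
                path = Chem.GetShortestPath(mol, a, b)
                if len(path) >= 3:  # ring size >= 3
                    mol.AddBond(a, b, Chem.BondType.SINGLE)
                    done = True
                    break
    Chem.SanitizeMol(mol)
    return mol.GetMol()


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate molecules with targets = sum of atomic contributions + noise.

    Deterministic given ``spec.seed``; every emitted SMILES parses with
    :func:`mogat.mol_graph.build_graph`.
    """
    rng = np.random.default_rng(spec.seed)
    table = spec.table
    molecules: list[SyntheticMolecule] = []
    for _ in range(spec.n_molecules):
        mol = _random_molecule(rng, spec)
        smiles = Chem.MolToSmiles(mol)
        canonical = Chem.MolFromSmiles(smiles)
        contribs = [table.values[a.GetSymbol()] for a in canonical.GetAtoms()]
        clean = float(np.sum(contribs))
        noise = float(rng.normal(0.0, table.noise_sd)) if table.noise_sd > 0 else 0.0
        molecules.append(SyntheticMolecule(
            smiles=smiles,
            target=clean + noise,
            noise_free_target=clean,
            atom_contributions=contribs,
        ))
    return SyntheticDataset(molecules=molecules, spec=spec)


def fixture_graphs() -> dict[str, MolecularGraph]:
    """Small hand-picked fixtures used across the test-suite.

    - ``"CNN"``: methyl hydrazine, the canonical 3-atom interpretation
      example (experimental logS 1.34);
    - ``"C"``: a single-atom molecule exercising the self-loop fallback;
    - ``"path3"``: a 3-atom heteroatom path (C-O-C, dimethyl ether);
    - ``"pair"``: a symmetric 2-atom molecule (ethane) whose two atoms
      have identical environments;
    - ``"synthetic_path3"``: a hand-assembled (not parsed) 3-atom path
      whose feature vectors are written directly, for model-math tests
      that need full control of the inputs.
    """
    mol = Chem.MolFromSmiles("CCO")
    atoms = [featurize_atom(a) for a in mol.GetAtoms()]
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), featurize_bond(b))
        for b in mol.GetBonds()
    ]
    synthetic_path3 = MolecularGraph(
        atoms=atoms, bonds=bonds, smiles="CCO", target=None)
    return {
        "CNN": build_graph("CNN", target=1.34),
        "C": build_graph("C"),
        "path3": build_graph("COC"),
        "pair": build_graph("CC"),
        "synthetic_path3": synthetic_path3,
    }
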