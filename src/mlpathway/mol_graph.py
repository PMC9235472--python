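"""SMILES to molecular graphs with 78-dimensional binary atom features.

A compound is represented as its heavy-atom graph: nodes are non-hydrogen
atoms, edges are chemical bonds (bond order is not encoded), and each atom
carries a 78-d binary feature vector made of four one-hot blocks plus an
aromaticity flag:

* atom symbol over a fixed 44-symbol vocabulary (43 elements + "other"),
* number of adjacent heavy atoms, buckets 0..10,
* number of attached hydrogens, buckets 0..10,
* implicit valence, buckets 0..10,
* 1 bit for membership in an aromatic system.

The symbol vocabulary follows the widely used DeepChem graph-convolution
featurizer convention and is frozen here because any change would shift
feature indices of trained models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.error")

# Frozen 44-symbol vocabulary (43 symbols + trailing "other" slot).
ATOM_SYMBOLS: tuple[str, ...] = (
    "C", "N", "O", "S", "F", "Si", "P", "Cl", "Br", "Mg", "Na", "Ca", "Fe",
    "As", "Al", "I", "B", "V", "K", "Tl", "Yb", "Sb", "Sn", "Ag", "Pd", "Co",
    "Se", "Ti", "Zn", "H", "Li", "Ge", "Cu", "Au", "Ni", "Cd", "In", "Mn",
    "Zr", "Cr", "Pt", "Hg", "Pb", "other",
)

N_SYMBOLS = len(ATOM_SYMBOLS)  # 44
N_BUCKETS = 11                 # degree / H-count / valence buckets 0..10
FEATURE_DIM = N_SYMBOLS + 3 * N_BUCKETS + 1  # 78

_SYMBOL_INDEX = {s: i for i, s in enumerate(ATOM_SYMBOLS)}


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be converted to a molecular graph."""


@dataclass
class MoleculeGraph:
    """Heavy-atom graph of one compound.

    Attributes
    ----------
    n_atoms : number of heavy atoms N.
    atom_features : (N, 78) binary matrix.
    adjacency : (N, N) symmetric 0/1 matrix with zero diagonal.
    bond_list : undirected bonds as (i, j) with i < j.
    smiles : the input SMILES (kept for provenance and drawing).
    """

    n_atoms: int
    atom_features: np.ndarray
    adjacency: np.ndarray
    bond_list: list[tuple[int, int]]
    smiles: str = ""
    atom_symbols: list[str] = field(default_factory=list)

    def normalized_adjacency(self) -> np.ndarray:
        """Symmetric GCN propagation operator D^{-1/2} (A + I) D^{-1/2}."""
        a_tilde = self.adjacency + np.eye(self.n_atoms)
        d_inv_sqrt = 1.0 / np.sqrt(a_tilde.sum(axis=1))
        return a_tilde * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]

    def neighborhood_mask(self) -> np.ndarray:
        """Boolean (N, N) mask of attention neighborhoods (bonded atoms plus
        the atom itself)."""
        return (self.adjacency + np.eye(self.n_atoms)) > 0


def _one_hot(index: int, size: int) -> np.ndarray:
    v = np.zeros(size)
    v[index] = 1.0
    return v


def featurize_atom(symbol: str, degree: int, num_h: int,
                   implicit_valence: int, aromatic: bool) -> np.ndarray:
    """78-d binary feature vector for a single atom.

    Unknown symbols map to the "other" slot; counts above 10 clamp to the
    last bucket. The result always has exactly four ones in the one-hot
    blocks, plus the aromatic bit.
    """
    sym_idx = _SYMBOL_INDEX.get(symbol, N_SYMBOLS - 1)
    parts = [
        _one_hot(sym_idx, N_SYMBOLS),
        _one_hot(min(max(degree, 0), N_BUCKETS - 1), N_BUCKETS),
        _one_hot(min(max(num_h, 0), N_BUCKETS - 1), N_BUCKETS),
        _one_hot(min(max(implicit_valence, 0), N_BUCKETS - 1), N_BUCKETS),
        np.array([1.0 if aromatic else 0.0]),
    ]
    return np.concatenate(parts)


def smiles_to_graph(smiles: str) -> MoleculeGraph:
    """Parse a SMILES string into a :class:`MoleculeGraph`.

    Hydrogens stay implicit; atom order is RDKit's canonical order for the
    canonicalised molecule, so two SMILES spellings of the same structure
    yield the same graph.

    Raises
    ------
    SmilesParseError
        if RDKit cannot parse or sanitise the SMILES.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"cannot parse SMILES: {smiles!r}")
    if mol.GetNumAtoms() == 0:
        raise SmilesParseError(f"SMILES has no heavy atoms: {smiles!r}")
    # renumber atoms canonically so the graph is spelling-independent
    order = Chem.CanonicalRankAtoms(mol, breakTies=True)
    mol = Chem.RenumberAtoms(mol, [int(i) for i in np.argsort(order)])

    n = mol.GetNumAtoms()
    feats = np.zeros((n, FEATURE_DIM))
    symbols: list[str] = []
    for atom in mol.GetAtoms():
        feats[atom.GetIdx()] = featurize_atom(
            atom.GetSymbol(),
            atom.GetDegree(),
            atom.GetTotalNumHs(),
            atom.GetImplicitValence(),
            atom.GetIsAromatic(),
        )
        symbols.append(atom.GetSymbol())

    adj = np.zeros((n, n))
    bonds: list[tuple[int, int]] = []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        adj[i, j] = adj[j, i] = 1.0
        bonds.append((min(i, j), max(i, j)))
    bonds.sort()

    return MoleculeGraph(
        n_atoms=n,
        atom_features=feats,
        adjacency=adj,
        bond_list=bonds,
        smiles=smiles,
        atom_symbols=symbols,
    )


def mol_from_sdf(path: str) -> list[MoleculeGraph]:
    """Read structures from an SDF file (connectivity only; labels still come
    from the CSV table)."""
    graphs = []
    for mol in Chem.SDMolSupplier(str(path)):
        if mol is None:
            continue
        graphs.append(smiles_to_graph(Chem.MolToSmiles(mol)))
    return graphs
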