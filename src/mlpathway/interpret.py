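"""Attention-based interpretation: per-bond importance weights.

The GAT layer's attention coefficients are direction- and head-specific;
the importance of an undirected chemical bond (i, j) is their mean over all
heads and both directions.  High-weight bonds indicate substructures the
model relies on when assigning pathways (e.g. sulfur- or phosphorus-bearing
groups for energy-like labels).  Raw weights are always exported; an
optional per-compound min-max rescaling to [0, 1] is available for display.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .compound_encoder import AttentionMap
from .mol_graph import MoleculeGraph

__all__ = ["BondImportance", "bond_importance", "export_importance",
           "read_importance", "draw_molecule_svg"]


@dataclass
class BondImportance:
    """Per-bond attention weights of one compound."""

    compound_id: str
    bonds: list[tuple[int, int, float]]  # (atom_i, atom_j, weight)
    normalization: str = "raw"  # "raw" or "minmax"

    def weights(self) -> np.ndarray:
        return np.array([w for _, _, w in self.bonds])


def bond_importance(attn: AttentionMap, graph: MoleculeGraph,
                    compound_id: str = "", rescale: bool = False) -> BondImportance:
    """Head- and direction-averaged attention weight per undirected bond.

    ``rescale`` applies per-compound min-max normalisation to [0, 1]
    (display aid; raw weights are the primary output).
    """
    n = graph.n_atoms
    for a in attn.head_alphas:
        if a.shape != (n, n):
            raise ValueError(
                f"attention map shape {a.shape} does not match graph with "
                f"{n} atoms")
    weights = np.array([attn.bond_weight(i, j) for i, j in graph.bond_list])
    mode = "raw"
    if rescale and weights.size:
        lo, hi = weights.min(), weights.max()
        if hi > lo:
            weights = (weights - lo) / (hi - lo)
        else:
            weights = np.ones_like(weights)
        mode = "minmax"
    bonds = [(i, j, float(w)) for (i, j), w in zip(graph.bond_list, weights)]
    return BondImportance(compound_id=compound_id or graph.smiles,
                          bonds=bonds, normalization=mode)


def export_importance(imps: BondImportance | list[BondImportance],
                      path: str | Path) -> None:
    """Write bond weights as CSV (compound_id, atom_i, atom_j, weight)."""
    if isinstance(imps, BondImportance):
        imps = [imps]
    rows = [(imp.compound_id, i, j, w)
            for imp in imps for i, j, w in imp.bonds]
    df = pd.DataFrame(rows, columns=["compound_id", "atom_i", "atom_j", "weight"])
    df.to_csv(path, index=False)


def read_importance(path: str | Path) -> list[BondImportance]:
    df = pd.read_csv(path)
    out = []
    for cid, grp in df.groupby("compound_id", sort=False):
        bonds = [(int(r.atom_i), int(r.atom_j), float(r.weight))
                 for r in grp.itertuples()]
        out.append(BondImportance(compound_id=str(cid), bonds=bonds))
    return out


def draw_molecule_svg(graph: MoleculeGraph, imp: BondImportance,
                      path: str | Path, size: int = 400) -> None:
    """2-D depiction with bonds coloured by attention weight (white -> red),
    written as SVG. Purely optional; all analyses use the CSV export."""
    from rdkit import Chem
    from rdkit.Chem.Draw import rdMolDraw2D

    mol = Chem.MolFromSmiles(graph.smiles)
    order = np.argsort(Chem.CanonicalRankAtoms(mol, breakTies=True))
    mol = Chem.RenumberAtoms(mol, [int(i) for i in order])
    w = imp.weights()
    lo, hi = (w.min(), w.max()) if w.size else (0.0, 1.0)
    span = hi - lo if hi > lo else 1.0
    highlight_bonds = []
    bond_colors = {}
    for (i, j, weight) in imp.bonds:
        bond = mol.GetBondBetweenAtoms(i, j)
        if bond is None:
            continue
        t = (weight - lo) / span
        highlight_bonds.append(bond.GetIdx())
        bond_colors[bond.GetIdx()] = (1.0, 1.0 - t, 1.0 - t)
    drawer = rdMolDraw2D.MolDraw2DSVG(size, size)
    rdMolDraw2D.PrepareAndDrawMolecule(
        drawer, mol, highlightBonds=highlight_bonds,
        highlightBondColors=bond_colors)
    drawer.FinishDrawing()
    Path(path).write_text(drawer.GetDrawingText())
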