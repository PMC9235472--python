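"""Compound-pathway tables: reading, writing, filtering, fold splitting and
synthetic fixture generation.

The unit of data is a :class:`LabeledCompoundTable`: compounds identified by
id, described by a SMILES string, and annotated with a binary membership
vector over C pathway classes.  Every compound carries at least one positive
label (the data model covers pathway-annotated compounds only).

The fixture generator produces small but structurally honest datasets: SMILES
assembled from a curated vocabulary of valid fragments, and label vectors
drawn from a Gaussian copula matched to a requested matrix of pairwise joint
probabilities, so planted label co-occurrence and substructure-label
associations are available for end-to-end and interpretability tests.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from scipy import stats
from scipy.optimize import brentq

from .mol_graph import SmilesParseError, smiles_to_graph

__all__ = [
    "LabeledCompoundTable",
    "CvSplit",
    "LabelStatistics",
    "DatasetFormatError",
    "DatasetValidationError",
    "read_dataset",
    "write_dataset",
    "filter_valid_structures",
    "label_statistics",
    "make_cv_split",
    "generate_fixture",
    "default_cooccurrence_spec",
    "default_fragment_associations",
    "write_demo_wordvec_file",
    "FRAGMENT_CLASSES",
    "DEFAULT_PATHWAY_NAMES",
]


class DatasetFormatError(ValueError):
    """A required column is missing or the file cannot be read as a table."""


class DatasetValidationError(ValueError):
    """Cell-level content violates the data model (e.g. non-binary label)."""


@dataclass
class LabeledCompoundTable:
    """Compounds with SMILES strings and binary pathway-membership vectors."""

    ids: list[str]
    smiles: list[str]
    Y: np.ndarray  # (n, C) int 0/1
    pathway_names: list[str]

    def __post_init__(self):
        self.Y = np.asarray(self.Y, dtype=np.int8)
        n, C = self.Y.shape
        if C < 2:
            raise DatasetValidationError("need at least 2 pathway labels")
        if len(self.ids) != n or len(self.smiles) != n:
            raise DatasetValidationError("ids / smiles / labels length mismatch")
        if len(set(self.ids)) != n:
            raise DatasetValidationError("compound ids are not unique")
        if len(self.pathway_names) != C:
            raise DatasetValidationError("pathway_names length != label width")
        empty = np.flatnonzero(self.Y.sum(axis=1) == 0)
        if empty.size:
            raise DatasetValidationError(
                f"records without any positive label at rows {empty[:5].tolist()}")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_labels(self) -> int:
        return self.Y.shape[1]

    def labelsets(self) -> list[set[int]]:
        return [set(np.flatnonzero(row)) for row in self.Y]

    def subset(self, indices: Sequence[int]) -> "LabeledCompoundTable":
        idx = np.asarray(indices)
        return LabeledCompoundTable(
            ids=[self.ids[i] for i in idx],
            smiles=[self.smiles[i] for i in idx],
            Y=self.Y[idx],
            pathway_names=list(self.pathway_names),
        )


@dataclass
class CvSplit:
    """Fold assignment of each record to one of k folds."""

    fold_assignments: np.ndarray
    k: int
    seed: int

    def iter_folds(self) -> Iterator[tuple[np.ndarray, np.ndarray]]:
        """Yield (train_indices, test_indices) per fold."""
        for fold in range(self.k):
            test = np.flatnonzero(self.fold_assignments == fold)
            train = np.flatnonzero(self.fold_assignments != fold)
            yield train, test


@dataclass
class LabelStatistics:
    per_label: np.ndarray
    n_single: int
    n_multi: int
    n_all: int
    total_entries: int


def read_dataset(path: str | Path,
                 label_columns: Sequence[str] | None = None) -> LabeledCompoundTable:
    """Read a compound-pathway CSV (columns: id, smiles, then label columns).

    ``label_columns`` defaults to every column after id and smiles; their
    header strings are taken as the pathway names.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype={"id": str})
    for col in ("id", "smiles"):
        if col not in df.columns:
            raise DatasetFormatError(f"{path}: missing required column {col!r}")
    if label_columns is None:
        label_columns = [c for c in df.columns if c not in ("id", "smiles")]
    else:
        for col in label_columns:
            if col not in df.columns:
                raise DatasetFormatError(f"{path}: missing label column {col!r}")
    if len(label_columns) < 2:
        raise DatasetFormatError(f"{path}: need at least 2 label columns")
    raw = df[list(label_columns)].to_numpy()
    Y = np.zeros(raw.shape, dtype=np.int8)
    for r in range(raw.shape[0]):
        for c in range(raw.shape[1]):
            v = raw[r, c]
            try:
                fv = float(v)
            except (TypeError, ValueError):
                raise DatasetValidationError(
                    f"{path}: non-numeric label {v!r} at row {r}, "
                    f"column {label_columns[c]!r}") from None
            if fv not in (0.0, 1.0):
                raise DatasetValidationError(
                    f"{path}: non-binary label value {v!r} at row {r}, "
                    f"column {label_columns[c]!r}")
            Y[r, c] = int(fv)
    return LabeledCompoundTable(
        ids=df["id"].astype(str).tolist(),
        smiles=df["smiles"].astype(str).tolist(),
        Y=Y,
        pathway_names=list(label_columns),
    )


def write_dataset(table: LabeledCompoundTable, path: str | Path) -> None:
    """Write the table back to CSV in the same dialect read_dataset expects."""
    df = pd.DataFrame({"id": table.ids, "smiles": table.smiles})
    for c, name in enumerate(table.pathway_names):
        df[name] = table.Y[:, c]
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df.to_csv(path, sep=sep, index=False)


def filter_valid_structures(
        table: LabeledCompoundTable) -> tuple[LabeledCompoundTable, list[str]]:
    """Drop records whose SMILES cannot be converted to a molecular graph.

    Returns the filtered table and the removed compound ids (for logging).
    Unparsable records are removed, never fatal.
    """
    keep: list[int] = []
    removed: list[str] = []
    for i, smi in enumerate(table.smiles):
        try:
            smiles_to_graph(smi)
        except SmilesParseError:
            removed.append(table.ids[i])
        else:
            keep.append(i)
    return table.subset(keep), removed


def label_statistics(table: LabeledCompoundTable) -> LabelStatistics:
    """Per-label counts and single/multi/all-label compound counts."""
    row_sums = table.Y.sum(axis=1)
    C = table.n_labels
    return LabelStatistics(
        per_label=table.Y.sum(axis=0).astype(int),
        n_single=int((row_sums == 1).sum()),
        n_multi=int((row_sums > 1).sum()),
        n_all=int((row_sums == C).sum()),
        total_entries=int(row_sums.sum()),
    )


def make_cv_split(table: LabeledCompoundTable, k: int, seed: int) -> CvSplit:
    """Uniform random compound-level k-fold split; fold sizes differ by <= 1."""
    n = len(table)
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} available records")
    rng = np.random.default_rng(seed)
    assignments = np.empty(n, dtype=int)
    assignments[rng.permutation(n)] = np.arange(n) % k
    return CvSplit(fold_assignments=assignments, k=k, seed=seed)


# ---------------------------------------------------------------------------
# synthetic fixtures

# Curated vocabulary of known-valid SMILES fragments, grouped by chemistry so
# substructure-label associations can be planted.
FRAGMENT_CLASSES: dict[str, tuple[str, ...]] = {
    "alkane": ("C", "CC", "CCC", "CC(C)C", "CCCC", "CC(C)CC"),
    "long_alkane": ("CCCCCCCC", "CCCCCCCCCC", "CCCCCC(C)CC", "CCCCCCCCCCCC"),
    "alcohol": ("CO", "CCO", "OCCO", "OCC(O)CO", "OCC(O)C(O)CO", "CC(O)CO"),
    "amine": ("CN", "CCN", "NCCN", "CC(C)N", "NCCCN"),
    "acid": ("CC(=O)O", "OC(=O)CC(=O)O", "CCC(=O)O", "OC(=O)CCC(=O)O"),
    "amino_acid": ("NCC(=O)O", "CC(N)C(=O)O", "NCCC(=O)O"),
    "aromatic": ("c1ccccc1", "Cc1ccccc1", "Oc1ccccc1", "Clc1ccccc1",
                 "c1ccc2ccccc2c1"),
    "heteroaromatic": ("c1ccncc1", "c1cncnc1", "c1ccoc1", "c1ccsc1"),
    "phosphate": ("OP(=O)(O)O", "COP(=O)(O)O", "OCCOP(=O)(O)O",
                  "OP(=O)(O)OP(=O)(O)O"),
    "thiol": ("CS", "CCS", "SCCS", "CC(C)S", "SCC(N)C(=O)O"),
}

# KEGG-style top-level metabolism category names used for fixture labels.
DEFAULT_PATHWAY_NAMES: tuple[str, ...] = (
    "Carbohydrate metabolism",
    "Glycan biosynthesis and metabolism",
    "Energy metabolism",
    "Amino acid metabolism",
    "Xenobiotics biodegradation and metabolism",
    "Lipid metabolism",
    "Nucleotide metabolism",
    "Metabolism of other amino acids",
    "Metabolism of cofactors and vitamins",
    "Metabolism of terpenoids and polyketides",
    "Biosynthesis of other secondary metabolites",
)


def default_fragment_associations(n_pathways: int) -> dict[int, tuple[str, ...]]:
    """Default substructure planting for the fixture labels.

    Label 1 (glycan-like) deliberately has no fragment of its own: its only
    signal is its strong co-occurrence with label 0, which is what the
    pathway-dependence encoder is meant to exploit.
    """
    assoc = {
        0: ("alcohol",),
        2: ("thiol", "phosphate"),
        3: ("amine", "amino_acid", "acid"),
        4: ("aromatic", "heteroaromatic"),
        5: ("long_alkane",),
    }
    return {k: v for k, v in assoc.items() if k < n_pathways}


def default_cooccurrence_spec(n_pathways: int,
                              dependent_pair: tuple[int, int] = (0, 1),
                              conditional: float = 0.95) -> np.ndarray:
    """Pairwise joint-probability matrix (marginals on the diagonal) with one
    strongly dependent label pair and the rest independent."""
    base = [0.35, 0.35, 0.25, 0.30, 0.25, 0.25]
    p = np.array([base[i] if i < len(base) else 0.2 for i in range(n_pathways)])
    spec = np.outer(p, p)
    np.fill_diagonal(spec, p)
    i, j = dependent_pair
    if i < n_pathways and j < n_pathways:
        spec[i, j] = spec[j, i] = conditional * min(p[i], p[j])
    return spec


def _validate_spec(spec: np.ndarray) -> np.ndarray:
    spec = np.asarray(spec, dtype=float)
    C = spec.shape[0]
    if spec.shape != (C, C):
        raise ValueError("cooccurrence_spec must be square")
    p = np.diag(spec)
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("marginals (diagonal) must lie strictly in (0, 1)")
    if not np.allclose(spec, spec.T):
        raise ValueError("cooccurrence_spec must be symmetric")
    for i in range(C):
        for j in range(i + 1, C):
            joint = spec[i, j]
            if joint > min(p[i], p[j]) + 1e-9:
                raise ValueError(
                    f"infeasible spec: joint({i},{j})={joint} exceeds "
                    f"min marginal {min(p[i], p[j])}")
            if joint < max(0.0, p[i] + p[j] - 1.0) - 1e-9:
                raise ValueError(
                    f"infeasible spec: joint({i},{j})={joint} below the "
                    f"Frechet lower bound")
    return spec


def _solve_copula_rho(pi: float, pj: float, joint: float) -> float:
    """Latent bivariate-normal correlation reproducing the target joint."""
    ti, tj = stats.norm.ppf(pi), stats.norm.ppf(pj)
    upper = min(pi, pj)
    lower = max(0.0, pi + pj - 1.0)
    if joint >= upper - 1e-9:
        return 1.0
    if joint <= lower + 1e-9:
        return -1.0

    def f(rho: float) -> float:
        cov = [[1.0, rho], [rho, 1.0]]
        return stats.multivariate_normal.cdf([ti, tj], mean=[0, 0], cov=cov) - joint

    return brentq(f, -0.999, 0.999, xtol=1e-6)


def _copula_correlation(spec: np.ndarray) -> np.ndarray:
    C = spec.shape[0]
    p = np.diag(spec)
    R = np.eye(C)
    for i in range(C):
        for j in range(i + 1, C):
            R[i, j] = R[j, i] = _solve_copula_rho(p[i], p[j], spec[i, j])
    # pairwise-consistent correlations may not be jointly PSD: clip and rescale
    w, V = np.linalg.eigh(R)
    if w.min() < 1e-8:
        R = (V * np.clip(w, 1e-8, None)) @ V.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
    return R


def _sample_labels(spec: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    p = np.diag(spec)
    C = spec.shape[0]
    thresholds = stats.norm.ppf(p)
    L = np.linalg.cholesky(_copula_correlation(spec) + 1e-10 * np.eye(C))
    Y = np.zeros((n, C), dtype=np.int8)
    todo = np.arange(n)
    for _ in range(1000):
        if todo.size == 0:
            break
        Z = rng.standard_normal((todo.size, C)) @ L.T
        Y[todo] = (Z < thresholds).astype(np.int8)
        todo = todo[Y[todo].sum(axis=1) == 0]  # resample empty label vectors
    if todo.size:  # pathological specs: force the most prevalent label
        Y[todo, int(np.argmax(p))] = 1
    # exact containment for pairs specified at the Frechet upper bound
    for i in range(C):
        for j in range(C):
            if i != j and spec[i, j] >= min(p[i], p[j]) - 1e-9 and p[i] <= p[j]:
                Y[Y[:, i] == 1, j] = 1
    return Y


def _join_smiles(a: str, b: str, rng: np.random.Generator) -> str:
    """Connect two fragments with a single bond at H-bearing atoms; fall back
    to a disconnected pair if sanitisation rejects the bond."""
    ma, mb = Chem.MolFromSmiles(a), Chem.MolFromSmiles(b)
    cand_a = [at.GetIdx() for at in ma.GetAtoms() if at.GetTotalNumHs() > 0]
    cand_b = [at.GetIdx() for at in mb.GetAtoms() if at.GetTotalNumHs() > 0]
    if not cand_a or not cand_b:
        return a + "." + b
    ia = cand_a[rng.integers(len(cand_a))]
    ib = int(ma.GetNumAtoms()) + cand_b[rng.integers(len(cand_b))]
    combo = Chem.RWMol(Chem.CombineMols(ma, mb))
    combo.AddBond(int(ia), int(ib), Chem.BondType.SINGLE)
    try:
        mol = combo.GetMol()
        Chem.SanitizeMol(mol)
        return Chem.MolToSmiles(mol)
    except Exception:
        return a + "." + b


def generate_fixture(
    n_compounds: int,
    n_pathways: int = 6,
    cooccurrence_spec: np.ndarray | None = None,
    seed: int = 0,
    pathway_names: Sequence[str] | None = None,
    fragment_associations: Mapping[int, Sequence[str]] | None = None,
    distractor_rate: float = 0.4,
) -> LabeledCompoundTable:
    """Generate a synthetic compound-pathway table.

    Label vectors are sampled from a Gaussian copula whose pairwise joints
    match ``cooccurrence_spec`` (marginals on the diagonal); each record gets
    at least one positive label.  SMILES are assembled from the curated
    fragment vocabulary: a small random backbone, plus one fragment per
    positive label listed in ``fragment_associations`` — so substructure
    content genuinely predicts those labels.  With probability
    ``distractor_rate`` a compound additionally carries one fragment drawn
    from a random class regardless of its labels: real molecules contain
    substructures unrelated to their pathways, and without such confusable
    content the prediction task is unrealistically separable.
    """
    if n_pathways < 2:
        raise ValueError("n_pathways must be >= 2")
    if cooccurrence_spec is None:
        cooccurrence_spec = default_cooccurrence_spec(n_pathways)
    spec = _validate_spec(cooccurrence_spec)
    if spec.shape[0] != n_pathways:
        raise ValueError("cooccurrence_spec size must equal n_pathways")
    if pathway_names is None:
        pathway_names = [DEFAULT_PATHWAY_NAMES[i] if i < len(DEFAULT_PATHWAY_NAMES)
                         else f"Pathway class {i}" for i in range(n_pathways)]
    if fragment_associations is None:
        fragment_associations = default_fragment_associations(n_pathways)

    rng = np.random.default_rng(seed)
    Y = _sample_labels(spec, n_compounds, rng)

    smiles: list[str] = []
    for row in Y:
        smi = FRAGMENT_CLASSES["alkane"][rng.integers(len(FRAGMENT_CLASSES["alkane"]))]
        for label in np.flatnonzero(row):
            classes = fragment_associations.get(int(label))
            if not classes:
                continue
            cls = classes[rng.integers(len(classes))]
            frag = FRAGMENT_CLASSES[cls][rng.integers(len(FRAGMENT_CLASSES[cls]))]
            smi = _join_smiles(smi, frag, rng)
        if rng.random() < distractor_rate:
            all_classes = list(FRAGMENT_CLASSES)
            cls = all_classes[rng.integers(len(all_classes))]
            frag = FRAGMENT_CLASSES[cls][rng.integers(len(FRAGMENT_CLASSES[cls]))]
            smi = _join_smiles(smi, frag, rng)
        smiles.append(smi)

    width = len(str(n_compounds))
    ids = [f"CPD{i:0{width}d}" for i in range(n_compounds)]
    return LabeledCompoundTable(ids=ids, smiles=smiles, Y=Y,
                                pathway_names=list(pathway_names))


# Semantic clusters for the synthetic word-vector file: tokens in one cluster
# get nearby vectors, emulating the key property of pre-trained embeddings
# (semantically related pathway names end up with similar features).
_TOKEN_CLUSTERS: dict[str, tuple[str, ...]] = {
    "sugar": ("carbohydrate", "glycan", "sugar", "saccharide"),
    "protein": ("amino", "acid", "acids", "peptide", "protein"),
    "energetic": ("energy", "phosphorylation", "respiration"),
    "fat": ("lipid", "fatty", "sterol"),
    "foreign": ("xenobiotics", "biodegradation", "degradation"),
    "nucleic": ("nucleotide", "purine", "pyrimidine"),
    "vitamin": ("cofactors", "vitamins", "coenzyme"),
    "natural_product": ("terpenoids", "polyketides", "secondary",
                        "metabolites", "biosynthesis"),
    "generic": ("metabolism", "of", "and", "other", "pathway", "class"),
}


def write_demo_wordvec_file(path: str | Path, r: int = 50,
                            extra_tokens: Sequence[str] = ()) -> Path:
    """Write a tiny deterministic *synthetic* GloVe text-format file covering
    the tokens of the default pathway names (plus any extras).

    The vectors are not trained: each token's vector is a cluster centre
    (tokens grouped by domain, see ``_TOKEN_CLUSTERS``) plus token-specific
    noise, both seeded by stable hashes — so related tokens get similar
    vectors, emulating the semantic-neighbourhood property of real
    pre-trained embeddings, and the file content is identical across runs
    and platforms.
    """
    from .pathway_graph import tokenize_name

    tokens: list[str] = []
    for name in DEFAULT_PATHWAY_NAMES:
        for tok in tokenize_name(name):
            if tok not in tokens:
                tokens.append(tok)
    for tok in extra_tokens:
        if tok not in tokens:
            tokens.append(tok)
    cluster_of = {tok: cl for cl, toks in _TOKEN_CLUSTERS.items() for tok in toks}

    def _hash_rng(key: str) -> np.random.Generator:
        h = int.from_bytes(hashlib.md5(key.encode()).digest()[:4], "little")
        return np.random.default_rng(h)

    path = Path(path)
    with open(path, "w") as fh:
        for tok in tokens:
            cluster = cluster_of.get(tok)
            if cluster is None:
                vec = _hash_rng("token:" + tok).standard_normal(r)
            else:
                centre = _hash_rng("cluster:" + cluster).standard_normal(r)
                vec = centre + 0.3 * _hash_rng("token:" + tok).standard_normal(r)
            fh.write(tok + " " + " ".join(f"{x:.6f}" for x in vec) + "\n")
    return path
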