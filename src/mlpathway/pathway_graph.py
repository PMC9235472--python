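"""Pathway-label dependence graph: co-occurrence statistics, conditional
probabilities, thresholding, re-weighting and word-vector node features.

Pathway crosstalk is modelled as a *directed* graph over the C pathway
labels.  From the training labels we count pairwise co-occurrences U and
per-label totals N, form the asymmetric conditional-probability matrix
P[i, j] = P(label j | label i) = U[i, j] / N[i], drop weak edges with a hard
threshold tau, and re-weight the surviving binary edges so each column sums
to one.  Node features are pre-trained word vectors of the pathway names
(GloVe text format), averaged over the name's tokens.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "CooccurrenceStats",
    "DependenceGraph",
    "count_cooccurrence",
    "conditional_probability",
    "binarize",
    "reweight",
    "load_word_vectors",
    "init_pathway_features",
    "build_dependence_graph",
]


@dataclass
class CooccurrenceStats:
    """Pairwise co-occurrence counts U (zero diagonal) and per-label totals N."""

    U: np.ndarray
    N: np.ndarray


@dataclass
class DependenceGraph:
    """The full dependence-graph chain plus node features.

    P is the asymmetric conditional-probability matrix, M its binarisation at
    threshold tau, M_w the column-normalised re-weighting of M, and Q the
    (C, r) node-feature matrix.
    """

    P: np.ndarray
    M: np.ndarray
    M_w: np.ndarray
    tau: float
    node_features: np.ndarray


def count_cooccurrence(labelsets: Iterable[Iterable[int]], C: int) -> CooccurrenceStats:
    """Count pairwise label co-occurrences over a collection of label sets.

    U[i, j] is the number of compounds annotated with both label i and label
    j (i != j; the diagonal stays zero — self-dependence is carried by the
    identity term added during propagation).  N[i] is the number of
    compounds annotated with label i.
    """
    U = np.zeros((C, C))
    N = np.zeros(C)
    for labels in labelsets:
        ls = sorted(set(labels))
        if ls and (ls[0] < 0 or ls[-1] >= C):
            raise ValueError(f"label out of range [0, {C}): {ls}")
        for i in ls:
            N[i] += 1
        for a_idx, i in enumerate(ls):
            for j in ls[a_idx + 1:]:
                U[i, j] += 1
                U[j, i] += 1
    return CooccurrenceStats(U=U, N=N)


def conditional_probability(stats: CooccurrenceStats) -> np.ndarray:
    """P[i, j] = U[i, j] / N[i]; rows with N[i] = 0 (a label absent from the
    training fold) are zero."""
    N = stats.N
    P = np.divide(stats.U, N[:, None], out=np.zeros_like(stats.U), where=N[:, None] > 0)
    return P


def binarize(P: np.ndarray, tau: float) -> np.ndarray:
    """Hard-threshold the conditional probabilities: edge iff P[i, j] >= tau.

    Removes the long tail of weak, noisy dependences. Diagonal is forced to
    zero.
    """
    if not 0.0 < tau < 1.0:
        raise ValueError(f"tau must be in (0, 1), got {tau}")
    M = (P >= tau).astype(float)
    np.fill_diagonal(M, 0.0)
    return M


def reweight(M: np.ndarray, normalize: str = "column") -> np.ndarray:
    """Re-weight binary edges by their column sums: M_w[i, j] = M[i, j] / sum_k M[k, j].

    Columns that sum to zero stay zero.  ``normalize="row"`` divides by row
    sums instead (exposed because the printed formula is typographically
    ambiguous; column is the default, as printed).
    """
    if normalize == "column":
        s = M.sum(axis=0, keepdims=True)
    elif normalize == "row":
        s = M.sum(axis=1, keepdims=True)
    else:
        raise ValueError(f"normalize must be 'column' or 'row', got {normalize!r}")
    return np.divide(M, s, out=np.zeros_like(M), where=s > 0)


# ---------------------------------------------------------------------------
# word-vector node features

_TOKEN_RE = re.compile(r"[a-z0-9]+")


def load_word_vectors(path: str | Path) -> dict[str, np.ndarray]:
    """Load a GloVe text-format file: one token followed by its
    whitespace-separated float components per line."""
    vectors: dict[str, np.ndarray] = {}
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split()
            if not parts:
                continue
            token, rest = parts[0], parts[1:]
            try:
                vec = np.array([float(x) for x in rest])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: malformed vector on line {lineno}") from exc
            if width is None:
                width = vec.size
            elif vec.size != width:
                raise ValueError(
                    f"{path}: inconsistent vector width on line {lineno} "
                    f"({vec.size} != {width})")
            vectors[token] = vec
    if not vectors:
        raise ValueError(f"{path}: no vectors found")
    return vectors


def tokenize_name(name: str) -> list[str]:
    """Lowercase, strip punctuation, split on whitespace."""
    return _TOKEN_RE.findall(name.lower())


def init_pathway_features(
    pathway_names: Sequence[str],
    wordvec_file: str | Path | None,
    r: int,
    rng: np.random.Generator | None = None,
    random_init: bool = False,
) -> np.ndarray:
    """Build the (C, r) node-feature matrix Q from pathway names.

    Each name's feature is the unweighted mean of its in-vocabulary token
    vectors; out-of-vocabulary tokens are skipped.  A name with no
    in-vocabulary token — or every name, when ``random_init`` is set (the
    random-initialisation ablation) — gets a standard-normal vector drawn
    from ``rng``.

    Word-vector features are standardised per dimension across labels (zero
    mean, unit variance).  Pathway names share generic tokens ("metabolism"
    appears in nearly every name), so raw token means carry a large common
    component and small between-label differences; standardisation removes
    the shared offset, matches the feature scale of the random-init
    ablation, and keeps only the between-label similarity structure that the
    embeddings are meant to contribute.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    C = len(pathway_names)
    if random_init or wordvec_file is None:
        return rng.standard_normal((C, r))
    vectors = load_word_vectors(wordvec_file)
    width = next(iter(vectors.values())).size
    if width != r:
        raise ValueError(f"word vectors have width {width}, expected r={r}")
    Q = np.zeros((C, r))
    for c, name in enumerate(pathway_names):
        hits = [vectors[t] for t in tokenize_name(name) if t in vectors]
        Q[c] = np.mean(hits, axis=0) if hits else rng.standard_normal(r)
    mu, sd = Q.mean(axis=0), Q.std(axis=0)
    return (Q - mu) / np.where(sd > 1e-12, sd, 1.0)


def build_dependence_graph(
    labelsets: Iterable[Iterable[int]],
    C: int,
    tau: float,
    pathway_names: Sequence[str] | None = None,
    wordvec_file: str | Path | None = None,
    r: int = 300,
    rng: np.random.Generator | None = None,
    random_init: bool = False,
    normalize: str = "column",
) -> DependenceGraph:
    """Full chain: counts -> conditional probabilities -> binarise -> re-weight,
    plus node-feature initialisation."""
    stats = count_cooccurrence(labelsets, C)
    P = conditional_probability(stats)
    M = binarize(P, tau)
    M_w = reweight(M, normalize=normalize)
    if pathway_names is None:
        pathway_names = [f"pathway {i}" for i in range(C)]
    Q = init_pathway_features(pathway_names, wordvec_file, r, rng=rng,
                              random_init=random_init)
    return DependenceGraph(P=P, M=M, M_w=M_w, tau=tau, node_features=Q)
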