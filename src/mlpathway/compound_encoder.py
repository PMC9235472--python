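"""Compound encoder: multi-head graph attention, graph convolution, and a
max-and-mean readout.

The encoder maps a molecular graph to a fixed-length embedding in three
stages.  A single multi-head GAT layer updates each atom by a softmax-
normalised attention-weighted sum over its neighbourhood (bonded atoms plus
the atom itself), with per-head outputs concatenated.  A GCN layer then
propagates through the symmetrically normalised adjacency
D^{-1/2}(A + I)D^{-1/2}.  Finally global max-pooling and global mean-pooling
over atoms run in parallel and are concatenated, so the default
configuration (10 heads x 78 dims -> 780 -> 780) yields a 1560-d compound
embedding.  The attention coefficients are retained: averaged over heads and
directions they score the importance of each chemical bond.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .mol_graph import MoleculeGraph

__all__ = [
    "GatParams",
    "GcnParams",
    "AttentionMap",
    "gat_layer",
    "gcn_layer",
    "readout",
    "encode_compound",
]


@dataclass
class GatParams:
    """K attention heads, each with a linear map W (q -> s) and a scoring
    vector a split into source/destination halves.

    The attention score for the (directed) pair i -> j is
    LeakyReLU(a^T [W h_i || W h_j]) with the configured negative slope.
    """

    heads: list[dict[str, Tensor]]
    leaky_slope: float = 0.2

    @classmethod
    def init(cls, rng: np.random.Generator, in_dim: int, head_dim: int,
             n_heads: int, leaky_slope: float = 0.2) -> "GatParams":
        if n_heads < 1:
            raise ValueError("need at least one attention head")
        heads = []
        for _ in range(n_heads):
            heads.append({
                "W": ad.parameter(ad.glorot_uniform(rng, in_dim, head_dim)),
                "a_src": ad.parameter(ad.glorot_uniform(rng, head_dim, 1)),
                "a_dst": ad.parameter(ad.glorot_uniform(rng, head_dim, 1)),
            })
        return cls(heads=heads, leaky_slope=leaky_slope)

    @property
    def n_heads(self) -> int:
        return len(self.heads)

    def tensors(self) -> list[Tensor]:
        return [t for head in self.heads for t in head.values()]


@dataclass
class GcnParams:
    """Single weight matrix of the compound GCN layer (K*s -> G)."""

    W: Tensor

    @classmethod
    def init(cls, rng: np.random.Generator, in_dim: int, out_dim: int) -> "GcnParams":
        return cls(W=ad.parameter(ad.glorot_uniform(rng, in_dim, out_dim)))

    def tensors(self) -> list[Tensor]:
        return [self.W]


@dataclass
class AttentionMap:
    """Per-head attention coefficients over one molecule.

    ``head_alphas[k]`` is an (N, N) matrix whose row i holds the attention
    that atom i pays to each neighbourhood member (zeros elsewhere); each row
    over the neighbourhood sums to 1.
    """

    head_alphas: list[np.ndarray]
    mask: np.ndarray = field(repr=False, default=None)

    @property
    def n_heads(self) -> int:
        return len(self.head_alphas)

    def bond_weight(self, i: int, j: int) -> float:
        """Mean over heads and both directions of the attention on bond (i, j)."""
        vals = [(a[i, j] + a[j, i]) / 2.0 for a in self.head_alphas]
        return float(np.mean(vals))


def gat_layer(graph: MoleculeGraph, params: GatParams,
              x: Tensor | None = None) -> tuple[Tensor, AttentionMap]:
    """One multi-head attention pass over the molecular graph.

    Returns the (N, K*s) concatenated head outputs (ReLU applied per head
    before concatenation) and the attention map.  ``x`` may supply a cached
    constant feature tensor.
    """
    if x is None:
        x = ad.constant(graph.atom_features)
    mask = graph.neighborhood_mask()
    outs: list[Tensor] = []
    alphas: list[np.ndarray] = []
    for head in params.heads:
        Wh = x @ head["W"]                      # (N, s)
        f_src = Wh @ head["a_src"]              # (N, 1)
        f_dst = Wh @ head["a_dst"]              # (N, 1)
        scores = ad.leaky_relu(f_src + f_dst.T, params.leaky_slope)
        alpha = ad.masked_row_softmax(scores, mask)
        outs.append(ad.relu(alpha @ Wh))
        alphas.append(alpha.data)
    return ad.concat(outs, axis=1), AttentionMap(head_alphas=alphas, mask=mask)


def gcn_layer(features: Tensor, graph: MoleculeGraph, params: GcnParams,
              s_hat: Tensor | None = None) -> Tensor:
    """Graph convolution ReLU(D^{-1/2}(A+I)D^{-1/2} H W) over atom features."""
    if s_hat is None:
        s_hat = ad.constant(graph.normalized_adjacency())
    return ad.relu(s_hat @ features @ params.W)


def readout(atom_features: Tensor) -> Tensor:
    """Concatenate column-wise max and mean over atoms into a (1, 2t) row."""
    return ad.concat([ad.max_rows(atom_features), ad.mean_rows(atom_features)],
                     axis=1)


def encode_compound(graph: MoleculeGraph, gat: GatParams, gcn: GcnParams,
                    x: Tensor | None = None,
                    s_hat: Tensor | None = None) -> tuple[Tensor, AttentionMap]:
    """Full compound encoder: GAT -> GCN -> max-and-mean readout."""
    h_a, attn = gat_layer(graph, gat, x=x)
    h_c = gcn_layer(h_a, graph, gcn, s_hat=s_hat)
    return readout(h_c), attn
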