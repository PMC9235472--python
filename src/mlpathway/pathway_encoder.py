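"""Pathway encoder: two graph convolutions over the label dependence graph.

The propagation operator is the row-normalised D_x^{-1} M_x with
M_x = alpha * M_w + I_C, where M_w is the re-weighted dependence matrix and
the trade-off coefficient alpha in [0, 1] sets how strongly neighbouring
labels are mixed into each label's own representation (alpha = 0 reduces to
independent per-label dense layers).  Row normalisation makes the operator
row-stochastic, and it is deliberately asymmetric — the dependence graph is
directed.  Both layers use a LeakyReLU activation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "PathwayGcnParams",
    "propagation_operator",
    "pathway_gcn_layer",
    "encode_pathways",
]


@dataclass
class PathwayGcnParams:
    """Weights of the two label-graph GCN layers plus the mixing coefficient."""

    W0: Tensor  # (r, d)
    W1: Tensor  # (d, B)
    alpha: float = 0.3
    leaky_slope: float = 0.01

    @classmethod
    def init(cls, rng: np.random.Generator, r: int, hidden: int, out: int,
             alpha: float = 0.3, leaky_slope: float = 0.01) -> "PathwayGcnParams":
        if not 0.0 <= alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {alpha}")
        return cls(
            W0=ad.parameter(ad.glorot_uniform(rng, r, hidden)),
            W1=ad.parameter(ad.glorot_uniform(rng, hidden, out)),
            alpha=alpha,
            leaky_slope=leaky_slope,
        )

    def tensors(self) -> list[Tensor]:
        return [self.W0, self.W1]


def propagation_operator(M_w: np.ndarray, alpha: float) -> np.ndarray:
    """Row-stochastic operator D_x^{-1} (alpha * M_w + I)."""
    C = M_w.shape[0]
    M_x = alpha * M_w + np.eye(C)
    return M_x / M_x.sum(axis=1, keepdims=True)


def pathway_gcn_layer(H: Tensor, M_w: np.ndarray, W: Tensor, alpha: float,
                      leaky_slope: float = 0.01,
                      s_hat: Tensor | None = None) -> Tensor:
    """One label-graph convolution LeakyReLU(D_x^{-1} M_x H W)."""
    if s_hat is None:
        s_hat = ad.constant(propagation_operator(M_w, alpha))
    return ad.leaky_relu(s_hat @ H @ W, leaky_slope)


def encode_pathways(Q: Tensor | np.ndarray, M_w: np.ndarray,
                    params: PathwayGcnParams,
                    s_hat: Tensor | None = None) -> Tensor:
    """Two stacked label-graph convolutions: the (C, B) pathway embedding
    matrix O."""
    if not isinstance(Q, Tensor):
        Q = ad.constant(Q)
    if s_hat is None:
        s_hat = ad.constant(propagation_operator(M_w, params.alpha))
    h1 = pathway_gcn_layer(Q, M_w, params.W0, params.alpha,
                           params.leaky_slope, s_hat=s_hat)
    return pathway_gcn_layer(h1, M_w, params.W1, params.alpha,
                             params.leaky_slope, s_hat=s_hat)
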