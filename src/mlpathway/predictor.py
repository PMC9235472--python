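"""Multi-label predictor: adapter, dot-product scoring, loss and decisions.

Compound embeddings (2t-dimensional) live in a different space than pathway
embeddings (B-dimensional), so a small dense adapter — input, one hidden
layer, output — maps compounds into the pathway space.  The logit for
pathway i is then the plain inner product of its embedding row with the
adapted compound vector; no bias.  Training minimises the mean per-label
binary cross-entropy with logits, and decisions threshold the sigmoid
probabilities (ranking metrics never use the threshold).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "AdapterParams",
    "adapt",
    "score",
    "multilabel_loss",
    "sigmoid",
    "decide",
]


@dataclass
class AdapterParams:
    """Dense input -> hidden -> output map (default 1560 -> 1500 -> 1024),
    ReLU on the hidden layer."""

    W1: Tensor
    b1: Tensor
    W2: Tensor
    b2: Tensor

    @classmethod
    def init(cls, rng: np.random.Generator, in_dim: int, hidden: int,
             out_dim: int) -> "AdapterParams":
        return cls(
            W1=ad.parameter(ad.glorot_uniform(rng, in_dim, hidden)),
            b1=ad.parameter(np.zeros((1, hidden))),
            W2=ad.parameter(ad.glorot_uniform(rng, hidden, out_dim)),
            b2=ad.parameter(np.zeros((1, out_dim))),
        )

    def tensors(self) -> list[Tensor]:
        return [self.W1, self.b1, self.W2, self.b2]


def adapt(z: Tensor, params: AdapterParams) -> Tensor:
    """Map a (1, 2t) compound embedding into the (1, B) pathway space."""
    if z.shape[1] != params.W1.shape[0]:
        raise ValueError(
            f"embedding width {z.shape[1]} != adapter input {params.W1.shape[0]}")
    hidden = ad.relu(z @ params.W1 + params.b1)
    return hidden @ params.W2 + params.b2


def score(O: Tensor | np.ndarray, z_adapted: Tensor | np.ndarray) -> Tensor:
    """Proximity logits: one inner product per pathway row of O (no bias)."""
    if not isinstance(O, Tensor):
        O = ad.constant(O)
    if not isinstance(z_adapted, Tensor):
        z_adapted = ad.constant(np.atleast_2d(z_adapted))
    if O.shape[1] != z_adapted.shape[1]:
        raise ValueError(
            f"pathway width {O.shape[1]} != compound width {z_adapted.shape[1]}")
    return z_adapted @ O.T


def multilabel_loss(logits: Tensor | np.ndarray, y: np.ndarray) -> Tensor:
    """Mean per-label binary cross-entropy with logits.

    loss = (1/C) sum_i [ y_i softplus(-yhat_i) + (1 - y_i) softplus(yhat_i) ],
    numerically stable for large |logits|; the gradient at yhat_i is
    (sigma(yhat_i) - y_i) / C.
    """
    if not isinstance(logits, Tensor):
        logits = ad.constant(logits)
    y = np.asarray(y, dtype=np.float64)
    if logits.data.shape != np.atleast_2d(y).shape and logits.data.shape != y.shape:
        raise ValueError(f"shape mismatch: logits {logits.shape} vs labels {y.shape}")
    return ad.bce_with_logits_mean(logits, y)


def sigmoid(x: np.ndarray) -> np.ndarray:
    return ad._sigmoid(np.asarray(x, dtype=np.float64))


def decide(logits: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binary decisions: sigma(logit) >= threshold (probability scale)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    return (sigmoid(np.asarray(logits)) >= threshold).astype(np.int8)
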