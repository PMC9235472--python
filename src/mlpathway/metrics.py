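"""Multi-label evaluation metrics.

Two families: decision-based (accuracy, precision, recall, F1, Hamming loss
— micro-averaged over every (sample, label) cell) and ranking-based (ranking
loss, coverage, one-error — computed from real-valued scores and invariant
to any strictly monotone rescaling of them).

Conventions, fixed and tested: micro accuracy is (TP+TN)/(n*C), so
accuracy + Hamming loss = 1 identically; zero-division in precision/recall
yields 0; ranking ties break by ascending label index; a tied true/false
score pair counts as reversed in ranking loss; coverage is reported 1-based
by default (the rank of the deepest true label), with a 0-based switch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "hamming_loss",
    "ranking_loss",
    "coverage",
    "one_error",
    "prf_accuracy",
    "compute_all_metrics",
    "MetricsReport",
    "METRIC_NAMES",
]

METRIC_NAMES = ("accuracy", "precision", "recall", "f1",
                "hamming_loss", "ranking_loss", "coverage", "one_error")


def _check(Y: np.ndarray, other: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    Y = np.atleast_2d(np.asarray(Y))
    other = np.atleast_2d(np.asarray(other))
    if Y.shape != other.shape:
        raise ValueError(f"shape mismatch: {Y.shape} vs {other.shape}")
    return Y, other


def hamming_loss(Y: np.ndarray, D: np.ndarray) -> float:
    """Fraction of (sample, label) cells where decision disagrees with truth."""
    Y, D = _check(Y, D)
    return float(np.mean(Y != D))


def ranking_loss(Y: np.ndarray, S: np.ndarray) -> float:
    """Average fraction of (true, false) label pairs with
    score(true) <= score(false); samples without such a pair are skipped."""
    Y, S = _check(Y, S)
    vals = []
    for y, s in zip(Y.astype(bool), S):
        pos, neg = s[y], s[~y]
        if pos.size == 0 or neg.size == 0:
            continue
        reversed_pairs = (pos[:, None] <= neg[None, :]).sum()
        vals.append(reversed_pairs / (pos.size * neg.size))
    return float(np.mean(vals)) if vals else 0.0


def _ranks(s: np.ndarray) -> np.ndarray:
    """1-based rank of each label when sorted by descending score, ties broken
    by ascending label index."""
    order = np.lexsort((np.arange(s.size), -s))
    ranks = np.empty(s.size, dtype=int)
    ranks[order] = np.arange(1, s.size + 1)
    return ranks


def coverage(Y: np.ndarray, S: np.ndarray, zero_based: bool = False) -> float:
    """Average rank of the worst-ranked true label (how far down the ranked
    list one must go to cover all true labels)."""
    Y, S = _check(Y, S)
    depths = []
    for y, s in zip(Y.astype(bool), S):
        if not y.any():
            continue
        depths.append(_ranks(s)[y].max())
    if not depths:
        return 0.0
    out = float(np.mean(depths))
    return out - 1.0 if zero_based else out


def one_error(Y: np.ndarray, S: np.ndarray) -> float:
    """Fraction of samples whose top-ranked label (ties -> lowest index) is
    not a true label."""
    Y, S = _check(Y, S)
    top = np.argmax(S, axis=1)
    return float(np.mean(Y[np.arange(Y.shape[0]), top] == 0))


def prf_accuracy(Y: np.ndarray, D: np.ndarray) -> tuple[float, float, float, float]:
    """Micro label-based accuracy, precision, recall and F1 over all cells.

    Zero-division (no predicted or no true positives) yields 0 with a warning.
    """
    Y, D = _check(Y, D)
    tp = float(np.sum((Y == 1) & (D == 1)))
    fp = float(np.sum((Y == 0) & (D == 1)))
    fn = float(np.sum((Y == 1) & (D == 0)))
    acc = float(np.mean(Y == D))
    if tp + fp == 0 or tp + fn == 0:
        if tp + fp == 0:
            warnings.warn("no positive predictions; precision set to 0",
                          stacklevel=2)
        if tp + fn == 0:
            warnings.warn("no positive truths; recall set to 0", stacklevel=2)
    prec = tp / (tp + fp) if tp + fp > 0 else 0.0
    rec = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0
    return acc, prec, rec, f1


def compute_all_metrics(Y: np.ndarray, S: np.ndarray, D: np.ndarray,
                        zero_based_coverage: bool = False) -> dict[str, float]:
    """All eight metrics from truth Y, scores S and decisions D."""
    acc, prec, rec, f1 = prf_accuracy(Y, D)
    return {
        "accuracy": acc,
        "precision": prec,
        "recall": rec,
        "f1": f1,
        "hamming_loss": hamming_loss(Y, D),
        "ranking_loss": ranking_loss(Y, S),
        "coverage": coverage(Y, S, zero_based=zero_based_coverage),
        "one_error": one_error(Y, S),
    }


@dataclass
class MetricsReport:
    """Per-fold values of the eight metrics with mean and standard deviation."""

    per_fold: dict[str, list[float]] = field(
        default_factory=lambda: {m: [] for m in METRIC_NAMES})

    def add_fold(self, values: dict[str, float]) -> None:
        for m in METRIC_NAMES:
            self.per_fold[m].append(float(values[m]))

    def mean(self, metric: str) -> float:
        return float(np.mean(self.per_fold[metric]))

    def sd(self, metric: str) -> float:
        vals = self.per_fold[metric]
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0

    def summary(self) -> dict[str, tuple[float, float]]:
        return {m: (self.mean(m), self.sd(m)) for m in METRIC_NAMES}

    def format_table(self) -> str:
        """Render all eight metrics as ``name  mean ± sd`` lines, the
        percentage metrics scaled to percent."""
        lines = []
        for m in METRIC_NAMES:
            mean, sd = self.mean(m), self.sd(m)
            if m in ("accuracy", "precision", "recall", "f1"):
                lines.append(f"{m:<14} {100 * mean:6.2f} ± {100 * sd:.2f} %")
            else:
                lines.append(f"{m:<14} {mean:6.3f} ± {sd:.3f}")
        return "\n".join(lines)
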