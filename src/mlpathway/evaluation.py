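"""Cross-validation orchestration, evaluation and the tau/alpha grid utility.

The dependence graph is rebuilt inside each training fold from that fold's
labels only, so no co-occurrence statistics leak from held-out compounds.
"""

from __future__ import annotations

import json
import time
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import clone

from .dataset_io import LabeledCompoundTable, make_cv_split
from .metrics import MetricsReport, compute_all_metrics
from .model import MetabolicPathwayClassifier

__all__ = ["evaluate", "cross_validate", "grid_search", "RunLog"]


class RunLog:
    """Structured JSON-lines run log (seed, config, per-fold metrics)."""

    def __init__(self, path: str | Path | None = None):
        self.path = Path(path) if path is not None else None
        self.records: list[dict] = []

    def write(self, event: str, **payload) -> None:
        record = {"time": time.time(), "event": event, **payload}
        self.records.append(record)
        if self.path is not None:
            with open(self.path, "a") as fh:
                fh.write(json.dumps(record) + "\n")


def evaluate(model: MetabolicPathwayClassifier,
             table: LabeledCompoundTable,
             zero_based_coverage: bool = False) -> dict[str, float]:
    """All eight metrics of a fitted model on a held-out table."""
    if model.n_labels_ != table.n_labels:
        raise ValueError(
            f"model trained with C={model.n_labels_}, table has C={table.n_labels}")
    scores = model.decision_function(table.smiles)
    decisions = (scores >= _logit(model.decision_threshold)).astype(np.int8)
    return compute_all_metrics(table.Y, scores, decisions,
                               zero_based_coverage=zero_based_coverage)


def _logit(p: float) -> float:
    p = min(max(p, 1e-12), 1 - 1e-12)
    return float(np.log(p / (1 - p)))


def cross_validate(table: LabeledCompoundTable,
                   estimator: MetabolicPathwayClassifier | None = None,
                   k: int = 10, seed: int = 0,
                   run_log: RunLog | None = None) -> MetricsReport:
    """k-fold cross-validation: train on k-1 folds, evaluate on the held-out
    fold, aggregate mean and standard deviation per metric."""
    if estimator is None:
        estimator = MetabolicPathwayClassifier(random_state=seed)
    split = make_cv_split(table, k, seed)
    report = MetricsReport()
    if run_log is not None:
        run_log.write("cv_start", k=k, seed=seed,
                      config=_jsonable(estimator.get_params()), n=len(table))
    for fold, (train_idx, test_idx) in enumerate(split.iter_folds()):
        model = clone(estimator)
        model.set_params(pathway_names=table.pathway_names)
        train = table.subset(train_idx)
        test = table.subset(test_idx)
        model.fit(train.smiles, train.Y)
        fold_metrics = evaluate(model, test)
        report.add_fold(fold_metrics)
        if run_log is not None:
            run_log.write("fold_done", fold=fold, metrics=fold_metrics,
                          final_train_loss=model.loss_curve_[-1])
    if run_log is not None:
        run_log.write("cv_done", summary={m: list(v) for m, v in
                                          report.summary().items()})
    return report


def grid_search(table: LabeledCompoundTable,
                tau_values: Sequence[float], alpha_values: Sequence[float],
                estimator: MetabolicPathwayClassifier | None = None,
                test_fraction: float = 0.2, seed: int = 0,
                run_log: RunLog | None = None) -> np.ndarray:
    """Accuracy surface over a (tau, alpha) grid on a single held-out split.

    Returns an array of shape (len(tau_values), len(alpha_values)).
    """
    if estimator is None:
        estimator = MetabolicPathwayClassifier(random_state=seed)
    rng = np.random.default_rng(seed)
    n = len(table)
    perm = rng.permutation(n)
    n_test = max(1, int(round(test_fraction * n)))
    test = table.subset(perm[:n_test])
    train = table.subset(perm[n_test:])
    surface = np.zeros((len(tau_values), len(alpha_values)))
    for i, tau in enumerate(tau_values):
        for j, alpha in enumerate(alpha_values):
            model = clone(estimator)
            model.set_params(tau=tau, alpha=alpha,
                             pathway_names=table.pathway_names)
            model.fit(train.smiles, train.Y)
            surface[i, j] = evaluate(model, test)["accuracy"]
    if run_log is not None:
        best = np.unravel_index(np.argmax(surface), surface.shape)
        run_log.write("grid_done",
                      tau_values=list(map(float, tau_values)),
                      alpha_values=list(map(float, alpha_values)),
                      surface=surface.tolist(),
                      best_tau=float(tau_values[best[0]]),
                      best_alpha=float(alpha_values[best[1]]),
                      best_accuracy=float(surface[best]))
    return surface


def _jsonable(params: Mapping) -> dict:
    out = {}
    for k, v in params.items():
        try:
            json.dumps(v)
            out[k] = v
        except TypeError:
            out[k] = repr(v)
    return out
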