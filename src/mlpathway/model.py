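"""The multi-label pathway classifier as a scikit-learn-style estimator.

:class:`MetabolicPathwayClassifier` ties the three components together into
one end-to-end trainable model:

* a compound encoder (multi-head GAT -> GCN -> max-and-mean readout) over
  molecular graphs,
* a pathway encoder (two GCN layers over the label-dependence graph built
  from the *training* labels only, with word-vector node features), and
* a predictor (dense adapter into pathway space, dot-product logits,
  mean per-label binary cross-entropy loss, Adam).

``fit`` takes a sequence of SMILES strings (or pre-built MoleculeGraph
objects) and an (n, C) binary label matrix; ``decision_function``,
``predict_proba`` and ``predict`` follow scikit-learn multilabel
conventions.  Three ablation switches reproduce the model variants used to
probe the architecture: replacing the pathway encoder with a free label
embedding, removing the adapter, and random Gaussian label initialisation.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import autodiff as ad
from .autodiff import Adam, Tensor
from .compound_encoder import (AttentionMap, GatParams, GcnParams,
                               encode_compound)
from .mol_graph import FEATURE_DIM, MoleculeGraph, smiles_to_graph
from .pathway_encoder import PathwayGcnParams, encode_pathways, propagation_operator
from .pathway_graph import DependenceGraph, build_dependence_graph
from .predictor import AdapterParams, adapt, decide, multilabel_loss, sigmoid

ABLATIONS = ("none", "no_pathway_encoder", "no_adapter", "random_label_init")


class MetabolicPathwayClassifier(BaseEstimator, ClassifierMixin):
    """Multi-label metabolic-pathway classifier over molecular graphs.

    Parameters
    ----------
    n_heads : attention heads in the GAT layer (default 10).
    gat_head_dim : output width s per head (default 78; concatenated K*s).
    gcn_dim : output width of the compound GCN layer (default 780).
    adapter_hidden : hidden width of the dense adapter (default 1500).
    pathway_dim : width of both pathway-GCN layers and of the pathway
        embeddings B (default 1024).
    wordvec_dim : width r of the word-vector node features (default 300).
    tau : hard threshold on conditional label co-occurrence probabilities
        when building the dependence graph (default 0.5).
    alpha : trade-off coefficient mixing neighbouring labels into each
        label's own representation, in [0, 1] (default 0.3).
    epochs, batch_size, learning_rate : Adam training schedule
        (defaults 200 / 256 / 5e-4).
    decision_threshold : probability threshold for ``predict`` (default 0.5;
        ranking metrics never use it).
    ablation : one of ``none``, ``no_pathway_encoder`` (free learnable label
        embedding instead of the pathway encoder), ``no_adapter`` (dot
        products taken directly in compound space; pathway width is forced
        to 2t), ``random_label_init`` (Gaussian node features instead of
        word vectors).
    wordvec_file : GloVe text-format file for label-name features; when
        None, node features fall back to seeded Gaussian vectors.
    pathway_names : the C label names (used for word-vector lookup); when
        None, generic names are used.
    dependence_normalize : ``column`` (default) or ``row`` edge re-weighting.
    random_state : seed for parameter initialisation and batch shuffling.

    Attributes (after fit)
    ----------------------
    n_labels_ : number of pathway classes C.
    dependence_ : the :class:`DependenceGraph` built from the training fold.
    pathway_embeddings_ : final (C, B) pathway embedding matrix O.
    loss_curve_ : mean training loss per epoch.
    """

    def __init__(self, *, n_heads: int = 10, gat_head_dim: int = 78,
                 gcn_dim: int = 780, adapter_hidden: int = 1500,
                 pathway_dim: int = 1024, wordvec_dim: int = 300,
                 tau: float = 0.5, alpha: float = 0.3, epochs: int = 200,
                 batch_size: int = 256, learning_rate: float = 5e-4,
                 decision_threshold: float = 0.5, gat_leaky_slope: float = 0.2,
                 pathway_leaky_slope: float = 0.01, ablation: str = "none",
                 wordvec_file: str | None = None,
                 pathway_names: Sequence[str] | None = None,
                 dependence_normalize: str = "column",
                 random_state: int | None = None, verbose: int = 0):
        self.n_heads = n_heads
        self.gat_head_dim = gat_head_dim
        self.gcn_dim = gcn_dim
        self.adapter_hidden = adapter_hidden
        self.pathway_dim = pathway_dim
        self.wordvec_dim = wordvec_dim
        self.tau = tau
        self.alpha = alpha
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.decision_threshold = decision_threshold
        self.gat_leaky_slope = gat_leaky_slope
        self.pathway_leaky_slope = pathway_leaky_slope
        self.ablation = ablation
        self.wordvec_file = wordvec_file
        self.pathway_names = pathway_names
        self.dependence_normalize = dependence_normalize
        self.random_state = random_state
        self.verbose = verbose

    # -- helpers --------------------------------------------------------

    @staticmethod
    def _as_graphs(X) -> list[MoleculeGraph]:
        graphs = []
        for item in X:
            if isinstance(item, MoleculeGraph):
                graphs.append(item)
            else:
                graphs.append(smiles_to_graph(item))
        return graphs

    def _embedding_width(self) -> int:
        return 2 * self.gcn_dim

    def _pathway_width(self) -> int:
        if self.ablation == "no_adapter":
            return self._embedding_width()
        return self.pathway_dim

    def _parameters(self) -> list[Tensor]:
        out = self.gat_.tensors() + self.gcn_.tensors()
        if self.adapter_ is not None:
            out += self.adapter_.tensors()
        if self.pathway_params_ is not None:
            out += self.pathway_params_.tensors()
        if self.free_label_embedding_ is not None:
            out.append(self.free_label_embedding_)
        return out

    def _pathway_matrix(self) -> Tensor:
        """The (C, B) pathway embedding matrix O under the current weights."""
        if self.ablation == "no_pathway_encoder":
            return self.free_label_embedding_
        return encode_pathways(self._Q_tensor_, self.dependence_.M_w,
                               self.pathway_params_, s_hat=self._prop_tensor_)

    def _encode(self, graph: MoleculeGraph,
                cache: tuple[Tensor, Tensor] | None = None
                ) -> tuple[Tensor, AttentionMap]:
        x, s_hat = cache if cache is not None else (None, None)
        z, attn = encode_compound(graph, self.gat_, self.gcn_, x=x, s_hat=s_hat)
        if self.adapter_ is not None:
            z = adapt(z, self.adapter_)
        return z, attn

    # -- estimator API ---------------------------------------------------

    def fit(self, X, y) -> "MetabolicPathwayClassifier":
        """Train end-to-end on SMILES (or graphs) X and binary labels y."""
        if self.ablation not in ABLATIONS:
            raise ValueError(f"ablation must be one of {ABLATIONS}, "
                             f"got {self.ablation!r}")
        Y = np.asarray(y)
        if Y.ndim != 2 or Y.shape[1] < 2:
            raise ValueError("y must be an (n, C) binary matrix with C >= 2")
        if not np.isin(Y, (0, 1)).all():
            raise ValueError("y must be binary")
        graphs = self._as_graphs(X)
        if len(graphs) != Y.shape[0]:
            raise ValueError("X and y lengths differ")
        if len(graphs) == 0:
            raise ValueError("empty training set")

        n, C = Y.shape
        self.n_labels_ = C
        rng = np.random.default_rng(self.random_state)

        names = (list(self.pathway_names) if self.pathway_names is not None
                 else [f"pathway {i}" for i in range(C)])
        if len(names) != C:
            raise ValueError(f"{len(names)} pathway names for C={C} labels")
        self.pathway_names_ = names

        # label-dependence graph from the training labels only
        labelsets = [set(np.flatnonzero(row)) for row in Y]
        self.dependence_ = build_dependence_graph(
            labelsets, C, self.tau, pathway_names=names,
            wordvec_file=self.wordvec_file, r=self.wordvec_dim, rng=rng,
            random_init=(self.ablation == "random_label_init"),
            normalize=self.dependence_normalize,
        )

        # parameters
        B = self._pathway_width()
        self.gat_ = GatParams.init(rng, FEATURE_DIM, self.gat_head_dim,
                                   self.n_heads, self.gat_leaky_slope)
        self.gcn_ = GcnParams.init(rng, self.n_heads * self.gat_head_dim,
                                   self.gcn_dim)
        if self.ablation == "no_adapter":
            self.adapter_ = None
        else:
            self.adapter_ = AdapterParams.init(
                rng, self._embedding_width(), self.adapter_hidden, B)
        if self.ablation == "no_pathway_encoder":
            self.pathway_params_ = None
            self.free_label_embedding_ = ad.parameter(
                ad.glorot_uniform(rng, C, B))
        else:
            self.pathway_params_ = PathwayGcnParams.init(
                rng, self.wordvec_dim, self.pathway_dim, B,
                alpha=self.alpha, leaky_slope=self.pathway_leaky_slope)
            self.free_label_embedding_ = None
        self._Q_tensor_ = ad.constant(self.dependence_.node_features)
        self._prop_tensor_ = ad.constant(
            propagation_operator(self.dependence_.M_w, self.alpha))

        # cache per-compound constant tensors
        caches = [(ad.constant(g.atom_features),
                   ad.constant(g.normalized_adjacency())) for g in graphs]

        opt = Adam(self._parameters(), lr=self.learning_rate)
        self.loss_curve_: list[float] = []
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                opt.zero_grad()
                O = self._pathway_matrix()
                zs = [self._encode(graphs[i], caches[i])[0] for i in idx]
                logits = ad.concat(zs, axis=0) @ O.T
                loss = multilabel_loss(logits, Y[idx])
                loss.backward()
                opt.step()
                epoch_loss += float(loss.data) * len(idx)
            self.loss_curve_.append(epoch_loss / n)
            if self.verbose and (epoch % max(1, self.epochs // 10) == 0
                                 or epoch == self.epochs - 1):
                print(f"epoch {epoch + 1}/{self.epochs} "
                      f"loss {self.loss_curve_[-1]:.4f}")

        self.pathway_embeddings_ = self._pathway_matrix().data.copy()
        return self

    def decision_function(self, X) -> np.ndarray:
        """Raw proximity logits, shape (n, C)."""
        self._check_fitted()
        graphs = self._as_graphs(X)
        O = self.pathway_embeddings_
        out = np.empty((len(graphs), self.n_labels_))
        for i, g in enumerate(graphs):
            z, _ = self._encode(g)
            out[i] = z.data[0] @ O.T
        return out

    def predict_proba(self, X) -> np.ndarray:
        """Per-label sigmoid probabilities, shape (n, C)."""
        return sigmoid(self.decision_function(X))

    def predict(self, X) -> np.ndarray:
        """Binary decisions at the configured probability threshold."""
        return decide(self.decision_function(X), self.decision_threshold)

    def bond_attention(self, X) -> list[tuple[MoleculeGraph, AttentionMap]]:
        """Attention maps of the fitted GAT layer for each input compound."""
        self._check_fitted()
        out = []
        for g in self._as_graphs(X):
            _, attn = self._encode(g)
            out.append((g, attn))
        return out

    def _check_fitted(self) -> None:
        if not hasattr(self, "pathway_embeddings_"):
            raise RuntimeError("estimator is not fitted; call fit first")

    # -- checkpointing ----------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Serialise config + weights to a single .npz checkpoint."""
        self._check_fitted()
        arrays: dict[str, np.ndarray] = {}
        for k, head in enumerate(self.gat_.heads):
            for key, t in head.items():
                arrays[f"gat.{k}.{key}"] = t.data
        arrays["gcn.W"] = self.gcn_.W.data
        if self.adapter_ is not None:
            for key in ("W1", "b1", "W2", "b2"):
                arrays[f"adapter.{key}"] = getattr(self.adapter_, key).data
        if self.pathway_params_ is not None:
            arrays["pathway.W0"] = self.pathway_params_.W0.data
            arrays["pathway.W1"] = self.pathway_params_.W1.data
        if self.free_label_embedding_ is not None:
            arrays["free_label_embedding"] = self.free_label_embedding_.data
        arrays["dependence.M_w"] = self.dependence_.M_w
        arrays["dependence.P"] = self.dependence_.P
        arrays["dependence.M"] = self.dependence_.M
        arrays["dependence.Q"] = self.dependence_.node_features
        arrays["pathway_embeddings"] = self.pathway_embeddings_
        config = dict(self.get_params())
        config["pathway_names"] = self.pathway_names_
        config["n_labels"] = self.n_labels_
        arrays["config_json"] = np.array(json.dumps(config))
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "MetabolicPathwayClassifier":
        with np.load(path, allow_pickle=False) as data:
            config = json.loads(str(data["config_json"]))
            n_labels = config.pop("n_labels")
            names = config.pop("pathway_names")
            est = cls(**{**config, "pathway_names": names})
            est.n_labels_ = n_labels
            est.pathway_names_ = names
            est.dependence_ = DependenceGraph(
                P=data["dependence.P"], M=data["dependence.M"],
                M_w=data["dependence.M_w"], tau=config["tau"],
                node_features=data["dependence.Q"])
            heads = []
            k = 0
            while f"gat.{k}.W" in data:
                heads.append({key: ad.parameter(data[f"gat.{k}.{key}"])
                              for key in ("W", "a_src", "a_dst")})
                k += 1
            est.gat_ = GatParams(heads=heads, leaky_slope=config["gat_leaky_slope"])
            est.gcn_ = GcnParams(W=ad.parameter(data["gcn.W"]))
            if "adapter.W1" in data:
                est.adapter_ = AdapterParams(
                    **{key: ad.parameter(data[f"adapter.{key}"])
                       for key in ("W1", "b1", "W2", "b2")})
            else:
                est.adapter_ = None
            if "pathway.W0" in data:
                est.pathway_params_ = PathwayGcnParams(
                    W0=ad.parameter(data["pathway.W0"]),
                    W1=ad.parameter(data["pathway.W1"]),
                    alpha=config["alpha"],
                    leaky_slope=config["pathway_leaky_slope"])
            else:
                est.pathway_params_ = None
            if "free_label_embedding" in data:
                est.free_label_embedding_ = ad.parameter(
                    data["free_label_embedding"])
            else:
                est.free_label_embedding_ = None
            est._Q_tensor_ = ad.constant(est.dependence_.node_features)
            est._prop_tensor_ = ad.constant(
                propagation_operator(est.dependence_.M_w, config["alpha"]))
            est.loss_curve_ = []
            est.pathway_embeddings_ = data["pathway_embeddings"]
        return est


def small_layout(**overrides) -> dict:
    """A reduced layer layout for experiments on synthetic fixtures.

    Same architecture, narrower layers (4 heads x 16, GCN 64, adapter hidden
    64, pathway width 64, word vectors r=50) so that training runs in
    seconds on one CPU core.
    """
    layout = dict(n_heads=4, gat_head_dim=16, gcn_dim=64, adapter_hidden=64,
                  pathway_dim=64, wordvec_dim=50, batch_size=64)
    layout.update(overrides)
    return layout
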