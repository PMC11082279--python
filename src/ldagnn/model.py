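"""Model / Results interface for lncRNA-drug association prediction.

:class:`LncRNADrugGNN` bundles an association matrix with a
:class:`~ldagnn.network.ModelConfig`; :meth:`LncRNADrugGNN.fit` trains
the GCN/GAT scoring network on all known associations plus an equal
number of sampled negatives and returns a
:class:`LncRNADrugGNNResults` carrying the trained parameters,
training diagnostics, prediction and ranking methods, and a
``summary()`` table.  :meth:`LncRNADrugGNN.cross_validate` runs the
repeated 5-fold evaluation protocol.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import evaluate
from .evaluate import (CVPlan, MetricsReport, TrainingContext, compute_metrics,
                       rank_pairs, sample_negatives)
from .io import AssociationMatrix, read_associations, write_rankings
from .network import ModelConfig, Tensor

__all__ = ["LncRNADrugGNN", "LncRNADrugGNNResults"]


class LncRNADrugGNN:
    """GCN/GAT link-prediction model over a lncRNA-drug association table.

    Parameters
    ----------
    assoc : AssociationMatrix
        Binary incidence matrix of known associations.
    config : ModelConfig, optional
        Network and training hyperparameters; defaults to the tuned
        1 GCN + 3 GAT architecture.

    Examples
    --------
    >>> from ldagnn import LncRNADrugGNN, ModelConfig, synthetic
    >>> data = synthetic.generate()
    >>> model = LncRNADrugGNN(data.assoc, ModelConfig(epochs=5))
    >>> res = model.fit(seed=0)
    >>> res.rank_candidates("DRUG00", side="drug", top_k=3)  # doctest: +SKIP
    """

    def __init__(self, assoc: AssociationMatrix,
                 config: ModelConfig | None = None):
        if assoc.n_positives == 0:
            raise ValueError("association matrix has no positives")
        self.assoc = assoc
        self.config = config or ModelConfig()

    # ------------------------------------------------------- constructors
    @classmethod
    def from_edge_list(cls, path, config: ModelConfig | None = None,
                       delimiter: str | None = None) -> "LncRNADrugGNN":
        return cls(read_associations(path, delimiter), config)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       config: ModelConfig | None = None) -> "LncRNADrugGNN":
        return cls(AssociationMatrix.from_dataframe(df), config)

    # ------------------------------------------------------------ fitting
    def fit(self, seed: int | None = None) -> "LncRNADrugGNNResults":
        """Train on all positives plus an equal sampled negative set."""
        seed = self.config.seed if seed is None else seed
        ctx = TrainingContext.build(self.assoc, self.config)
        pos = self.assoc.positive_pairs()
        neg_rng = np.random.default_rng(np.random.SeedSequence((seed, 0xA5)))
        neg = sample_negatives(self.assoc, len(pos), neg_rng)
        train_rng = np.random.default_rng(np.random.SeedSequence((seed, 0x5A)))
        params, history = ctx.train(pos, neg, train_rng)
        train_pairs = np.vstack([pos, neg])
        train_labels = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
        train_metrics = compute_metrics(ctx.score(train_pairs, params),
                                        train_labels)
        return LncRNADrugGNNResults(
            model=self, context=ctx, params=params, loss_history=history,
            seed=seed, train_metrics=train_metrics)

    def cross_validate(self, n_folds: int = 5, n_repeats: int = 3,
                       seed: int = 0, plan: CVPlan | None = None) -> MetricsReport:
        """Repeated stratified k-fold CV under this model's config."""
        return evaluate.run_cv(self.assoc, self.config, n_folds=n_folds,
                               n_repeats=n_repeats, seed=seed, plan=plan)


@dataclass
class LncRNADrugGNNResults:
    """Fitted scoring network plus diagnostics and prediction methods."""

    model: LncRNADrugGNN
    context: TrainingContext
    params: dict[str, Tensor]
    loss_history: list[float]
    seed: int
    train_metrics: object = None

    # ---------------------------------------------------------- prediction
    def predict_proba(self, pairs) -> np.ndarray:
        """Association probabilities for (lnc_id, drug_id) pairs.

        ``pairs`` may be id tuples or integer index pairs.
        """
        assoc = self.model.assoc
        idx = []
        for a, b in pairs:
            if isinstance(a, str) or isinstance(b, str):
                idx.append((assoc.lnc_index(str(a)), assoc.drug_index(str(b))))
            else:
                idx.append((int(a), int(b)))
        return self.context.score(np.asarray(idx, int), self.params)

    def rank_candidates(self, query: str, side: str = "drug",
                        top_k: int = 10) -> list[tuple[str, str, float]]:
        """Top-k unknown pairs involving ``query``, by predicted score."""
        return rank_pairs(
            lambda p: self.context.score(p, self.params),
            self.model.assoc, query, side, top_k)

    def write_rankings(self, query: str, side: str, path,
                       top_k: int = 10) -> None:
        write_rankings(self.rank_candidates(query, side, top_k), path)

    # ---------------------------------------------------------- reporting
    def summary(self) -> str:
        cfg = self.model.config
        assoc = self.model.assoc
        tm = self.train_metrics
        lines = [
            "lncRNA-drug association GNN (GCN/GAT enclosing-subgraph scorer)",
            "=" * 64,
            f"lncRNAs: {assoc.n_lnc}   drugs: {assoc.n_drug}   "
            f"known associations: {assoc.n_positives}",
            f"architecture: {cfg.n_gcn_layers} GCN + {cfg.n_gat_layers} GAT "
            f"(ablation={cfg.ablation}), hidden={cfg.hidden_dim}, "
            f"heads={cfg.attention_heads}",
            f"training: Adam lr={cfg.learning_rate}, epochs={cfg.epochs}, "
            f"batch={cfg.batch_size}, seed={self.seed}",
            f"features: PCA dim request={cfg.pca_dim} "
            f"(a={self.context.lnc_feats.d}, b={self.context.drug_feats.d}; "
            f"node width {4 + self.context.lnc_feats.d + self.context.drug_feats.d})",
            f"final training loss: {self.loss_history[-1]:.4f}",
        ]
        if tm is not None:
            lines.append(
                f"training-set AUC: {tm.auc:.4f}   AUPR: {tm.aupr:.4f}   "
                f"accuracy: {tm.accuracy:.4f}")
        return "\n".join(lines)

    # -------------------------------------------------------- persistence
    def save(self, path) -> None:
        """Checkpoint: npz archive of parameters + JSON-embedded config."""
        arrays = {k: p.value for k, p in self.params.items()}
        meta = json.dumps({"config": self.model.config.to_dict(),
                           "seed": self.seed,
                           "loss_history": self.loss_history})
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path, assoc: AssociationMatrix) -> "LncRNADrugGNNResults":
        with np.load(path) as npz:
            meta = json.loads(bytes(npz["__meta__"]).decode())
            params = {k: Tensor(npz[k], requires_grad=True)
                      for k in npz.files if k != "__meta__"}
        config = ModelConfig.from_dict(meta["config"])
        model = LncRNADrugGNN(assoc, config)
        ctx = TrainingContext.build(assoc, config)
        return cls(model=model, context=ctx, params=params,
                   loss_history=meta["loss_history"], seed=meta["seed"])
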