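"""Negative sampling, cross-validated evaluation and candidate ranking.

Known associations are the positive class; an equal number of unknown
(zero) cells is drawn uniformly without replacement as presumed
negatives.  Evaluation is repeated stratified 5-fold cross-validation:
each repeat re-samples negatives and re-splits the positives, each
fold trains on the remaining four and scores the held-out fold.
Similarities, PCA features and the bipartite graph are rebuilt from
the training fold's matrix (held-out edges zeroed) unless the config
requests paper-style full-matrix construction.

Metrics: confusion counts at threshold 0.5; precision, recall, F1 and
accuracy from the counts; AUC as the Mann-Whitney concordance
probability (ties counted 1/2); AUPR as the area under the
precision-recall step curve.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field, asdict, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .features import assemble_node_features, pca_reduce
from .io import AssociationMatrix
from .network import ModelConfig, Tensor, predict_scores, train_network
from .similarity import gip_similarity
from .subgraph import BipartiteGraph, build_bipartite_graph, extract_subgraph

logger = logging.getLogger(__name__)

__all__ = ["FoldMetrics", "MetricsReport", "CVPlan", "sample_negatives",
           "compute_metrics", "run_cv", "grid_search", "rank_pairs",
           "TrainingContext"]

_METRIC_KEYS = ("auc", "aupr", "precision", "recall", "f1", "accuracy")


# ----------------------------------------------------------------- metrics

@dataclass(frozen=True)
class FoldMetrics:
    """Confusion counts and derived metrics for one evaluated fold."""

    tp: int
    fp: int
    tn: int
    fn: int
    auc: float
    aupr: float
    precision: float
    recall: float
    f1: float
    accuracy: float
    n: int

    def to_dict(self) -> dict:
        return asdict(self)


def _auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """P(score_pos > score_neg) with ties counted 1/2, via rank sums."""
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _aupr_step(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the precision-recall step curve.

    Thresholds sweep the distinct score values from high to low; the
    area is sum over steps of (recall gain) x (precision at the step),
    with tied scores entering together.
    """
    order = np.argsort(-scores, kind="mergesort")
    s, y = scores[order], labels[order]
    n_pos = int(y.sum())
    tp = np.cumsum(y)
    fp = np.cumsum(1 - y)
    # last index of each tied block = points on the curve
    distinct = np.nonzero(np.diff(s, append=np.nan))[0]
    precision = tp[distinct] / (tp[distinct] + fp[distinct])
    recall = tp[distinct] / n_pos
    recall_prev = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - recall_prev) * precision))


def compute_metrics(scores: np.ndarray, labels: np.ndarray,
                    threshold: float = 0.5) -> FoldMetrics:
    """Confusion counts at ``threshold`` plus AUC/AUPR and Eq-style ratios.

    Raises
    ------
    ValueError
        If only one class is present (AUC/AUPR undefined).
    """
    scores = np.asarray(scores, float).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if labels.min() == labels.max():
        raise ValueError("labels contain a single class; AUC/AUPR undefined")
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    accuracy = (tp + tn) / len(labels)
    return FoldMetrics(
        tp=tp, fp=fp, tn=tn, fn=fn,
        auc=_auc_mann_whitney(scores, labels),
        aupr=_aupr_step(scores, labels),
        precision=precision, recall=recall, f1=f1, accuracy=accuracy,
        n=len(labels),
    )


@dataclass
class MetricsReport:
    """Per-fold metrics with mean +/- sd aggregation."""

    per_fold: list[FoldMetrics]
    n_folds: int
    n_repeats: int

    def mean(self, key: str) -> float:
        return float(np.mean([getattr(m, key) for m in self.per_fold]))

    def sd(self, key: str) -> float:
        vals = [getattr(m, key) for m in self.per_fold]
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0

    def to_dict(self) -> dict:
        return {
            "n_folds": self.n_folds,
            "n_repeats": self.n_repeats,
            "mean": {k: self.mean(k) for k in _METRIC_KEYS},
            "sd": {k: self.sd(k) for k in _METRIC_KEYS},
            "per_fold": [m.to_dict() for m in self.per_fold],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def summary(self) -> str:
        lines = [
            f"Cross-validation: {self.n_folds} folds x {self.n_repeats} "
            f"repeat(s), {len(self.per_fold)} evaluated fold(s)",
            f"{'metric':<10}{'mean':>10}{'sd':>10}",
        ]
        for k in _METRIC_KEYS:
            lines.append(f"{k:<10}{self.mean(k):>10.4f}{self.sd(k):>10.4f}")
        return "\n".join(lines)


# ------------------------------------------------------- negative sampling

def sample_negatives(assoc: AssociationMatrix, k: int,
                     seed: int | np.random.Generator = 0) -> np.ndarray:
    """Draw ``k`` distinct zero cells of LD uniformly without replacement."""
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    zeros = assoc.zero_pairs()
    if k > len(zeros):
        raise ValueError(
            f"requested {k} negatives but only {len(zeros)} zero cells exist")
    pick = rng.choice(len(zeros), size=k, replace=False)
    return zeros[pick]


# ------------------------------------------------------------------ CV plan

@dataclass(frozen=True)
class FoldSplit:
    train_pos: np.ndarray
    train_neg: np.ndarray
    test_pos: np.ndarray
    test_neg: np.ndarray


@dataclass(frozen=True)
class CVPlan:
    """Fold assignments of positives and per-fold sampled negatives."""

    repeats: tuple[tuple[FoldSplit, ...], ...]
    seed: int

    @classmethod
    def build(cls, assoc: AssociationMatrix, n_folds: int = 5,
              n_repeats: int = 1, seed: int = 0) -> "CVPlan":
        pos = assoc.positive_pairs()
        if len(pos) < n_folds:
            raise ValueError("fewer positives than folds")
        reps = []
        for r in range(n_repeats):
            rng = np.random.default_rng(
                np.random.SeedSequence((seed, r, 0xC0FFEE)))
            neg = sample_negatives(assoc, len(pos), rng)
            pos_perm = pos[rng.permutation(len(pos))]
            neg_perm = neg[rng.permutation(len(neg))]
            pos_folds = np.array_split(pos_perm, n_folds)
            neg_folds = []
            start = 0
            for pf in pos_folds:  # negatives matched 1:1 to each fold
                neg_folds.append(neg_perm[start:start + len(pf)])
                start += len(pf)
            splits = []
            for f in range(n_folds):
                train_pos = np.vstack([pos_folds[g] for g in range(n_folds)
                                       if g != f])
                train_neg = np.vstack([neg_folds[g] for g in range(n_folds)
                                       if g != f])
                splits.append(FoldSplit(train_pos, train_neg,
                                        pos_folds[f], neg_folds[f]))
            reps.append(tuple(splits))
        return cls(tuple(reps), seed)


# ------------------------------------------------------- training pipeline

@dataclass
class TrainingContext:
    """Graph, similarity features and subgraph cache for one training run."""

    assoc: AssociationMatrix
    train_matrix: np.ndarray
    graph: BipartiteGraph
    lnc_feats: object
    drug_feats: object
    config: ModelConfig
    _cache: dict = field(default_factory=dict)

    @classmethod
    def build(cls, assoc: AssociationMatrix, config: ModelConfig,
              held_out_pos: np.ndarray | None = None) -> "TrainingContext":
        mat = assoc.matrix.astype(np.int8).copy()
        if held_out_pos is not None and not config.use_full_matrix:
            mat[held_out_pos[:, 0], held_out_pos[:, 1]] = 0
        if mat.sum() == 0:
            raise ValueError("training matrix has no associations")
        ls = gip_similarity(mat, entity_axis="lncRNA")
        ds = gip_similarity(mat.T, entity_axis="drug")
        return cls(
            assoc=assoc,
            train_matrix=mat,
            graph=build_bipartite_graph(mat),
            lnc_feats=pca_reduce(ls, config.pca_dim),
            drug_feats=pca_reduce(ds, config.pca_dim),
            config=config,
        )

    def subgraphs_for(self, pairs: np.ndarray):
        """Labeled subgraphs + node features for (i, j) index pairs."""
        sgs, feats = [], []
        for i, j in pairs:
            key = (int(i), int(j))
            hit = self._cache.get(key)
            if hit is None:
                sg = extract_subgraph(self.graph, int(i), int(j),
                                      self.config.remove_target_edge)
                hit = (sg, assemble_node_features(sg, self.lnc_feats,
                                                  self.drug_feats))
                self._cache[key] = hit
            sgs.append(hit[0])
            feats.append(hit[1])
        return sgs, feats

    def train(self, pos: np.ndarray, neg: np.ndarray,
              rng: np.random.Generator) -> tuple[dict[str, Tensor], list[float]]:
        pairs = np.vstack([pos, neg])
        labels = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
        sgs, feats = self.subgraphs_for(pairs)
        return train_network(sgs, feats, labels, self.config, rng)

    def score(self, pairs: np.ndarray, params: dict[str, Tensor]) -> np.ndarray:
        sgs, feats = self.subgraphs_for(pairs)
        return predict_scores(sgs, feats, params, self.config)


Scorer = Callable[[TrainingContext, np.ndarray], np.ndarray]


# ------------------------------------------------------------------ run_cv

def run_cv(
    assoc: AssociationMatrix,
    config: ModelConfig,
    n_folds: int = 5,
    n_repeats: int = 3,
    seed: int = 0,
    scorer: Scorer | None = None,
    plan: CVPlan | None = None,
) -> MetricsReport:
    """Repeated stratified 5-fold cross-validation of the scoring model.

    ``scorer`` overrides model training for diagnostic runs: it is
    called as ``scorer(ctx, pairs) -> scores`` on the held-out pairs
    (e.g. to inject an oracle scorer).
    """
    if plan is None:
        plan = CVPlan.build(assoc, n_folds, n_repeats, seed)
    per_fold: list[FoldMetrics] = []
    for r, splits in enumerate(plan.repeats):
        for f, split in enumerate(splits):
            if len(split.test_pos) == 0 or len(split.test_neg) == 0:
                logger.warning("skipping degenerate fold %d/%d", r, f)
                continue
            ctx = TrainingContext.build(assoc, config,
                                        held_out_pos=split.test_pos)
            test_pairs = np.vstack([split.test_pos, split.test_neg])
            test_labels = np.concatenate([
                np.ones(len(split.test_pos)), np.zeros(len(split.test_neg))])
            if scorer is None:
                rng = np.random.default_rng(
                    np.random.SeedSequence((seed, config.seed, r, f)))
                params, _ = ctx.train(split.train_pos, split.train_neg, rng)
                scores = ctx.score(test_pairs, params)
            else:
                scores = np.asarray(scorer(ctx, test_pairs), float)
            per_fold.append(compute_metrics(scores, test_labels))
            logger.info("repeat %d fold %d: auc=%.4f aupr=%.4f",
                        r, f, per_fold[-1].auc, per_fold[-1].aupr)
    return MetricsReport(per_fold, n_folds, len(plan.repeats))


# -------------------------------------------------------------- grid search

def grid_search(
    assoc: AssociationMatrix,
    grid: dict[str, Sequence],
    base: ModelConfig | None = None,
    n_folds: int = 5,
    n_repeats: int = 1,
    seed: int = 0,
) -> tuple[ModelConfig, pd.DataFrame]:
    """Exhaustive hyperparameter search scored by mean CV AUC.

    Ties prefer the smaller model (fewer layers, then smaller hidden
    and PCA dimensions).  Returns the best config and the full table.
    """
    if not grid:
        raise ValueError("empty grid")
    base = base or ModelConfig()
    keys = sorted(grid)
    rows = []
    for combo in itertools.product(*(grid[k] for k in keys)):
        cfg = replace(base, **dict(zip(keys, combo)))
        report = run_cv(assoc, cfg, n_folds=n_folds, n_repeats=n_repeats,
                        seed=seed)
        rows.append({**dict(zip(keys, combo)),
                     "mean_auc": report.mean("auc"),
                     "mean_aupr": report.mean("aupr"),
                     "config": cfg})
    table = pd.DataFrame(rows)
    order = sorted(
        range(len(rows)),
        key=lambda i: (
            -rows[i]["mean_auc"],
            rows[i]["config"].effective_layers(),
            rows[i]["config"].hidden_dim,
            rows[i]["config"].pca_dim,
        ),
    )
    best = rows[order[0]]["config"]
    return best, table.drop(columns=["config"]).assign(
        rank=np.argsort(order).astype(int) + 1)


# ------------------------------------------------------------------ ranking

def rank_pairs(
    score_fn: Callable[[np.ndarray], np.ndarray],
    assoc: AssociationMatrix,
    query: str,
    side: str,
    top_k: int = 10,
) -> list[tuple[str, str, float]]:
    """Rank the unknown pairs involving ``query`` by a scoring callable.

    ``side`` names what the query is ("lncRNA" or "drug"); candidates
    are the zero cells in the query's row/column.  Returns at most
    ``top_k`` (lnc_id, drug_id, score) triples sorted by score
    descending, ties broken by id.
    """
    if side not in ("lncRNA", "drug"):
        raise ValueError("side must be 'lncRNA' or 'drug'")
    if side == "lncRNA":
        i = assoc.lnc_index(query)
        cand = np.nonzero(assoc.matrix[i] == 0)[0]
        pairs = np.column_stack([np.full(len(cand), i), cand])
    else:
        j = assoc.drug_index(query)
        cand = np.nonzero(assoc.matrix[:, j] == 0)[0]
        pairs = np.column_stack([cand, np.full(len(cand), j)])
    if len(pairs) == 0:
        raise ValueError(f"query {query!r} has no unknown pairs to rank")
    if top_k <= 0:
        return []
    scores = np.asarray(score_fn(pairs), float).ravel()
    triples = [(assoc.lnc_ids[i], assoc.drug_ids[j], float(s))
               for (i, j), s in zip(pairs, scores)]
    triples.sort(key=lambda t: (-t[2], t[0], t[1]))
    return triples[:top_k]
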