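"""GCN/GAT scoring network over labeled enclosing subgraphs.

Architecture (defaults follow the tuned choice of 1 GCN layer followed
by 3 GAT layers, learning rate 1e-3):

* GCN layer:  h_i' = ReLU( sum_{j in N(i) ∪ {i}} (d_i d_j)^{-1/2} h_j W ),
  degrees taken on the self-loop-augmented subgraph.
* GAT layer:  e_ij = LeakyReLU( a^T [W h_i ‖ W h_j] ) over j in
  N(i) ∪ {i}; α_ij = softmax_j(e_ij); h_i' = ELU( Σ_j α_ij W h_j ).
  Multiple heads are averaged.
* Readout: the target lncRNA and target drug embeddings are
  concatenated and a learned linear head maps them to two logits; the
  softmax positive-class probability is the pair score.
* Loss: mean binary cross-entropy with scores clamped to
  [1e-7, 1 - 1e-7].

Training uses Adam with Glorot-uniform initialization from the run
seed.  Graphs are trained in minibatches as one disjoint union (block
diagonal adjacency), so a batch is a single forward pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Sequence

import numpy as np
from scipy import sparse

from . import autodiff as ad
from .autodiff import Tensor
from .features import NodeFeatureMatrix
from .subgraph import EnclosingSubgraph

__all__ = ["ModelConfig", "init_parameters", "SubgraphBatch", "forward_scores",
           "gcn_forward", "gat_attention", "gat_forward", "score_pair",
           "bce_loss", "AdamOptimizer", "train_network"]

SCORE_EPS = 1e-7
LEAKY_SLOPE = 0.2


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the scoring network and its training run.

    Defaults are the tuned architecture: one GCN layer feeding three
    GAT layers, learning rate 0.001, 40 epochs, batch size 64, PCA
    dimension 128 (capped per side by feasibility).
    """

    n_gcn_layers: int = 1
    n_gat_layers: int = 3
    hidden_dim: int = 32
    attention_heads: int = 1
    learning_rate: float = 0.001
    epochs: int = 40
    batch_size: int = 64
    pca_dim: int = 128
    seed: int = 0
    ablation: str = "both"          # "gcn_only" | "gat_only" | "both"
    dropout: float = 0.0
    remove_target_edge: bool = True
    use_full_matrix: bool = False   # build similarities/graph from full LD

    def __post_init__(self) -> None:
        if self.ablation not in ("gcn_only", "gat_only", "both"):
            raise ValueError(f"unknown ablation mode: {self.ablation!r}")
        if self.effective_layers() < 1:
            raise ValueError("need at least one GCN or GAT layer")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")

    def effective_layers(self) -> int:
        n_gcn = self.n_gcn_layers if self.ablation != "gat_only" else 0
        n_gat = self.n_gat_layers if self.ablation != "gcn_only" else 0
        return n_gcn + n_gat

    def layer_plan(self) -> list[str]:
        """Layer kinds in forward order after applying the ablation switch."""
        plan: list[str] = []
        if self.ablation != "gat_only":
            plan += ["gcn"] * self.n_gcn_layers
        if self.ablation != "gcn_only":
            plan += ["gat"] * self.n_gat_layers
        return plan

    def with_ablation(self, mode: str) -> "ModelConfig":
        return replace(self, ablation=mode)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


# ------------------------------------------------------------- parameters

def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
            shape=None) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))


def init_parameters(config: ModelConfig, in_dim: int,
                    rng: np.random.Generator | int | None = None) -> dict[str, Tensor]:
    """Glorot-uniform parameters for the configured layer stack."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(config.seed if rng is None else rng)
    params: dict[str, Tensor] = {}
    dim = in_dim
    h = config.hidden_dim
    for k, kind in enumerate(config.layer_plan()):
        if kind == "gcn":
            params[f"layer{k}.W"] = Tensor(_glorot(rng, dim, h), requires_grad=True)
        else:
            for head in range(config.attention_heads):
                params[f"layer{k}.head{head}.W"] = Tensor(
                    _glorot(rng, dim, h), requires_grad=True)
                params[f"layer{k}.head{head}.a"] = Tensor(
                    _glorot(rng, 2 * h, 1, shape=(2 * h, 1)), requires_grad=True)
        dim = h
    params["head.W"] = Tensor(_glorot(rng, 2 * dim, 2), requires_grad=True)
    params["head.b"] = Tensor(np.zeros(2), requires_grad=True)
    return params


# ---------------------------------------------------------------- batching

@dataclass
class SubgraphBatch:
    """Disjoint union of enclosing subgraphs as one message-passing graph.

    ``edge_src``/``edge_dst`` are directed message edges including both
    orientations of every bipartite edge plus one self-loop per node
    (so every attention neighborhood is nonempty).  ``a_hat`` is the
    symmetric-normalized self-loop-augmented adjacency used by GCN
    layers.
    """

    x: np.ndarray
    edge_src: np.ndarray
    edge_dst: np.ndarray
    a_hat: sparse.csr_matrix
    lnc_pos: np.ndarray     # global node index of each graph's target lncRNA
    drug_pos: np.ndarray    # global node index of each graph's target drug
    n_nodes: int
    n_graphs: int
    scatter_src: sparse.csr_matrix = None  # (n_nodes x n_edges) adjoints of
    scatter_dst: sparse.csr_matrix = None  # gather by src / dst

    @classmethod
    def from_graph_arrays(cls, x: np.ndarray, edges: np.ndarray,
                          lnc_pos, drug_pos) -> "SubgraphBatch":
        """Build from a single already-merged graph (local = global)."""
        return cls._assemble(x, edges, np.atleast_1d(lnc_pos),
                             np.atleast_1d(drug_pos))

    @classmethod
    def from_subgraphs(cls, sgs: Sequence[EnclosingSubgraph],
                       feats: Sequence[NodeFeatureMatrix]) -> "SubgraphBatch":
        offsets = np.cumsum([0] + [sg.n_nodes for sg in sgs])
        x = np.vstack([f.rows for f in feats])
        edge_chunks = [sg.edges + off for sg, off in zip(sgs, offsets)
                       if len(sg.edges)]
        edges = (np.vstack(edge_chunks) if edge_chunks
                 else np.empty((0, 2), dtype=int))
        lnc_pos = offsets[:-1]          # target lncRNA is local node 0
        drug_pos = offsets[:-1] + 1     # target drug is local node 1
        return cls._assemble(x, edges, lnc_pos, drug_pos)

    @classmethod
    def _assemble(cls, x, edges, lnc_pos, drug_pos) -> "SubgraphBatch":
        n = x.shape[0]
        u, v = (edges[:, 0], edges[:, 1]) if len(edges) else \
            (np.empty(0, int), np.empty(0, int))
        loops = np.arange(n)
        src = np.concatenate([u, v, loops])
        dst = np.concatenate([v, u, loops])
        data = np.ones(len(src))
        adj = sparse.csr_matrix((data, (dst, src)), shape=(n, n))
        deg = np.asarray(adj.sum(axis=1)).ravel()
        dinv = 1.0 / np.sqrt(deg)
        a_hat = sparse.diags(dinv) @ adj @ sparse.diags(dinv)
        ne = len(src)
        eye = np.ones(ne)
        erange = np.arange(ne)
        scatter_src = sparse.csr_matrix((eye, (src, erange)), shape=(n, ne))
        scatter_dst = sparse.csr_matrix((eye, (dst, erange)), shape=(n, ne))
        return cls(x=np.asarray(x, float), edge_src=src, edge_dst=dst,
                   a_hat=sparse.csr_matrix(a_hat),
                   lnc_pos=np.asarray(lnc_pos, int),
                   drug_pos=np.asarray(drug_pos, int),
                   n_nodes=n, n_graphs=len(np.atleast_1d(lnc_pos)),
                   scatter_src=scatter_src, scatter_dst=scatter_dst)


# ----------------------------------------------------------------- layers

def _gcn_layer(H: Tensor, batch: SubgraphBatch, W: Tensor,
               activation: bool = True) -> Tensor:
    out = ad.matmul(ad.spmm(batch.a_hat, H), W)
    return ad.relu(out) if activation else out


def _gat_edge_logits(H: Tensor, batch: SubgraphBatch, W: Tensor,
                     a: Tensor) -> tuple[Tensor, Tensor]:
    """Per-edge attention logits e and transformed features Z = H W.

    a^T [W h_i ‖ W h_j] splits as a_dst·Wh_i + a_src·Wh_j with
    a = [a_dst ; a_src] (i the aggregating node, j the neighbor).
    """
    h = W.shape[1]
    Z = ad.matmul(H, W)
    # keep the split differentiable: slice via matmul with constant selectors
    sel_dst = np.zeros((2 * h, h)); sel_dst[:h, :] = np.eye(h)
    sel_src = np.zeros((2 * h, h)); sel_src[h:, :] = np.eye(h)
    a_dst = ad.matmul(Tensor(sel_dst.T), a)   # (h, 1)
    a_src = ad.matmul(Tensor(sel_src.T), a)
    s_dst = ad.matmul(Z, a_dst)               # (n, 1)
    s_src = ad.matmul(Z, a_src)
    e = ad.leaky_relu(
        ad.add(ad.gather(s_dst, batch.edge_dst, batch.scatter_dst),
               ad.gather(s_src, batch.edge_src, batch.scatter_src)),
        slope=LEAKY_SLOPE)
    return e, Z


def _segment_softmax(e: Tensor, batch: SubgraphBatch) -> Tensor:
    """Softmax of edge logits within each destination-node segment."""
    seg, n_seg = batch.edge_dst, batch.n_nodes
    shift = np.full(n_seg, -np.inf)
    np.maximum.at(shift, seg, e.value.ravel())
    shift = np.where(np.isfinite(shift), shift, 0.0)  # nodes w/o edges
    ex = ad.exp(ad.sub(e, shift[seg][:, None]))
    denom = ad.segment_sum(ex, seg, n_seg, batch.scatter_dst)
    return ad.div(ex, ad.gather(denom, seg, batch.scatter_dst))


def _gat_layer(H: Tensor, batch: SubgraphBatch, Ws: Sequence[Tensor],
               avs: Sequence[Tensor], activation: bool = True) -> Tensor:
    """One (possibly multi-head, averaged) GAT layer."""
    outs = []
    for W, a in zip(Ws, avs):
        e, Z = _gat_edge_logits(H, batch, W, a)
        alpha = _segment_softmax(e, batch)
        msgs = ad.mul(alpha, ad.gather(Z, batch.edge_src, batch.scatter_src))
        agg = ad.segment_sum(msgs, batch.edge_dst, batch.n_nodes,
                             batch.scatter_dst)
        outs.append(agg)
    if len(outs) == 1:
        out = outs[0]
    else:
        acc = outs[0]
        for o in outs[1:]:
            acc = ad.add(acc, o)
        out = ad.mul(acc, 1.0 / len(outs))
    return ad.elu(out) if activation else out


def forward_scores(batch: SubgraphBatch, params: dict[str, Tensor],
                   config: ModelConfig, dropout_rng=None) -> Tensor:
    """Positive-class probability for every graph in the batch."""
    H = Tensor(batch.x)
    for k, kind in enumerate(config.layer_plan()):
        if kind == "gcn":
            H = _gcn_layer(H, batch, params[f"layer{k}.W"])
        else:
            Ws = [params[f"layer{k}.head{h}.W"]
                  for h in range(config.attention_heads)]
            avs = [params[f"layer{k}.head{h}.a"]
                   for h in range(config.attention_heads)]
            H = _gat_layer(H, batch, Ws, avs)
        if config.dropout > 0.0 and dropout_rng is not None:
            keep = (dropout_rng.random(H.shape) >= config.dropout)
            H = ad.mul(H, keep / (1.0 - config.dropout))
    f = ad.concat([ad.gather(H, batch.lnc_pos), ad.gather(H, batch.drug_pos)],
                  axis=1)
    logits = ad.add(ad.matmul(f, params["head.W"]), params["head.b"])
    # softmax over the 2 logits; return p_pos
    m = logits.value.max(axis=1, keepdims=True)
    ex = ad.exp(ad.sub(logits, m))
    denom = ad.matmul(ex, Tensor(np.ones((2, 1))))
    probs = ad.div(ex, denom)
    p_pos = ad.matmul(probs, Tensor(np.array([[0.0], [1.0]])))
    return p_pos  # (n_graphs, 1)


def bce_loss_t(scores: Tensor, labels: np.ndarray) -> Tensor:
    """Differentiable mean binary cross-entropy with clamped scores."""
    y = np.asarray(labels, float).reshape(scores.shape)
    p = ad.clip(scores, SCORE_EPS, 1.0 - SCORE_EPS)
    one_minus_p = ad.sub(np.ones_like(y), p)
    ll = ad.add(ad.mul(ad.log(p), y), ad.mul(ad.log(one_minus_p), 1.0 - y))
    return ad.neg(ad.mean(ll))


# --------------------------------------------- public per-subgraph surface

def _single_graph_batch(sg: EnclosingSubgraph, H: np.ndarray) -> SubgraphBatch:
    if H.shape[0] != sg.n_nodes:
        raise ValueError("feature row count does not match subgraph node count")
    return SubgraphBatch.from_graph_arrays(H, sg.edges, 0, 1)


def gcn_forward(H: np.ndarray, sg: EnclosingSubgraph, W: np.ndarray,
                activation: bool = True) -> np.ndarray:
    """One GCN layer on a single subgraph (self-loop-normalized, ReLU)."""
    if H.shape[1] != np.asarray(W).shape[0]:
        raise ValueError("feature width does not match W rows")
    batch = _single_graph_batch(sg, np.asarray(H, float))
    return _gcn_layer(Tensor(batch.x), batch, Tensor(W),
                      activation=activation).value


def gat_attention(H: np.ndarray, sg: EnclosingSubgraph, W: np.ndarray,
                  a: np.ndarray) -> np.ndarray:
    """Dense attention matrix α for one GAT layer on a single subgraph.

    Row i holds α_ij over j in N(i) ∪ {i} (zero elsewhere); every row
    sums to 1.
    """
    batch = _single_graph_batch(sg, np.asarray(H, float))
    e, _ = _gat_edge_logits(Tensor(batch.x), batch, Tensor(W),
                            Tensor(np.asarray(a, float).reshape(-1, 1)))
    alpha = _segment_softmax(e, batch)
    out = np.zeros((sg.n_nodes, sg.n_nodes))
    out[batch.edge_dst, batch.edge_src] = alpha.value.ravel()
    return out


def gat_forward(H: np.ndarray, sg: EnclosingSubgraph, W: np.ndarray,
                a: np.ndarray, activation: bool = True) -> np.ndarray:
    """One single-head GAT layer on a single subgraph (ELU activation)."""
    batch = _single_graph_batch(sg, np.asarray(H, float))
    return _gat_layer(Tensor(batch.x), batch, [Tensor(W)],
                      [Tensor(np.asarray(a, float).reshape(-1, 1))],
                      activation=activation).value


def score_pair(sg: EnclosingSubgraph, features: NodeFeatureMatrix,
               params: dict[str, Tensor], config: ModelConfig) -> float:
    """Full forward pass on one subgraph; returns p_pos in [0, 1]."""
    batch = SubgraphBatch.from_subgraphs([sg], [features])
    return float(forward_scores(batch, params, config).value[0, 0])


def bce_loss(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mean binary cross-entropy with scores clamped to (0, 1)."""
    p = np.clip(np.asarray(scores, float), SCORE_EPS, 1.0 - SCORE_EPS)
    y = np.asarray(labels, float)
    if p.shape != y.shape:
        y = y.reshape(p.shape)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


# ---------------------------------------------------------------- training

class AdamOptimizer:
    """Standard Adam with bias correction."""

    def __init__(self, params: dict[str, Tensor], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(p.value) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.value) for k, p in params.items()}
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            g = p.grad if p.grad is not None else np.zeros_like(p.value)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g ** 2
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.value = p.value - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


def train_network(
    sgs: Sequence[EnclosingSubgraph],
    feats: Sequence[NodeFeatureMatrix],
    labels: np.ndarray,
    config: ModelConfig,
    rng: np.random.Generator,
    params: dict[str, Tensor] | None = None,
) -> tuple[dict[str, Tensor], list[float]]:
    """Minibatch Adam training of the scoring network.

    Returns the trained parameters and the per-epoch mean training
    loss.  ``rng`` drives initialization, shuffling and dropout; pass
    the same generator state for bit-identical runs.
    """
    labels = np.asarray(labels, float)
    in_dim = feats[0].rows.shape[1]
    if params is None:
        params = init_parameters(config, in_dim, rng)
    opt = AdamOptimizer(params, config.learning_rate)
    n = len(sgs)
    # batch membership is fixed once (random), batch order reshuffled
    # per epoch; batches are prebuilt so the disjoint-union graphs and
    # their scatter matrices are reused across epochs
    perm = rng.permutation(n)
    batches = []
    for start in range(0, n, config.batch_size):
        idx = perm[start:start + config.batch_size]
        batches.append((
            SubgraphBatch.from_subgraphs([sgs[i] for i in idx],
                                         [feats[i] for i in idx]),
            labels[idx], len(idx)))
    history: list[float] = []
    for _ in range(config.epochs):
        epoch_loss = 0.0
        for b in rng.permutation(len(batches)):
            batch, y, sz = batches[b]
            opt.zero_grad()
            scores = forward_scores(batch, params, config,
                                    dropout_rng=rng if config.dropout else None)
            loss = bce_loss_t(scores, y)
            loss.backward()
            opt.step()
            epoch_loss += float(loss.value) * sz
        history.append(epoch_loss / n)
    return params, history


def predict_scores(
    sgs: Sequence[EnclosingSubgraph],
    feats: Sequence[NodeFeatureMatrix],
    params: dict[str, Tensor],
    config: ModelConfig,
    batch_size: int = 256,
) -> np.ndarray:
    """Scores for a list of subgraphs, batched for speed."""
    out = np.empty(len(sgs))
    for start in range(0, len(sgs), batch_size):
        chunk = slice(start, start + batch_size)
        batch = SubgraphBatch.from_subgraphs(sgs[chunk], feats[chunk])
        out[chunk] = forward_scores(batch, params, config).value.ravel()
    return out
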