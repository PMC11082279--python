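"""Node features: PCA-reduced similarity profiles plus role one-hots.

Each entity's raw feature vector is its row of the GIP similarity
matrix (length m for lncRNAs, n for drugs).  PCA reduces these to a
lncRNAs and b drug dimensions; a per-subgraph node feature row is then

    [ one-hot(role label, 4) | lncRNA block (a) | drug block (b) ]

of fixed width 4 + a + b, where the block of the other side is
zero-filled so lncRNA and drug nodes share one feature space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .similarity import SimilarityMatrix
from .subgraph import EnclosingSubgraph, N_ROLE_LABELS

__all__ = ["ReducedFeatures", "NodeFeatureMatrix", "pca_reduce",
           "assemble_node_features"]


@dataclass(frozen=True)
class ReducedFeatures:
    """k x d PCA scores, one row per entity, deterministic sign."""

    components: np.ndarray
    d: int

    def __post_init__(self) -> None:
        c = np.asarray(self.components, dtype=float)
        if c.ndim != 2 or c.shape[1] != self.d:
            raise ValueError("components must be k x d")
        object.__setattr__(self, "components", c)

    @property
    def k(self) -> int:
        return self.components.shape[0]


@dataclass(frozen=True)
class NodeFeatureMatrix:
    """Per-subgraph node feature rows of width 4 + a + b."""

    rows: np.ndarray
    a: int
    b: int

    @property
    def width(self) -> int:
        return N_ROLE_LABELS + self.a + self.b


def pca_reduce(sim: SimilarityMatrix | np.ndarray, dim: int) -> ReducedFeatures:
    """Project mean-centered similarity rows onto the top-d principal axes.

    ``d`` is capped at the feasible maximum min(dim, k-1): after mean
    centering, k points span at most k-1 dimensions.  Each component's
    sign is fixed so its largest-magnitude loading is positive, making
    the output deterministic (eigenvector signs are otherwise
    arbitrary).
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    X = sim.matrix if isinstance(sim, SimilarityMatrix) else np.asarray(sim, float)
    k = X.shape[0]
    d = max(1, min(int(dim), k - 1)) if k > 1 else 1
    if k == 1:
        # single entity: centered data is identically zero
        return ReducedFeatures(np.zeros((1, 1)), 1)
    pca = PCA(n_components=d, svd_solver="full")
    scores = pca.fit_transform(X)
    # deterministic sign: largest-|loading| coordinate of each axis positive
    load = pca.components_
    flip = np.sign(load[np.arange(d), np.argmax(np.abs(load), axis=1)])
    flip[flip == 0] = 1.0
    return ReducedFeatures(scores * flip, d)


def assemble_node_features(
    sg: EnclosingSubgraph,
    lnc_feats: ReducedFeatures,
    drug_feats: ReducedFeatures,
) -> NodeFeatureMatrix:
    """Stack per-node feature rows for a subgraph, in subgraph node order."""
    a, b = lnc_feats.d, drug_feats.d
    width = N_ROLE_LABELS + a + b
    rows = np.zeros((sg.n_nodes, width))
    rows[np.arange(sg.n_nodes), sg.labels] = 1.0
    for pos, (side, idx) in enumerate(zip(sg.sides, sg.indices)):
        if side == 0:
            if idx >= lnc_feats.k:
                raise ValueError(f"no feature row for lncRNA index {idx}")
            rows[pos, N_ROLE_LABELS:N_ROLE_LABELS + a] = lnc_feats.components[idx]
        else:
            if idx >= drug_feats.k:
                raise ValueError(f"no feature row for drug index {idx}")
            rows[pos, N_ROLE_LABELS + a:] = drug_feats.components[idx]
    return NodeFeatureMatrix(rows, a, b)
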