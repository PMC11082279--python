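"""Bipartite association graph and labeled one-hop enclosing subgraphs.

Every candidate (lncRNA, drug) pair is scored from the subgraph that
encloses it: the pair itself plus the one-hop neighbors of each side,
with the induced bipartite edges.  Node labels record structural roles
relative to the target pair:

    0  target lncRNA          1  target drug
    2  drug neighbor of the target lncRNA (2i with hop order i = 1)
    3  lncRNA neighbor of the target drug (2i+1 with i = 1)

Target labels take priority when a neighbor coincides with the other
target, so each node carries exactly one label.  For positive pairs the
target edge is removed from the subgraph by default, so the instance
does not contain its own label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .io import AssociationMatrix

__all__ = ["BipartiteGraph", "EnclosingSubgraph", "build_bipartite_graph",
           "extract_subgraph"]

LABEL_TARGET_LNC = 0
LABEL_TARGET_DRUG = 1
LABEL_NEIGHBOR_DRUG = 2
LABEL_NEIGHBOR_LNC = 3
N_ROLE_LABELS = 4


class BipartiteGraph:
    """Undirected bipartite graph between lncRNA and drug nodes.

    Edges are exactly the nonzero cells of the association matrix; the
    partition is implicit in the (side, index) node addressing used
    throughout (side 0 = lncRNA, side 1 = drug).
    """

    def __init__(self, matrix: np.ndarray):
        mat = np.asarray(matrix)
        if mat.ndim != 2 or not np.isin(mat, (0, 1)).all():
            raise ValueError("need a binary 2-D association matrix")
        self._csr = sparse.csr_matrix(mat)          # lnc -> drugs
        self._csc = sparse.csc_matrix(mat)          # drug -> lncs
        self.n_lnc, self.n_drug = mat.shape

    @property
    def n_edges(self) -> int:
        return int(self._csr.nnz)

    def drug_neighbors(self, li: int) -> np.ndarray:
        """Sorted drug indices adjacent to lncRNA ``li``."""
        if not 0 <= li < self.n_lnc:
            raise IndexError(f"unknown lncRNA node index: {li}")
        return self._csr.indices[self._csr.indptr[li]:self._csr.indptr[li + 1]]

    def lnc_neighbors(self, dj: int) -> np.ndarray:
        """Sorted lncRNA indices adjacent to drug ``dj``."""
        if not 0 <= dj < self.n_drug:
            raise IndexError(f"unknown drug node index: {dj}")
        return self._csc.indices[self._csc.indptr[dj]:self._csc.indptr[dj + 1]]

    def has_edge(self, li: int, dj: int) -> bool:
        return dj in self.drug_neighbors(li)

    def edge_set(self) -> set[tuple[int, int]]:
        """All edges as (lnc index, drug index) pairs."""
        coo = self._csr.tocoo()
        return set(zip(coo.row.tolist(), coo.col.tolist()))


@dataclass(frozen=True)
class EnclosingSubgraph:
    """Labeled one-hop enclosing subgraph of a target (lncRNA, drug) pair.

    Nodes are stored in a fixed deterministic order: target lncRNA
    (local 0), target drug (local 1), then drug neighbors of the target
    lncRNA in ascending index order, then lncRNA neighbors of the
    target drug in ascending order.  ``edges`` are (lnc-local,
    drug-local) pairs of the induced bipartite edges.
    """

    target_lnc: int
    target_drug: int
    sides: np.ndarray      # 0 = lncRNA node, 1 = drug node, per local node
    indices: np.ndarray    # entity index per local node
    labels: np.ndarray     # role label per local node, in {0, 1, 2, 3}
    edges: np.ndarray      # (n_edges, 2) local index pairs (lnc_node, drug_node)
    target_edge_removed: bool

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    def node_ids(self) -> list[tuple[int, int]]:
        """Nodes as (side, entity index) pairs in local order."""
        return list(zip(self.sides.tolist(), self.indices.tolist()))


def build_bipartite_graph(assoc: AssociationMatrix | np.ndarray) -> BipartiteGraph:
    """Bipartite graph with one edge per known association."""
    mat = assoc.matrix if isinstance(assoc, AssociationMatrix) else assoc
    return BipartiteGraph(mat)


def extract_subgraph(
    G: BipartiteGraph,
    li: int,
    dj: int,
    remove_target_edge: bool = True,
) -> EnclosingSubgraph:
    """Extract the labeled one-hop enclosing subgraph of pair (li, dj).

    The node set is {li, dj} plus the one-hop neighbors of each target;
    the edge set is the induced bipartite subgraph, minus the
    (li, dj) edge itself when ``remove_target_edge`` is set (the
    default: a scored instance must not contain its own label).
    """
    drug_nb = G.drug_neighbors(li)       # validates li
    lnc_nb = G.lnc_neighbors(dj)         # validates dj
    # neighbors that coincide with a target keep the target label/slot
    drug_nb = drug_nb[drug_nb != dj]
    lnc_nb = lnc_nb[lnc_nb != li]

    sides = np.concatenate([[0, 1],
                            np.ones(len(drug_nb), dtype=int),
                            np.zeros(len(lnc_nb), dtype=int)])
    indices = np.concatenate([[li, dj], drug_nb, lnc_nb])
    labels = np.concatenate([[LABEL_TARGET_LNC, LABEL_TARGET_DRUG],
                             np.full(len(drug_nb), LABEL_NEIGHBOR_DRUG),
                             np.full(len(lnc_nb), LABEL_NEIGHBOR_LNC)])

    # local lookup per side
    lnc_local = {li: 0}
    lnc_local.update({int(v): 2 + len(drug_nb) + k for k, v in enumerate(lnc_nb)})
    drug_local = {dj: 1}
    drug_local.update({int(v): 2 + k for k, v in enumerate(drug_nb)})

    edges = []
    for lv, lloc in lnc_local.items():
        for dv in G.drug_neighbors(lv):
            dloc = drug_local.get(int(dv))
            if dloc is None:
                continue
            if remove_target_edge and lv == li and dv == dj:
                continue
            edges.append((lloc, dloc))
    edges_arr = (np.array(sorted(edges), dtype=int)
                 if edges else np.empty((0, 2), dtype=int))
    return EnclosingSubgraph(
        target_lnc=li,
        target_drug=dj,
        sides=sides.astype(int),
        indices=indices.astype(int),
        labels=labels.astype(int),
        edges=edges_arr,
        target_edge_removed=bool(remove_target_edge),
    )
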