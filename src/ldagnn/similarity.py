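"""Gaussian interaction profile (GIP) kernel similarities.

Each lncRNA is described by its interaction profile IP(l_i) — row i of
the binary association matrix LD — and each drug by column j.  The GIP
kernel similarity between two entities is a Gaussian of the Euclidean
distance between their profiles,

    S[i, j] = exp(-r * ||IP(i) - IP(j)||^2),

with the bandwidth r set to the reciprocal of the mean squared profile
norm over all entities on that axis (rl for lncRNAs, rd for drugs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .io import AssociationMatrix

__all__ = [
    "SimilarityMatrix",
    "gip_bandwidth",
    "gip_similarity",
    "lncrna_similarity",
    "drug_similarity",
]


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric k x k GIP kernel matrix with unit diagonal."""

    matrix: np.ndarray
    entity_axis: str  # "lncRNA" | "drug"
    bandwidth: float

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("similarity matrix must be square")
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        object.__setattr__(self, "matrix", m)

    @property
    def k(self) -> int:
        return self.matrix.shape[0]

    def to_csv(self, path, ids=None) -> None:
        """Dense CSV dump with an id header row/column."""
        import pandas as pd

        ids = list(ids) if ids is not None else [str(i) for i in range(self.k)]
        pd.DataFrame(self.matrix, index=ids, columns=ids).to_csv(path)

    @classmethod
    def from_csv(cls, path, entity_axis: str, bandwidth: float) -> "SimilarityMatrix":
        import pandas as pd

        m = pd.read_csv(path, index_col=0).to_numpy(dtype=float)
        return cls(m, entity_axis, bandwidth)


def _check_profiles(profiles: np.ndarray) -> np.ndarray:
    p = np.asarray(profiles)
    if p.ndim != 2:
        raise ValueError("profiles must be a 2-D array (one row per entity)")
    if not np.isin(p, (0, 1)).all():
        raise ValueError("profiles must be binary (rows/columns of LD)")
    return p.astype(float)


def gip_bandwidth(profiles: np.ndarray) -> float:
    """Kernel bandwidth: 1 / mean squared Euclidean norm of the profiles.

    Raises
    ------
    ValueError
        If every profile is all-zero (empty association matrix), in
        which case the bandwidth is undefined.
    """
    p = _check_profiles(profiles)
    mean_sq = float(np.mean((p ** 2).sum(axis=1)))
    if mean_sq == 0.0:
        raise ValueError("empty association matrix; GIP bandwidth undefined")
    return 1.0 / mean_sq


def gip_similarity(
    profiles: np.ndarray,
    bandwidth: float | None = None,
    entity_axis: str = "lncRNA",
) -> SimilarityMatrix:
    """GIP kernel matrix over binary profiles.

    When ``bandwidth`` is None it is computed from the same profiles
    via :func:`gip_bandwidth`.
    """
    p = _check_profiles(profiles)
    if bandwidth is None:
        bandwidth = gip_bandwidth(p)
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    if p.shape[0] == 1:
        sq = np.zeros((1, 1))
    else:
        sq = squareform(pdist(p, metric="sqeuclidean"))
    mat = np.exp(-bandwidth * sq)
    np.fill_diagonal(mat, 1.0)
    # enforce exact symmetry against round-off
    mat = (mat + mat.T) / 2.0
    return SimilarityMatrix(mat, entity_axis, float(bandwidth))


def lncrna_similarity(assoc: AssociationMatrix) -> SimilarityMatrix:
    """LS: GIP similarity over rows of LD (lncRNA interaction profiles)."""
    return gip_similarity(assoc.matrix, entity_axis="lncRNA")


def drug_similarity(assoc: AssociationMatrix) -> SimilarityMatrix:
    """DS: GIP similarity over columns of LD (drug interaction profiles)."""
    return gip_similarity(assoc.matrix.T, entity_axis="drug")
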