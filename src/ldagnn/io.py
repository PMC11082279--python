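"""Edge-list input/output and the indexed binary association matrix.

The association data is a two-column table of (lncRNA id, drug id)
pairs, one known association per row.  It is materialised as a binary
incidence matrix ``LD`` (rows = lncRNAs, columns = drugs) with both
axes sorted lexicographically so construction is deterministic across
runs and platforms.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["AssociationMatrix", "read_associations", "write_rankings"]

#: header tokens recognised when sniffing a header row
_HEADER_TOKENS = {
    "lncrna", "lncrna_id", "lnc", "lnc_id", "lncrnas",
    "drug", "drug_id", "drugs", "compound", "score", "label",
}


@dataclass(frozen=True, eq=False)
class AssociationMatrix:
    """Binary m x n lncRNA-by-drug incidence matrix with id maps.

    Attributes
    ----------
    matrix : ndarray of shape (m, n)
        ``matrix[i, j] == 1`` iff lncRNA ``lnc_ids[i]`` is associated
        with drug ``drug_ids[j]``.
    lnc_ids, drug_ids : tuple of str
        Unique identifiers, sorted lexicographically.
    """

    matrix: np.ndarray
    lnc_ids: tuple[str, ...]
    drug_ids: tuple[str, ...]
    _lnc_index: dict = field(default=None, repr=False, compare=False)
    _drug_index: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        mat = np.asarray(self.matrix)
        if mat.ndim != 2:
            raise ValueError("association matrix must be 2-D")
        if not np.isin(mat, (0, 1)).all():
            raise ValueError("association matrix entries must be 0 or 1")
        if mat.shape != (len(self.lnc_ids), len(self.drug_ids)):
            raise ValueError("matrix shape does not match id lists")
        if len(set(self.lnc_ids)) != len(self.lnc_ids):
            raise ValueError("duplicate lncRNA identifiers")
        if len(set(self.drug_ids)) != len(self.drug_ids):
            raise ValueError("duplicate drug identifiers")
        object.__setattr__(self, "matrix", mat.astype(np.int8))
        object.__setattr__(self, "lnc_ids", tuple(self.lnc_ids))
        object.__setattr__(self, "drug_ids", tuple(self.drug_ids))
        object.__setattr__(
            self, "_lnc_index", {s: i for i, s in enumerate(self.lnc_ids)})
        object.__setattr__(
            self, "_drug_index", {s: i for i, s in enumerate(self.drug_ids)})

    def __eq__(self, other) -> bool:
        if not isinstance(other, AssociationMatrix):
            return NotImplemented
        return (self.lnc_ids == other.lnc_ids
                and self.drug_ids == other.drug_ids
                and np.array_equal(self.matrix, other.matrix))

    def __hash__(self) -> int:
        return hash((self.lnc_ids, self.drug_ids, self.matrix.tobytes()))

    # -- constructors ---------------------------------------------------
    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "AssociationMatrix":
        """Build the matrix from (lncRNA id, drug id) pairs.

        Duplicate pairs collapse to a single 1 (with a logged warning),
        matching how merged association tables are deduplicated.
        """
        pairs = [(str(a), str(b)) for a, b in pairs]
        if not pairs:
            raise ValueError("no associations given")
        uniq = set(pairs)
        if len(uniq) < len(pairs):
            logger.warning(
                "collapsed %d duplicate association(s)", len(pairs) - len(uniq))
        lnc_ids = tuple(sorted({a for a, _ in uniq}))
        drug_ids = tuple(sorted({b for _, b in uniq}))
        li = {s: i for i, s in enumerate(lnc_ids)}
        di = {s: i for i, s in enumerate(drug_ids)}
        mat = np.zeros((len(lnc_ids), len(drug_ids)), dtype=np.int8)
        for a, b in uniq:
            mat[li[a], di[b]] = 1
        return cls(mat, lnc_ids, drug_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "AssociationMatrix":
        """Build from a DataFrame whose first two columns are the ids."""
        if df.shape[1] < 2:
            raise ValueError("need at least two columns (lncRNA id, drug id)")
        return cls.from_pairs(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))

    # -- accessors ------------------------------------------------------
    @property
    def n_lnc(self) -> int:
        return len(self.lnc_ids)

    @property
    def n_drug(self) -> int:
        return len(self.drug_ids)

    @property
    def n_positives(self) -> int:
        return int(self.matrix.sum())

    def lnc_index(self, lnc_id: str) -> int:
        try:
            return self._lnc_index[lnc_id]
        except KeyError:
            raise KeyError(f"unknown lncRNA id: {lnc_id!r}") from None

    def drug_index(self, drug_id: str) -> int:
        try:
            return self._drug_index[drug_id]
        except KeyError:
            raise KeyError(f"unknown drug id: {drug_id!r}") from None

    def positive_pairs(self) -> np.ndarray:
        """Index pairs (i, j) with ``matrix[i, j] == 1``, row-major order."""
        return np.argwhere(self.matrix == 1)

    def zero_pairs(self) -> np.ndarray:
        """Index pairs (i, j) of unknown (zero) cells, row-major order."""
        return np.argwhere(self.matrix == 0)

    def to_pairs(self) -> list[tuple[str, str]]:
        return [(self.lnc_ids[i], self.drug_ids[j]) for i, j in self.positive_pairs()]

    def to_edge_list(self, path, delimiter: str = "\t", header: bool = True) -> None:
        """Write the positive pairs as a 2-column edge list."""
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
            if header:
                w.writerow(["lncRNA_id", "drug_id"])
            for a, b in self.to_pairs():
                w.writerow([a, b])


def _sniff(first_line: str, delimiter: str | None) -> tuple[str, bool]:
    """Return (delimiter, has_header) for an edge-list file."""
    if delimiter is None:
        delimiter = "\t" if "\t" in first_line else ","
    fields = [f.strip().lower() for f in first_line.rstrip("\n").split(delimiter)]
    has_header = any(f in _HEADER_TOKENS for f in fields)
    return delimiter, has_header


def read_associations(path, delimiter: str | None = None) -> AssociationMatrix:
    """Read a 2-column (lncRNA id, drug id) edge list into a matrix.

    Headered or headerless TSV/CSV is auto-detected from the first line;
    pass ``delimiter`` explicitly to override sniffing.

    Raises
    ------
    FileNotFoundError
        If the file does not exist.
    ValueError
        On an empty file or a row with fewer than two fields (the error
        names the offending line number).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"association file not found: {path}")
    with open(path, newline="") as fh:
        first = fh.readline()
        if not first.strip():
            raise ValueError(f"empty association file: {path}")
        delimiter, has_header = _sniff(first, delimiter)
        fh.seek(0)
        reader = csv.reader(fh, delimiter=delimiter)
        pairs: list[tuple[str, str]] = []
        for lineno, row in enumerate(reader, start=1):
            if has_header and lineno == 1:
                continue
            if not row or (len(row) == 1 and not row[0].strip()):
                continue  # blank line
            if len(row) < 2:
                raise ValueError(
                    f"{path}:{lineno}: malformed row (need >=2 fields): {row!r}")
            pairs.append((row[0].strip(), row[1].strip()))
    if not pairs:
        raise ValueError(f"no association rows in {path}")
    return AssociationMatrix.from_pairs(pairs)


def write_rankings(records: Sequence[tuple[str, str, float]], path) -> None:
    """Write (lnc_id, drug_id, score) triples as a ranked TSV.

    Rows are sorted by score descending; ties break by (lnc_id, drug_id)
    ascending so output is deterministic.  Scores must be finite and in
    [0, 1].
    """
    rows = [(str(a), str(b), float(s)) for a, b, s in records]
    for a, b, s in rows:
        if not np.isfinite(s) or not (0.0 <= s <= 1.0):
            raise ValueError(f"score out of [0, 1] for pair ({a}, {b}): {s}")
    rows.sort(key=lambda r: (-r[2], r[0], r[1]))
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["lncRNA_id", "drug_id", "score"])
        for a, b, s in rows:
            w.writerow([a, b, f"{s:.6g}"])
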