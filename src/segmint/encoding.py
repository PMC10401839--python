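"""Roster validation and one-hot encoding into the co-occurrence matrix.

The clustering model consumes a binary individual x variable-level matrix
``n(i, v)``: within each variable's block of columns each row carries
exactly one 1, so every row sums to the number of variables (13 for the
default codebook).  Sex is a stratifier, never a column — separate models
are fitted per sex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codebook import SEXES, Codebook


class RosterError(ValueError):
    """Raised when a roster fails validation against the codebook."""


@dataclass
class CooccurrenceMatrix:
    """Binary individual x variable-level matrix with its labels.

    Attributes
    ----------
    n : (I, V) int8 array with entries in {0, 1}.
    row_ids : roster ids, in roster order.
    column_labels : ``variable:level`` labels, in codebook order.
    var_slices : per-variable column slice (the one-hot block).
    """

    n: np.ndarray
    row_ids: list
    column_labels: list[str]
    var_slices: dict[str, slice]

    @property
    def shape(self) -> tuple[int, int]:
        return self.n.shape

    def to_mtx(self, path, labels_path=None) -> None:
        """MatrixMarket export plus an optional labels sidecar CSV."""
        from scipy.io import mmwrite
        from scipy.sparse import csr_matrix

        mmwrite(str(path), csr_matrix(self.n))
        if labels_path is not None:
            pd.DataFrame(
                {
                    "axis": ["row"] * len(self.row_ids) + ["column"] * len(self.column_labels),
                    "index": list(range(len(self.row_ids))) + list(range(len(self.column_labels))),
                    "label": [str(r) for r in self.row_ids] + self.column_labels,
                }
            ).to_csv(labels_path, index=False)


def validate_roster(roster: pd.DataFrame, codebook: Codebook) -> None:
    """Check ids, sex values and level codes; raise :class:`RosterError` on failure."""
    if "id" not in roster.columns:
        raise RosterError("roster has no 'id' column")
    if roster["id"].duplicated().any():
        dup = roster.loc[roster["id"].duplicated(), "id"].iloc[0]
        raise RosterError(f"duplicate roster id {dup!r}")
    if "sex" in roster.columns:
        bad = set(roster["sex"].unique()) - set(SEXES)
        if bad:
            raise RosterError(f"invalid sex value(s) {sorted(bad)!r}; expected {SEXES}")
    for var in codebook.variables:
        if var not in roster.columns:
            raise RosterError(f"roster is missing variable column {var!r}")
        if roster[var].isna().any():
            rid = roster.loc[roster[var].isna(), "id"].iloc[0]
            raise RosterError(f"missing value for variable {var!r} at row id {rid!r}")
        valid = set(codebook.level_codes(var))
        mask = ~roster[var].isin(valid)
        if mask.any():
            row = roster.loc[mask].iloc[0]
            raise RosterError(
                f"row id {row['id']!r}: unknown level {row[var]!r} for variable {var!r}"
            )


def encode(roster: pd.DataFrame, codebook: Codebook) -> CooccurrenceMatrix:
    """One-hot expand each variable; columns in codebook order, rows in roster order."""
    validate_roster(roster, codebook)
    n_rows = len(roster)
    n_cols = codebook.n_levels_total
    mat = np.zeros((n_rows, n_cols), dtype=np.int8)
    var_slices: dict[str, slice] = {}
    start = 0
    for var in codebook.variables:
        codes = codebook.level_codes(var)
        stop = start + len(codes)
        var_slices[var] = slice(start, stop)
        idx = pd.Categorical(roster[var], categories=codes).codes
        mat[np.arange(n_rows), start + idx] = 1
        start = stop
    return CooccurrenceMatrix(
        n=mat,
        row_ids=list(roster["id"]),
        column_labels=codebook.column_labels(),
        var_slices=var_slices,
    )


def decode(matrix: CooccurrenceMatrix, codebook: Codebook) -> pd.DataFrame:
    """Reconstruct the roster variables from a one-hot matrix (round-trip of :func:`encode`)."""
    data: dict[str, list] = {"id": list(matrix.row_ids)}
    for var in codebook.variables:
        block = matrix.n[:, matrix.var_slices[var]]
        if not np.all(block.sum(axis=1) == 1):
            raise RosterError(f"matrix block for {var!r} is not one-hot")
        codes = np.asarray(codebook.level_codes(var))
        data[var] = list(codes[np.argmax(block, axis=1)])
    return pd.DataFrame(data)


def stratify_by_sex(roster: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition a roster into (male, female) sub-rosters, order preserved."""
    if "sex" not in roster.columns:
        raise RosterError("roster has no 'sex' column")
    bad = set(roster["sex"].unique()) - set(SEXES)
    if bad:
        raise RosterError(f"invalid sex value(s) {sorted(bad)!r}; expected {SEXES}")
    male = roster[roster["sex"] == "male"].reset_index(drop=True)
    female = roster[roster["sex"] == "female"].reset_index(drop=True)
    return male, female
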