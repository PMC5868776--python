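"""Weighted bipartite matrices and connectance.

Three network views of one interaction table: plant-herbivore (PH),
herbivore-enemy (HE), and the composite PHE matrix whose rows are the
producers (plants and herbivores) and columns the consumers (herbivores
and enemies), with the PH and HE count blocks filled and all other cells
structurally zero.  Empty rows and columns are deleted before computing
network-level metrics; structurally-zero cells inside retained rows and
columns stay in the connectance denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyNetworkError
from .webgen import InteractionTable

__all__ = ["build_matrices", "clean_matrix", "connectance", "ConnectanceValue"]


def _pair_counts(frame: pd.DataFrame, row_col: str, col_col: str) -> pd.DataFrame:
    sub = frame.dropna(subset=[row_col, col_col])
    if len(sub) == 0:
        return pd.DataFrame()
    mat = pd.crosstab(sub[row_col], sub[col_col])
    mat.index.name = None
    mat.columns.name = None
    return mat.astype(np.int64)


def clean_matrix(M: pd.DataFrame) -> pd.DataFrame:
    """Drop all-zero rows and columns (the pre-metric cleaning step)."""
    if M.size == 0:
        return M
    M = M.loc[M.sum(axis=1) > 0, :]
    return M.loc[:, M.sum(axis=0) > 0]


def build_matrices(table: InteractionTable) -> dict[str, pd.DataFrame]:
    """Weighted PH, HE and composite PHE matrices for one community.

    Cell weights are interaction event counts (individuals, not species
    co-occurrence).  Matrices are cleaned of empty rows/columns; a network
    with no events yields an empty (0x0) frame.
    """
    frame = table.frame
    ph = _pair_counts(frame, "plant_sp", "herb_sp")
    he = _pair_counts(frame, "herb_sp", "enemy_sp")

    if ph.size == 0 and he.size == 0:
        phe = pd.DataFrame()
    else:
        rows = list(ph.index) + [h for h in he.index if h not in ph.index]
        cols = list(ph.columns) + [e for e in he.columns if e not in ph.columns]
        phe = pd.DataFrame(0, index=rows, columns=cols, dtype=np.int64)
        if ph.size:
            phe.loc[ph.index, ph.columns] += ph
        if he.size:
            phe.loc[he.index, he.columns] += he.astype(np.int64)
        phe = clean_matrix(phe)

    return {"PH": clean_matrix(ph), "HE": clean_matrix(he), "PHE": phe}


@dataclass(frozen=True)
class ConnectanceValue:
    value: float
    links: int
    possible: int


def connectance(M: pd.DataFrame) -> ConnectanceValue:
    """Realized links / possible links of a cleaned bipartite matrix."""
    if M.size == 0:
        raise EmptyNetworkError("connectance undefined for an empty network")
    arr = M.to_numpy()
    links = int(np.count_nonzero(arr))
    possible = int(arr.shape[0] * arr.shape[1])
    return ConnectanceValue(value=links / possible, links=links, possible=possible)
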