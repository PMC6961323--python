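"""Jaccard drug-drug distances over significant-diagnosis sets.

Each drug is identified with the set of diagnoses it is significantly
associated with (a row of the binary association matrix); the distance
between two drugs is one minus the Jaccard similarity of their sets,

    d_J(d_i, d_j) = 1 - |d_i & d_j| / |d_i | d_j|.

Two empty sets get distance 0: drugs with no significant association are
mutually identical (and at distance 1 from every associated drug), so they
collect into one tight cluster downstream.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def jaccard_distance(set_i, set_j) -> float:
    """Jaccard distance between two diagnosis sets (any iterables)."""
    a, b = set(set_i), set(set_j)
    union = a | b
    if not union:
        return 0.0
    return 1.0 - len(a & b) / len(union)


def distance_matrix(binmat: pd.DataFrame) -> pd.DataFrame:
    """All pairwise Jaccard distances between rows of a 0/1 matrix.

    Returns a symmetric drugs x drugs DataFrame with zero diagonal, values
    in [0, 1], and the empty-empty convention above.
    """
    if len(binmat) < 2:
        raise ValueError("need at least 2 drugs to build a distance matrix")
    B = (binmat.to_numpy() != 0).astype(np.float64)
    inter = B @ B.T
    sizes = B.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = 1.0 - np.where(union > 0, inter / np.where(union > 0, union, 1.0), 1.0)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, 1.0)
    out = pd.DataFrame(dist, index=binmat.index, columns=binmat.index)
    out.index.name = out.columns.name = "drug_code"
    return out
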