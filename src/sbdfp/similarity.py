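"""Tanimoto similarity and the three inter-dataset comparison methodologies.

Two compound sets can be compared (a) exhaustively, as the median Tanimoto
over all cross-set compound pairs (ACC, all-compound comparisons), or (b)
after condensing each set into a single fingerprint (DFP or SB-DFP) and
taking one Tanimoto value.  A similarity matrix over many sets is converted
to a distance matrix as distance = 1 - similarity for clustering, and its
value range serves as a resolution measure.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .builders import build_dfp, build_sbdfp, count_bits
from .core import (
    METHOD_DFP,
    METHOD_SBDFP,
    METHODOLOGY_ACC,
    BitCountProfile,
    BitMatrix,
    SimilarityMatrix,
    check_same_scheme,
)

__all__ = [
    "tanimoto",
    "tanimoto_matrix",
    "intra_set_median",
    "acc_similarity",
    "similarity_matrix",
    "to_distance",
    "matrix_range_summary",
]


def tanimoto(a, b, zero_zero: float = 0.0) -> float:
    """Tanimoto coefficient |a AND b| / |a OR b| of two binary vectors.

    The undefined 0/0 case (both vectors all-zero) returns ``zero_zero``,
    default 0: an empty fingerprint carries no shared features, and this
    keeps an all-zero condensed fingerprint from looking maximally similar
    to everything.  Pass ``zero_zero=1.0`` to match toolkits that use the
    other convention.
    """
    a = np.ravel(np.asarray(a, dtype=bool))
    b = np.ravel(np.asarray(b, dtype=bool))
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape[0]} vs {b.shape[0]}")
    union = int(np.count_nonzero(a | b))
    if union == 0:
        return float(zero_zero)
    return float(np.count_nonzero(a & b) / union)


def tanimoto_matrix(rows_a: np.ndarray, rows_b: np.ndarray) -> np.ndarray:
    """All-pairs Tanimoto between two stacks of binary fingerprints.

    Vectorised: intersections via an integer matrix product, unions from the
    row popcounts.  0/0 pairs get 0, consistent with :func:`tanimoto`.
    """
    a = np.asarray(rows_a, dtype=np.int64)
    b = np.asarray(rows_b, dtype=np.int64)
    inter = a @ b.T
    union = a.sum(axis=1)[:, None] + b.sum(axis=1)[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.where(union > 0, union, 1), 0.0)
    return sim


def intra_set_median(matrix: BitMatrix) -> float:
    """Median Tanimoto over all unordered distinct pairs within a set."""
    n = matrix.n_molecules
    if n < 2:
        raise ValueError("intra-set similarity needs at least 2 molecules")
    sim = tanimoto_matrix(matrix.rows, matrix.rows)
    iu = np.triu_indices(n, k=1)
    return float(np.median(sim[iu]))


def acc_similarity(mat_a: BitMatrix, mat_b: BitMatrix) -> float:
    """All-compound-comparisons similarity between two sets.

    Median Tanimoto over the full |A| x |B| cross product; a set compared
    against itself uses the intra-set median over distinct pairs (this is
    what populates the diagonal of an ACC matrix, and it need not be 1).
    """
    check_same_scheme(mat_a, mat_b)
    if mat_a is mat_b or (mat_a.ids == mat_b.ids and mat_a == mat_b):
        return intra_set_median(mat_a)
    return float(np.median(tanimoto_matrix(mat_a.rows, mat_b.rows)))


def similarity_matrix(
    datasets: Mapping[str, BitMatrix],
    methodology: str,
    reference_profile: BitCountProfile | None = None,
    alpha: float = 0.01,
    threshold: float = 0.5,
) -> SimilarityMatrix:
    """Pairwise similarity matrix over named compound sets.

    ``methodology`` is ``"ACC"`` (median Tanimoto over all cross-set
    compound pairs), ``"DFP"`` or ``"SB-DFP"`` (each set condensed once,
    then one Tanimoto per pair; diagonal exactly 1).  ``reference_profile``
    is required for SB-DFP.
    """
    names = list(datasets)
    if len(names) < 2:
        raise ValueError("need at least two datasets")
    mats = [datasets[k] for k in names]
    for m in mats[1:]:
        check_same_scheme(mats[0], m)
    scheme = mats[0].scheme_tag
    n = len(names)
    values = np.zeros((n, n))

    if methodology == METHODOLOGY_ACC:
        for i in range(n):
            values[i, i] = intra_set_median(mats[i])
            for j in range(i + 1, n):
                values[i, j] = values[j, i] = acc_similarity(mats[i], mats[j])
    elif methodology in (METHOD_DFP, METHOD_SBDFP):
        if methodology == METHOD_SBDFP:
            if reference_profile is None:
                raise ValueError("SB-DFP similarity requires a reference profile")
            fps = [
                build_sbdfp(count_bits(m), reference_profile, alpha=alpha).bits
                for m in mats
            ]
        else:
            fps = [build_dfp(count_bits(m), threshold=threshold).bits for m in mats]
        for i in range(n):
            values[i, i] = 1.0  # single-fingerprint self-comparison
            for j in range(i + 1, n):
                values[i, j] = values[j, i] = tanimoto(fps[i], fps[j])
    else:
        raise ValueError(f"unknown methodology {methodology!r}")

    return SimilarityMatrix(
        labels=names, values=values, methodology=methodology, scheme_tag=scheme
    )


def to_distance(sim: SimilarityMatrix) -> pd.DataFrame:
    """Distance matrix (1 - similarity) as a labelled square DataFrame."""
    if ((sim.values < 0) | (sim.values > 1)).any():
        raise ValueError("similarity values must lie in [0, 1]")
    return pd.DataFrame(1.0 - sim.values, index=sim.labels, columns=sim.labels)


def matrix_range_summary(
    sim: SimilarityMatrix, include_diagonal: bool = False
) -> dict[str, float]:
    """Min / average / max / range of a similarity matrix.

    Computed over the unique off-diagonal entries by default (the upper
    triangle); set ``include_diagonal`` to include self-similarities.  The
    range is a resolution measure: a methodology spreading sets over a wider
    similarity band discriminates between them better.
    """
    iu = np.triu_indices(sim.n, k=0 if include_diagonal else 1)
    vals = sim.values[iu]
    return {
        "min": float(vals.min()),
        "average": float(vals.mean()),
        "max": float(vals.max()),
        "range": float(vals.max() - vals.min()),
    }
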