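"""Intra-layer similarity matrices.

The lncRNA layer is weighted by the absolute Pearson correlation between
expression profiles; the protein layer by a symmetric degree-normalised
version of the weighted PPI score matrix, SP'(i,j) = SP(i,j)/sqrt(M(i,i)
M(j,j)) with M(j,j) the row sum of SP. Both matrices are symmetric, bounded
in [0, 1] and have a zero diagonal (self-loops would distort the walk).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data_io import ExpressionMatrix, NodeRegistry, WeightedPPITable

__all__ = ["LncSimilarityMatrix", "NormalizedPPIMatrix", "expression_similarity", "normalize_ppi"]


@dataclass(frozen=True)
class LncSimilarityMatrix:
    """n x n absolute-Pearson-correlation similarity between lncRNAs."""

    values: np.ndarray
    lncrna_ids: tuple[str, ...]


@dataclass(frozen=True)
class NormalizedPPIMatrix:
    """m x m symmetric-normalised weighted PPI matrix."""

    values: np.ndarray
    protein_ids: tuple[str, ...]


def expression_similarity(
    expr: ExpressionMatrix, registry: NodeRegistry | None = None
) -> LncSimilarityMatrix:
    """Absolute Pearson correlation between every pair of expression profiles.

    Zero-variance profiles have no defined correlation; such lncRNAs get
    similarity 0 to all others (with a warning). If ``registry`` is given the
    matrix is aligned to its lncRNA ordering, with all-zero rows for lncRNAs
    lacking an expression profile.

    Raises
    ------
    ValueError
        If fewer than 2 conditions are present.
    """
    x = np.asarray(expr.values, dtype=float)
    if x.shape[1] < 2:
        raise ValueError("expression similarity needs >=2 conditions per profile")
    sd = x.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        warnings.warn(
            f"{flat.size} zero-variance expression profile(s); similarity set to 0: "
            + ", ".join(expr.lncrna_ids[i] for i in flat[:5])
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        sl = np.abs(np.corrcoef(x))
    sl = np.atleast_2d(sl)
    sl[flat, :] = 0.0
    sl[:, flat] = 0.0
    np.clip(sl, 0.0, 1.0, out=sl)
    np.fill_diagonal(sl, 0.0)

    if registry is None:
        return LncSimilarityMatrix(sl, tuple(expr.lncrna_ids))

    n = registry.n_lncrnas
    out = np.zeros((n, n))
    idx = np.array([registry.lncrna_index(l) for l in expr.lncrna_ids])
    out[np.ix_(idx, idx)] = sl
    return LncSimilarityMatrix(out, registry.lncrna_ids)


def normalize_ppi(ppi: WeightedPPITable, registry: NodeRegistry) -> NormalizedPPIMatrix:
    """Symmetric normalisation of the weighted PPI score matrix.

    SP is assembled symmetric with zero diagonal from the edge list, then
    SP'(i,j) = SP(i,j)/sqrt(M(i,i) M(j,j)) with M(j,j) the j-th row sum of
    SP. Proteins with zero total score keep all-zero rows/columns. For an
    unweighted graph this reduces to 1/sqrt(d_i d_j).
    """
    m = registry.n_proteins
    sp = np.zeros((m, m))
    for a, b, s in ppi.edges:
        i, j = registry.protein_index(a), registry.protein_index(b)
        sp[i, j] = s
        sp[j, i] = s
    rowsum = sp.sum(axis=1)
    scale = np.zeros(m)
    nz = rowsum > 0
    scale[nz] = 1.0 / np.sqrt(rowsum[nz])
    spn = sp * scale[:, None] * scale[None, :]
    return NormalizedPPIMatrix(spn, registry.protein_ids)
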