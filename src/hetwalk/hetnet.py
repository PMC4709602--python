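"""Heterogeneous network assembly: interaction matrix, block transition
matrix and initial probability vectors for the restart walk.

The transition matrix W is laid out in blocks

    W = [ W_P   W_PL ]      proteins occupy indices 0..m-1,
        [ W_LP  W_L  ]      lncRNAs indices m..m+n-1,

where W_P and W_L are row-normalised intra-layer transitions, scaled by
(1 - gamma) whenever the node has a known cross-layer interaction, and
W_PL / W_LP distribute the jump probability gamma uniformly over a node's
known interaction partners. Every row sums to 1, except rows of fully
isolated nodes which sum to 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data_io import InteractionTable, NodeRegistry
from .similarity import LncSimilarityMatrix, NormalizedPPIMatrix

__all__ = [
    "RWRParams",
    "InteractionMatrix",
    "TransitionMatrix",
    "ProbabilityVector",
    "build_interaction_matrix",
    "build_transition_matrix",
    "build_initial_vector",
    "dump_transition_matrix",
]


@dataclass(frozen=True)
class RWRParams:
    """Walk parameters.

    delta : restart probability per step, in (0, 1]
    beta  : initial-mass weight of the lncRNA layer, in (0, 1)
    gamma : probability of jumping between layers along a known
            interaction, in (0, 1)
    tol   : L1 convergence tolerance on successive probability vectors
    """

    delta: float = 0.3
    beta: float = 0.5
    gamma: float = 0.5
    tol: float = 1e-10
    max_iter: int = 10_000

    def __post_init__(self) -> None:
        if not 0.0 < self.delta <= 1.0:
            raise ValueError(f"delta must be in (0, 1], got {self.delta}")
        if not 0.0 < self.beta < 1.0:
            raise ValueError(f"beta must be in (0, 1), got {self.beta}")
        if not 0.0 < self.gamma < 1.0:
            raise ValueError(f"gamma must be in (0, 1), got {self.gamma}")
        if not self.tol > 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass(frozen=True)
class InteractionMatrix:
    """Binary m x n matrix; rows are proteins, columns lncRNAs."""

    values: np.ndarray
    registry: NodeRegistry

    def with_edge_removed(self, protein_idx: int, lncrna_idx: int) -> "InteractionMatrix":
        v = self.values.copy()
        v[protein_idx, lncrna_idx] = 0
        return InteractionMatrix(v, self.registry)


@dataclass(frozen=True)
class TransitionMatrix:
    w_p: np.ndarray
    w_l: np.ndarray
    w_pl: np.ndarray
    w_lp: np.ndarray
    gamma: float

    @property
    def matrix(self) -> np.ndarray:
        """Assembled (m+n) x (m+n) transition matrix, protein indices first."""
        return np.block([[self.w_p, self.w_pl], [self.w_lp, self.w_l]])

    @property
    def n_proteins(self) -> int:
        return self.w_p.shape[0]

    @property
    def n_lncrnas(self) -> int:
        return self.w_l.shape[0]


@dataclass(frozen=True)
class ProbabilityVector:
    """Probability mass over the network, partitioned as (u proteins, v lncRNAs)."""

    u: np.ndarray
    v: np.ndarray

    @property
    def full(self) -> np.ndarray:
        return np.concatenate([self.u, self.v])

    @property
    def total(self) -> float:
        return float(self.u.sum() + self.v.sum())


def build_interaction_matrix(
    table: InteractionTable, registry: NodeRegistry
) -> InteractionMatrix:
    """Binary adjacency of known lncRNA-protein interactions."""
    values = np.zeros((registry.n_proteins, registry.n_lncrnas))
    for lid, pid in table.edges:
        values[registry.protein_index(pid), registry.lncrna_index(lid)] = 1.0
    return InteractionMatrix(values, registry)


def _layer_rows(
    intra: np.ndarray, cross_degree: np.ndarray, gamma: float
) -> tuple[np.ndarray, np.ndarray]:
    """Row-normalise one layer and split mass (1-gamma)/gamma where a node
    has cross-layer partners.

    Returns (intra_rows, cross_scale) where cross_scale[i] is the total mass
    the row sends across layers (gamma normally; 1 when the node has cross
    partners but no intra-layer neighbours; 0 when it has no cross partner).
    """
    rowsum = intra.sum(axis=1)
    has_intra = rowsum > 0
    has_cross = cross_degree > 0
    out = np.zeros_like(intra)
    out[has_intra] = intra[has_intra] / rowsum[has_intra, None]
    out[has_intra & has_cross] *= 1.0 - gamma
    cross_scale = np.where(has_cross, np.where(has_intra, gamma, 1.0), 0.0)
    return out, cross_scale


def build_transition_matrix(
    sl: LncSimilarityMatrix,
    sp: NormalizedPPIMatrix,
    imat: InteractionMatrix,
    gamma: float,
) -> TransitionMatrix:
    """Assemble the block transition matrix from the two intra-layer
    similarity matrices and the interaction matrix.

    A protein row with at least one lncRNA partner splits its mass
    (1-gamma) over PPI neighbours and gamma uniformly over its partner
    lncRNAs; a protein without partners stays inside the PPI layer.
    lncRNA rows are handled symmetrically. A node with cross partners but no
    intra-layer neighbour sends its entire mass across (the row must remain
    stochastic); a fully isolated node keeps an all-zero row.
    """
    i_vals = imat.values
    m, n = i_vals.shape
    if sp.values.shape != (m, m) or sl.values.shape != (n, n):
        raise ValueError(
            f"dimension mismatch: SP' {sp.values.shape}, SL {sl.values.shape}, I {i_vals.shape}"
        )
    p_deg = i_vals.sum(axis=1)  # lncRNA partners per protein
    l_deg = i_vals.sum(axis=0)  # protein partners per lncRNA

    w_p, p_cross = _layer_rows(sp.values, p_deg, gamma)
    w_l, l_cross = _layer_rows(sl.values, l_deg, gamma)

    w_pl = np.zeros((m, n))
    rows = p_deg > 0
    w_pl[rows] = i_vals[rows] / p_deg[rows, None] * p_cross[rows, None]

    w_lp = np.zeros((n, m))
    cols = l_deg > 0
    w_lp[cols] = i_vals.T[cols] / l_deg[cols, None] * l_cross[cols, None]

    return TransitionMatrix(w_p=w_p, w_l=w_l, w_pl=w_pl, w_lp=w_lp, gamma=gamma)


def build_initial_vector(
    query_lnc: int, imat: InteractionMatrix, beta: float
) -> ProbabilityVector:
    """Initial probability for a query lncRNA.

    The query gets mass beta in the lncRNA partition; its known partner
    proteins share mass (1 - beta) equally. A query with no known partner
    carries all mass itself (the vector always sums to 1).
    """
    m, n = imat.values.shape
    if not 0 <= query_lnc < n:
        raise IndexError(f"lncRNA index {query_lnc} out of range [0, {n})")
    seeds = imat.values[:, query_lnc] > 0
    u = np.zeros(m)
    v = np.zeros(n)
    if seeds.any():
        u[seeds] = (1.0 - beta) / seeds.sum()
        v[query_lnc] = beta
    else:
        v[query_lnc] = 1.0
    return ProbabilityVector(u=u, v=v)


def dump_transition_matrix(tm: TransitionMatrix, path: str | Path) -> None:
    """Debug dump of W as a Matrix Market sparse file."""
    from scipy import io as spio
    from scipy import sparse

    spio.mmwrite(str(path), sparse.coo_matrix(tm.matrix))
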