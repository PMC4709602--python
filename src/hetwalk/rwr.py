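"""Random walk with restart and candidate ranking.

The walk iterates Y_{t+1} = (1 - delta) W^T Y_t + delta Y_0 from Y_0 until
the L1 change between successive vectors falls below the tolerance. The map
is a contraction with factor (1 - delta), so convergence is guaranteed for
delta in (0, 1]. Candidate proteins for a query lncRNA are all proteins not
already known to interact with it, scored by the protein partition of the
stationary vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hetnet import InteractionMatrix, ProbabilityVector, RWRParams, TransitionMatrix
from .similarity import NormalizedPPIMatrix

__all__ = ["PropagationResult", "RankedPredictions", "propagate", "rank_candidates", "rwr_protein_baseline"]


@dataclass(frozen=True)
class PropagationResult:
    y_inf: ProbabilityVector
    iterations: int
    converged: bool
    final_delta: float


@dataclass(frozen=True)
class RankedPredictions:
    """Candidate proteins for one query, sorted by descending score.

    Ties break lexicographically on protein id; ranks are 1-based and
    consecutive.
    """

    query: str
    entries: tuple[tuple[str, float, int], ...]


def propagate(
    tm: TransitionMatrix, y0: ProbabilityVector, params: RWRParams
) -> PropagationResult:
    """Iterate the restart walk to its fixed point.

    Non-convergence within ``params.max_iter`` is reported via the
    ``converged`` flag, not an exception.
    """
    m = tm.n_proteins
    wt = np.ascontiguousarray(tm.matrix.T)
    start = y0.full
    delta = params.delta
    y = start.copy()
    change = np.inf
    iterations = 0
    for iterations in range(1, params.max_iter + 1):
        y_next = (1.0 - delta) * (wt @ y) + delta * start
        change = float(np.abs(y_next - y).sum())
        y = y_next
        if change < params.tol:
            break
    return PropagationResult(
        y_inf=ProbabilityVector(u=y[:m], v=y[m:]),
        iterations=iterations,
        converged=change < params.tol,
        final_delta=change,
    )


def rank_candidates(
    result: PropagationResult, imat: InteractionMatrix, query_lnc: int
) -> RankedPredictions:
    """Rank all proteins not already known to interact with the query.

    Scores are the protein-partition entries of the stationary vector
    (a constant scale factor does not change ranks).
    """
    registry = imat.registry
    known = imat.values[:, query_lnc] > 0
    scored = [
        (registry.protein_ids[i], float(result.y_inf.u[i]))
        for i in range(registry.n_proteins)
        if not known[i]
    ]
    scored.sort(key=lambda e: (-e[1], e[0]))
    entries = tuple((pid, s, rank) for rank, (pid, s) in enumerate(scored, start=1))
    return RankedPredictions(query=registry.lncrna_ids[query_lnc], entries=entries)


def rwr_protein_baseline(
    sp: NormalizedPPIMatrix,
    seeds: np.ndarray | list[int],
    delta: float,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> np.ndarray:
    """Plain restart walk on the PPI layer alone (single-layer comparison).

    The transition matrix is the row-normalised SP'; restart is to the
    uniform distribution over the seed proteins. Returns the stationary
    score of every protein.
    """
    seeds = np.asarray(seeds, dtype=int)
    if seeds.size == 0:
        raise ValueError("baseline walk needs at least one seed protein")
    mvals = sp.values
    rowsum = mvals.sum(axis=1)
    t = np.zeros_like(mvals)
    nz = rowsum > 0
    t[nz] = mvals[nz] / rowsum[nz, None]
    tt = t.T
    y0 = np.zeros(mvals.shape[0])
    y0[seeds] = 1.0 / seeds.size
    y = y0.copy()
    for _ in range(max_iter):
        y_next = (1.0 - delta) * (tt @ y) + delta * y0
        if np.abs(y_next - y).sum() < tol:
            return y_next
        y = y_next
    return y
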