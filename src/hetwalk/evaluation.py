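"""Leave-one-out cross-validation and the metric suite.

Each known lncRNA-protein interaction is hidden in turn; the network and
the initial vector for that trial are rebuilt without the hidden pair (the
hidden protein may remain a seed for *other* lncRNAs), and the method must
re-rank the hidden protein among the query's candidate proteins. Only
lncRNAs with at least two known partners contribute trials, so every trial
still has at least one seed protein.

Scores are pooled across trials into a single ROC curve; fold enrichment of
a trial with candidate-set size N and held-out rank n is N/(2n), with 1 the
random expectation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn import metrics as skmetrics

from .data_io import ExpressionMatrix, InteractionTable, NodeRegistry, WeightedPPITable
from .hetnet import (
    InteractionMatrix,
    ProbabilityVector,
    RWRParams,
    build_initial_vector,
    build_interaction_matrix,
    build_transition_matrix,
)
from .rwr import propagate, rank_candidates, rwr_protein_baseline
from .similarity import expression_similarity, normalize_ppi

__all__ = [
    "LoocvTrial",
    "ConfusionMetrics",
    "run_loocv",
    "roc_auc",
    "confusion_metrics",
    "confusion_from_counts",
    "precision_recall_at_k",
    "fold_enrichment",
    "percentile_retrieval",
    "randomized_baseline",
]


@dataclass(frozen=True)
class LoocvTrial:
    """One cross-validation trial: one hidden interaction."""

    query: str
    held_out: str
    rank_of_held_out: int
    n_candidates: int
    scores: tuple[tuple[str, float, int], ...]  # (protein id, score, label)
    seed_proteins: tuple[str, ...] = ()
    training_matrix: np.ndarray | None = field(default=None, compare=False)


@dataclass(frozen=True)
class ConfusionMetrics:
    threshold: float
    sn: float
    sp: float
    acc: float
    pre: float
    mcc: float
    no_positive_predictions: bool = False


def _pooled(trials: list[LoocvTrial]) -> tuple[np.ndarray, np.ndarray]:
    scores = np.array([s for t in trials for _, s, _ in t.scores])
    labels = np.array([lab for t in trials for _, _, lab in t.scores])
    return scores, labels


def retained_queries(imat: InteractionMatrix, min_partners: int = 2) -> list[int]:
    """Indices of lncRNAs with at least ``min_partners`` known partners."""
    return [int(j) for j in np.flatnonzero(imat.values.sum(axis=0) >= min_partners)]


def _prepare_network(
    interactions: InteractionTable,
    expression: ExpressionMatrix,
    ppi: WeightedPPITable,
):
    registry = NodeRegistry.from_tables(interactions, expression, ppi)
    sl = expression_similarity(expression, registry)
    sp = normalize_ppi(ppi, registry)
    imat = build_interaction_matrix(interactions, registry)
    return registry, sl, sp, imat


def run_loocv(
    interactions: InteractionTable,
    expression: ExpressionMatrix,
    ppi: WeightedPPITable,
    params: RWRParams,
    method: str = "hetwalk",
    keep_matrices: bool = False,
) -> list[LoocvTrial]:
    """One trial per known interaction of every lncRNA with >=2 partners.

    ``method`` is either ``"hetwalk"`` (the heterogeneous-network walk) or
    ``"ppi-rwr"`` (the single-layer PPI walk used as comparison baseline).
    """
    if method not in ("hetwalk", "ppi-rwr"):
        raise ValueError(f"unknown method {method!r}")
    registry, sl, sp, imat = _prepare_network(interactions, expression, ppi)
    queries = retained_queries(imat)
    if not queries:
        raise ValueError("no lncRNA has >=2 known protein partners; LOOCV impossible")

    trials: list[LoocvTrial] = []
    for q in queries:
        for p in np.flatnonzero(imat.values[:, q] > 0):
            trial_imat = imat.with_edge_removed(int(p), q)
            seeds = np.flatnonzero(trial_imat.values[:, q] > 0)
            if method == "hetwalk":
                tm = build_transition_matrix(sl, sp, trial_imat, params.gamma)
                y0 = build_initial_vector(q, trial_imat, params.beta)
                res = propagate(tm, y0, params)
                ranked = rank_candidates(res, trial_imat, q)
            else:
                y = rwr_protein_baseline(sp, seeds, params.delta, params.tol, params.max_iter)
                ranked = _rank_protein_scores(registry, q, y, seeds)
            held_id = registry.protein_ids[int(p)]
            trials.append(
                _make_trial(
                    query=registry.lncrna_ids[q],
                    held_id=held_id,
                    ranked=ranked.entries,
                    seed_ids=tuple(registry.protein_ids[i] for i in seeds),
                    training_matrix=trial_imat.values if keep_matrices else None,
                )
            )
    return trials


def _rank_protein_scores(registry, q, y, seed_idx):
    from .rwr import RankedPredictions

    seed_set = set(int(i) for i in seed_idx)
    scored = [
        (registry.protein_ids[i], float(y[i]))
        for i in range(registry.n_proteins)
        if i not in seed_set
    ]
    scored.sort(key=lambda e: (-e[1], e[0]))
    entries = tuple((pid, s, r) for r, (pid, s) in enumerate(scored, start=1))
    return RankedPredictions(query=registry.lncrna_ids[q], entries=entries)


def _make_trial(query, held_id, ranked, seed_ids, training_matrix=None) -> LoocvTrial:
    rank = next(r for pid, _, r in ranked if pid == held_id)
    return LoocvTrial(
        query=query,
        held_out=held_id,
        rank_of_held_out=rank,
        n_candidates=len(ranked),
        scores=tuple((pid, s, int(pid == held_id)) for pid, s, _ in ranked),
        seed_proteins=seed_ids,
        training_matrix=training_matrix,
    )


def roc_auc(trials: list[LoocvTrial]) -> tuple[float, np.ndarray]:
    """Pooled ROC over all trials; AUC by trapezoidal integration.

    Returns (auc, roc_points) with roc_points an array of (1-Sp, Sn) pairs.
    """
    if not trials:
        raise ValueError("no trials")
    scores, labels = _pooled(trials)
    if labels.min() == labels.max():
        raise ValueError("ROC undefined: all pooled labels identical")
    fpr, tpr, _ = skmetrics.roc_curve(labels, scores)
    return float(skmetrics.auc(fpr, tpr)), np.column_stack([fpr, tpr])


def confusion_from_counts(tp: int, fp: int, tn: int, fn: int) -> dict[str, float]:
    """Sensitivity, specificity, accuracy, precision and MCC from a
    confusion table; any zero denominator yields 0 for that metric."""
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / (tp + tn + fp + fn) if tp + tn + fp + fn else 0.0
    pre = tp / (tp + fp) if tp + fp else 0.0
    denom = (tp + fn) * (tp + fp) * (tn + fn) * (tn + fp)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
    return {"sn": sn, "sp": sp, "acc": acc, "pre": pre, "mcc": mcc}


def confusion_metrics(trials: list[LoocvTrial], sp_level: float) -> ConfusionMetrics:
    """Operating-point metrics at the threshold whose specificity is the
    closest achievable value >= ``sp_level`` on the pooled scores."""
    scores, labels = _pooled(trials)
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("confusion metrics undefined: one class absent")

    # cumulative counts when predicting positive for the top-k scores;
    # thresholds sit between distinct score values, plus the all-negative
    # point above the top score (Sp = 1 by construction)
    tp_cum = np.cumsum(sorted_labels)
    fp_cum = np.cumsum(1 - sorted_labels)
    distinct = np.flatnonzero(np.diff(sorted_scores, append=-np.inf) != 0)
    sp_vals = 1.0 - fp_cum[distinct] / n_neg
    feasible = np.flatnonzero(sp_vals >= sp_level)
    if feasible.size == 0:
        return ConfusionMetrics(
            threshold=float("inf"),
            no_positive_predictions=True,
            **confusion_from_counts(0, 0, n_neg, n_pos),
        )
    k = distinct[feasible[-1]]  # most positives while Sp >= sp_level
    tp, fp = int(tp_cum[k]), int(fp_cum[k])
    fn, tn = n_pos - tp, n_neg - fp
    vals = confusion_from_counts(tp, fp, tn, fn)
    return ConfusionMetrics(
        threshold=float(sorted_scores[k]),
        no_positive_predictions=(tp + fp) == 0,
        **vals,
    )


def precision_recall_at_k(
    trials: list[LoocvTrial], k_max: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pooled precision and recall of the top-k candidate slots, k = 1..k_max.

    precision@k = (trials whose hidden rank <= k) / (trials * k);
    recall@k    = (trials whose hidden rank <= k) / trials.
    """
    if not trials:
        raise ValueError("no trials")
    max_n = max(t.n_candidates for t in trials)
    if k_max > max_n:
        warnings.warn(f"k_max {k_max} exceeds candidate-set size; clamped to {max_n}")
        k_max = max_n
    ranks = np.array([t.rank_of_held_out for t in trials])
    ks = np.arange(1, k_max + 1)
    hits = (ranks[None, :] <= ks[:, None]).sum(axis=1)
    precision = hits / (len(trials) * ks)
    recall = hits / len(trials)
    return ks, precision, recall


def fold_enrichment(trials: list[LoocvTrial]) -> float:
    """Mean of N/(2n) over trials: candidate-set size over twice the rank."""
    return float(np.mean([t.n_candidates / (2.0 * t.rank_of_held_out) for t in trials]))


def percentile_retrieval(
    trials: list[LoocvTrial], percentiles: list[float]
) -> dict[float, int]:
    """Trials whose hidden rank falls within the top q% of candidates,
    with a ceiling cutoff so the bucket is never empty."""
    out: dict[float, int] = {}
    for q in percentiles:
        out[q] = sum(
            t.rank_of_held_out <= math.ceil(q * t.n_candidates / 100.0) for t in trials
        )
    return out


def randomized_baseline(
    interactions: InteractionTable,
    expression: ExpressionMatrix,
    ppi: WeightedPPITable,
    params: RWRParams,
    n_reps: int,
    seed: int,
) -> float:
    """Chance-level reference: LOOCV repeated with each query's seed
    proteins replaced by a uniformly random protein set of the same size.

    The random set excludes the trial's hidden protein, which therefore
    stays a pure candidate. The interaction matrix used to build the
    transition matrix keeps only the random pseudo-partners in the query's
    column (the randomisation rewires the query's interactions, not just the
    restart vector), so no true-partner signal survives for the query.
    Returns the mean pooled AUC over ``n_reps`` repetitions.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    registry, sl, sp, imat = _prepare_network(interactions, expression, ppi)
    queries = retained_queries(imat)
    if not queries:
        raise ValueError("no lncRNA has >=2 known protein partners")
    rng = np.random.default_rng(seed)
    m = registry.n_proteins

    pairs = [
        (q, int(p)) for q in queries for p in np.flatnonzero(imat.values[:, q] > 0)
    ]
    aucs = []
    for _ in range(n_reps):
        rep_trials: list[LoocvTrial] = []
        for q, p in pairs:
            n_seeds = int(imat.values[:, q].sum()) - 1
            pool = np.delete(np.arange(m), p)
            seeds = rng.choice(pool, size=n_seeds, replace=False)
            trial_imat = InteractionMatrix(imat.values.copy(), registry)
            trial_imat.values[:, q] = 0.0
            trial_imat.values[seeds, q] = 1.0
            tm = build_transition_matrix(sl, sp, trial_imat, params.gamma)
            y0 = build_initial_vector(q, trial_imat, params.beta)
            res = propagate(tm, y0, params)
            ranked = rank_candidates(res, trial_imat, q)
            rep_trials.append(
                _make_trial(
                    query=registry.lncrna_ids[q],
                    held_id=registry.protein_ids[p],
                    ranked=ranked.entries,
                    seed_ids=tuple(registry.protein_ids[i] for i in seeds),
                )
            )
        aucs.append(roc_auc(rep_trials)[0])
    return float(np.mean(aucs))
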