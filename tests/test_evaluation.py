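import numpy as np
import pytest
from scipy import stats

from hetwalk import evaluation as ev
from hetwalk.data_io import ExpressionMatrix, InteractionTable, WeightedPPITable
from hetwalk.hetnet import RWRParams


def make_trial(ranks_scores, held="H", query="L"):
    """Build a trial from (pid, score) pairs; the held-out protein is 'H'."""
    entries = sorted(ranks_scores, key=lambda e: (-e[1], e[0]))
    scores = tuple((pid, s, int(pid == held)) for pid, s in entries)
    rank = next(i for i, (pid, _) in enumerate(entries, 1) if pid == held)
    return ev.LoocvTrial(
        query=query,
        held_out=held,
        rank_of_held_out=rank,
        n_candidates=len(entries),
        scores=scores,
    )


def small_tables():
    """3 lncRNAs with 3, 2 and 1 partner proteins among 4 proteins."""
    interactions = InteractionTable(
        (
            ("L1", "P1"), ("L1", "P2"), ("L1", "P3"),
            ("L2", "P1"), ("L2", "P4"),
            ("L3", "P2"),
        )
    )
    rng = np.random.default_rng(7)
    expression = ExpressionMatrix(
        ("L1", "L2", "L3"),
        tuple(f"T{i}" for i in range(6)),
        rng.standard_normal((3, 6)),
    )
    ppi = WeightedPPITable(
        (("P1", "P2", 0.8), ("P2", "P3", 0.6), ("P3", "P4", 0.9), ("P1", "P4", 0.5))
    )
    return interactions, expression, ppi


def test_loocv_filters_single_partner_lncrnas_and_counts_trials():
    trials = ev.run_loocv(*small_tables(), RWRParams())
    assert len(trials) == 5  # 3 + 2 trials; L3 (one partner) excluded
    assert all(t.query in ("L1", "L2") for t in trials)


def test_loocv_candidate_set_size():
    trials = ev.run_loocv(*small_tables(), RWRParams())
    for t in trials:
        # N = m - (remaining training partners of the query)
        assert t.n_candidates == 4 - len(t.seed_proteins)
        assert t.held_out not in t.seed_proteins
        assert 1 <= t.rank_of_held_out <= t.n_candidates


def test_loocv_hides_the_held_out_pair_from_the_training_matrix():
    interactions, expression, ppi = small_tables()
    trials = ev.run_loocv(interactions, expression, ppi, RWRParams(), keep_matrices=True)
    from hetwalk.data_io import NodeRegistry

    reg = NodeRegistry.from_tables(interactions, expression, ppi)
    for t in trials:
        i = reg.protein_index(t.held_out)
        j = reg.lncrna_index(t.query)
        assert t.training_matrix[i, j] == 0


def test_loocv_errors_when_no_lncrna_passes_filter():
    interactions = InteractionTable((("L1", "P1"), ("L2", "P2")))
    _, expression, ppi = small_tables()
    expression = ExpressionMatrix(("L1", "L2"), expression.condition_labels, expression.values[:2])
    with pytest.raises(ValueError, match=">=2"):
        ev.run_loocv(interactions, expression, ppi, RWRParams())


def test_loocv_rejects_unknown_method():
    with pytest.raises(ValueError, match="unknown method"):
        ev.run_loocv(*small_tables(), RWRParams(), method="prince")


def test_ppi_rwr_method_excludes_seeds_from_candidates():
    trials = ev.run_loocv(*small_tables(), RWRParams(), method="ppi-rwr")
    assert len(trials) == 5
    for t in trials:
        assert t.held_out not in t.seed_proteins
        assert all(pid not in t.seed_proteins for pid, _, _ in t.scores)


def test_perfect_ranking_gives_auc_one():
    trials = [make_trial([("H", 0.9), ("A", 0.1), ("B", 0.05)]) for _ in range(3)]
    auc, points = ev.roc_auc(trials)
    assert auc == 1.0
    assert points[:, 0].max() <= 1 and points[:, 1].max() <= 1


def test_single_discordant_pair_gives_auc_three_quarters():
    # pooled positives {0.9, 0.5}, negatives {0.6, 0.4}: 3 of 4 pairs concordant
    trials = [
        make_trial([("H", 0.9), ("A", 0.4)]),
        make_trial([("H", 0.5), ("A", 0.6)]),
    ]
    auc, _ = ev.roc_auc(trials)
    assert auc == pytest.approx(0.75)


def test_auc_equals_mann_whitney_rank_statistic():
    # independent oracle: normalized rank-sum over pooled scores
    rng = np.random.default_rng(3)
    trials = []
    for _ in range(20):
        pairs = [(f"P{k}", float(rng.random())) for k in range(15)] + [
            ("H", float(rng.choice([0.2, 0.8])))
        ]
        trials.append(make_trial(pairs))
    scores = np.array([s for t in trials for _, s, _ in t.scores])
    labels = np.array([l for t in trials for _, _, l in t.scores])
    ranks = stats.rankdata(scores)
    n_pos, n_neg = labels.sum(), (1 - labels).sum()
    mw_auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    auc, _ = ev.roc_auc(trials)
    assert abs(auc - mw_auc) < 1e-10


def test_random_scores_give_chance_level_auc():
    rng = np.random.default_rng(11)
    trials = []
    for _ in range(400):
        pairs = [(f"P{k}", float(rng.random())) for k in range(20)]
        pairs.append(("H", float(rng.random())))
        trials.append(make_trial(pairs))
    auc, _ = ev.roc_auc(trials)
    assert auc == pytest.approx(0.5, abs=0.05)


def test_roc_requires_both_classes():
    t = make_trial([("H", 0.9)])
    with pytest.raises(ValueError, match="labels identical"):
        ev.roc_auc([t])


def test_confusion_counts_match_direct_arithmetic():
    # TP=3, FN=1, TN=4, FP=2, straight from the defining formulas
    out = ev.confusion_from_counts(tp=3, fp=2, tn=4, fn=1)
    assert out["sn"] == pytest.approx(0.75)
    assert out["sp"] == pytest.approx(2 / 3)
    assert out["acc"] == pytest.approx(0.7)
    assert out["pre"] == pytest.approx(0.6)
    assert out["mcc"] == pytest.approx((3 * 4 - 2 * 1) / np.sqrt(4 * 5 * 5 * 6))
    # independent cross-check of the MCC arithmetic
    from sklearn.metrics import matthews_corrcoef

    y_true = [1] * 3 + [1] + [0] * 4 + [0] * 2
    y_pred = [1] * 3 + [0] + [0] * 4 + [1] * 2
    assert out["mcc"] == pytest.approx(matthews_corrcoef(y_true, y_pred))


def test_perfect_classifier_metrics_all_one():
    out = ev.confusion_from_counts(tp=5, fp=0, tn=5, fn=0)
    assert all(out[k] == 1.0 for k in ("sn", "sp", "acc", "pre", "mcc"))


def test_all_negative_predictions_zero_out_pre_and_mcc():
    out = ev.confusion_from_counts(tp=0, fp=0, tn=6, fn=4)
    assert out["pre"] == 0.0 and out["mcc"] == 0.0


def test_confusion_metrics_pick_threshold_at_requested_specificity():
    # 2 positives at 0.9/0.5, 4 negatives at 0.6/0.4/0.3/0.2
    trials = [
        make_trial([("H", 0.9), ("A", 0.4), ("B", 0.3)]),
        make_trial([("H", 0.5), ("A", 0.6), ("B", 0.2)]),
    ]
    cm = ev.confusion_metrics(trials, sp_level=0.75)
    # threshold 0.5: TP=2, FP=1 -> Sp=0.75, the closest value >= 0.75
    assert cm.sp == pytest.approx(0.75)
    assert cm.sn == pytest.approx(1.0)
    assert not cm.no_positive_predictions
    strict = ev.confusion_metrics(trials, sp_level=1.0)
    # only the top score (a positive) is above all negatives -> Sp=1 with TP=1
    assert strict.sp == 1.0 and strict.sn == pytest.approx(0.5)


def test_confusion_metrics_flag_empty_positive_set():
    # top pooled score is a negative, so Sp = 1 forces zero predictions
    trials = [make_trial([("H", 0.5), ("A", 0.6)]), make_trial([("H", 0.4), ("B", 0.3)])]
    cm = ev.confusion_metrics(trials, sp_level=1.0)
    assert cm.no_positive_predictions
    assert cm.pre == 0.0 and cm.mcc == 0.0 and cm.sp == 1.0


def test_precision_recall_at_k():
    trials = [
        make_trial([("H", 0.9), ("A", 0.4), ("B", 0.3), ("C", 0.1), ("D", 0.05)]),
        make_trial([("A", 0.9), ("H", 0.4), ("B", 0.3), ("C", 0.1), ("D", 0.05)]),
        make_trial([("A", 0.9), ("B", 0.4), ("C", 0.3), ("D", 0.1), ("H", 0.05)]),
    ]
    ks, precision, recall = ev.precision_recall_at_k(trials, 5)
    assert recall[1] == pytest.approx(2 / 3)  # ranks {1,2,5}: two within top 2
    assert precision[0] == pytest.approx(1 / 3)
    assert np.all(np.diff(recall) >= 0)
    assert recall[-1] == 1.0


def test_precision_recall_at_k_perfect_and_clamped():
    trials = [make_trial([("H", 0.9), ("A", 0.1)]) for _ in range(4)]
    ks, precision, recall = ev.precision_recall_at_k(trials, 2)
    assert precision[0] == 1.0 and recall[0] == 1.0
    with pytest.warns(UserWarning, match="clamped"):
        ks, _, _ = ev.precision_recall_at_k(trials, 99)
    assert ks[-1] == 2


@pytest.mark.parametrize(
    "pairs, expected",
    [
        ([(96, 1)], 48.0),
        ([(10, 5)], 1.0),  # rank at N/2: the random-expectation calibration
        ([(10, 1), (10, 5)], 3.0),
    ],
)
def test_fold_enrichment(pairs, expected):
    trials = []
    for n, rank in pairs:
        entries = [(f"P{k}", 1.0 - k / n) for k in range(n)]
        held_pid = entries[rank - 1][0]
        scores = tuple((pid, s, int(pid == held_pid)) for pid, s in entries)
        trials.append(
            ev.LoocvTrial(
                query="L", held_out=held_pid, rank_of_held_out=rank,
                n_candidates=n, scores=scores,
            )
        )
    assert ev.fold_enrichment(trials) == pytest.approx(expected)


def test_percentile_retrieval_counts():
    def trial(rank, n):
        return ev.LoocvTrial(
            query="L", held_out="H", rank_of_held_out=rank, n_candidates=n, scores=()
        )

    trials = [trial(1, 100), trial(2, 100), trial(50, 100)]
    counts = ev.percentile_retrieval(trials, [2, 50, 100])
    assert counts[2] == 2
    assert counts[50] == 3
    assert counts[100] == len(trials)
    vals = [counts[q] for q in (2, 50, 100)]
    assert vals == sorted(vals)


def test_randomized_baseline_is_reproducible_and_near_chance():
    interactions, expression, ppi = small_tables()
    a = ev.randomized_baseline(interactions, expression, ppi, RWRParams(), n_reps=3, seed=5)
    b = ev.randomized_baseline(interactions, expression, ppi, RWRParams(), n_reps=3, seed=5)
    assert a == b
    with pytest.raises(ValueError, match="n_reps"):
        ev.randomized_baseline(interactions, expression, ppi, RWRParams(), n_reps=0, seed=5)
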