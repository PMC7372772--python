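import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dcanet.evaluation import (
    ConfusionCounts,
    CVConfig,
    benchmark_baseline,
    confusion_metrics,
    make_folds,
    roc_pr_curves,
    run_cv,
    sample_negatives,
)
from dcanet.synthetic import generate_bipartite


def rank_auc(scores, labels):
    """Independent oracle: tie-corrected Mann-Whitney statistic."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            wins += 1.0 if p > q else (0.5 if p == q else 0.0)
    return wins / (len(pos) * len(neg))


def test_fold_arithmetic_at_reference_scale():
    edges = [(i // 97, i % 97) for i in range(2174)]
    folds = make_folds(edges, CVConfig(n_folds=10, seed=0))
    assert len(folds) == 10
    for train, test in folds:
        assert len(test) == 217
        assert len(train) == 2174 - 217
    all_test = [e for _, test in folds for e in test]
    assert len(set(all_test)) == len(all_test) == 2170
    remainder = set(edges) - set(all_test)
    assert len(remainder) == 4
    for train, _ in folds:
        assert remainder <= set(train)


def test_fold_partition_no_remainder():
    edges = [(0, i) for i in range(20)]
    folds = make_folds(edges, CVConfig(n_folds=10, seed=1))
    assert all(len(test) == 2 for _, test in folds)
    assert sorted(e for _, t in folds for e in t) == sorted(edges)


def test_fold_errors_and_determinism():
    with pytest.raises(ValueError):
        make_folds([(0, 0)], CVConfig(n_folds=2))
    edges = [(0, i) for i in range(25)]
    f1 = make_folds(edges, CVConfig(n_folds=5, seed=3))
    f2 = make_folds(edges, CVConfig(n_folds=5, seed=3))
    f3 = make_folds(edges, CVConfig(n_folds=5, seed=4))
    assert f1 == f2
    assert f1 != f3


def test_sample_negatives_matched_count_and_disjoint():
    net = generate_bipartite(97, 97, density=0.231, seed=5)
    positives = net.edges()[:217]
    negs = sample_negatives(net, positives, ratio=1.0, rng=0)
    assert len(negs) == 217
    edge_set = set(net.edges())
    assert not (set(negs) & edge_set)
    assert sample_negatives(net, positives, ratio=1.0, rng=0) == negs


def test_sample_negatives_dense_network_errors():
    net = generate_bipartite(3, 3, density=0.0, seed=0)
    A = np.ones((3, 3), dtype=np.int8)
    from dcanet.network import DCANetwork

    dense = DCANetwork.from_adjacency(A)
    with pytest.raises(ValueError, match="non-edges"):
        sample_negatives(dense, [(0, 0)], ratio=1.0, rng=0)


def test_auc_hand_example():
    scores = np.array([0.9, 0.7, 0.8, 0.6])
    labels = np.array([1, 1, 0, 0])
    out = roc_pr_curves(scores, labels)
    assert out["auc"] == pytest.approx(0.75)


def test_auc_perfect_and_all_ties():
    out = roc_pr_curves(np.array([3.0, 2.0, 1.0, 0.5]), np.array([1, 1, 0, 0]))
    assert out["auc"] == pytest.approx(1.0)
    assert out["aupr"] == pytest.approx(1.0)
    out = roc_pr_curves(np.ones(6), np.array([1, 1, 1, 0, 0, 0]))
    assert out["auc"] == pytest.approx(0.5)


def test_single_class_errors():
    with pytest.raises(ValueError):
        roc_pr_curves(np.array([1.0, 2.0]), np.array([1, 1]))


@settings(derandomize=True, max_examples=60)
@given(st.integers(0, 2**31 - 1))
def test_trapezoid_auc_equals_rank_statistic(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 40))
    # discrete scores force ties
    scores = rng.integers(0, 6, size=n).astype(float)
    labels = np.zeros(n, dtype=int)
    labels[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = 1
    if labels.min() == labels.max():
        labels[0] = 1 - labels[0]
    out = roc_pr_curves(scores, labels)
    assert abs(out["auc"] - rank_auc(scores, labels)) < 1e-10


def test_confusion_metrics_hand_values():
    out = confusion_metrics(ConfusionCounts(TP=3, FN=1, FP=2, TN=4))
    assert out["TPR"] == pytest.approx(0.75)
    assert out["FPR"] == pytest.approx(1 / 3)
    assert out["specificity"] == pytest.approx(2 / 3)
    out = confusion_metrics(ConfusionCounts(TP=3, FP=2, TN=0, FN=1))
    assert out["F1"] == pytest.approx(2 / 3)
    out = confusion_metrics(ConfusionCounts(TP=5, FP=0, TN=2, FN=1))
    assert out["precision"] == 1.0


def test_zero_denominators_are_undefined_not_zero():
    out = confusion_metrics(ConfusionCounts(TP=0, FP=0, TN=3, FN=0))
    assert out["TPR"] is None
    assert out["precision"] is None


def test_run_cv_deterministic_and_null_behavior():
    net = generate_bipartite(40, 40, density=0.2, seed=8)
    cfg = CVConfig(n_folds=5, seed=8)
    r1 = run_cv(net, "CN", cfg)
    r2 = run_cv(net, "CN", cfg)
    assert r1.to_dict() == r2.to_dict()
    assert r1.mean_auc != run_cv(net, "CN", dataclasses.replace(cfg, seed=9)).mean_auc
    # independent-edge networks carry no signal: AUC near 1/2
    aucs = [
        run_cv(generate_bipartite(40, 40, 0.2, seed=s), "CN", CVConfig(n_folds=5, seed=s)).mean_auc
        for s in range(6)
    ]
    assert abs(np.mean(aucs) - 0.5) < 3 * np.std(aucs, ddof=1) / np.sqrt(len(aucs)) + 0.02


def test_benchmark_baseline_chance_level_and_reproducible():
    net = generate_bipartite(50, 50, density=0.23, seed=2)
    cfg = CVConfig(n_folds=5, repetitions=25, seed=2)
    rep = benchmark_baseline(net, "CN", cfg)
    se = rep.baseline_roc["auc_se"]
    assert abs(rep.baseline_auc - 0.5) < 3 * se + 0.01
    assert rep.adjusted["auc"] == pytest.approx(rep.mean_auc - rep.baseline_auc)
    rep2 = benchmark_baseline(net, "CN", cfg)
    assert rep.baseline_auc == rep2.baseline_auc
    single = benchmark_baseline(net, "CN", dataclasses.replace(cfg, repetitions=1))
    assert single.baseline_roc["auc_per_repetition"] == benchmark_baseline(
        net, "CN", dataclasses.replace(cfg, repetitions=1)
    ).baseline_roc["auc_per_repetition"]


def test_report_summary_and_serialization(tmp_path):
    from dcanet.io import read_report, write_report

    net = generate_bipartite(30, 30, density=0.25, seed=4)
    rep = run_cv(net, "JA", CVConfig(n_folds=3, seed=4))
    text = rep.summary()
    assert "AUC" in text and "JA" in text
    path = tmp_path / "report.json"
    write_report(rep, path)
    back = read_report(path)
    assert back["mean_auc"] == pytest.approx(rep.mean_auc, rel=1e-11)
    assert back["method"] == "JA"
    assert 0.0 <= back["mean_auc"] <= 1.0
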