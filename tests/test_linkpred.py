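import numpy as np
import pytest

from dcanet.cluster import cluster_trimers
from dcanet.io import ComplexRecord
from dcanet.linkpred import (
    ScoreMatrix,
    SignificanceThresholds,
    expand_predictions,
    score_all,
    score_cn,
    score_jaccard,
    score_pa,
    scores_from_adjacency,
    threshold_matrix,
)
from dcanet.network import build_network
from dcanet.synthetic import generate_bipartite
from dcanet.trimers import extract_trimers, trimer_vector_table


def brute_force_scores(A, method):
    """Independent oracle: explicit set construction per pair."""
    n, m = A.shape
    gamma = [set(np.nonzero(A[x])[0]) for x in range(n)]
    ghat = []
    for y in range(m):
        s = set()
        for w in range(n):
            if A[w, y]:
                s |= gamma[w]
        ghat.append(s)
    S = np.zeros((n, m))
    for x in range(n):
        for y in range(m):
            if method == "CN":
                S[x, y] = len(gamma[x] & ghat[y])
            elif method == "JA":
                union = gamma[x] | ghat[y]
                S[x, y] = len(gamma[x] & ghat[y]) / len(union) if union else 0.0
            elif method == "PA":
                S[x, y] = len(gamma[x]) * int(A[:, y].sum())
    return S


def test_toy_graph_values(toy_network):
    assert score_cn(toy_network, "d1", "c3") == 1
    assert score_jaccard(toy_network, "d1", "c3") == pytest.approx(1 / 3)
    assert score_pa(toy_network, "d1", "c3") == 2
    sm = score_all(toy_network, "CN")
    expected = brute_force_scores(toy_network.adjacency, "CN")
    np.testing.assert_array_equal(sm.scores, expected)


def test_isolated_drug_scores_zero():
    net = generate_bipartite(5, 4, density=0.4, seed=1)
    A = net.adjacency.copy()
    A[2, :] = 0
    from dcanet.network import DCANetwork

    net = DCANetwork.from_adjacency(A)
    for y in net.clusters:
        assert score_cn(net, net.drugs[2], y) == 0
        assert score_pa(net, net.drugs[2], y) == 0


def test_jaccard_identity_and_empty_convention(toy_network):
    ns_scores = score_all(toy_network, "JA").scores
    cn = score_all(toy_network, "CN").scores
    # JA = CN / |union| exactly, and in [0, 1]
    assert ns_scores.min() >= 0 and ns_scores.max() <= 1
    from dcanet.network import DCANetwork

    empty = DCANetwork.from_adjacency(np.zeros((2, 2), dtype=np.int8))
    assert score_jaccard(empty, empty.drugs[0], 0) == 0.0
    assert cn[0, 0] >= ns_scores[0, 0]  # CN >= JA since union >= 1 when CN > 0


@pytest.mark.parametrize("method", ["CN", "JA", "PA"])
def test_matrix_matches_scalar_calls(method, toy_network):
    sm = score_all(toy_network, method)
    fns = {"CN": score_cn, "JA": score_jaccard, "PA": score_pa}
    for i, d in enumerate(toy_network.drugs):
        for j, c in enumerate(toy_network.clusters):
            assert sm.scores[i, j] == pytest.approx(fns[method](toy_network, d, c))


@pytest.mark.parametrize("method", ["CN", "JA", "PA"])
def test_oracle_equivalence_random_graphs(method):
    rng = np.random.default_rng(42)
    for _ in range(40):
        n, m = rng.integers(2, 16, size=2)
        A = (rng.random((n, m)) < rng.uniform(0.1, 0.6)).astype(np.int8)
        ours = scores_from_adjacency(A, method)
        oracle = brute_force_scores(A, method)
        np.testing.assert_array_equal(ours, oracle)


def test_cn_bound_and_pa_monotonicity():
    rng = np.random.default_rng(7)
    A = (rng.random((10, 8)) < 0.3).astype(np.int8)
    cn = scores_from_adjacency(A, "CN")
    gamma_sizes = A.sum(axis=1)
    for x in range(10):
        assert np.all(cn[x] <= gamma_sizes[x])
    pa = scores_from_adjacency(A, "PA")
    zeros = np.argwhere(A == 0)
    i, j = zeros[0]
    A2 = A.copy()
    A2[i, j] = 1
    assert np.all(scores_from_adjacency(A2, "PA") >= pa)


def test_threshold_matrix_hand_example():
    scores = np.array([[0.0, 100.0, 150.0], [200.0, 410.0, 500.0]])
    sm = ScoreMatrix("CN", ("d1", "d2"), (0, 1, 2), scores)
    sig, imp, counts = threshold_matrix(
        sm, SignificanceThresholds(significant_cutoff=143, important_fraction=0.2)
    )
    assert counts["n_significant"] == 4
    assert counts["n_important"] == 1
    assert imp[0][2] == 500.0
    assert set(imp) <= set(sig)


def test_threshold_edge_cases():
    scores = np.array([[1.0, 2.0]])
    sm = ScoreMatrix("CN", ("d1",), (0, 1), scores)
    sig, imp, _ = threshold_matrix(sm, SignificanceThresholds(10.0))
    assert sig == [] and imp == []
    sig, imp, _ = threshold_matrix(
        sm, SignificanceThresholds(0.5, important_fraction=1.0)
    )
    assert imp == sig
    # boundary ties all included
    tied = ScoreMatrix("CN", ("d1",), (0, 1, 2, 3), np.array([[5.0, 5.0, 5.0, 5.0]]))
    sig, imp, _ = threshold_matrix(
        tied, SignificanceThresholds(1.0, important_fraction=0.25)
    )
    assert len(imp) == 4  # all tie at the boundary score


def _evidence_network(embedding):
    cxs = [
        ComplexRecord("cx1", "p1", "d1", tuple((i + 1, aa) for i, aa in enumerate("NGMG"))),
        ComplexRecord("cx2", "p2", "d2", tuple((i + 1, aa) for i, aa in enumerate("NGMG"))),
    ]
    trimers = [t for cx in cxs for t in extract_trimers(cx.site_sequence)]
    vectors = trimer_vector_table(embedding, trimers)
    clustering = cluster_trimers(vectors, k=2)
    return build_network(cxs, clustering, embedding), clustering


def test_expand_predictions(embedding):
    net, clustering = _evidence_network(embedding)
    # pick the cluster holding NGM's key; both proteins contain it
    key = extract_trimers("NGM")[0].key
    c = clustering.labels[key]
    sig = [("d1", c, 9.0)]
    dt, dp = expand_predictions(net, sig)
    keys = {r["trimer_key"] for r in dt}
    assert key in keys
    assert {r["protein_id"] for r in dp} == {"p1", "p2"}
    known = {r["protein_id"]: r["novel"] for r in dp}
    assert known["p1"] is False  # d1-p1 is an observed complex
    assert known["p2"] is True


def test_expand_requires_evidence():
    net = generate_bipartite(4, 4, density=0.5, seed=0)
    with pytest.raises(ValueError, match="evidence"):
        expand_predictions(net, [("drug000", 0, 1.0)])


def test_expand_empty_significant(embedding):
    net, _ = _evidence_network(embedding)
    assert expand_predictions(net, []) == ([], [])
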