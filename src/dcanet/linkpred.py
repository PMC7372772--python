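"""Bipartite similarity indices for drug-cluster link prediction.

In a bipartite network a drug's neighbors are clusters while a cluster's
neighbors are drugs, so the classical one-mode indices are adapted by
replacing the cluster's neighborhood with its two-hop set
GammaHat(y) = { clusters adjacent to any drug adjacent to y }:

    CN'(x, y) = |Gamma(x) ∩ GammaHat(y)|
    JA'(x, y) = |Gamma(x) ∩ GammaHat(y)| / |Gamma(x) ∪ GammaHat(y)|
    PA (x, y) = k_x * k_y

GammaHat uses set semantics (no path multiplicity) by default; a
multiset (path-counting) variant is available for sensitivity analysis.
Known edges are scored like any other pair and flagged via the known
mask; they are excluded only during evaluation.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable

import numpy as np

from .network import DCANetwork, neighbor_sets

__all__ = [
    "ScoreMatrix",
    "SignificanceThresholds",
    "score_cn",
    "score_jaccard",
    "score_pa",
    "score_all",
    "scores_from_adjacency",
    "threshold_matrix",
    "expand_predictions",
    "estimate_significance_cutoff",
]

METHODS = ("CN", "JA", "PA")


@dataclasses.dataclass(frozen=True)
class ScoreMatrix:
    method: str
    drugs: tuple
    clusters: tuple
    scores: np.ndarray
    known_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")


@dataclasses.dataclass(frozen=True)
class SignificanceThresholds:
    """Cutoffs turning raw scores into significant / important calls.

    Scores strictly above ``significant_cutoff`` are significant. The
    important set is either the top ``important_fraction`` of the
    significant entries by score (count = ceil(fraction * n_significant),
    boundary ties all included) or, when ``important_cutoff`` is given,
    the significant entries strictly above it.
    """

    significant_cutoff: float
    important_fraction: float | None = 0.2
    important_cutoff: float | None = None

    def __post_init__(self) -> None:
        if self.important_cutoff is None:
            if self.important_fraction is None or not (0 < self.important_fraction <= 1):
                raise ValueError("important_fraction must be in (0, 1]")


def scores_from_adjacency(A: np.ndarray, method: str, multiset: bool = False) -> np.ndarray:
    """All-pairs index scores from a 0/1 drug x cluster adjacency matrix."""
    B = np.asarray(A, dtype=np.int64)
    if method == "PA":
        return np.outer(B.sum(axis=1), B.sum(axis=0)).astype(float)
    co = B.T @ B  # cluster x cluster shared-drug path counts
    if not multiset:
        co = (co > 0).astype(np.int64)
    cn = B @ co  # (x, y) -> |Gamma(x) ∩ GammaHat(y)| (or path-weighted)
    if method == "CN":
        return cn.astype(float)
    if method == "JA":
        kx = B.sum(axis=1)
        ghat = co.sum(axis=0)  # |GammaHat(y)| (set) or total path count (multiset)
        union = kx[:, None] + ghat[None, :] - cn
        with np.errstate(invalid="ignore", divide="ignore"):
            ja = np.where(union > 0, cn / np.where(union > 0, union, 1), 0.0)
        return ja.astype(float)
    raise ValueError(f"unknown method {method!r}")


def score_cn(network: DCANetwork, drug, cluster) -> int:
    """Bipartite common-neighbors score |Gamma(x) ∩ GammaHat(y)|."""
    ns = neighbor_sets(network, drug, cluster)
    return len(ns.gamma_x & ns.gamma_hat_y)


def score_jaccard(network: DCANetwork, drug, cluster) -> float:
    """Bipartite Jaccard score; 0 when both neighborhoods are empty."""
    ns = neighbor_sets(network, drug, cluster)
    union = ns.gamma_x | ns.gamma_hat_y
    if not union:
        return 0.0
    return len(ns.gamma_x & ns.gamma_hat_y) / len(union)


def score_pa(network: DCANetwork, drug, cluster) -> int:
    """Preferential-attachment score k_x * k_y."""
    ns = neighbor_sets(network, drug, cluster)
    return ns.k_x * ns.k_y


def score_all(network: DCANetwork, method: str, multiset: bool = False) -> ScoreMatrix:
    """Score every (drug, cluster) pair, known edges included."""
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")
    scores = scores_from_adjacency(network.adjacency, method, multiset=multiset)
    return ScoreMatrix(
        method=method,
        drugs=network.drugs,
        clusters=network.clusters,
        scores=scores,
        known_mask=network.adjacency.astype(bool).copy(),
    )


def threshold_matrix(
    matrix: ScoreMatrix, thresholds: SignificanceThresholds
) -> tuple[list, list, dict]:
    """Split scored pairs into significant and important sets.

    Returns (significant, important, counts) where each set is a list of
    (drug, cluster, score) triples in decreasing-score order (ties by
    row-major position).
    """
    S = matrix.scores
    sig_idx = np.argwhere(S > thresholds.significant_cutoff)
    triples = [
        (matrix.drugs[i], matrix.clusters[j], float(S[i, j])) for i, j in sig_idx
    ]
    order = sorted(range(len(triples)), key=lambda t: (-triples[t][2], t))
    significant = [triples[t] for t in order]
    if thresholds.important_cutoff is not None:
        important = [t for t in significant if t[2] > thresholds.important_cutoff]
    elif significant:
        n_imp = math.ceil(thresholds.important_fraction * len(significant))
        boundary = significant[n_imp - 1][2]
        important = [t for t in significant if t[2] >= boundary]
    else:
        important = []
    counts = {
        "n_scored": int(S.size),
        "n_nonzero": int((S > 0).sum()),
        "n_significant": len(significant),
        "n_important": len(important),
    }
    return significant, important, counts


def expand_predictions(
    network: DCANetwork, significant: Iterable[tuple]
) -> tuple[list[dict], list[dict]]:
    """Expand significant drug-cluster links to trimer and protein candidates.

    For each significant (drug d, cluster c): every member trimer t of c
    observed at some binding site yields a (d, t) candidate, and every
    protein containing such a trimer yields a (d, p) candidate. The
    novelty flag marks pairs with no observed complex support.
    """
    if network.evidence is None or network.protein_index is None:
        raise ValueError(
            "prediction expansion requires a network with evidence "
            "(synthetic bare networks cannot be expanded)"
        )
    # cluster -> {trimer key -> set of proteins containing it}
    cluster_trimer_proteins: dict[int, dict[str, set]] = {}
    for protein, pairs in network.protein_index.items():
        for key, c in pairs:
            cluster_trimer_proteins.setdefault(c, {}).setdefault(key, set()).add(protein)
    known_drug_trimers = {
        (d, key)
        for (d, _c), ev in network.evidence.items()
        for (_p, _cx, key) in ev
    }
    known_pairs = network.known_pairs or frozenset()

    drug_trimer: list[dict] = []
    drug_protein_seen: set[tuple[str, str]] = set()
    drug_protein: list[dict] = []
    for d, c, score in significant:
        ci = network.cluster_index(c)
        for key, proteins in sorted(cluster_trimer_proteins.get(ci, {}).items()):
            drug_trimer.append(
                {
                    "drug_id": d,
                    "trimer_key": key,
                    "cluster_index": ci,
                    "score": score,
                    "novel": (d, key) not in known_drug_trimers,
                }
            )
            for p in sorted(proteins):
                if (d, p) in drug_protein_seen:
                    continue
                drug_protein_seen.add((d, p))
                drug_protein.append(
                    {
                        "drug_id": d,
                        "protein_id": p,
                        "via_cluster": ci,
                        "score": score,
                        "novel": (d, p) not in known_pairs,
                    }
                )
    return drug_trimer, drug_protein


def estimate_significance_cutoff(
    network: DCANetwork, method: str, n_folds: int = 10, seed: int = 0
) -> float:
    """Average per-pair standard error of scores across CV training networks.

    The known edges are split into ``n_folds`` folds; each fold's edges
    are removed in turn and all pairs rescored on the reduced network.
    The cutoff is the mean over pairs of the ddof=1 standard deviation of
    their scores across folds — a resampling estimate of score
    uncertainty usable as an absolute significance cutoff.
    """
    from .evaluation import CVConfig, make_folds

    edges = network.edges()
    folds = make_folds(edges, CVConfig(n_folds=n_folds, seed=seed))
    stack = np.empty((len(folds),) + network.adjacency.shape)
    for f, (_train, test) in enumerate(folds):
        A = network.adjacency.copy()
        for i, j in test:
            A[i, j] = 0
        stack[f] = scores_from_adjacency(A, method)
    return float(stack.std(axis=0, ddof=1).mean())
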