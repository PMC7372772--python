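"""Agglomerative clustering of trimer vectors into k groups.

Trimers in the same cluster share physicochemical character, so a
cluster acts as a chemical "group" that a drug binds. The agglomeration
is implemented directly (Lance-Williams updates over a full distance
matrix) because the contract requires bit-reproducible partitions across
platforms: merge-distance ties are broken by the lexicographically
smallest pair of cluster representative keys, a rule generic library
implementations do not guarantee. Default linkage is average on
Euclidean distances; single, complete and ward are available.

k defaults to the number of distinct drugs in the data, following the
one-cluster-per-drug-type convention (97 in the reference dataset).
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = ["TrimerClustering", "cluster_trimers", "assign_trimer"]

_LINKAGES = ("single", "complete", "average", "ward")


@dataclasses.dataclass(frozen=True)
class TrimerClustering:
    """A fitted flat cut of the agglomeration tree.

    ``labels`` maps canonical trimer key -> cluster index in 0..k-1;
    indices are assigned by decreasing cluster size, ties by smallest
    member key. ``linkage_record`` is the merge history as
    (rep_key_a, rep_key_b, merge_distance, merged_size) tuples.
    """

    k: int
    linkage: str
    labels: dict[str, int]
    centroids: np.ndarray
    members: tuple[tuple[str, ...], ...]
    linkage_record: tuple[tuple[str, str, float, int], ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.labels.items()), columns=["canonical_key", "cluster_index"]
        )

    def to_tsv(self, labels_path, centroids_path=None) -> None:
        self.to_frame().to_csv(labels_path, sep="\t", index=False)
        if centroids_path is not None:
            pd.DataFrame(
                self.centroids,
                columns=[f"pc{i+1}" for i in range(self.centroids.shape[1])],
            ).to_csv(centroids_path, sep="\t", index_label="cluster_index",
                     float_format="%.12g")


def _merge_distance_update(
    linkage: str,
    d_ik: np.ndarray,
    d_jk: np.ndarray,
    d_ij: float,
    n_i: int,
    n_j: int,
    n_k: np.ndarray,
) -> np.ndarray:
    if linkage == "single":
        return np.minimum(d_ik, d_jk)
    if linkage == "complete":
        return np.maximum(d_ik, d_jk)
    if linkage == "average":
        return (n_i * d_ik + n_j * d_jk) / (n_i + n_j)
    if linkage == "ward":
        tot = n_i + n_j + n_k
        sq = (
            (n_i + n_k) * d_ik**2 + (n_j + n_k) * d_jk**2 - n_k * d_ij**2
        ) / tot
        return np.sqrt(np.maximum(sq, 0.0))
    raise ValueError(f"unknown linkage {linkage!r}")


def cluster_trimers(
    vectors: Mapping[str, Sequence[float]] | Mapping[str, np.ndarray],
    k: int,
    linkage: str = "average",
) -> TrimerClustering:
    """Agglomerate trimer vectors and cut the tree at exactly k clusters.

    Starts from singletons; at each step the two clusters at smallest
    linkage distance merge, ties broken by the lexicographically smallest
    (representative key, representative key) pair, where a cluster's
    representative is its smallest member key. Input order never affects
    the result: keys are sorted before anything else.
    """
    if linkage not in _LINKAGES:
        raise ValueError(f"linkage must be one of {_LINKAGES}, got {linkage!r}")
    if k < 1:
        raise ValueError("k must be >= 1")
    keys = sorted(vectors)
    n = len(keys)
    if n < k:
        raise ValueError(f"cannot form k={k} clusters from {n} trimers")
    X = np.asarray([np.asarray(vectors[key], dtype=float) for key in keys])
    if X.ndim != 2:
        raise ValueError("all vectors must share one dimensionality")

    D = cdist(X, X)
    np.fill_diagonal(D, np.inf)
    active = np.ones(n, dtype=bool)
    size = np.ones(n, dtype=int)
    rep = list(keys)  # representative (smallest member) key per slot
    members: list[list[int]] = [[i] for i in range(n)]
    history: list[tuple[str, str, float, int]] = []

    for _ in range(n - k):
        d_min = D.min()
        ii, jj = np.nonzero(D == d_min)
        # candidate unordered pairs; pick lexicographically smallest rep pair
        best = None
        for a, b in zip(ii, jj):
            if a >= b:
                continue
            pair = (rep[a], rep[b]) if rep[a] < rep[b] else (rep[b], rep[a])
            if best is None or pair < best[0]:
                best = (pair, a, b)
        _, a, b = best
        if rep[b] < rep[a]:
            a, b = b, a  # keep the slot whose rep key is smaller
        n_a, n_b = int(size[a]), int(size[b])
        history.append((rep[a], rep[b], float(d_min), n_a + n_b))

        others = active.copy()
        others[a] = others[b] = False
        idx = np.nonzero(others)[0]
        if idx.size:
            new_d = _merge_distance_update(
                linkage, D[a, idx], D[b, idx], float(d_min), n_a, n_b, size[idx]
            )
            D[a, idx] = new_d
            D[idx, a] = new_d
        D[b, :] = np.inf
        D[:, b] = np.inf
        D[a, a] = np.inf
        active[b] = False
        size[a] = n_a + n_b
        members[a].extend(members[b])
        members[b] = []

    slots = np.nonzero(active)[0]
    # cluster index order: decreasing size, ties by smallest member key
    order = sorted(slots, key=lambda s: (-size[s], rep[s]))
    labels: dict[str, int] = {}
    centroids = np.empty((k, X.shape[1]))
    member_keys: list[tuple[str, ...]] = []
    for ci, s in enumerate(order):
        ks = sorted(keys[i] for i in members[s])
        member_keys.append(tuple(ks))
        for key in ks:
            labels[key] = ci
        centroids[ci] = X[members[s]].mean(axis=0)
    return TrimerClustering(
        k=k,
        linkage=linkage,
        labels=labels,
        centroids=centroids,
        members=tuple(member_keys),
        linkage_record=tuple(history),
    )


def assign_trimer(clustering: TrimerClustering, vector: Sequence[float]) -> int:
    """Index of the nearest centroid (Euclidean); ties -> lowest index."""
    v = np.asarray(vector, dtype=float)
    d = np.linalg.norm(clustering.centroids - v, axis=1)
    return int(np.argmin(d))
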