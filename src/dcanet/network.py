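"""The bipartite drug-cluster association (DCA) network G(D, C, E).

Drugs connect to trimer clusters: a(d, c) = 1 iff some complex binding
drug d has a binding-site trimer assigned to cluster c. Every edge keeps
its evidence — the (protein, complex, trimer) occurrences that created
it — so that predicted drug-cluster links can later be expanded back to
concrete drug-trimer and drug-protein candidates.
"""

from __future__ import annotations

import dataclasses
from collections import defaultdict
from typing import Sequence

import numpy as np
import pandas as pd

from .cluster import TrimerClustering, assign_trimer
from .embedding import EmbeddingModel
from .io import ComplexRecord
from .trimers import extract_trimers, trimer_vector_table

__all__ = ["DCANetwork", "NeighborSets", "build_network", "neighbor_sets", "degree_summary"]


@dataclasses.dataclass(frozen=True)
class NeighborSets:
    """Two-hop neighborhood view around a (drug x, cluster y) pair.

    gamma_x: clusters adjacent to drug x. gamma_hat_y: clusters adjacent
    to any drug that is adjacent to cluster y (set semantics). k_x, k_y:
    plain degrees.
    """

    gamma_x: frozenset
    gamma_hat_y: frozenset
    k_x: int
    k_y: int


@dataclasses.dataclass(frozen=True)
class DCANetwork:
    """Bipartite network over ordered drug and cluster sets.

    ``adjacency`` is the n x m 0/1 matrix a_ij. ``evidence`` maps
    (drug_id, cluster_index) -> list of (protein_id, complex_id,
    trimer_key) supporting the edge; it is None for bare synthetic
    networks, which support link prediction but not prediction
    expansion. ``known_pairs`` holds the observed (drug_id, protein_id)
    complexes.
    """

    drugs: tuple[str, ...]
    clusters: tuple[int, ...]
    adjacency: np.ndarray
    evidence: dict | None = None
    protein_index: dict | None = None
    known_pairs: frozenset | None = None
    synthetic: bool = False
    skipped_complexes: int = 0

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency, dtype=np.int8)
        object.__setattr__(self, "adjacency", A)
        if A.shape != (len(self.drugs), len(self.clusters)):
            raise ValueError("adjacency shape does not match drug/cluster sets")
        if not np.isin(A, (0, 1)).all():
            raise ValueError("adjacency must be binary")
        if self.evidence is not None:
            di = {d: i for i, d in enumerate(self.drugs)}
            for (d, c), ev in self.evidence.items():
                if not ev or A[di[d], c] != 1:
                    raise ValueError(f"edge ({d}, {c}) lacks consistent evidence")

    @property
    def n_drugs(self) -> int:
        return len(self.drugs)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum())

    def drug_index(self, drug) -> int:
        try:
            return self.drugs.index(drug)
        except ValueError:
            raise KeyError(f"unknown drug {drug!r}") from None

    def cluster_index(self, cluster) -> int:
        try:
            return self.clusters.index(cluster)
        except ValueError:
            raise KeyError(f"unknown cluster {cluster!r}") from None

    def edges(self) -> list[tuple[int, int]]:
        """Edge list as (drug index, cluster index) pairs, row-major order."""
        return [tuple(e) for e in np.argwhere(self.adjacency == 1)]

    def edge_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(self.drugs[i], self.clusters[j]) for i, j in self.edges()],
            columns=["drug_id", "cluster_index"],
        )

    @classmethod
    def from_adjacency(
        cls, adjacency: np.ndarray, drugs=None, clusters=None, synthetic: bool = True
    ) -> "DCANetwork":
        A = np.asarray(adjacency)
        n, m = A.shape
        return cls(
            drugs=tuple(drugs) if drugs else tuple(f"drug{i:03d}" for i in range(n)),
            clusters=tuple(clusters) if clusters else tuple(range(m)),
            adjacency=A,
            synthetic=synthetic,
        )


def build_network(
    complexes: Sequence[ComplexRecord],
    clustering: TrimerClustering,
    model: EmbeddingModel,
) -> DCANetwork:
    """Assemble the drug-cluster network from complexes and a clustering.

    Each complex's site is broken into trimers; each trimer's cluster is
    its training label when the canonical key was clustered, otherwise
    the nearest centroid. Drugs appearing in several complexes pool their
    evidence. Complexes whose site is shorter than 3 residues are skipped
    and counted. Orderings (sorted drug ids, cluster 0..k-1) make the
    build deterministic.
    """
    drugs = tuple(sorted({c.drug_id for c in complexes}))
    clusters = tuple(range(clustering.k))
    di = {d: i for i, d in enumerate(drugs)}
    A = np.zeros((len(drugs), clustering.k), dtype=np.int8)
    evidence: dict[tuple[str, int], list] = defaultdict(list)
    protein_index: dict[str, set] = defaultdict(set)
    known_pairs: set[tuple[str, str]] = set()
    skipped = 0
    vec_cache = trimer_vector_table(model, [])
    X = model.vectors()

    for cx in complexes:
        seq = cx.site_sequence
        if len(seq) < 3:
            skipped += 1
            continue
        known_pairs.add((cx.drug_id, cx.protein_id))
        for t in extract_trimers(seq, cx.complex_id):
            label = clustering.labels.get(t.key)
            if label is None:
                if t.key not in vec_cache:
                    a, b = t.flanks
                    vec_cache[t.key] = X[t.center] + (X[a] + X[b]) / 4.0
                label = assign_trimer(clustering, vec_cache[t.key])
            A[di[cx.drug_id], label] = 1
            evidence[(cx.drug_id, label)].append(
                (cx.protein_id, cx.complex_id, t.key)
            )
            protein_index[cx.protein_id].add((t.key, label))

    return DCANetwork(
        drugs=drugs,
        clusters=clusters,
        adjacency=A,
        evidence=dict(evidence),
        protein_index=dict(protein_index),
        known_pairs=frozenset(known_pairs),
        skipped_complexes=skipped,
    )


def neighbor_sets(network: DCANetwork, drug, cluster) -> NeighborSets:
    """Gamma(x), the two-hop cluster set GammaHat(y), and both degrees."""
    x = network.drug_index(drug)
    y = network.cluster_index(cluster)
    A = network.adjacency
    gamma_x = frozenset(network.clusters[j] for j in np.nonzero(A[x])[0])
    drugs_of_y = np.nonzero(A[:, y])[0]
    ghat = frozenset(
        network.clusters[j]
        for j in np.nonzero(A[drugs_of_y].any(axis=0))[0]
    ) if drugs_of_y.size else frozenset()
    return NeighborSets(
        gamma_x=gamma_x,
        gamma_hat_y=ghat,
        k_x=int(A[x].sum()),
        k_y=int(A[:, y].sum()),
    )


def degree_summary(
    network: DCANetwork,
    drug_band: tuple[int, int] | None = None,
    cluster_below: int | None = None,
) -> dict:
    """Degree histograms, density and the banded fractions of the data survey.

    ``drug_band=(lo, hi)`` reports the fraction of drugs with degree in
    [lo, hi]; ``cluster_below=t`` the fraction of clusters with degree
    < t. Diagnostics include both set- and multiset-valued two-hop
    neighborhood totals for the cluster side.
    """
    A = network.adjacency
    kd = A.sum(axis=1)
    kc = A.sum(axis=0)
    n, m = A.shape
    B = A.astype(bool)
    co_set = (B.T @ B)  # paths between cluster pairs through shared drugs
    out = {
        "drug_degrees": {d: int(k) for d, k in zip(network.drugs, kd)},
        "cluster_degrees": {c: int(k) for c, k in zip(network.clusters, kc)},
        "drug_degree_hist": dict(zip(*np.unique(kd, return_counts=True))),
        "cluster_degree_hist": dict(zip(*np.unique(kc, return_counts=True))),
        "n_edges": int(A.sum()),
        "density": float(A.sum() / (n * m)) if n * m else 0.0,
        "two_hop_cluster_set_total": int((co_set > 0).sum()),
        "two_hop_cluster_multiset_total": int(co_set.sum()),
    }
    if drug_band is not None:
        lo, hi = drug_band
        out["drug_degree_band_fraction"] = float(
            ((kd >= lo) & (kd <= hi)).mean()
        ) if n else float("nan")
    if cluster_below is not None:
        out["cluster_degree_below_fraction"] = float(
            (kc < cluster_below).mean()
        ) if m else float("nan")
    return out
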