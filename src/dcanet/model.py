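"""Model/Results facade over the drug-cluster association pipeline.

``DCAModel`` holds the raw inputs (complex records and the amino-acid
property table) plus hyperparameters; ``fit()`` runs embedding ->
trimer extraction -> clustering -> network construction and returns a
``DCAResults`` object carrying the fitted artifacts, from which scores,
thresholded predictions, expansions and cross-validated evaluations
hang.

    >>> model = DCAModel.from_synthetic(seed=0)
    >>> res = model.fit()
    >>> report = res.evaluate("CN", CVConfig(seed=0))
    >>> print(res.summary())
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cluster import TrimerClustering, cluster_trimers
from .embedding import EmbeddingModel, fit_embedding
from .evaluation import CVConfig, EvaluationReport, benchmark_baseline, run_cv
from .io import AminoAcidPropertyTable, ComplexRecord, read_complex_table, read_property_table
from .linkpred import (
    ScoreMatrix,
    SignificanceThresholds,
    estimate_significance_cutoff,
    expand_predictions,
    score_all,
    threshold_matrix,
)
from .network import DCANetwork, build_network, degree_summary
from .trimers import Trimer, extract_trimers, trimer_multiplicity, trimer_vector_table

__all__ = ["DCAModel", "DCAResults"]


class DCAModel:
    """Drug-cluster association model over binding-site trimers.

    Parameters
    ----------
    complexes : protein-drug complex records with binding-site sequences.
    property_table : 20 x P amino-acid physicochemical properties.
    n_components : PCA dimensionality of the amino-acid embedding (5).
    k : number of trimer clusters, or "auto" = number of distinct drugs.
    linkage : agglomeration linkage (single/complete/average/ward).
    """

    def __init__(
        self,
        complexes: Sequence[ComplexRecord],
        property_table: AminoAcidPropertyTable,
        n_components: int = 5,
        k: int | str = "auto",
        linkage: str = "average",
    ) -> None:
        self.complexes = list(complexes)
        self.property_table = property_table
        self.n_components = n_components
        self.k = k
        self.linkage = linkage

    @classmethod
    def from_files(cls, property_path, complex_path, **kwargs) -> "DCAModel":
        return cls(
            read_complex_table(complex_path),
            read_property_table(property_path),
            **kwargs,
        )

    @classmethod
    def from_synthetic(cls, spec=None, seed: int | None = None, **kwargs) -> "DCAModel":
        """Model over the planted-signal synthetic preset.

        The generated ground truth is attached as ``model.ground_truth``.
        """
        from .synthetic import SyntheticSpec, generate_complexes, generate_property_table

        if spec is None:
            spec = SyntheticSpec(seed=0 if seed is None else seed)
        elif seed is not None:
            import dataclasses as _dc

            spec = _dc.replace(spec, seed=seed)
        table = generate_property_table(spec)
        syn = generate_complexes(spec)
        model = cls(list(syn.records), table, **kwargs)
        model.ground_truth = syn
        return model

    def resolved_k(self) -> int:
        if self.k == "auto":
            return len({c.drug_id for c in self.complexes})
        return int(self.k)

    def fit(self) -> "DCAResults":
        embedding = fit_embedding(self.property_table, self.n_components)
        trimers: list[tuple[Trimer, str, str]] = []  # (trimer, protein, drug)
        skipped = 0
        for cx in self.complexes:
            seq = cx.site_sequence
            if len(seq) < 3:
                skipped += 1
                continue
            for t in extract_trimers(seq, cx.complex_id):
                trimers.append((t, cx.protein_id, cx.drug_id))
        vectors = trimer_vector_table(embedding, [t for t, _, _ in trimers])
        k = self.resolved_k()
        if len(vectors) < k:
            raise ValueError(
                f"only {len(vectors)} distinct trimers for k={k} clusters"
            )
        clustering = cluster_trimers(vectors, k=k, linkage=self.linkage)
        network = build_network(self.complexes, clustering, embedding)
        return DCAResults(
            model=self,
            embedding=embedding,
            trimers=trimers,
            trimer_vectors=vectors,
            clustering=clustering,
            network=network,
            skipped_complexes=skipped,
        )


class DCAResults:
    """Fitted artifacts of a :class:`DCAModel` plus downstream analyses."""

    def __init__(
        self,
        model: DCAModel,
        embedding: EmbeddingModel,
        trimers: list,
        trimer_vectors: dict,
        clustering: TrimerClustering,
        network: DCANetwork,
        skipped_complexes: int = 0,
    ) -> None:
        self.model = model
        self.embedding = embedding
        self.trimers = trimers
        self.trimer_vectors = trimer_vectors
        self.clustering = clustering
        self.network = network
        self.skipped_complexes = skipped_complexes

    # -- descriptive statistics -------------------------------------------
    def trimer_table(self) -> pd.DataFrame:
        rows = [
            {
                "complex_id": t.source[0] if t.source else "",
                "protein_id": protein,
                "drug_id": drug,
                "position": t.source[1] if t.source else -1,
                "raw": t.raw,
                "canonical_key": t.key,
                "cluster_index": self.clustering.labels.get(t.key, -1),
            }
            for t, protein, drug in self.trimers
        ]
        return pd.DataFrame(rows)

    def multiplicity(self) -> dict[int, float]:
        return trimer_multiplicity((t, p) for t, p, _ in self.trimers)

    def degrees(self, drug_band=None, cluster_below=None) -> dict:
        return degree_summary(self.network, drug_band, cluster_below)

    # -- prediction --------------------------------------------------------
    def score(self, method: str = "CN", multiset: bool = False) -> ScoreMatrix:
        return score_all(self.network, method, multiset=multiset)

    def predict(
        self,
        method: str = "CN",
        thresholds: SignificanceThresholds | None = None,
        cv_seed: int = 0,
    ) -> dict:
        """Score all pairs, threshold, and expand to trimer/protein candidates.

        Without explicit thresholds the significance cutoff is the
        fold-resampling standard-error estimate.
        """
        matrix = self.score(method)
        if thresholds is None:
            cutoff = estimate_significance_cutoff(
                self.network, method, seed=cv_seed
            )
            thresholds = SignificanceThresholds(significant_cutoff=cutoff)
        significant, important, counts = threshold_matrix(matrix, thresholds)
        drug_trimer, drug_protein = expand_predictions(self.network, significant)
        return {
            "matrix": matrix,
            "thresholds": thresholds,
            "significant": significant,
            "important": important,
            "counts": counts,
            "drug_trimer": drug_trimer,
            "drug_protein": drug_protein,
        }

    # -- evaluation --------------------------------------------------------
    def evaluate(
        self,
        method: str = "CN",
        config: CVConfig | None = None,
        benchmark: bool = False,
    ) -> EvaluationReport:
        config = config or CVConfig()
        if benchmark:
            return benchmark_baseline(self.network, method, config)
        return run_cv(self.network, method, config)

    def summary(self) -> str:
        net = self.network
        ev = self.embedding.eigenvalues
        mult = self.multiplicity()
        lines = [
            "Drug-cluster association model",
            "=" * 46,
            f"complexes            {len(self.model.complexes):6d}"
            f"   (skipped short sites: {self.skipped_complexes})",
            f"drugs                {net.n_drugs:6d}",
            f"trimer occurrences   {len(self.trimers):6d}",
            f"distinct trimers     {len(self.trimer_vectors):6d}",
            f"clusters (k)         {self.clustering.k:6d}   linkage={self.clustering.linkage}",
            f"network edges        {net.n_edges:6d}   density={net.n_edges / max(net.n_drugs * net.n_clusters, 1):.3f}",
            f"embedding eigenvalues {np.array2string(ev, precision=2)}",
            f"single-protein trimer fraction {mult.get(1, 0.0):.3f}",
        ]
        return "\n".join(lines)
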