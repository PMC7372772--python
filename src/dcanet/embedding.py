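"""PCA embedding of amino acids from physicochemical properties.

The 20 x P property matrix (P mixes units: volumes, polarizabilities,
free energies, ...) is column-standardized and reduced by principal
component analysis to a 5-dimensional coordinate per amino acid. The
retained factorization is the score convention: coordinates are
projections of the standardized rows onto unit-norm principal axes, so
the variance of component ``i`` over the 20 amino acids equals the
eigenvalue ``lambda_i``, i.e. the score matrix factors as
``(sqrt(l1) E1, ..., sqrt(l5) E5)`` in the usual notation.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from ._aa import validate_code
from .io import AminoAcidPropertyTable

__all__ = ["EmbeddingModel", "AminoAcidVector", "fit_embedding", "embed_amino_acid"]


@dataclasses.dataclass(frozen=True)
class AminoAcidVector:
    code: str
    vector: np.ndarray


@dataclasses.dataclass(frozen=True)
class EmbeddingModel:
    """Standardization parameters and the top principal axes.

    Attributes
    ----------
    amino_acids : order of the 20 rows the model was fitted on.
    column_means, column_sds : per kept property column (ddof=1 sd).
    eigenvalues : descending eigenvalues of the standardized covariance.
    axes : (n_components, n_kept) orthonormal principal axes, sign-fixed
        so each axis's largest-magnitude loading is positive.
    kept_columns : indices (into the original property list) of the
        non-degenerate columns used for the fit.
    """

    amino_acids: tuple[str, ...]
    column_means: np.ndarray
    column_sds: np.ndarray
    eigenvalues: np.ndarray
    axes: np.ndarray
    kept_columns: tuple[int, ...]
    _scores: np.ndarray  # cached 20 x n_components coordinates

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)

    def vectors(self) -> dict[str, np.ndarray]:
        """All 20 amino-acid coordinates keyed by one-letter code."""
        return {aa: self._scores[i] for i, aa in enumerate(self.amino_acids)}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "amino_acids": list(self.amino_acids),
            "column_means": self.column_means.tolist(),
            "column_sds": self.column_sds.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "axes": self.axes.tolist(),
            "kept_columns": list(self.kept_columns),
            "scores": self._scores.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "EmbeddingModel":
        d = json.loads(Path(path).read_text())
        return cls(
            amino_acids=tuple(d["amino_acids"]),
            column_means=np.asarray(d["column_means"], dtype=float),
            column_sds=np.asarray(d["column_sds"], dtype=float),
            eigenvalues=np.asarray(d["eigenvalues"], dtype=float),
            axes=np.asarray(d["axes"], dtype=float),
            kept_columns=tuple(d["kept_columns"]),
            _scores=np.asarray(d["scores"], dtype=float),
        )


def fit_embedding(
    table: AminoAcidPropertyTable, n_components: int = 5
) -> EmbeddingModel:
    """Standardize property columns and fit the top principal components.

    Zero-variance columns are dropped (and recorded via ``kept_columns``)
    before standardization. Eigenpairs come from the SVD of the
    standardized matrix; eigenvalues use the ddof=1 covariance so that
    their sum equals the number of kept columns (trace conservation).

    Raises
    ------
    ValueError
        If ``n_components`` exceeds the available rank (at most 19 after
        centering, and at most the number of kept columns).
    """
    if n_components < 1:
        raise ValueError("n_components must be positive")
    X = table.values
    sds_all = X.std(axis=0, ddof=1)
    kept = np.flatnonzero(sds_all > 0)
    if len(kept) < 5:
        raise ValueError(f"only {len(kept)} non-degenerate properties; need >= 5")
    max_rank = min(X.shape[0] - 1, len(kept))
    if n_components > max_rank:
        raise ValueError(
            f"n_components={n_components} exceeds available rank {max_rank}"
        )
    Xk = X[:, kept]
    means = Xk.mean(axis=0)
    sds = Xk.std(axis=0, ddof=1)
    Z = (Xk - means) / sds

    # SVD of the standardized matrix: Z = U S Vt, covariance eigenvalues
    # are S^2/(n-1) and the principal axes are the rows of Vt.
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    eigenvalues = (S**2) / (X.shape[0] - 1)
    axes = Vt[:n_components]
    eigenvalues = eigenvalues[:n_components]

    # sign convention: largest-magnitude loading on each axis is positive
    flip = np.sign(axes[np.arange(n_components), np.argmax(np.abs(axes), axis=1)])
    flip[flip == 0] = 1.0
    axes = axes * flip[:, None]

    scores = Z @ axes.T
    return EmbeddingModel(
        amino_acids=table.amino_acids,
        column_means=means,
        column_sds=sds,
        eigenvalues=eigenvalues,
        axes=axes,
        kept_columns=tuple(int(j) for j in kept),
        _scores=scores,
    )


def embed_amino_acid(model: EmbeddingModel, code: str) -> AminoAcidVector:
    """Project one amino acid's standardized property row onto the axes."""
    validate_code(code)
    if code not in model.amino_acids:
        raise ValueError(f"amino acid {code!r} not in fitted model")
    i = model.amino_acids.index(code)
    return AminoAcidVector(code, model._scores[i].copy())
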