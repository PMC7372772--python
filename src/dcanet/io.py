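"""Tabular input/output with strict validation.

Two inputs drive the whole pipeline: a 20 x P table of amino-acid
physicochemical properties, and a complex table with one row per
protein-drug complex carrying the binding-site residue sequence.
Outputs (score matrices, edge lists, evaluation reports) are written as
plain TSV / JSON so that every artifact round-trips losslessly.
"""

from __future__ import annotations

import dataclasses
import json
import math
import re
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._aa import STANDARD_AA_SET

__all__ = [
    "AminoAcidPropertyTable",
    "ComplexRecord",
    "read_property_table",
    "read_complex_table",
    "write_property_table",
    "write_complex_table",
    "write_score_matrix",
    "read_score_matrix",
    "write_edge_list",
    "write_report",
    "read_report",
]

_FLOAT_FMT = "%.12g"


@dataclasses.dataclass(frozen=True)
class AminoAcidPropertyTable:
    """20 amino acids x P physicochemical descriptors.

    ``values[i, j]`` is the value of property ``properties[j]`` for amino
    acid ``amino_acids[i]``.
    """

    amino_acids: tuple[str, ...]
    properties: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        missing = STANDARD_AA_SET - set(self.amino_acids)
        if missing:
            raise ValueError(f"missing amino acids: {sorted(missing)}")
        if len(set(self.amino_acids)) != len(self.amino_acids):
            dups = sorted(
                {c for c in self.amino_acids if self.amino_acids.count(c) > 1}
            )
            raise ValueError(f"duplicate amino-acid codes: {dups}")
        if len(self.amino_acids) != 20:
            raise ValueError(
                f"property table must have exactly 20 amino-acid rows, "
                f"got {len(self.amino_acids)}"
            )
        if len(self.properties) < 5:
            raise ValueError(
                f"need at least 5 properties, got {len(self.properties)}"
            )
        if values.shape != (20, len(self.properties)):
            raise ValueError(
                f"value matrix shape {values.shape} does not match "
                f"(20, {len(self.properties)})"
            )
        if not np.all(np.isfinite(values)):
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite value at amino acid {self.amino_acids[i]!r}, "
                f"property {self.properties[j]!r}"
            )

    @property
    def n_properties(self) -> int:
        return len(self.properties)

    def row(self, code: str) -> np.ndarray:
        """Property vector of one amino acid."""
        try:
            i = self.amino_acids.index(code)
        except ValueError:
            raise KeyError(f"unknown amino-acid code {code!r}") from None
        return self.values[i]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.amino_acids), columns=list(self.properties)
        )


@dataclasses.dataclass(frozen=True)
class ComplexRecord:
    """One protein-drug complex and its binding-site residues.

    ``site_residues`` is ordered by residue number; the concatenated
    one-letter codes form the continuous site sequence that trimer
    extraction slides over.
    """

    complex_id: str
    protein_id: str
    drug_id: str
    site_residues: tuple[tuple[int, str], ...]

    def __post_init__(self) -> None:
        if not self.site_residues:
            raise ValueError(f"complex {self.complex_id!r}: empty binding site")
        numbers = [n for n, _ in self.site_residues]
        if any(b <= a for a, b in zip(numbers, numbers[1:])):
            raise ValueError(
                f"complex {self.complex_id!r}: residue numbers not strictly "
                "increasing after ordering"
            )
        for n, aa in self.site_residues:
            if aa not in STANDARD_AA_SET:
                raise ValueError(
                    f"complex {self.complex_id!r}: invalid amino-acid code "
                    f"{aa!r} at residue {n}"
                )

    @property
    def site_sequence(self) -> str:
        return "".join(aa for _, aa in self.site_residues)


def read_property_table(path: str | Path) -> AminoAcidPropertyTable:
    """Read a 20 x P amino-acid property table (TSV or CSV).

    Header row holds the property names; the first column holds the
    one-letter amino-acid codes. Raises ``ValueError`` naming the
    offending row/column on any validation failure.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    codes = [str(c).strip() for c in df.index]
    properties = tuple(str(c) for c in df.columns)
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        for i, cell in enumerate(df[col]):
            try:
                values[i, j] = float(cell)
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-numeric value {cell!r} at amino acid {codes[i]!r}, "
                    f"property {col!r}"
                ) from None
    return AminoAcidPropertyTable(tuple(codes), properties, values)


def write_property_table(table: AminoAcidPropertyTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", float_format=_FLOAT_FMT)


_RESIDUE_LIST_RE = re.compile(r"^\s*\d+\s*:\s*[A-Za-z]\s*(;\s*\d+\s*:\s*[A-Za-z]\s*)*;?\s*$")


def _parse_site(complex_id: str, site: str) -> tuple[tuple[int, str], ...]:
    site = site.strip()
    if not site:
        raise ValueError(f"complex {complex_id!r}: empty binding site")
    if _RESIDUE_LIST_RE.match(site):
        pairs = []
        for item in filter(None, (s.strip() for s in site.split(";"))):
            num_s, aa = item.split(":")
            pairs.append((int(num_s), aa.strip().upper()))
        pairs.sort(key=lambda p: p[0])
        return tuple(pairs)
    # plain sequence string; assign consecutive 1-based numbers
    return tuple((i + 1, aa.upper()) for i, aa in enumerate(site))


def read_complex_table(path: str | Path) -> list[ComplexRecord]:
    """Read a complex table (TSV: complex_id, protein_id, drug_id, site).

    ``site`` is either a plain amino-acid sequence or a numbered residue
    list ``"num:AA;num:AA;..."``; numbered residues are sorted by residue
    number before assembly.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = ["complex_id", "protein_id", "drug_id", "site"]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ValueError(f"complex table missing columns: {missing_cols}")
    records: list[ComplexRecord] = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        cid = str(row.complex_id)
        if cid in seen:
            raise ValueError(f"duplicate complex_id {cid!r}")
        seen.add(cid)
        records.append(
            ComplexRecord(
                complex_id=cid,
                protein_id=str(row.protein_id),
                drug_id=str(row.drug_id),
                site_residues=_parse_site(cid, str(row.site)),
            )
        )
    return records


def write_complex_table(records: Iterable[ComplexRecord], path: str | Path) -> None:
    rows = [
        {
            "complex_id": r.complex_id,
            "protein_id": r.protein_id,
            "drug_id": r.drug_id,
            "site": ";".join(f"{n}:{aa}" for n, aa in r.site_residues),
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_score_matrix(matrix, path: str | Path) -> None:
    """Write a ScoreMatrix as a dense drugs x clusters TSV."""
    df = pd.DataFrame(
        matrix.scores,
        index=list(matrix.drugs),
        columns=[str(c) for c in matrix.clusters],
    )
    df.index.name = f"drug\\{matrix.method}"
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_score_matrix(path: str | Path):
    """Read back a dense score-matrix TSV written by :func:`write_score_matrix`."""
    from .linkpred import ScoreMatrix

    df = pd.read_csv(path, sep="\t", index_col=0)
    method = str(df.index.name).split("\\")[-1]
    return ScoreMatrix(
        method=method,
        drugs=tuple(str(d) for d in df.index),
        clusters=tuple(int(c) if str(c).isdigit() else str(c) for c in df.columns),
        scores=df.to_numpy(dtype=float),
        known_mask=None,
    )


def write_edge_list(rows: Sequence[dict], path: str | Path, columns: Sequence[str] | None = None) -> None:
    """Write a long-form edge list (one dict per edge) as TSV."""
    df = pd.DataFrame(list(rows), columns=list(columns) if columns else None)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def _round_floats(obj, sig: int = 12):
    if isinstance(obj, float):
        if not math.isfinite(obj):
            return obj
        return float(f"%.{sig}g" % obj)
    if isinstance(obj, dict):
        return {k: _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, sig) for v in obj]
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist(), sig)
    if isinstance(obj, (np.floating,)):
        return _round_floats(float(obj), sig)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def write_report(report, path: str | Path) -> None:
    """Serialize an EvaluationReport to a structured JSON document."""
    payload = report.to_dict() if hasattr(report, "to_dict") else dict(report)
    with open(path, "w") as fh:
        json.dump(_round_floats(payload), fh, indent=1)
        fh.write("\n")


def read_report(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
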