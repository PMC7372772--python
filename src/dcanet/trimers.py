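"""Binding-site trimers: extraction, vectorization, descriptive statistics.

A trimer is a 3-residue sliding window over an assembled binding-site
sequence. Its central residue is the major position; the two flanking
(subordinate) residues are unordered, so windows ``ABC`` and ``CBA``
denote the same trimer. The trimer's 5-d coordinate weights the center
fully and the flanks at a quarter each:

    v(trimer) = X(center) + (X(left) + X(right)) / 4

which is symmetric in the flanks by construction.
"""

from __future__ import annotations

import dataclasses
from collections import Counter, defaultdict
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._aa import KYTE_DOOLITTLE, SIDE_CHAIN_CHARGE, STANDARD_AA_SET
from .embedding import EmbeddingModel

__all__ = [
    "Trimer",
    "TrimerVector",
    "extract_trimers",
    "vectorize_trimer",
    "trimer_vector_table",
    "canonical_key",
    "trimer_multiplicity",
    "trimer_physchem_summary",
]


def canonical_key(window: str) -> str:
    """Canonical identity of a 3-residue window: center + sorted flanks.

    Rendered ``"C(AB)"`` with the center first and the flanks sorted, the
    display used for cluster members throughout.
    """
    if len(window) != 3:
        raise ValueError(f"trimer window must have length 3, got {window!r}")
    a, b = sorted((window[0], window[2]))
    return f"{window[1]}({a}{b})"


@dataclasses.dataclass(frozen=True)
class Trimer:
    """One 3-residue window with provenance.

    ``raw`` is the window as read; ``center``/``flanks`` are the
    order-insensitive identity; ``source`` is (complex_id, 1-based window
    start).
    """

    raw: str
    source: tuple[str, int] | None = None

    def __post_init__(self) -> None:
        if len(self.raw) != 3:
            raise ValueError(f"trimer must have 3 residues, got {self.raw!r}")
        bad = set(self.raw) - STANDARD_AA_SET
        if bad:
            raise ValueError(f"invalid amino-acid codes in trimer: {sorted(bad)}")

    @property
    def center(self) -> str:
        return self.raw[1]

    @property
    def flanks(self) -> tuple[str, str]:
        a, b = sorted((self.raw[0], self.raw[2]))
        return (a, b)

    @property
    def key(self) -> str:
        return canonical_key(self.raw)


@dataclasses.dataclass(frozen=True)
class TrimerVector:
    key: str
    vector: np.ndarray


def extract_trimers(site_sequence: str, complex_id: str | None = None) -> list[Trimer]:
    """Slide a width-3, step-1 window over a site sequence.

    Returns exactly ``len(site_sequence) - 2`` trimers in sequence order;
    window positions are 1-based.
    """
    if len(site_sequence) < 3:
        raise ValueError(
            f"site too short for trimer extraction: {site_sequence!r} "
            f"(length {len(site_sequence)} < 3)"
        )
    bad = set(site_sequence) - STANDARD_AA_SET
    if bad:
        raise ValueError(f"invalid amino-acid codes in site: {sorted(bad)}")
    return [
        Trimer(site_sequence[i : i + 3], source=(complex_id, i + 1) if complex_id else None)
        for i in range(len(site_sequence) - 2)
    ]


def vectorize_trimer(model: EmbeddingModel, trimer: Trimer | str) -> TrimerVector:
    """5-d trimer coordinate: center weighted 1, each flank weighted 1/4."""
    t = Trimer(trimer) if isinstance(trimer, str) else trimer
    X = model.vectors()
    a, b = t.flanks
    vec = X[t.center] + (X[a] + X[b]) / 4.0
    return TrimerVector(t.key, vec)


def trimer_vector_table(
    model: EmbeddingModel, trimers: Iterable[Trimer]
) -> dict[str, np.ndarray]:
    """Map each distinct canonical key to its 5-d vector."""
    X = model.vectors()
    out: dict[str, np.ndarray] = {}
    for t in trimers:
        if t.key not in out:
            a, b = t.flanks
            out[t.key] = X[t.center] + (X[a] + X[b]) / 4.0
    return out


def trimer_multiplicity(
    trimer_proteins: Iterable[tuple[Trimer | str, str]],
) -> dict[int, float]:
    """Distribution of how many distinct proteins contain each trimer.

    Input is (trimer, protein_id) occurrence pairs; identity is the
    canonical key. Returns {protein count: fraction of distinct trimers},
    fractions summing to 1.
    """
    proteins_by_key: dict[str, set[str]] = defaultdict(set)
    for t, protein in trimer_proteins:
        key = canonical_key(t) if isinstance(t, str) else t.key
        proteins_by_key[key].add(protein)
    if not proteins_by_key:
        return {}
    counts = Counter(len(ps) for ps in proteins_by_key.values())
    total = len(proteins_by_key)
    return {k: counts[k] / total for k in sorted(counts)}


def trimer_physchem_summary(
    trimers: Iterable[Trimer | str],
    hydropathy: Mapping[str, float] = KYTE_DOOLITTLE,
    charge: Mapping[str, float] = SIDE_CHAIN_CHARGE,
) -> dict:
    """Classify trimers by hydropathy and net side-chain charge.

    A trimer's hydropathy is the mean of its residues' scale values
    (hydrophobic if > 0); its net charge is the sum of side-chain charges
    at pH 7 (positive / neutral / negative). Defaults: Kyte-Doolittle
    hydropathy; K,R=+1, H=+0.1, D,E=-1 charges.
    """
    per_trimer: list[dict] = []
    agg = Counter()
    for t in trimers:
        t = Trimer(t) if isinstance(t, str) else t
        try:
            h = sum(hydropathy[aa] for aa in t.raw) / 3.0
            q = sum(charge[aa] for aa in t.raw)
        except KeyError as e:
            raise ValueError(f"scale missing residue {e.args[0]!r}") from None
        h_class = "hydrophobic" if h > 0 else "hydrophilic"
        q_class = "positive" if q > 0 else ("negative" if q < 0 else "neutral")
        per_trimer.append(
            {
                "key": t.key,
                "hydropathy": h,
                "hydropathy_class": h_class,
                "charge": q,
                "charge_class": q_class,
            }
        )
        agg[(h_class, q_class)] += 1
    return {
        "per_trimer": per_trimer,
        "counts": {f"{h}/{q}": n for (h, q), n in sorted(agg.items())},
        "hydrophobic_fraction": (
            sum(1 for r in per_trimer if r["hydropathy_class"] == "hydrophobic")
            / len(per_trimer)
            if per_trimer
            else float("nan")
        ),
    }
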