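"""Synthetic data generators emulating the scPDB-derived study inputs.

Three generators cover every input the pipeline consumes:

* a 20 x P amino-acid property table with planted rank-5 structure plus
  noise, so a 5-component PCA is meaningful;
* protein-drug complexes whose binding sites are seeded with planted
  trimer motifs shared within latent drug families, so genuine
  drug-cluster affinity exists and held-out edges are recoverable;
* bare random bipartite networks at a chosen density for link-prediction
  unit tests at the reference scale (97 x 97, density ~0.231 ~ 2174
  edges).

Defaults mirror the reference dataset's scale: 97 drugs over 110
complexes, site lengths 20-40, 237 properties. Everything is a pure
function of (spec, seed).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from ._aa import STANDARD_AA
from .io import AminoAcidPropertyTable, ComplexRecord
from .network import DCANetwork
from .trimers import canonical_key

__all__ = [
    "SyntheticSpec",
    "SyntheticComplexes",
    "generate_property_table",
    "generate_complexes",
    "generate_bipartite",
]


@dataclasses.dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic study conditions.

    ``n_motifs`` planted trimer motifs are split among ``n_families``
    latent drug families (``motifs_per_family`` each, drawn with
    replacement across families); every drug inherits its family's motif
    set. ``noise`` is the probability that a 3-residue site unit is
    random sequence rather than a preferred motif.
    """

    n_drugs: int = 97
    n_proteins: int = 100
    n_complexes: int = 110
    site_length: tuple[int, int] = (20, 40)
    n_properties: int = 237
    n_motifs: int = 60
    n_families: int = 12
    motifs_per_family: int = 12
    noise: float = 0.1
    property_noise: float = 0.05
    density: float = 0.231
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_drugs, self.n_proteins, self.n_complexes) < 1:
            raise ValueError("counts must be positive")
        if not (0 < self.density < 1):
            raise ValueError("density must be in (0, 1)")
        if not (0 <= self.noise <= 1):
            raise ValueError("noise must be in [0, 1]")
        if self.n_properties < 5:
            raise ValueError("need at least 5 properties")


@dataclasses.dataclass(frozen=True)
class SyntheticComplexes:
    """Generated complexes plus the planted ground truth."""

    records: tuple[ComplexRecord, ...]
    drug_motifs: dict[str, frozenset[str]]  # drug -> preferred motif keys
    families: dict[str, int]  # drug -> family index
    motif_pool: tuple[str, ...]  # raw 3-residue motif strings


def generate_property_table(
    spec: SyntheticSpec, seed: int | None = None
) -> AminoAcidPropertyTable:
    """20 x P property table with 5 latent factors plus Gaussian noise."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    latent = rng.normal(size=(20, 5))
    loadings = rng.normal(size=(5, spec.n_properties))
    values = latent @ loadings
    if spec.property_noise > 0:
        values = values + spec.property_noise * rng.normal(size=values.shape)
    props = tuple(f"prop{j:03d}" for j in range(spec.n_properties))
    return AminoAcidPropertyTable(tuple(STANDARD_AA), props, values)


def _random_trimer(rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(STANDARD_AA), size=3))


def generate_complexes(
    spec: SyntheticSpec, seed: int | None = None
) -> SyntheticComplexes:
    """Complexes whose sites share planted motifs within drug families.

    Sites are assembled from 3-residue units: with probability
    ``1 - noise`` a unit is a motif from the drug's preferred set, else
    random sequence. The first ``n_drugs`` complexes get distinct drugs
    so every drug is observed; extra complexes draw drugs at random
    (some drugs appear in several complexes, as in the reference data).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    # distinct motif pool (distinct canonical keys)
    pool: list[str] = []
    seen: set[str] = set()
    while len(pool) < spec.n_motifs:
        t = _random_trimer(rng)
        k = canonical_key(t)
        if k not in seen:
            seen.add(k)
            pool.append(t)

    family_motifs = [
        tuple(rng.choice(spec.n_motifs, size=spec.motifs_per_family, replace=False))
        for _ in range(spec.n_families)
    ]
    drugs = [f"drug{i:03d}" for i in range(spec.n_drugs)]
    families = {d: int(rng.integers(spec.n_families)) for d in drugs}
    drug_motifs = {
        d: frozenset(canonical_key(pool[m]) for m in family_motifs[families[d]])
        for d in drugs
    }

    lo, hi = spec.site_length
    records: list[ComplexRecord] = []
    for i in range(spec.n_complexes):
        drug = drugs[i] if i < spec.n_drugs else drugs[int(rng.integers(spec.n_drugs))]
        target_len = int(rng.integers(lo, hi + 1))
        units: list[str] = []
        length = 0
        my_motifs = family_motifs[families[drug]]
        # signal units walk the family's cyclic motif order from a random
        # phase, so junction windows between adjacent motifs repeat across
        # family-mates (overlapping binding sites share runs, not just
        # isolated trimers)
        ptr = int(rng.integers(len(my_motifs)))
        while length < target_len:
            if rng.random() >= spec.noise:
                unit = pool[int(my_motifs[ptr])]
                ptr = (ptr + 1) % len(my_motifs)
            else:
                unit = _random_trimer(rng)
            units.append(unit)
            length += 3
        seq = "".join(units)[:target_len]
        protein = f"prot{int(rng.integers(spec.n_proteins)):03d}"
        records.append(
            ComplexRecord(
                complex_id=f"cpx{i:04d}",
                protein_id=protein,
                drug_id=drug,
                site_residues=tuple((j + 1, aa) for j, aa in enumerate(seq)),
            )
        )
    return SyntheticComplexes(
        records=tuple(records),
        drug_motifs=drug_motifs,
        families=families,
        motif_pool=tuple(pool),
    )


def generate_bipartite(
    n_drugs: int = 97,
    n_clusters: int = 97,
    density: float = 0.231,
    seed: int = 0,
) -> DCANetwork:
    """Evidence-free random bipartite network: each cell ~ Bernoulli(density)."""
    if not (0 <= density < 1):
        raise ValueError("density must be in [0, 1)")
    rng = np.random.default_rng(seed)
    A = (rng.random((n_drugs, n_clusters)) < density).astype(np.int8)
    return DCANetwork.from_adjacency(A, synthetic=True)
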