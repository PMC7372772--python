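# dcanet — drug–cluster association networks for DNA-binding proteins

`dcanet` predicts interactions between drugs and DNA-binding proteins
(DBPs) from the *local* chemistry of drug-binding sites. Instead of
relating whole proteins to drugs, it breaks each binding site into
amino-acid **trimers** (3-residue sliding windows), groups trimers of
similar physicochemical character into clusters, and links drugs to the
clusters their binding sites contain. Unobserved drug–cluster links are
then ranked purely from the topology of this bipartite network, and
significant links are expanded back into concrete drug–trimer and
drug–protein candidates. It is aimed at computational chemists and
network biologists who have binding-site sequences (e.g. scPDB-style
pocket annotations) and want interpretable, site-level interaction
hypotheses.

## The model

1. **Amino-acid embedding.** Each of the 20 amino acids is described by
   *P* physicochemical properties (volume, polarizability, solvation
   free energy, ...; *P* = 237 in the reference data). The 20 × *P*
   matrix is column-standardized and reduced by PCA; the amino-acid
   coordinate is the score vector
   X(\*) = (√λ₁E₁, …, √λ₅E₅),
   so component *i* has variance λᵢ over the 20 amino acids.
2. **Trimer vectors.** A window α₀₁–α₀₀–α₁₀ (center α₀₀, unordered
   flanks) maps to
   α_tri = X(α₀₀) + (X(α₀₁) + X(α₁₀)) / 4,
   weighting the central residue and symmetric in the flanks.
3. **Clustering.** Distinct trimers are agglomerated (Euclidean,
   average linkage by default) and the tree is cut at *k* clusters,
   with *k* equal to the number of distinct drugs by default.
4. **Bipartite network.** G(D, C, E) with adjacency a_ij = 1 iff some
   complex binding drug dᵢ contains a trimer of cluster cⱼ.
5. **Link prediction.** With Γ(x) the clusters of drug x and
   Γ̂(y) the clusters adjacent to any drug adjacent to cluster y:
   - CN′(x,y) = |Γ(x) ∩ Γ̂(y)|
   - JA′(x,y) = |Γ(x) ∩ Γ̂(y)| / |Γ(x) ∪ Γ̂(y)|
   - PA(x,y) = k_x · k_y
6. **Evaluation.** 10-fold cross-validation over the known edges with
   1:1 negative sampling, threshold-swept ROC/PR curves
   (positive ⇔ score ≥ threshold), and a 100-repetition randomized-
   interaction benchmark that estimates the chance baseline.

## Worked example

```python
import dcanet
from dcanet.synthetic import SyntheticSpec

model = dcanet.DCAModel.from_synthetic(SyntheticSpec(seed=0))
res = model.fit()
print(res.summary())
rep = res.evaluate("CN", dcanet.CVConfig(seed=0, repetitions=100), benchmark=True)
print(rep.summary())
```

prints

```
Drug-cluster association model
==============================================
complexes               110   (skipped short sites: 0)
drugs                    97
trimer occurrences     3054
distinct trimers        725
clusters (k)             97   linkage=average
network edges          2144   density=0.228
embedding eigenvalues [87.71 63.1  37.41 32.54 16.07]
single-protein trimer fraction 0.535

Cross-validated link prediction (CN)
  folds=10  neg/pos=1.0  seed=0
  AUC           0.7378
  AUPR          0.7151
  F1            0.7240
  Sensitivity   0.8925
  Specificity   0.4257
  baseline AUC  0.4995
  adjusted AUC  0.2384
```

The synthetic preset plants drug families that share trimer motifs, so
a genuine drug–cluster affinity exists: the common-neighbors index
recovers held-out edges at AUC ≈ 0.74, about 0.24 above its own
randomized-interaction baseline (≈ 0.5, i.e. chance). `res.predict("CN")`
then yields the significant/important drug–cluster pairs and their
expansion into drug–trimer and drug–protein candidates with novelty
flags.

The same pipeline runs from the shell:

```sh
dca simulate --seed 0 --out sim/
dca run --properties sim/properties.tsv --complexes sim/complexes.tsv --out out/ --seed 0
```

writing every stage's artifact (embedding, trimer table, clustering,
network edge list, score matrix, significant/important edges, expanded
predictions, evaluation report) plus a manifest under `out/`.

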