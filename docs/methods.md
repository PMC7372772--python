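# Methods

## Model and assumptions

`dcanet` treats drug binding as a local event: the information carried
by a protein–drug complex is assumed to live in short windows of the
binding-site sequence rather than in the whole protein. The working
units are amino-acid trimers — width-3, step-1 windows over the
assembled site sequence — with a central (major) residue and two
unordered flanking (subordinate) residues. Two consequences of that
identity are enforced throughout: windows that differ only by flank
order share a canonical key (`center(sorted flanks)`), and counting or
clustering always operates on canonical keys, never raw windows (the
raw window and its provenance are kept for audit).

Binding sites arrive as pre-extracted residue lists. Discontinuous
residues are concatenated in residue-number order; this is the one
reproducible ordering available without structures, and spatial
reordering is deliberately not attempted. Sites shorter than three
residues cannot produce a window and are rejected (in bulk pipelines,
skipped and counted) rather than padded, since padding would fabricate
residues. Nonstandard residue codes are rejected, not imputed: the
property table defines exactly 20 amino acids.

## Amino-acid embedding

The 20 × P property matrix mixes units (volumes, energies,
polarizabilities), so columns are standardized (mean 0, variance 1 over
the 20 amino acids, ddof = 1) before PCA; an unstandardized PCA would
be dominated by the largest-unit properties. Zero-variance columns are
dropped first and recorded. The factorization follows the score
convention: amino-acid coordinates are projections of standardized rows
onto unit-norm principal axes, so the variance of component *i* equals
the eigenvalue λᵢ and the coordinate matrix is literally
(√λ₁E₁, …, √λ₅E₅). Eigenpairs come from the SVD of the standardized
matrix; each axis's sign is fixed so its largest-magnitude loading is
positive, which makes results identical across linear-algebra backends.
`n_components` defaults to 5 and can be at most min(19, #kept columns)
— the rank bound after centering 20 rows.

## Clustering

Trimer vectors are agglomerated bottom-up and the tree is cut at
exactly *k* clusters, with *k* defaulting to the number of distinct
drugs (one physicochemical "group" per drug type; 97 at the reference
scale). Average linkage on Euclidean distances is the default: single
linkage chains badly in a 5-d continuous space, and the
cluster-as-chemical-group reading wants compact clusters. Single,
complete and Ward updates are available.

The agglomeration is implemented directly via Lance–Williams updates
over a full distance matrix rather than through a library routine,
because the determinism contract is part of the method: merge-distance
ties are broken by the lexicographically smallest pair of cluster
representative keys (a cluster's representative is its smallest member
key), and cluster indices are assigned by decreasing size with ties by
smallest member key. This makes the partition a pure function of the
key → vector map — invariant to input order and platform. The naive
O(n³) recomputation oracle and scipy's implementation (on tie-free
data) both serve as cross-checks in the test suite. The merge history
is retained for audit, and cutting at k versus k−1 differs by exactly
one merge by construction.

Out-of-vocabulary trimers (keys absent from the fitted clustering, as
in independent test sets) are assigned to the nearest centroid,
ties to the lowest cluster index.

## Network

The drug–cluster network is bipartite and binary: an edge means "some
complex binding this drug contains a trimer of this cluster". Trimer
multiplicity deliberately does not weight the adjacency — it lives in
the per-edge evidence lists ((protein, complex, trimer) triples), which
the prediction-expansion step uses to turn significant drug–cluster
links into drug–trimer and drug–protein candidates with novelty flags.
Drugs observed in several complexes pool evidence onto the same edges.
Empty clusters are retained with degree zero so the n × m shape is
stable across CV folds. Degree summaries expose both set- and
multiset-valued two-hop totals, since two-hop "neighbor counts" are
ambiguous between the two conventions.

## Link prediction

In a bipartite graph a drug's neighbors are clusters and a cluster's
neighbors are drugs, so the classical indices are adapted by replacing
the cluster's neighborhood with its two-hop cluster set Γ̂(y). Γ̂ uses
set semantics by default ("the set of neighbors of the neighbors"); a
path-counting multiset variant is available behind a flag for
sensitivity analysis. y itself belongs to Γ̂(y) whenever it has any
neighbor, and known edges are scored like every other pair — they are
excluded only during evaluation, via the known mask.

Thresholding is configuration, not estimation: scores strictly above
the significance cutoff are significant, and the important set is the
top fraction (default 20 %) of significant entries by score, count
rounded up, boundary ties all included — or an absolute cutoff when
given. When no cutoff is supplied, a fold-resampling estimate is used:
each CV fold's training network rescoring gives per-pair score spread,
and the cutoff is the mean over pairs of the across-fold standard
deviation. This is an uncertainty-scale heuristic, not a significance
test.

## Evaluation

Known edges are shuffled once (seeded) and split into test folds of
exactly floor(|E|/n_folds); the remainder edges stay in every training
set, so every fold has equal size (217 positives per fold at the
reference scale of 2174 edges). Before scoring, the fold's test
positives are removed from the adjacency — the only non-leaking
protocol, since CN would otherwise read the answer off the edge itself.
Negatives are drawn uniformly without replacement from never-observed
pairs, one per positive by default (434-pair test sets at reference
scale).

Curves sweep thresholds over the distinct observed scores plus a
sentinel above the maximum, calling a pair positive when score ≥
threshold. Tied scores share one threshold step, making the trapezoidal
ROC AUC equal to the tie-corrected Mann–Whitney statistic (ties count
½) — an identity the tests assert to 1e-10. The PR curve takes the best
precision at each recall level before trapezoidal integration. Scalar
F1/sensitivity/specificity are reported at the per-fold max-F1
threshold (ties resolve to the larger threshold); the convention is
declared rather than claimed to match any particular published table,
and the full curves are emitted so other conventions can be recovered.
Metrics with zero denominators are reported as undefined, never 0.

The benchmark baseline replaces each fold's test positives with an
equal-size uniform sample of non-edges ("randomly created invalid
interactions"), keeps the matched negative sampling, and evaluates
identically; 100 repetitions (default) are averaged, with the baseline
ROC curve vertically averaged on a 101-point FPR grid. Because fake
positives and negatives are then exchangeable draws from the same pool,
the baseline AUC is ≈ 0.5 by construction, and adjusted metrics (real −
baseline) measure lift over chance. A degree-preserving randomization
is intentionally not the default; the resampling scheme matches the
plain "invalid interactions" description.

All stochastic steps derive from a single integer seed through separate
seed sequences (fold shuffle, per-fold negative draws, per-repetition
benchmark draws), so every reported number is bit-reproducible from
(config, seed).

## Synthetic data

The generators emulate the three study inputs at the reference scale.

*Property tables* are 20 × 237 with five latent Gaussian factors plus
noise (σ = 0.05 by default), so PCA to 5 components captures nearly all
variance; they do not attempt to mimic real amino-acid property
correlations beyond that low-rank structure.

*Complexes* (110 complexes over 97 drugs, site lengths uniform 20–40)
plant the signal the model is supposed to find. Drugs belong to one of
12 latent families; each family prefers 12 of 60 planted trimer motifs.
A site is assembled from 3-residue units: with probability 0.9 the next
unit walks the family's cyclic motif order (so junction windows between
adjacent motifs are shared within a family, the way overlapping real
binding sites share runs of sequence), and with probability 0.1
(the noise level) it is a random trimer. The family/motif/noise values
were fixed once by simulation so that the emergent network matches the
reference dataset's descriptive statistics — ~2100–2300 edges
(reference: 2174), ~3000 trimer occurrences (reference: 3240 distinct
from 3463 sites), ~90 % of drugs with degree 15–30 (reference: 87.6 %)
— and so that held-out edges are genuinely recoverable (CN AUC ≈
0.73–0.78 across seeds, comfortably above the chance baseline). The
generator returns the drug → motif ground truth so recovery can be
scored without peeking at generator internals.

What passing recovery tests show is therefore that the pipeline finds
planted, family-structured trimer sharing at realistic density and
degree structure; they do not show that real scPDB-derived sites carry
that much signal, and published AUCs on the authors' deposited data are
not reproduced here.

*Bare bipartite networks* draw each cell independently at a chosen
density. They carry no evidence and are flagged synthetic; prediction
expansion refuses them, and they are used for index unit tests and the
chance-level benchmark, where independence guarantees a 0.5 baseline.

## Numerical and degenerate-input choices

- Jaccard of two empty neighborhoods is 0 (documented convention).
- Equidistant centroid assignment returns the lowest index.
- Exact float equality defines merge-distance ties; the lexicographic
  rule then makes the choice deterministic.
- Score matrices and reports serialize at 12 significant digits and
  round-trip losslessly at that precision.
- Single-class score sets raise rather than return a degenerate AUC.

## Problem sizes

Default test and acceptance runs use the reference-scale preset (97
drugs, 110 complexes, ~700 distinct trimers, 97 clusters) and 97 × 97
random networks; the full suite and the acceptance script each complete
in well under a minute per headline computation on one CPU. These sizes
are the package's chosen study conditions, matching the reference
dataset's scale.

## Known limitations

- The published headline AUCs and score-matrix counts of the reference
  analysis depend on its deposited dataset and unstated linkage and
  cutoff conventions; they are out of scope here and not asserted.
- Only k = 3 windows are supported; the trimer arithmetic is specific
  to a center-plus-two-flanks window.
- The significance cutoff is configuration; the fold-resampling
  estimate is a heuristic scale, not a calibrated error rate.
- Structure parsing (PDB/mmCIF/MOL2) and pocket detection are out of
  scope; the package consumes pre-extracted site sequences.
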