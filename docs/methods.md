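# Methods

## Problem and model

Given a protein structure, a ligand, and a pool of candidate pockets from
a cavity-detection tool, the task is to rank the candidates by how likely
each is the ligand's native binding pocket. The model treats this as
binary classification of a ligand–pocket pair vector.

**Pair vector.** The ligand is parsed (SMILES, or SDF/MOL2/PDB with
perception) into a molecular graph and decomposed into Morgan circular
substructure identifiers — one per heavy atom at radius 0 and one at
radius 1, the word2vec-over-substructures convention. Each identifier is
looked up in an embedding table (word2vec text format: a `<vocab> <dim>`
header, then one identifier plus `dim` floats per line) and the molecule
vector is the element-wise sum; out-of-vocabulary identifiers contribute
nothing by default (a shared UNK vector is available). A pocket is the
multiset of its residue names; each residue is featurized through the
canonical SMILES of the free amino acid and the pocket vector is the sum
over residues. Free-amino-acid fragments avoid broken-bond valence
artifacts and need no 3-D perception; the representation is therefore
purely compositional — it ignores residue order and pocket geometry, by
design, since geometry enters through the labeling protocol instead. The
classifier input concatenates ligand vector (indices 0–299 at the default
dimension 300) and pocket vector (300–599).

**Classifier.** A densely connected feed-forward network: with h₀ = x,
block k (k = 1…16) computes h_k = dropout(ReLU(W_k·[h₀,…,h_{k−1}] + b_k))
with 100 units and dropout rate 0.25, and the output is
σ(w·[h₀,…,h₁₆] + b). Every concatenation includes the raw input as layer
zero, and the output layer consumes all block outputs; both choices follow
the densest consistent reading of "each layer takes all outputs of its
preceding layers". Training minimizes binary cross-entropy with mini-batch
Adam (default learning rate 1e-3, batch 128); the default 1,500 epochs is
the point at which validation curves for the real-scale task converge,
and is freely overridable — the synthetic experiments below converge in
tens of epochs. Weights use seeded He-style uniform initialization
(U(±√(6/fan_in))), appropriate for ReLU; the forward pass in inference
mode is a pure function, and probabilities are clipped to
[1e-12, 1−1e-12] so the output stays strictly inside (0,1) despite float
saturation. Implemented directly in numpy as a scikit-learn estimator
(`fit` / `predict_proba` / `get_params`), which keeps the arithmetic
simple enough to verify against a per-sample pure-python oracle.

## Labeling protocol and thresholds

All thresholds are stored in nm; PDB coordinates are Å and converted at
the boundary (1 nm = 10 Å).

| parameter | default | meaning |
|---|---|---|
| pocket_radius | 1.0 nm | residues with any atom this close to any ligand atom form the known pocket |
| near_native_max | 0.3 nm | decoys closer than this (Cα-centroid distance) are positives |
| negative_min | 1.0 nm | decoys farther than this are negative candidates |
| negatives_per_protein | 3 | uniform draw without replacement (all kept if fewer) |
| similarity_cutoff | 0.995 | candidates with cosine similarity ≥ cutoff to the known pocket's vector are removed before the draw |

"Cα-centroid distance" is read as the Euclidean distance between the
arithmetic means of the pockets' Cα coordinates — the simplest reading.
The 0.3–1 nm band is excluded as ambiguous rather than forced into either
class. The similarity boundary removes at S ≥ cutoff (equality counts as
"highly similar"); exact duplicate vectors are assigned S = 1 directly so
the boundary case is not lost to float rounding. A distance of "farther
than 3 nm" appears in qualitative descriptions of far decoys and is
carried as an informational field, not an extra filter. Normalization is
one scalar affine map (t − mean)/std over all 600 components — the
published constants are single scalars per strategy, not per-dimension —
either fixed from the training set (−0.5696/30.8744 near-native,
−0.9610/63.6607 native) or estimated from the matrix itself; fixed
training-set constants are the default at ranking time. Positives may be
replicated (default knob ×3) to balance the three negatives drawn per
complex.

Structure handling: first-listed alternate location kept per atom;
hydrogens kept but irrelevant to Cα centroids; waters and common
ions/additives never count as pocket residues; pockets without any Cα
are rejected (files: skipped with a warning). Candidate-pocket
directories follow the fpocket dialect `pocket<k>_atm.pdb` with a
configurable glob.

## Metrics

Accuracy, TPR (sensitivity), precision, specificity, and MCC come from
confusion counts at the probability threshold 0.5 (score ≥ 0.5 predicts
positive); ratios with zero denominator are NaN and MCC is 0 when a
marginal vanishes. AUC is the rank-based Mann–Whitney statistic with ties
counted ½. `counts_from_rates` inverts published summary rows:
TP = round(tpr·P), FP = round(TP·(1−precision)/precision), FN and TN by
complement, rounding half away from zero; because printed rates are
themselves rounded, reconstructed MCC/accuracy are asserted at two
decimals.

## Synthetic data: what it emulates and what it does not

The generators produce the exact dialects the pipeline consumes (PDB
files, fpocket-style pocket directories, word2vec-text tables), fully
reproducible from their seed.

* **Embedding tables** draw i.i.d. standard-normal vectors over the
  vocabulary actually produced by the 20 amino acids plus a small ligand
  alphabet. They preserve the lookup-and-sum structure but carry no
  learned chemistry.
* **Toy complexes** are geometric Cα scaffolds: the known pocket is a
  ring of residues 5 Å around a placed three-atom ligand, and each decoy
  is a ring whose centroid sits exactly at a requested distance from the
  known centroid, so intended labels under the thresholds are known by
  construction (verified to 0.01 nm). Residue names vary across the 20
  standard amino acids: near-native decoys reuse the known pocket's
  composition (one substitution) while far decoys draw from a disjoint
  half of the alphabet. This encodes native-likeness compositionally —
  the analogue of real near-native decoys being built from the native
  pocket's own residues — and keeps pocket vectors non-collinear, which a
  homogeneous (single-residue-type) scaffold would not do: with one
  residue type every pocket vector is a scalar multiple of the same
  vector and the similarity filter would remove all negatives.
* **Separable vector sets** are two spherical Gaussians in 600-d at mean
  distance s, for which the Bayes-optimal AUC has the closed form
  Φ(s/√2) ≈ 0.983 at s = 3 — an analytic anchor for training tests.

Passing on these fixtures demonstrates that the mechanics are correct
(parsing, labeling, featurization algebra, optimization, ranking), not
that the model attains its real-data performance: real performance
depends on a chemically trained embedding corpus and a large complex
collection, which the fixtures deliberately do not imitate.

## Experiment sizes and numerical choices

The end-to-end synthetic experiment uses 20 training complexes (five
decoys each → 100 labeled examples), a 32-d embedding table, and a 4-block
× 32-unit network trained 50 epochs at batch 16 — sizes at which the
experiment converges stably across seeds; smaller training sets were
observed to overfit occasionally, letting a far decoy outrank the
native-like one. The separable-data training check uses the full default
16×100 architecture on 2,000/2,000 training vectors at separation 3 for
12 epochs (chance-level control: shuffled labels, 5 epochs).

Ties in ranking break by pocket id ascending for determinism; pockets
that fail featurization are reported with a NaN-score sentinel rather
than dropped. Negative sampling, weight initialization, batch order and
dropout masks all derive from explicit seeds, making dataset construction
and training bit-reproducible; checkpoints store weights, the full
configuration and the normalization constants, and a loaded model
reproduces forward outputs exactly.

## Limitations

No cavity detection of its own (fpocket/P2Rank are upstream); no mmCIF
input; residue featurization ignores the bonded protein context; the
pocket representation discards geometry beyond the labeling thresholds;
no transfer to membrane-protein (GPCR) chemistry is attempted; training
the substructure-embedding corpus is out of scope — tables are loaded
from file or generated synthetically.
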