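# Methods

This note records what each stage of `pharmscreen` computes, the parameters
and their defaults, and the design decisions that the code alone does not
explain. Units are stated where they apply; defaults live in the module that
owns them.

## Compound preparation (`molprep`)

Input is a table of `(id, smiles, ec50_nm)` rows. Processing order is fixed:

1. **Standardisation** — parse, keep the largest organic fragment (most heavy
   atoms among carbon-containing fragments), neutralise simple charged groups,
   emit canonical isomeric SMILES. Unparseable rows are rejected with reason
   `parse_error`.
2. **Deduplication** — rows collapsing to the same canonical SMILES are
   reduced to the row whose pEC50 is closest to the group median (ties: lower
   EC50, then lexicographic id). Dedup runs *before* the activity filter so a
   compound measured both potent and weak is represented by its median
   potency, not its luckiest replicate.
3. **Rule-of-five filter** — a record passes with at most one violation of
   MW ≤ 500 Da, cLogP ≤ 5, H-bond donors ≤ 5, H-bond acceptors ≤ 10.
4. **Activity filter** — actives are records with EC50 strictly below
   100 nM (default). pEC50 = 9 − log10(EC50 in nM).

Every rejected row carries a machine-readable reason code.

## Clustering (`clustering`)

Fingerprints are Morgan radius-2 (ECFP4), 2048 bits by default. Similarity is
Tanimoto; the full matrix is stored upper-triangular. Clustering is the
exclusion-sphere (Butina) algorithm: count neighbours at Tanimoto ≥ τ
(default 0.35), visit compounds in descending neighbour count (stable order
for ties), and let each unflagged visit absorb its unflagged neighbours as a
new cluster with the visited compound as centroid. Singletons are size-1
clusters. Training sets are the centroids of clusters meeting a minimum size
(the viable-cluster ladder uses minimums 5, 25, 50, 75). Cluster quality can
be summarised with the silhouette coefficient on 1 − Tanimoto distances.

## Decoy generation (`decoygen`)

Stands in for a generative decoy model: decoys are *selected* from a supplied
candidate pool rather than generated de novo.

- Candidates with maximum ECFP4 Tanimoto to any active ≥ 0.35 (`sim_cap`) are
  excluded, so no decoy is a structural analogue of an active.
- Each remaining candidate is embedded in a 10-property space (MW, cLogP,
  HBD, HBA, rotatable bonds, TPSA, fraction Csp3, ring count, formal charge,
  heavy atoms), z-scored on actives ∪ eligible candidates.
- For each active in input order, the 50 (`ratio`) nearest unassigned
  candidates by Euclidean distance are taken. A shortfall raises an error
  reporting the deficit.

Quality statistics: **DOE** (mean over actives of the area between the
property-space nearest-neighbour ROC and the diagonal; 0 = matched,
0.5 = fully separable), **doppelganger** (per-decoy maximum Tanimoto to the
actives; mean and max reported), and **AUC-1NN** (leave-one-out
1-nearest-neighbour separability of actives vs decoys; 0.5 is ideal).

## Pharmacophore engine (`pharmacophore`)

Feature perception uses SMARTS definitions for donor, acceptor, hydrophobe,
aromatic ring, cation and anion; each feature's centre is the centroid of its
matched atoms in a 3D conformer. Tolerance radii default to 1.0 Å for all
types except hydrophobes at 1.4 Å.

Conformers come from RDKit ETKDGv3 with a fixed random seed, MMFF94
minimisation, and RMSD pruning (0.5 Å default) in energy order.

**Elucidation** enumerates every k-feature subset (k in 3..5) of every
training conformer as a candidate query (per conformer the 12
lowest-index features are considered, which bounds the subset enumeration).
A candidate is retained if it matches at least ⌈coverage × n_training⌉
training molecules (coverage default 0.5). Retained queries are deduplicated
by feature-type multiset plus a pairwise-distance signature binned at 0.5 Å.

**Matching** searches, over conformers and injective type-compatible
assignments of molecule features to query features, for the assignment whose
Kabsch least-squares superposition leaves every feature within its query
sphere (displacement ≤ radius, sphere-on-query semantics). The assignment
search is pruned by the triangle bound |d_conf − d_query| ≤ r_i + r_j.
Prediction is 1 if any feasible assignment exists; the reported RMSD is the
minimum over feasible assignments, and the rescore is
clip(1 − RMSD / r_max, 0, 1) where r_max is the largest query radius.

## Screening metrics (`metrics`)

With TP/FP/TN/FN counts: precision P, recall R, specificity S, FPR; any
denominator of zero yields 0 (this reproduces the all-inactive collapse where
GH = F1 = 0).

- **GH** = (0.75 P + 0.25 R) × S
- **F1** = 2PR / (P + R)
- **EF_χ%** = (n_s / N_s) · (N / n) with N_s = ⌈χN/100⌉ and pessimistic tie
  handling: inactives tied at the cutoff are ranked ahead of actives, so EF
  never benefits from ties. The ceiling at χ% is min(N_s, n)·N/(n·N_s).
- **ROC/AUC** via scikit-learn (ties contribute ½).

## Ensembles and protocol (`ensemble`)

Member models are represented by a matrix of binary predictions and
continuous rescores per molecule. Ensembling:

- **Filtering** — keep members with AUC ≥ θ (default 0.6) computed on the
  training portion only; descending-AUC order.
- **Voting** — active iff strictly more than half of the filtered members
  vote active; exact ties go inactive (conservative for 1:50 screens).
- **Stacking** — XGBoost meta-model on member predictions (`stack_predict`),
  rescores (`stack_score`), or both (`stack_global`); `stack_featsel`
  additionally screens features with a 300-tree random forest, keeping
  features with importance above the mean (all kept when ≤ 2 features).
  Meta-model hyperparameters are pinned (300 trees, depth 2, learning rate
  0.05, logloss, single thread) — shallow and slow to favour generalisation
  over fitting the fold. Single-class training data degrades to a constant
  majority-class model with a warning.

Protocol: stratified 80:20 split (fixed seed), member filtering on the 80%,
3×10 repeated stratified k-fold CV inside the 80% (30 per-fold AUC / EF1% /
GH / F1 values), refit on the full 80%, metrics on the untouched 20%.
Configurations are compared with the paired two-sided Wilcoxon signed-rank
test on per-fold series (≥ 6 pairs required; identical series give p = 1),
significance at p ≤ 0.05.

## Synthetic data (`synthdata`)

The generators provide ground-truth-bearing inputs; their defaults are the
study conditions used by the tests and the reproduction script.

- `synth_molecules` — scaffold-decoration chemistry: 5 fixed templates, 18
  substituents, 2 substitution slots. Emulates congeneric series whose
  scaffold labels Butina clustering should recover. It does **not** emulate
  realistic SAR, synthesisability or property coverage; in particular the
  cores are property-separable, so decoys selected across scaffolds score
  near the DOE ceiling.
- `synth_planted_conformers` — actives are the query's feature geometry plus
  isotropic Gaussian noise (`noise_sd`, Å) under a random rigid motion;
  decoys are uniform feature sets in a ball spanning the query. Emulates
  geometric signal only, not conformational energetics.
- `synth_score_matrix` — binormal model scores with prescribed AUCs
  (μ = √2·Φ⁻¹(AUC) for actives), optional equicorrelation via a shared latent
  factor, binary predictions thresholded at a decoy quantile (default 95th
  percentile ⇒ 5% member FPR). Emulates a panel of screening models with
  known individual skill and known dependence.

All randomness flows from explicit integer seeds; derived seeds stay below
2³¹.

## Numerical choices

- Tanimoto of two empty fingerprints is defined as 0.
- Silhouette with a single cluster raises (`undefined_silhouette`);
  scikit-learn's convention of 0 for singleton clusters is inherited.
- EF uses ⌈·⌉ for the selection size so the top set is never empty.
- Kabsch superposition uses SVD with a determinant reflection guard.
- Degenerate metric denominators return 0 rather than NaN so downstream
  aggregation never propagates missing values.
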