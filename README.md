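# pharmscreen

Ligand-based 3D pharmacophore virtual screening with clustering-driven model
building and ensemble learning, aimed at hit finding for targets where potent
agonists are known but no structure-based route is practical. The intended
audience is computational and medicinal chemists who want a transparent,
scriptable pipeline from an activity table to a ranked screen.

## What it does

Given a table of compounds with EC50 values, the pipeline:

1. **Prepares actives** — standardises structures, deduplicates, applies
   Lipinski's rule of five (≤ 1 violation), and keeps compounds with
   EC50 < 100 nM (pEC50 = 9 − log10 EC50).
2. **Clusters by chemotype** — exclusion-sphere (Butina) clustering on ECFP4
   Tanimoto similarity at τ = 0.35; cluster centroids of viable clusters
   become pharmacophore training sets.
3. **Generates property-matched decoys** — 50 decoys per active selected by
   nearest neighbour in z-scored physicochemical space, with an ECFP4
   similarity cap of 0.35 to the actives, plus DOE, doppelganger and AUC-1NN
   quality diagnostics.
4. **Elucidates and applies pharmacophores** — common-feature queries of 3–5
   typed spheres (donor/acceptor/hydrophobe/aromatic/ionic; radii 1.0 Å,
   hydrophobes 1.4 Å) enumerated from training conformers; a molecule matches
   when some conformer admits an injective feature assignment whose Kabsch
   superposition keeps every feature inside its sphere. Matches are rescored
   as 1 − RMSD/r_max.
5. **Scores screens** — GH = (0.75P + 0.25R)·Specificity, F1, enrichment
   factor EF_χ% = (n_s/N_s)(N/n), and ROC AUC.
6. **Ensembles the models** — AUC-filtered (θ ≥ 0.6) panels combined by
   strict-majority voting or by XGBoost stacking on member predictions and/or
   rescores, evaluated with a stratified 80:20 split, 3×10-fold
   cross-validation and paired Wilcoxon comparisons.

A `synthdata` module supplies seeded ground-truth generators (congeneric
series, planted feature geometries, prescribed-AUC score matrices) so every
claim the package makes can be checked against a known answer.

## Worked example

`examples/` contains one short narrative script per capability. Running
`python examples/05_ensemble_benchmark.py` — five conditionally independent
AUC-0.75 models on a 100-active / 5000-decoy screen — prints:

```
models passing the AUC >= 0.6 filter: 5 of 5
stacking CV AUC: 0.916 +/- 0.041 over 30 folds
holdout AUC  voting: 0.769   stacking: 0.847
holdout GH   voting: 0.775   stacking: 0.162
paired Wilcoxon on the 30 fold AUCs: p = 9.31e-09, significant = True
```

Both ensembles beat the individual members' 0.75 AUC on the untouched 20%
holdout, and score stacking beats voting on ranking quality by exploiting the
continuous rescores that voting discards. `examples/04_screening_metrics.py`
reproduces the worked confusion-matrix numbers (83% recall with an 11.57%
false positive rate from 31 false alarms among 268 inactives), and
`examples/01_prepare_and_cluster.py` shows Butina recovering 3 scaffold
clusters (sizes 14/13/9) from a 60-compound synthetic series.

## Layout

- `src/pharmscreen/` — `molprep`, `clustering`, `decoygen`, `pharmacophore`,
  `metrics`, `ensemble`, `synthdata`, `cli`
- `examples/` — runnable narrative scripts, one per capability
- `docs/methods.md` — parameters, conventions and design decisions
- `scripts/acceptance.py` — end-to-end reproduction script
- `tests/` — unit, property and end-to-end tests
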