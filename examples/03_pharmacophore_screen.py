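"""Elucidate a pharmacophore from real molecules and screen with it.

Generates 3D conformers for a few donor/acceptor/aromatic-rich molecules,
perceives chemical features, enumerates common-feature queries shared by at
least half of the training set, and then matches a test molecule against the
best query.
"""

from pharmscreen.pharmacophore import (
    elucidate_queries,
    ensemble_from_mol,
    generate_conformers,
    match,
)

training_smiles = [
    "Oc1ccc(CCN)cc1",          # tyramine
    "Oc1ccc(CC(N)C(=O)O)cc1",  # tyrosine
    "NCCc1ccc(O)c(O)c1",       # dopamine
]
ensembles = []
for i, smi in enumerate(training_smiles):
    mol = generate_conformers(smi, max_n=10, seed=7)
    ensembles.append(ensemble_from_mol(f"train_{i}", mol))
    n_feats = len(ensembles[-1].features[0])
    print(f"train_{i}: {mol.GetNumConformers()} conformers, "
          f"{n_feats} features on conformer 0")

queries = elucidate_queries(ensembles, k_range=(3, 4), coverage=0.5)
print(f"common-feature queries retained: {len(queries)}")
q = queries[0]
print(f"first query '{q.name}': feature types {q.types}")
print("-> each query is a set of typed spheres; a molecule matches when one of"
      " its conformers places compatible features inside every sphere")

test = generate_conformers("NCCc1ccc(O)cc1", max_n=10, seed=7)  # a congener
res = match(q, ensemble_from_mol("test", test))
print(f"test molecule: prediction = {res.prediction}, "
      f"rescore = {res.rescore:.3f}, best-fit RMSD = {res.rmsd:.3f} A")
print("-> rescore = 1 - RMSD / r_max; 1 is a perfect geometric fit, 0 is at"
      " the tolerance boundary")
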