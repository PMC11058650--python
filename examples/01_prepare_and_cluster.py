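"""Prepare an activity table and cluster the actives by scaffold.

Builds a small synthetic EC50 table, standardises and filters it to potent
actives, then runs exclusion-sphere (Butina) clustering on ECFP4 Tanimoto
similarity and picks the training set from the large clusters.
"""

from pharmscreen.clustering import butina_cluster, fingerprint_set, select_training_set
from pharmscreen.molprep import prepare_actives, records_to_frame
from pharmscreen.synthdata import synth_activity_table

table = synth_activity_table(60, 3, seed=42, active_fraction=0.6)
rejects: list = []
actives = prepare_actives(table, rejects=rejects)
print(f"input rows: {len(table)}, actives kept: {len(actives)}, "
      f"rejected: {len(rejects)}")
print("-> only standardised, rule-of-five-compliant records with EC50 < 100 nM survive")

frame = records_to_frame(actives)
print(f"pEC50 range of the actives: {frame['pec50'].min():.2f}"
      f" .. {frame['pec50'].max():.2f}")

fps = fingerprint_set(frame["id"].tolist(), frame["smiles_canonical"].tolist())
result = butina_cluster(fps, tau=0.35)
sizes = sorted((len(c) for c in result.clusters), reverse=True)
print(f"Butina clusters at tau = 0.35: {len(result.clusters)}, sizes {sizes}")
print("-> each cluster is one chemotype; the centroid is its most-connected member")

training = select_training_set(result, min_cluster_size=5)
print(f"training representatives (centroids of clusters >= 5): {len(training)}")
print("-> one centroid per viable cluster seeds pharmacophore elucidation;"
      " small clusters are held back")
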