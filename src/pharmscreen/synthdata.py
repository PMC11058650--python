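"""Seeded generators for every input the screening pipeline consumes.

Real pharmacophore screens start from proprietary activity tables, conformer
databases and vendor decoy pools.  For development and testing this module
fabricates all three, with known ground truth:

* ``synth_molecules``          — congeneric series: a handful of large
  scaffolds decorated with small substituents, so structural clusters are
  known by construction;
* ``synth_planted_conformers`` — feature-level conformer ensembles in which
  the "actives" carry a chosen pharmacophore geometry perturbed by isotropic
  Gaussian noise and the "decoys" carry random geometries of the same
  feature-type composition;
* ``synth_score_matrix``       — a molecules x models output matrix whose
  per-model AUCs are prescribed analytically (binormal model: decoy scores
  N(0,1), active scores N(mu_j,1) with mu_j = sqrt(2) * Phi^-1(AUC_j)), with
  an optional shared latent factor inducing inter-model correlation.

Every generator is bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import numpy as np
from rdkit import Chem
from scipy.stats import norm

from .ensemble import ModelOutputMatrix
from .pharmacophore import ConformerEnsemble, Feature, PharmacophoreQuery

__all__ = [
    "SCAFFOLDS",
    "SUBSTITUENTS",
    "synth_molecules",
    "synth_planted_conformers",
    "synth_score_matrix",
    "synth_activity_table",
]

#: Decoration templates: large distinctive cores with two substitution slots.
SCAFFOLDS: list[str] = [
    "O=C(Nc1ccc2ccccc2c1)c1ccc({R1})c({R2})c1",
    "O=S(=O)(N1CCN(c2ncccn2)CC1)c1ccc({R1})c({R2})c1",
    "O=C(OCC)C1CCN(Cc2ccc({R1})c({R2})c2)CC1",
    "O=C(NC1CCCCC1)c1cc({R1})cc({R2})c1O",
    "O=C(N1CCOCC1)c1csc(-c2ccc({R1})c({R2})c2)n1",
]

SUBSTITUENTS: list[str] = [
    "", "C", "CC", "CCC", "C(C)C", "O", "OC", "OCC", "N", "NC",
    "N(C)C", "F", "Cl", "Br", "C#N", "C(F)(F)F", "CO", "CCO",
]


def _decorate(template: str, r1: str, r2: str) -> str:
    smi = template
    smi = smi.replace("({R1})", f"({r1})" if r1 else "")
    smi = smi.replace("({R2})", f"({r2})" if r2 else "")
    return smi


def synth_molecules(
    n: int, scaffold_count: int = 3, seed: int = 0
) -> tuple[list[str], list[str], list[int]]:
    """Generate ``n`` valid, distinct SMILES over ``scaffold_count`` scaffolds.

    Returns ``(ids, canonical_smiles, scaffold_labels)``; the labels are the
    clustering ground truth.  Molecules are spread as evenly as possible over
    the scaffolds.
    """
    if not (1 <= scaffold_count <= len(SCAFFOLDS)):
        raise ValueError(f"scaffold_count must lie in 1..{len(SCAFFOLDS)}")
    if n < scaffold_count:
        raise ValueError("need at least one molecule per scaffold")
    rng = np.random.default_rng(seed)
    per = [n // scaffold_count + (1 if i < n % scaffold_count else 0)
           for i in range(scaffold_count)]
    ids, smiles, labels = [], [], []
    for s_idx in range(scaffold_count):
        template = SCAFFOLDS[s_idx]
        seen: set[str] = set()
        combos = [(a, b) for a in SUBSTITUENTS for b in SUBSTITUENTS]
        order = rng.permutation(len(combos))
        count = 0
        for k in order:
            if count == per[s_idx]:
                break
            r1, r2 = combos[k]
            mol = Chem.MolFromSmiles(_decorate(template, r1, r2))
            if mol is None:
                continue
            can = Chem.MolToSmiles(mol)
            if can in seen:
                continue
            seen.add(can)
            ids.append(f"s{s_idx}_m{count}")
            smiles.append(can)
            labels.append(s_idx)
            count += 1
        if count < per[s_idx]:
            raise ValueError(
                f"scaffold {s_idx} exhausted at {count} of {per[s_idx]} molecules"
            )
    return ids, smiles, labels


def synth_activity_table(
    n: int, scaffold_count: int = 3, seed: int = 0, active_fraction: float = 0.7
):
    """A raw activity table (id, smiles, ec50_nm) for exercising preparation.

    EC50 values are log-uniform: a fraction of compounds below 100 nM
    (actives), the rest above.
    """
    import pandas as pd

    ids, smiles, _ = synth_molecules(n, scaffold_count, seed)
    rng = np.random.default_rng(seed + 1)
    n_act = int(round(active_fraction * n))
    ec50 = np.concatenate([
        10 ** rng.uniform(-1, 2, size=n_act),        # 0.1 .. 100 nM
        10 ** rng.uniform(2.01, 4, size=n - n_act),  # > 100 nM
    ])
    rng.shuffle(ec50)
    return pd.DataFrame({"id": ids, "smiles": smiles, "ec50_nm": ec50})


# ---------------------------------------------------------------------------
# planted pharmacophore geometries
# ---------------------------------------------------------------------------

def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix, det +1)."""
    a = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(a)
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def synth_planted_conformers(
    query: PharmacophoreQuery,
    n_act: int,
    n_dec: int,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> tuple[list[ConformerEnsemble], np.ndarray]:
    """Feature-level ensembles with the query geometry planted in the actives.

    Actives carry the query's feature arrangement perturbed by isotropic
    Gaussian noise of ``noise_sd`` Å per coordinate, then rigidly transformed
    at random.  Decoys carry the same feature-type multiset placed uniformly
    at random inside a sphere whose radius equals the query's largest
    pairwise distance.  Returns ``(ensembles, labels)`` with labels 1 for
    actives.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    span = float(query.pairwise_distances().max())
    ensembles: list[ConformerEnsemble] = []
    labels = np.r_[np.ones(n_act, dtype=int), np.zeros(n_dec, dtype=int)]

    for i in range(n_act):
        pts = query.centers + rng.normal(scale=noise_sd, size=query.centers.shape)
        rot = _random_rotation(rng)
        shift = rng.uniform(-10, 10, size=3)
        pts = pts @ rot.T + shift
        feats = [Feature(type=t, center=tuple(p)) for t, p in zip(query.types, pts)]
        ensembles.append(ConformerEnsemble(mol_id=f"act_{i}", features=[feats]))

    for i in range(n_dec):
        # uniform in a ball of radius `span`
        pts = rng.normal(size=(query.k, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        pts *= span * rng.uniform(0, 1, size=(query.k, 1)) ** (1 / 3)
        feats = [Feature(type=t, center=tuple(p)) for t, p in zip(query.types, pts)]
        ensembles.append(ConformerEnsemble(mol_id=f"dec_{i}", features=[feats]))

    return ensembles, labels


# ---------------------------------------------------------------------------
# prescribed-AUC score matrices
# ---------------------------------------------------------------------------

def synth_score_matrix(
    n_act: int,
    n_dec: int,
    auc_targets: list[float],
    correlation: float = 0.0,
    seed: int = 0,
    specificity_cut: float = 0.95,
) -> ModelOutputMatrix:
    """A molecules x models output matrix with prescribed per-model AUCs.

    Binormal construction: each model's decoy scores are standard normal and
    its active scores are shifted by mu_j = sqrt(2) * Phi^-1(AUC_j), so the
    population AUC is exactly the target.  A shared standard-normal latent
    factor with weight sqrt(correlation) induces inter-model correlation
    without changing the marginals.  Binary predictions threshold each
    model's scores at its empirical decoy ``specificity_cut`` quantile.
    """
    auc_targets = list(auc_targets)
    if not all(0.5 < a < 1.0 for a in auc_targets):
        raise ValueError("AUC targets must lie in (0.5, 1)")
    if not (0.0 <= correlation < 1.0):
        raise ValueError("correlation must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    n = n_act + n_dec
    m = len(auc_targets)
    mu = np.sqrt(2.0) * norm.ppf(auc_targets)  # (m,)
    z = rng.standard_normal(size=(n, 1))  # shared latent factor
    eps = rng.standard_normal(size=(n, m))
    scores = np.sqrt(correlation) * z + np.sqrt(1.0 - correlation) * eps
    labels = np.r_[np.ones(n_act, dtype=int), np.zeros(n_dec, dtype=int)]
    scores[:n_act] += mu[None, :]

    cut = np.quantile(scores[n_act:], specificity_cut, axis=0)
    predictions = (scores >= cut[None, :]).astype(int)

    ids = [f"act_{i}" for i in range(n_act)] + [f"dec_{i}" for i in range(n_dec)]
    names = [f"model_{j}" for j in range(m)]
    return ModelOutputMatrix(
        molecule_ids=ids,
        model_names=names,
        predictions=predictions,
        rescores=scores,
        labels=labels,
    )
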