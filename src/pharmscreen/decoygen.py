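"""Property-matched decoy selection and decoy-quality statistics.

Decoys are presumed-inactive molecules used to estimate a screen's
discrimination.  Good decoys sit close to the actives in physicochemical
property space (so enrichment is not an artefact of trivially different
chemistry) while staying structurally dissimilar (so no decoy is secretly an
analogue of an active).  This module selects decoys from a user-supplied
candidate pool by nearest-neighbour matching in z-scored property space at a
fixed ratio (default 1 active : 50 decoys), with a hard fingerprint
similarity cap against every active.

Three statistics keep the selection honest:

* **DOE score** — deviation from optimal embedding: how far the per-active
  property-space ROC curves deviate from the diagonal (0 = actives and
  decoys are perfectly interleaved in property space, 0.5 = fully separated);
* **doppelganger score** — each decoy's maximum ECFP4 Tanimoto similarity to
  any active (reported as mean and max over decoys);
* **AUC-1NN** — leave-one-out 1-nearest-neighbour AUC separating actives
  from decoys; near 0.5 means the two sets are structurally indistinguishable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors

from .clustering import FingerprintSet, ecfp4, similarity_matrix
from .metrics import RankedScreen, roc_auc

__all__ = [
    "DEFAULT_PROPERTY_PANEL",
    "DecoySet",
    "property_vector",
    "property_matrix",
    "generate_decoys",
    "doppelganger",
    "doe_score",
    "auc_1nn",
]

logger = logging.getLogger(__name__)

#: Default physicochemical panel used for property matching.
DEFAULT_PROPERTY_PANEL: dict[str, callable] = {
    "mw": Descriptors.MolWt,
    "logp": Crippen.MolLogP,
    "hbd": Lipinski.NumHDonors,
    "hba": Lipinski.NumHAcceptors,
    "rotatable_bonds": Lipinski.NumRotatableBonds,
    "tpsa": rdMolDescriptors.CalcTPSA,
    "fraction_csp3": Lipinski.FractionCSP3,
    "ring_count": rdMolDescriptors.CalcNumRings,
    "formal_charge": Chem.GetFormalCharge,
    "heavy_atoms": lambda m: m.GetNumHeavyAtoms(),
}


def property_vector(
    mol_or_smiles: Chem.Mol | str, panel: dict | None = None
) -> np.ndarray:
    """Physicochemical property vector over the configured panel."""
    mol = (
        Chem.MolFromSmiles(mol_or_smiles)
        if isinstance(mol_or_smiles, str)
        else mol_or_smiles
    )
    if mol is None:
        raise ValueError("invalid molecule")
    panel = panel or DEFAULT_PROPERTY_PANEL
    vec = np.array([float(fn(mol)) for fn in panel.values()])
    if not np.isfinite(vec).all():
        raise ValueError("descriptor computation produced non-finite values")
    return vec


def property_matrix(smiles: list[str], panel: dict | None = None) -> np.ndarray:
    """Stack property vectors for a list of SMILES; raises on any failure."""
    return np.stack([property_vector(s, panel) for s in smiles])


@dataclass
class DecoySet:
    """Decoys paired to actives plus the quality report."""

    decoy_ids: list[str]
    decoy_smiles: list[str]
    pairing: dict[str, list[str]]  # active id -> decoy ids
    quality: dict[str, float]


def _zscore(values: np.ndarray, mean: np.ndarray, std: np.ndarray) -> np.ndarray:
    std = np.where(std > 0, std, 1.0)
    return (values - mean) / std


def generate_decoys(
    active_ids: list[str],
    active_smiles: list[str],
    candidate_ids: list[str],
    candidate_smiles: list[str],
    ratio: int = 50,
    sim_cap: float = 0.35,
    panel: dict | None = None,
    n_bits: int = 2048,
    compute_quality: bool = True,
) -> DecoySet:
    """Select ``ratio`` property-matched decoys per active from a candidate pool.

    For each active, in input order, the nearest still-unassigned candidates
    in z-scored property space are taken (Euclidean distance; ties broken by
    candidate input order).  Candidates with ECFP4 Tanimoto >= ``sim_cap`` to
    ANY active are excluded up front.

    Raises ``ValueError("insufficient_candidates")`` naming the deficit when
    the pool is exhausted.
    """
    if len(active_ids) == 0:
        raise ValueError("no actives supplied")
    act_props, act_fp_rows, kept_act = [], [], []
    for i, smi in enumerate(active_smiles):
        act_props.append(property_vector(smi, panel))
        act_fp_rows.append(ecfp4(smi, n_bits))
        kept_act.append(i)
    act_props = np.stack(act_props)
    act_fps = np.stack(act_fp_rows)

    cand_props, cand_fps, kept_cand = [], [], []
    for i, smi in enumerate(candidate_smiles):
        try:
            cand_props.append(property_vector(smi, panel))
            cand_fps.append(ecfp4(smi, n_bits))
            kept_cand.append(i)
        except ValueError:
            logger.warning("candidate %s skipped: descriptor failure", candidate_ids[i])
    if not kept_cand:
        raise ValueError("insufficient_candidates: no valid candidate")
    cand_props = np.stack(cand_props)
    cand_fps = np.stack(cand_fps)

    # structural exclusion: max Tanimoto to any active must stay below the cap
    max_sim = _max_tanimoto(cand_fps, act_fps)
    eligible = np.flatnonzero(max_sim < sim_cap)

    needed = ratio * len(active_ids)
    if len(eligible) < needed:
        raise ValueError(
            f"insufficient_candidates: need {needed}, "
            f"only {len(eligible)} eligible (deficit {needed - len(eligible)})"
        )

    # z-scoring fitted on actives union eligible candidates
    pool = np.vstack([act_props, cand_props[eligible]])
    mean, std = pool.mean(axis=0), pool.std(axis=0)
    act_z = _zscore(act_props, mean, std)
    cand_z = _zscore(cand_props, mean, std)

    assigned: set[int] = set()
    pairing: dict[str, list[str]] = {}
    decoy_rows: list[int] = []
    for a_idx, a_id in enumerate(active_ids):
        d = np.linalg.norm(cand_z[eligible] - act_z[a_idx], axis=1)
        order = np.lexsort((eligible, d))  # distance, then candidate order
        picks: list[int] = []
        for k in order:
            row = int(eligible[k])
            if row in assigned:
                continue
            picks.append(row)
            assigned.add(row)
            if len(picks) == ratio:
                break
        if len(picks) < ratio:
            raise ValueError(
                f"insufficient_candidates: active {a_id} short by {ratio - len(picks)}"
            )
        pairing[a_id] = [candidate_ids[kept_cand[r]] for r in picks]
        decoy_rows.extend(picks)

    decoy_ids = [candidate_ids[kept_cand[r]] for r in decoy_rows]
    decoy_smiles = [candidate_smiles[kept_cand[r]] for r in decoy_rows]

    quality: dict[str, float] = {}
    if compute_quality:
        dg_scores, dg_mean, dg_max = doppelganger(
            cand_fps[decoy_rows], act_fps
        )
        quality = {
            "doe": doe_score(act_props, cand_props[decoy_rows]),
            "doppelganger_mean": dg_mean,
            "doppelganger_max": dg_max,
            "auc_1nn": auc_1nn(act_fps, cand_fps[decoy_rows]),
        }
    return DecoySet(decoy_ids, decoy_smiles, pairing, quality)


def _max_tanimoto(fps_a: np.ndarray, fps_b: np.ndarray) -> np.ndarray:
    """Row-wise maximum Tanimoto of each fingerprint in A over all of B."""
    a = fps_a.astype(np.float64)
    b = fps_b.astype(np.float64)
    shared = a @ b.T
    pa = np.count_nonzero(fps_a, axis=1).astype(np.float64)
    pb = np.count_nonzero(fps_b, axis=1).astype(np.float64)
    denom = pa[:, None] + pb[None, :] - shared
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(denom > 0, shared / denom, 0.0)
    return sim.max(axis=1)


def doppelganger(
    decoy_fps: np.ndarray, active_fps: np.ndarray
) -> tuple[np.ndarray, float, float]:
    """Per-decoy max Tanimoto to any active; returns (scores, mean, max)."""
    if len(decoy_fps) == 0 or len(active_fps) == 0:
        raise ValueError("doppelganger requires nonempty decoy and active sets")
    scores = _max_tanimoto(np.asarray(decoy_fps), np.asarray(active_fps))
    return scores, float(scores.mean()), float(scores.max())


def doe_score(active_props: np.ndarray, decoy_props: np.ndarray) -> float:
    """Deviation from optimal embedding of actives among decoys.

    For each active, the remaining actives (positives) and all decoys
    (negatives) are ranked by Euclidean distance in z-scored property space
    (closer = higher score); the score is the mean over actives of the area
    between that ROC curve and the diagonal.  0 means the property clouds
    coincide; 0.5 means they are disjoint.
    """
    active_props = np.asarray(active_props, dtype=float)
    decoy_props = np.asarray(decoy_props, dtype=float)
    if len(active_props) < 2:
        raise ValueError("doe_score requires at least two actives")
    allp = np.vstack([active_props, decoy_props])
    mean, std = allp.mean(axis=0), allp.std(axis=0)
    az = _zscore(active_props, mean, std)
    dz = _zscore(decoy_props, mean, std)

    from sklearn.metrics import roc_curve as _roc_curve

    devs = []
    for i in range(len(az)):
        others = np.delete(az, i, axis=0)
        pts = np.vstack([others, dz])
        labels = np.r_[np.ones(len(others)), np.zeros(len(dz))]
        dist = np.linalg.norm(pts - az[i], axis=1)
        fpr, tpr, _ = _roc_curve(labels, -dist)
        devs.append(np.trapezoid(np.abs(tpr - fpr), fpr))
    return float(np.mean(devs))


def auc_1nn(active_fps: np.ndarray, decoy_fps: np.ndarray) -> float:
    """Leave-one-out 1-nearest-neighbour AUC separating actives from decoys.

    Each molecule is scored by (Tanimoto to its nearest active) minus
    (Tanimoto to its nearest decoy), excluding itself; the AUC of that score
    against the active/decoy label is returned.  0.5 = indistinguishable.
    """
    active_fps = np.asarray(active_fps)
    decoy_fps = np.asarray(decoy_fps)
    if len(active_fps) < 2 or len(decoy_fps) < 2:
        raise ValueError("auc_1nn requires at least two molecules per class")
    n_act = len(active_fps)
    fps = FingerprintSet(
        ids=[f"m{i}" for i in range(n_act + len(decoy_fps))],
        bits=np.vstack([active_fps, decoy_fps]),
        n_bits=active_fps.shape[1],
    )
    sim = similarity_matrix(fps).dense()
    np.fill_diagonal(sim, -np.inf)  # exclude self
    nn_act = sim[:, :n_act].max(axis=1)
    nn_dec = sim[:, n_act:].max(axis=1)
    labels = np.r_[np.ones(n_act, dtype=int), np.zeros(len(decoy_fps), dtype=int)]
    _, _, auc = roc_auc(RankedScreen(scores=nn_act - nn_dec, labels=labels))
    return auc
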