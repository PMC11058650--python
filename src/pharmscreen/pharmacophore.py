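"""Open ligand-based 3D pharmacophore engine.

A pharmacophore query is a small set (3-5) of typed feature spheres — hydrogen
bond donors (Don), acceptors (Acc), hydrophobes (Hyd), aromatic rings (Aro),
and positively/negatively ionisable groups (Cat/Ani) — each with a 3D centre
and a tolerance radius in Ångström.  A molecule matches the query when one of
its conformers can place features of the right types inside all spheres at
once, after an optimal rigid-body superposition.

The engine covers the full life cycle:

* ``perceive_features``  — SMARTS-based feature perception on a 3D conformer;
* ``generate_conformers`` — seeded distance-geometry conformer ensembles;
* ``elucidate_queries``  — enumerate candidate queries from training
  conformers and retain those shared by a coverage fraction of the training
  actives (a common-feature elucidation);
* ``match``              — injective type-compatible assignment search with
  least-squares superposition, yielding a 0/1 prediction and a continuous
  rescore 1 - RMSD/r_max.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit.Chem import rdMolAlign

__all__ = [
    "FEATURE_DEFINITIONS",
    "FEATURE_LETTERS",
    "Feature",
    "ConformerEnsemble",
    "PharmacophoreQuery",
    "MatchResult",
    "perceive_features",
    "generate_conformers",
    "ensemble_from_mol",
    "elucidate_queries",
    "match",
    "queries_to_json",
    "queries_from_json",
]

# ---------------------------------------------------------------------------
# feature definitions
# ---------------------------------------------------------------------------

#: SMARTS patterns per feature type.  Each pattern match instance becomes one
#: feature whose centre is the mean coordinate of the matched atoms.
FEATURE_DEFINITIONS: dict[str, list[str]] = {
    "Don": [
        "[$([N;!H0;v3]),$([N;!H0;+1;v4]),$([O,S;H1;+0]),$([n;H1;+0])]",
    ],
    "Acc": [
        "[$([O;H1;v2]),$([O;H0;v2;!$(O=N-*)]),$([O;-]),"
        "$([N;v3;!$(N-*=[O,N,P,S]);!$(N-a)]),$([nH0;+0]),$([o;+0])]",
    ],
    "Hyd": [
        # aliphatic carbon not bonded to a heteroatom or halogen
        "[C;!$(C~[#7,#8,#9,#16,#17,#35,#53]);!$(C=,#*)]",
    ],
    "Aro": [
        "a1aaaaa1",
        "a1aaaa1",
    ],
    "Cat": [
        "[$([N;H2;+0;!$(NC=[O,S,N]);!$(N-a)]),$([N;+1;!$([N+]~[O-])])]",
    ],
    "Ani": [
        "[$([C,S,P](=O)[O;H1,-1])]",
        "[-1;!$([-1]~[+1])]",
    ],
}

#: One-letter codes used to build query names (e.g. a Hyd/Hyd/Acc/Acc query
#: becomes "AAHH_<index>").
FEATURE_LETTERS = {"Don": "D", "Acc": "A", "Hyd": "H", "Aro": "R", "Cat": "P", "Ani": "N"}

#: Default tolerance radii in Ångström (hydrophobes are fuzzier than polar
#: contacts, hence the larger sphere).
DEFAULT_RADII = {"Don": 1.0, "Acc": 1.0, "Hyd": 1.4, "Aro": 1.0, "Cat": 1.0, "Ani": 1.0}

_COMPILED = {
    ftype: [Chem.MolFromSmarts(s) for s in patterns]
    for ftype, patterns in FEATURE_DEFINITIONS.items()
}


@dataclass(frozen=True)
class Feature:
    """A typed pharmacophoric point in 3D."""

    type: str
    center: tuple[float, float, float]

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.center, dtype=float)


@dataclass
class ConformerEnsemble:
    """A molecule's conformers with their perceived features.

    ``features[k]`` is the feature list of conformer ``k``.  The RDKit
    molecule is optional: planted synthetic ensembles carry features only.
    """

    mol_id: str
    features: list[list[Feature]]
    mol: Chem.Mol | None = None

    def __post_init__(self) -> None:
        if not self.features:
            raise ValueError("an ensemble needs at least one conformer")

    @property
    def n_conformers(self) -> int:
        return len(self.features)


@dataclass
class PharmacophoreQuery:
    """An ordered set of typed feature spheres."""

    name: str
    types: list[str]
    centers: np.ndarray  # (k, 3)
    radii: np.ndarray  # (k,)
    provenance: str = ""

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        k = len(self.types)
        if not (3 <= k <= 5):
            raise ValueError("a query carries between 3 and 5 features")
        if self.centers.shape != (k, 3) or self.radii.shape != (k,):
            raise ValueError("centers must be (k,3), radii (k,)")
        if (self.radii <= 0).any():
            raise ValueError("radii must be positive")
        d = np.linalg.norm(self.centers[:, None] - self.centers[None, :], axis=-1)
        if (d[np.triu_indices(k, 1)] <= 0).any():
            raise ValueError("query feature centres must be pairwise distinct")

    @property
    def k(self) -> int:
        return len(self.types)

    def pairwise_distances(self) -> np.ndarray:
        return np.linalg.norm(self.centers[:, None] - self.centers[None, :], axis=-1)


@dataclass(frozen=True)
class MatchResult:
    prediction: int
    rescore: float  # sentinel nan when prediction == 0
    rmsd: float  # nan when prediction == 0
    conformer_index: int  # -1 when prediction == 0


# ---------------------------------------------------------------------------
# perception and conformers
# ---------------------------------------------------------------------------

def perceive_features(
    mol: Chem.Mol, conf_id: int = 0, definitions: dict | None = None
) -> list[Feature]:
    """Perceive typed features on one conformer of a molecule.

    One feature per SMARTS match instance; the centre is the mean position of
    the matched atoms.  Raises ``ValueError("no_conformer")`` without 3D
    coordinates.
    """
    if mol.GetNumConformers() == 0:
        raise ValueError("no_conformer: molecule has no 3D coordinates")
    conf = mol.GetConformer(conf_id)
    coords = conf.GetPositions()
    compiled = (
        {t: [Chem.MolFromSmarts(s) for s in pats] for t, pats in definitions.items()}
        if definitions is not None
        else _COMPILED
    )
    feats: list[Feature] = []
    for ftype, patterns in compiled.items():
        seen: set[frozenset] = set()
        for patt in patterns:
            for match_atoms in mol.GetSubstructMatches(patt, uniquify=True):
                key = frozenset(match_atoms)
                if key in seen:
                    continue
                seen.add(key)
                center = coords[list(match_atoms)].mean(axis=0)
                feats.append(Feature(type=ftype, center=tuple(map(float, center))))
    return feats


def generate_conformers(
    mol_or_smiles: Chem.Mol | str,
    max_n: int = 20,
    energy_window: float | None = None,
    rmsd_prune: float = 0.5,
    seed: int = 7,
    minimize: bool = True,
) -> Chem.Mol:
    """Embed up to ``max_n`` distance-geometry conformers, minimise and prune.

    Pruning removes conformers within ``rmsd_prune`` Å heavy-atom RMSD of an
    already-kept one (kept in energy order when minimised).  Deterministic
    under a fixed ``seed``.  ``energy_window`` (kcal/mol above the minimum),
    when set, drops high-energy conformers after minimisation.
    """
    mol = (
        Chem.MolFromSmiles(mol_or_smiles)
        if isinstance(mol_or_smiles, str)
        else Chem.Mol(mol_or_smiles)
    )
    if mol is None:
        raise ValueError("invalid molecule")
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    params.numThreads = 1
    ids = list(AllChem.EmbedMultipleConfs(mol, numConfs=max_n, params=params))
    if not ids:
        raise ValueError(f"embedding failed for {Chem.MolToSmiles(mol)}")
    energies = {}
    if minimize:
        results = AllChem.MMFFOptimizeMoleculeConfs(mol, maxIters=500)
        for cid, (converged, energy) in zip(ids, results):
            energies[cid] = energy if energy is not None else math.inf
    mol = Chem.RemoveHs(mol)

    order = sorted(ids, key=lambda c: energies.get(c, 0.0))
    if energy_window is not None and energies:
        emin = min(energies.values())
        order = [c for c in order if energies[c] <= emin + energy_window]

    kept: list[int] = []
    noh = Chem.Mol(mol)
    for cid in order:
        dup = any(
            rdMolAlign.GetBestRMS(noh, noh, prbId=cid, refId=kc) < rmsd_prune
            for kc in kept
        )
        if not dup:
            kept.append(cid)

    out = Chem.Mol(mol)
    out.RemoveAllConformers()
    for cid in kept:
        conf = Chem.Conformer(mol.GetConformer(cid))
        out.AddConformer(conf, assignId=True)
    return out


def ensemble_from_mol(
    mol_id: str, mol: Chem.Mol, definitions: dict | None = None
) -> ConformerEnsemble:
    """Perceive features on every conformer of a molecule."""
    feats = [
        perceive_features(mol, conf.GetId(), definitions)
        for conf in mol.GetConformers()
    ]
    return ConformerEnsemble(mol_id=mol_id, features=feats, mol=mol)


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

def _kabsch_rmsd(p: np.ndarray, q: np.ndarray) -> float:
    """RMSD of p onto q after optimal rigid superposition (Kabsch)."""
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    h = pc.T @ qc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    r = vt.T @ diag @ u.T
    diff = (pc @ r.T) - qc
    return float(np.sqrt((diff**2).sum() / len(p)))


def _aligned_displacements(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Per-point displacement norms of p onto q after optimal superposition."""
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    h = pc.T @ qc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return np.linalg.norm((pc @ r.T) - qc, axis=1)


def _assignments(query: PharmacophoreQuery, feats: list[Feature]):
    """Yield injective type-compatible assignments (tuples of feature indices,
    one per query feature), pruned by pairwise-distance compatibility."""
    by_type: dict[str, list[int]] = {}
    for idx, f in enumerate(feats):
        by_type.setdefault(f.type, []).append(idx)
    candidates = [by_type.get(t, []) for t in query.types]
    if any(not c for c in candidates):
        return
    qd = query.pairwise_distances()
    coords = np.array([f.xyz for f in feats]) if feats else np.zeros((0, 3))
    k = query.k

    def extend(partial: list[int]):
        i = len(partial)
        if i == k:
            yield tuple(partial)
            return
        for c in candidates[i]:
            if c in partial:
                continue
            ok = True
            for j, pj in enumerate(partial):
                dd = np.linalg.norm(coords[c] - coords[pj])
                if abs(dd - qd[i, j]) > query.radii[i] + query.radii[j]:
                    ok = False
                    break
            if ok:
                yield from extend(partial + [c])

    yield from extend([])


def match(query: PharmacophoreQuery, ensemble: ConformerEnsemble) -> MatchResult:
    """Match a query against a conformer ensemble.

    A conformer matches when some injective, type-compatible assignment of
    its features to the query features leaves every assigned feature inside
    its query sphere after optimal rigid-body superposition.  Among matching
    assignments over all conformers, the minimum-RMSD one wins; the rescore
    is 1 - RMSD/r_max clipped to [0, 1], with r_max the largest query radius.
    """
    best: tuple[float, int] | None = None  # (rmsd, conformer index)
    for ci, feats in enumerate(ensemble.features):
        q = query.centers
        for assign in _assignments(query, feats):
            p = np.array([feats[a].xyz for a in assign])
            disp = _aligned_displacements(p, q)
            if (disp <= query.radii + 1e-9).all():
                rmsd = float(np.sqrt((disp**2).mean()))
                if best is None or rmsd < best[0]:
                    best = (rmsd, ci)
    if best is None:
        return MatchResult(prediction=0, rescore=float("nan"), rmsd=float("nan"),
                           conformer_index=-1)
    rmsd, ci = best
    r_max = float(query.radii.max())
    rescore = float(np.clip(1.0 - rmsd / r_max, 0.0, 1.0))
    return MatchResult(prediction=1, rescore=rescore, rmsd=rmsd, conformer_index=ci)


# ---------------------------------------------------------------------------
# query elucidation
# ---------------------------------------------------------------------------

def _query_signature(types: list[str], centers: np.ndarray, bin_width: float = 0.5):
    """Dedup key: type multiset + binned sorted pairwise distances."""
    d = np.linalg.norm(centers[:, None] - centers[None, :], axis=-1)
    k = len(types)
    tri = sorted(d[np.triu_indices(k, 1)])
    binned = tuple(int(round(x / bin_width)) for x in tri)
    return (tuple(sorted(types)), binned)


def _name_for(types: list[str], index: int) -> str:
    letters = "".join(sorted(FEATURE_LETTERS[t] for t in types))
    return f"{letters}_{index}"


def elucidate_queries(
    training_ensembles: list[ConformerEnsemble],
    k_range: tuple[int, int] = (3, 5),
    coverage: float = 0.5,
    radii: dict[str, float] | None = None,
    max_features_per_conformer: int = 12,
) -> list[PharmacophoreQuery]:
    """Enumerate common-feature pharmacophore queries from training actives.

    Every k-feature subset (k in ``k_range``) of every training conformer
    becomes a candidate query (centres from the conformer, radii from the
    per-type defaults).  A candidate survives iff it matches at least
    ``ceil(coverage * n_training)`` training molecules.  Survivors are
    deduplicated by type multiset and binned pairwise-distance signature
    (0.5 Å bins) and named by their feature-type letters plus a running index.
    """
    if len(training_ensembles) < 2:
        # a single training molecule is allowed for toy runs: every subset
        # self-matches, which the coverage rule then accepts
        pass
    radii = {**DEFAULT_RADII, **(radii or {})}
    n_train = len(training_ensembles)
    need = max(1, math.ceil(coverage * n_train))

    seen: set = set()
    queries: list[PharmacophoreQuery] = []
    index = 0
    for ens in training_ensembles:
        for ci, feats in enumerate(ens.features):
            feats = feats[:max_features_per_conformer]
            for k in range(k_range[0], k_range[1] + 1):
                if len(feats) < k:
                    continue
                for combo in itertools.combinations(range(len(feats)), k):
                    types = [feats[i].type for i in combo]
                    centers = np.array([feats[i].xyz for i in combo])
                    dmat = np.linalg.norm(
                        centers[:, None] - centers[None, :], axis=-1
                    )
                    if (dmat[np.triu_indices(k, 1)] <= 1e-6).any():
                        continue  # coincident centres (e.g. same atom in two types)
                    sig = _query_signature(types, centers)
                    if sig in seen:
                        continue
                    seen.add(sig)
                    cand = PharmacophoreQuery(
                        name=_name_for(types, index),
                        types=types,
                        centers=centers,
                        radii=np.array([radii[t] for t in types]),
                        provenance=f"{ens.mol_id}/conf{ci}",
                    )
                    hits = sum(
                        1 for e in training_ensembles if match(cand, e).prediction
                    )
                    if hits >= need:
                        queries.append(cand)
                        index += 1
    if not queries:
        raise ValueError("no_queries: no candidate met the coverage requirement")
    return queries


# ---------------------------------------------------------------------------
# JSON round trip
# ---------------------------------------------------------------------------

def queries_to_json(queries: list[PharmacophoreQuery]) -> str:
    payload = [
        {
            "name": q.name,
            "features": [
                {"type": t, "xyz": [float(x) for x in c], "radius": float(r)}
                for t, c, r in zip(q.types, q.centers, q.radii)
            ],
            "provenance": q.provenance,
        }
        for q in queries
    ]
    return json.dumps(payload, indent=2)


def queries_from_json(text: str) -> list[PharmacophoreQuery]:
    out = []
    for item in json.loads(text):
        feats = item["features"]
        out.append(
            PharmacophoreQuery(
                name=item["name"],
                types=[f["type"] for f in feats],
                centers=np.array([f["xyz"] for f in feats]),
                radii=np.array([f["radius"] for f in feats]),
                provenance=item.get("provenance", ""),
            )
        )
    return out
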