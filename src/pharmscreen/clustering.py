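"""ECFP4 fingerprints, Tanimoto similarity and Butina exclusion-sphere clustering.

Training-set diversity drives the quality of ligand-based pharmacophore
models.  This module fingerprints the actives (Morgan radius-2 circular
fingerprints, the open equivalent of ECFP4), builds the upper-triangular
Tanimoto matrix, runs Butina leader clustering and picks cluster centroids as
the structurally diverse training set.

The clustering proceeds exactly as the exclusion-sphere recipe: count each
molecule's neighbours at similarity >= tau, process molecules in descending
neighbour count, let each still-unflagged molecule seed a cluster (becoming
its centroid) and absorb all of its still-unflagged neighbours.  Molecules
never absorbed end up as singleton clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit import DataStructs
from rdkit.Chem import rdFingerprintGenerator
from sklearn.metrics import silhouette_score

__all__ = [
    "FingerprintSet",
    "SimilarityMatrix",
    "ClusterResult",
    "ecfp4",
    "fingerprint_set",
    "tanimoto",
    "similarity_matrix",
    "butina_cluster",
    "select_training_set",
    "silhouette",
]

_ALLOWED_NBITS = (1024, 2048, 4096)


def ecfp4(mol_or_smiles: Chem.Mol | str, n_bits: int = 2048) -> np.ndarray:
    """Radius-2 Morgan (ECFP4) fingerprint as a 0/1 numpy vector."""
    if n_bits not in _ALLOWED_NBITS:
        raise ValueError(f"n_bits must be one of {_ALLOWED_NBITS}")
    mol = (
        Chem.MolFromSmiles(mol_or_smiles)
        if isinstance(mol_or_smiles, str)
        else mol_or_smiles
    )
    if mol is None:
        raise ValueError("invalid molecule")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=n_bits)
    bv = gen.GetFingerprint(mol)
    arr = np.zeros(n_bits, dtype=np.uint8)
    DataStructs.ConvertToNumpyArray(bv, arr)
    return arr


@dataclass
class FingerprintSet:
    """Fixed-length binary fingerprints for a list of compounds."""

    ids: list[str]
    bits: np.ndarray  # (n, n_bits) uint8
    n_bits: int

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.ndim != 2 or self.bits.shape[1] != self.n_bits:
            raise ValueError("bits must be (n, n_bits)")
        if len(self.ids) != self.bits.shape[0]:
            raise ValueError("one fingerprint per id required")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("ids must be unique")

    def __len__(self) -> int:
        return len(self.ids)


def fingerprint_set(
    ids: list[str], smiles: list[str], n_bits: int = 2048
) -> FingerprintSet:
    """Fingerprint a parallel (ids, SMILES) list into a :class:`FingerprintSet`."""
    bits = np.stack([ecfp4(s, n_bits) for s in smiles])
    return FingerprintSet(ids=list(ids), bits=bits, n_bits=n_bits)


def tanimoto(fp_a: np.ndarray, fp_b: np.ndarray) -> float:
    """Tanimoto coefficient c / (a + b - c); 0 when both vectors are empty."""
    fp_a = np.asarray(fp_a)
    fp_b = np.asarray(fp_b)
    if fp_a.shape != fp_b.shape:
        raise ValueError("fingerprint length mismatch")
    a = int(np.count_nonzero(fp_a))
    b = int(np.count_nonzero(fp_b))
    c = int(np.count_nonzero(np.logical_and(fp_a, fp_b)))
    denom = a + b - c
    return c / denom if denom else 0.0


class SimilarityMatrix:
    """Upper-triangular store of pairwise Tanimoto coefficients.

    Only the strict upper triangle is stored; access is symmetric and the
    diagonal is defined as 1.
    """

    def __init__(self, n: int, values: np.ndarray):
        if values.shape != (n * (n - 1) // 2,):
            raise ValueError("triangular store has wrong length")
        self.n = n
        self._tri = values

    @staticmethod
    def _index(i: int, j: int, n: int) -> int:
        # flat index of (i, j), i < j, row-major upper triangle
        return i * n - i * (i + 1) // 2 + (j - i - 1)

    def __getitem__(self, ij: tuple[int, int]) -> float:
        i, j = ij
        if i == j:
            return 1.0
        if i > j:
            i, j = j, i
        return float(self._tri[self._index(i, j, self.n)])

    def dense(self) -> np.ndarray:
        out = np.eye(self.n)
        k = 0
        for i in range(self.n):
            for j in range(i + 1, self.n):
                out[i, j] = out[j, i] = self._tri[k]
                k += 1
        return out


def similarity_matrix(fps: FingerprintSet) -> SimilarityMatrix:
    """Pairwise Tanimoto matrix in a triangular store.

    Computed vectorised: for binary vectors the shared-bit counts are the
    Gram matrix of the bit matrix.
    """
    bits = fps.bits.astype(np.float64)
    shared = bits @ bits.T
    pop = np.count_nonzero(fps.bits, axis=1).astype(np.float64)
    denom = pop[:, None] + pop[None, :] - shared
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(denom > 0, shared / denom, 0.0)
    iu = np.triu_indices(len(fps), k=1)
    return SimilarityMatrix(len(fps), sim[iu])


@dataclass
class ClusterResult:
    """Outcome of Butina clustering.

    ``clusters`` partition the input ids; ``centroids[k]`` is the leader of
    ``clusters[k]``; every non-centroid member has similarity >= tau to its
    centroid.
    """

    clusters: list[list[str]]
    centroids: list[str]
    neighbor_counts: dict[str, int]
    flagged: set[str]
    tau: float
    singleton: list[bool] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.singleton:
            self.singleton = [len(c) == 1 for c in self.clusters]

    def sizes(self) -> list[int]:
        return [len(c) for c in self.clusters]


def butina_cluster(fps: FingerprintSet, tau: float = 0.35) -> ClusterResult:
    """Butina exclusion-sphere clustering at similarity threshold ``tau``.

    Ties in the neighbour-count ordering are broken by original input order
    (stable sort), so the result is deterministic.
    """
    if not (0.0 < tau <= 1.0):
        raise ValueError("tau must lie in (0, 1]")
    n = len(fps)
    if n == 0:
        raise ValueError("at least one fingerprint required")
    sim = similarity_matrix(fps)

    neigh = [sum(1 for j in range(n) if j != i and sim[i, j] >= tau) for i in range(n)]
    order = sorted(range(n), key=lambda i: -neigh[i])  # stable: ties keep input order

    flagged: set[int] = set()
    clusters: list[list[int]] = []
    centroids: list[int] = []
    for i in order:
        if i in flagged:
            continue
        members = [i]
        flagged.add(i)
        for j in order:
            if j != i and j not in flagged and sim[i, j] >= tau:
                members.append(j)
                flagged.add(j)
        clusters.append(members)
        centroids.append(i)

    ids = fps.ids
    return ClusterResult(
        clusters=[[ids[m] for m in c] for c in clusters],
        centroids=[ids[z] for z in centroids],
        neighbor_counts={ids[i]: neigh[i] for i in range(n)},
        flagged={ids[i] for i in flagged},
        tau=tau,
    )


def select_training_set(result: ClusterResult, min_cluster_size: int = 1) -> list[str]:
    """Centroids of clusters with at least ``min_cluster_size`` members.

    Ordered by cluster size descending (centroid id breaks ties) — the
    "viable cluster" ladder used to build training sets of decreasing size.
    """
    if min_cluster_size < 1:
        raise ValueError("min_cluster_size must be >= 1")
    chosen = [
        (len(c), z)
        for c, z in zip(result.clusters, result.centroids)
        if len(c) >= min_cluster_size
    ]
    if not chosen:
        raise ValueError("empty_training_set: no cluster meets the minimum size")
    chosen.sort(key=lambda t: (-t[0], t[1]))
    return [z for _, z in chosen]


def silhouette(fps: FingerprintSet, labels: list[int]) -> float:
    """Mean silhouette coefficient under the 1 - Tanimoto distance.

    Members of singleton clusters contribute 0 (the usual convention).
    """
    labels = np.asarray(labels)
    if len(labels) != len(fps):
        raise ValueError("one label per fingerprint required")
    if len(np.unique(labels)) < 2:
        raise ValueError("undefined_silhouette: need at least two clusters")
    dist = 1.0 - similarity_matrix(fps).dense()
    np.fill_diagonal(dist, 0.0)
    return float(silhouette_score(dist, labels, metric="precomputed"))
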