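"""Standardisation and filtering of raw compound activity tables.

Raw screening tables arrive as (id, SMILES, EC50) rows of uneven quality:
alternative SMILES notations for the same molecule, counter-ions, duplicate
measurements and compounds far outside oral drug-like space.  This module
turns such a table into a clean set of active :class:`CompoundRecord` objects:

* SMILES are canonicalised (largest organic fragment, neutralised where
  chemically safe),
* EC50 in nM is converted to pEC50 = 9 - log10(EC50),
* Lipinski rule-of-five compliance is enforced (at most one violation),
* duplicates (by canonical SMILES) are collapsed to the record with the
  median pEC50,
* only compounds with EC50 strictly below the activity threshold
  (default 100 nM) are kept.
"""

from __future__ import annotations

import logging
import math
import statistics
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdmolops

__all__ = [
    "CompoundRecord",
    "StandardizationError",
    "standardize",
    "ec50_to_pec50",
    "ro5_pass",
    "prepare_actives",
    "records_to_frame",
]

logger = logging.getLogger(__name__)

#: Default activity cutoff, nM.  Compounds are active iff EC50 < this value
#: (strict inequality).
DEFAULT_ACTIVITY_THRESHOLD_NM = 100.0


class StandardizationError(ValueError):
    """Raised when a SMILES cannot be parsed or standardised."""


@dataclass(frozen=True)
class CompoundRecord:
    """A standardised compound with optional activity annotation."""

    id: str
    smiles_raw: str
    smiles_canonical: str
    ec50: float | None = None  # nM
    pec50: float | None = None
    is_active: bool = False
    ro5_violations: int = 0

    def validate(self, activity_threshold: float = DEFAULT_ACTIVITY_THRESHOLD_NM) -> None:
        """Assert the record invariants; raises ``AssertionError`` on breach."""
        mol = Chem.MolFromSmiles(self.smiles_canonical)
        assert mol is not None, f"{self.id}: canonical SMILES does not parse"
        if self.ec50 is not None:
            assert self.ec50 > 0
            assert self.pec50 is not None
            assert abs(self.pec50 - (9.0 - math.log10(self.ec50))) < 1e-9
        if self.is_active:
            assert self.ec50 is not None and self.ec50 < activity_threshold
        assert self.ro5_violations >= 0


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

_NEUTRALIZE_PATTERNS = [
    # (charged pattern, neutral replacement) applied atom-wise below
    ("[n+;H]", "n"),
    ("[N+;!H0]", "N"),
    ("[$([O-]);!$([O-][#7])]", "O"),
    ("[S-;X1]", "S"),
    ("[$([N-;X2]S(=O)=O)]", "N"),
]


def _neutralize(mol: Chem.Mol) -> Chem.Mol:
    """Neutralise simple protonation-state charges in place (safe cases only)."""
    pattern = Chem.MolFromSmarts("[+1!h0!$([*]~[-1,-2,-3,-4]),-1!$([*]~[+1,+2,+3,+4])]")
    at_matches = mol.GetSubstructMatches(pattern)
    if not at_matches:
        return mol
    for (idx,) in at_matches:
        atom = mol.GetAtomWithIdx(idx)
        chg = atom.GetFormalCharge()
        h_count = atom.GetTotalNumHs()
        if chg > 0 and h_count == 0:
            continue  # quaternary N and friends: nothing to deprotonate
        atom.SetFormalCharge(0)
        atom.SetNumExplicitHs(max(0, h_count - chg))
        atom.UpdatePropertyCache(strict=False)
    Chem.SanitizeMol(mol, catchErrors=False)
    return mol


def standardize(smiles_raw: str, neutralize: bool = True) -> str:
    """Canonicalise a SMILES: keep the largest organic fragment, neutralise.

    Idempotent: ``standardize(standardize(s)) == standardize(s)``.

    Raises :class:`StandardizationError` with reason ``parse_error`` when the
    input does not parse.
    """
    if not smiles_raw or not smiles_raw.strip():
        raise StandardizationError("parse_error: empty SMILES")
    mol = Chem.MolFromSmiles(smiles_raw)
    if mol is None:
        raise StandardizationError(f"parse_error: {smiles_raw!r}")
    frags = rdmolops.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    # largest fragment by heavy-atom count, ties by canonical SMILES for
    # determinism; "organic" preference: fragments containing carbon win
    def _key(m: Chem.Mol) -> tuple:
        has_c = any(a.GetAtomicNum() == 6 for a in m.GetAtoms())
        return (has_c, m.GetNumHeavyAtoms(), Chem.MolToSmiles(m))

    mol = max(frags, key=_key)
    if neutralize:
        mol = _neutralize(Chem.RWMol(mol))
    return Chem.MolToSmiles(mol)


def ec50_to_pec50(ec50: float) -> float:
    """Convert EC50 in nM to pEC50 = 9 - log10(EC50).

    100 nM -> 7.0; 1 nM -> 9.0.  Raises ``ValueError`` for nonpositive input.
    """
    if ec50 is None or not math.isfinite(ec50) or ec50 <= 0:
        raise ValueError("invalid_concentration: EC50 must be a positive number in nM")
    return 9.0 - math.log10(ec50)


def ro5_pass(mol_or_smiles: Chem.Mol | str) -> tuple[bool, int]:
    """Lipinski rule-of-five check.

    Counts violations of MW <= 500, logP <= 5, HBD <= 5, HBA <= 10 and passes
    iff at most one rule is violated.

    Returns ``(passed, n_violations)``.
    """
    mol = (
        Chem.MolFromSmiles(mol_or_smiles)
        if isinstance(mol_or_smiles, str)
        else mol_or_smiles
    )
    if mol is None:
        raise StandardizationError("parse_error: cannot compute descriptors")
    violations = 0
    if Descriptors.MolWt(mol) > 500:
        violations += 1
    if Crippen.MolLogP(mol) > 5:
        violations += 1
    if Lipinski.NumHDonors(mol) > 5:
        violations += 1
    if Lipinski.NumHAcceptors(mol) > 10:
        violations += 1
    return violations <= 1, violations


# ---------------------------------------------------------------------------
# table-level pipeline
# ---------------------------------------------------------------------------

def prepare_actives(
    table: pd.DataFrame,
    activity_threshold: float = DEFAULT_ACTIVITY_THRESHOLD_NM,
    id_col: str = "id",
    smiles_col: str = "smiles",
    ec50_col: str = "ec50_nm",
    neutralize: bool = True,
    rejects: list | None = None,
) -> list[CompoundRecord]:
    """Standardise, deduplicate and filter an activity table into actives.

    Order of operations: standardise -> dedup by canonical SMILES ->
    rule-of-five filter -> activity filter (EC50 strictly below the
    threshold).  Duplicates collapse to the row whose pEC50 is the group
    median (ties: lowest EC50, then id) so the surviving potency is
    representative rather than an extreme.

    ``rejects``, if given, collects ``(id, reason)`` tuples for every dropped
    row, with reason codes ``parse_error``, ``invalid_concentration``,
    ``duplicate``, ``descriptor_error``, ``ro5_fail`` or ``inactive``.

    Raises ``ValueError("no_actives")`` if nothing survives.
    """
    for col in (id_col, smiles_col, ec50_col):
        if col not in table.columns:
            raise KeyError(f"missing column {col!r}")
    sink = rejects if rejects is not None else []

    rows: list[dict] = []
    for _, row in table.iterrows():
        rid = str(row[id_col])
        raw = str(row[smiles_col])
        try:
            canonical = standardize(raw, neutralize=neutralize)
        except StandardizationError:
            sink.append((rid, "parse_error"))
            logger.warning("rejected %s: parse_error", rid)
            continue
        try:
            ec50 = float(row[ec50_col])
            pec50 = ec50_to_pec50(ec50)
        except (TypeError, ValueError):
            sink.append((rid, "invalid_concentration"))
            logger.warning("rejected %s: invalid_concentration", rid)
            continue
        rows.append(
            {"id": rid, "smiles_raw": raw, "smiles_canonical": canonical,
             "ec50": ec50, "pec50": pec50}
        )

    # dedup by canonical SMILES: keep the median-pEC50 record
    by_smiles: dict[str, list[dict]] = {}
    for r in rows:
        by_smiles.setdefault(r["smiles_canonical"], []).append(r)
    deduped: list[dict] = []
    for group in by_smiles.values():
        # keep the record whose pEC50 is closest to the group median;
        # ties broken by lowest EC50 then id for determinism
        med = statistics.median(r["pec50"] for r in group)
        group = sorted(group, key=lambda r: (abs(r["pec50"] - med), r["ec50"], r["id"]))
        keep = group[0]
        for other in group[1:]:
            sink.append((other["id"], "duplicate"))
        deduped.append(keep)

    records: list[CompoundRecord] = []
    for r in deduped:
        try:
            passed, nviol = ro5_pass(r["smiles_canonical"])
        except StandardizationError:
            sink.append((r["id"], "descriptor_error"))
            continue
        if not passed:
            sink.append((r["id"], "ro5_fail"))
            continue
        if not (r["ec50"] < activity_threshold):
            sink.append((r["id"], "inactive"))
            continue
        records.append(
            CompoundRecord(
                id=r["id"],
                smiles_raw=r["smiles_raw"],
                smiles_canonical=r["smiles_canonical"],
                ec50=r["ec50"],
                pec50=r["pec50"],
                is_active=True,
                ro5_violations=nviol,
            )
        )
    if not records:
        raise ValueError("no_actives: no compound survived standardisation and filtering")
    # deterministic order independent of input row order
    records.sort(key=lambda rec: (rec.smiles_canonical, rec.id))
    return records


def records_to_frame(records: Iterable[CompoundRecord]) -> pd.DataFrame:
    """Tabulate records for CSV output."""
    return pd.DataFrame(
        [
            {
                "id": r.id,
                "smiles_raw": r.smiles_raw,
                "smiles_canonical": r.smiles_canonical,
                "ec50_nm": r.ec50,
                "pec50": r.pec50,
                "is_active": r.is_active,
                "ro5_violations": r.ro5_violations,
            }
            for r in records
        ]
    )
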