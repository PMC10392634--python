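"""Ligand-dictionary curation: rejection filters and the ring-size statistic.

A SMILES dictionary (e.g. the chemical-component dictionary of a structural
database) is screened in a fixed order: species containing metals, species
without carbon, and strings with valence errors (including anything the
parser rejects outright) are dropped; the survivors are flagged as
macrocyclic when they contain a non-aromatic ring of seven or more atoms.
The summary statistic is the distribution, over kept ligands, of the largest
ring size in the smallest set of smallest rings (SSSR) — SSSR is used for
this statistic only, never for choosing rings to break.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

from rdkit import Chem
from rdkit import RDLogger

from .molgraph import ORGANIC_SUBSET, Molecule, from_rdkit

__all__ = [
    "LigandRecord",
    "CurationReport",
    "filter_record",
    "is_macrocyclic",
    "largest_sssr_ring",
    "curate",
]

RDLogger.DisableLog("rdApp.error")

STATUSES = ("kept", "rejected_metal", "rejected_no_carbon", "rejected_valence")


@dataclass
class LigandRecord:
    id: str
    smiles: str
    status: str
    is_macrocyclic: Optional[bool] = None
    largest_sssr_ring: Optional[int] = None


@dataclass
class CurationReport:
    counts: dict[str, int]
    macrocycle_fraction: float
    histogram: dict[int, int]  # largest SSSR ring size -> number of kept ligands
    records: list[LigandRecord] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "counts": self.counts,
                "macrocycle_fraction": self.macrocycle_fraction,
                "histogram": {str(k): v for k, v in sorted(self.histogram.items())},
            },
            indent=1,
        )


def _contains_metal(rdmol: Chem.Mol) -> bool:
    return any(at.GetSymbol() not in ORGANIC_SUBSET for at in rdmol.GetAtoms())


def filter_record(id: str, smiles: str) -> LigandRecord:
    """Classify one dictionary entry; rejections apply in a fixed order.

    Metal check first (any element outside the organic subset), then absence
    of carbon, then valence: a SMILES that fails sanitisation — or fails to
    parse at all — counts as a valence error.
    """
    raw = Chem.MolFromSmiles(smiles, sanitize=False)
    if raw is None:
        return LigandRecord(id=id, smiles=smiles, status="rejected_valence")
    if _contains_metal(raw):
        return LigandRecord(id=id, smiles=smiles, status="rejected_metal")
    if not any(at.GetSymbol() == "C" for at in raw.GetAtoms()):
        return LigandRecord(id=id, smiles=smiles, status="rejected_no_carbon")
    rdmol = Chem.MolFromSmiles(smiles)
    if rdmol is None:
        return LigandRecord(id=id, smiles=smiles, status="rejected_valence")
    rec = LigandRecord(id=id, smiles=smiles, status="kept")
    rec.is_macrocyclic = _is_macrocyclic_rd(rdmol)
    rec.largest_sssr_ring = _largest_sssr_rd(rdmol)
    return rec


def _is_macrocyclic_rd(rdmol: Chem.Mol, min_size: int = 7) -> bool:
    ri = rdmol.GetRingInfo()
    for ring in ri.BondRings():
        if len(ring) >= min_size and not all(
            rdmol.GetBondWithIdx(b).GetIsAromatic() for b in ring
        ):
            return True
    return False


def _largest_sssr_rd(rdmol: Chem.Mol) -> int:
    ri = rdmol.GetRingInfo()
    sizes = [len(r) for r in ri.AtomRings()]
    return max(sizes) if sizes else 0


def is_macrocyclic(mol: Molecule, min_size: int = 7) -> bool:
    """Does the molecule contain a non-aromatic ring of ``min_size``+ atoms?"""
    from .molgraph import to_rdkit

    return _is_macrocyclic_rd(to_rdkit(mol, with_coords=False), min_size=min_size)


def largest_sssr_ring(mol: Molecule) -> int:
    """Largest ring size in an SSSR basis; 0 for acyclic molecules."""
    from .molgraph import to_rdkit

    return _largest_sssr_rd(to_rdkit(mol, with_coords=False))


def curate(entries: Iterable[tuple[str, str]], keep_records: bool = True) -> CurationReport:
    """Run the full pipeline over ``(id, smiles)`` pairs."""
    counts = Counter({s: 0 for s in STATUSES})
    hist: Counter[int] = Counter()
    n_macro = 0
    records: list[LigandRecord] = []
    for lig_id, smiles in entries:
        rec = filter_record(lig_id, smiles)
        counts[rec.status] += 1
        if rec.status == "kept":
            hist[rec.largest_sssr_ring] += 1
            if rec.is_macrocyclic:
                n_macro += 1
        if keep_records:
            records.append(rec)
    kept = counts["kept"]
    return CurationReport(
        counts=dict(counts),
        macrocycle_fraction=(n_macro / kept) if kept else 0.0,
        histogram=dict(hist),
        records=records,
    )
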