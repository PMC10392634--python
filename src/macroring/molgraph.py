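"""Molecular data model, file I/O, hydrogen merging and rotatable-bond perception.

The in-memory model is a lightweight attributed graph (:class:`Molecule`)
tailored to docking preparation: heavy atoms plus polar hydrogens, with
non-polar hydrogens folded into a per-atom count, explicit bond orders and
aromaticity, optional 3D coordinates in Ångström, and tetrahedral
stereocentres recorded as ranked-neighbour parities so that chirality can be
audited from coordinates alone after conformational sampling.

RDKit does the heavy chemical lifting (parsing, sanitisation, aromaticity and
stereo perception, ETKDG conformer embedding); everything downstream of the
conversion works on the plain graph.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

__all__ = [
    "Atom",
    "Bond",
    "StereoCenter",
    "Molecule",
    "MoleculeError",
    "ParseError",
    "read_molecule",
    "merge_nonpolar_hydrogens",
    "define_rotatable_bonds",
    "generate_conformer",
    "write_sdf",
]

#: elements regarded as "organic" for curation purposes; everything else is
#: treated as a metal / inorganic species.
ORGANIC_SUBSET = frozenset(
    {"H", "B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Se", "Br", "I"}
)


class MoleculeError(ValueError):
    """Invalid molecule or operation precondition violation."""


class ParseError(MoleculeError):
    """Input could not be parsed in the requested format."""


@dataclass
class Atom:
    index: int
    element: str
    is_aromatic: bool = False
    formal_charge: int = 0
    coords: Optional[np.ndarray] = None
    merged_h_count: int = 0
    partial_charge: Optional[float] = None
    chiral_tag: int = 0  # RDKit ChiralType value; preserves input stereo flags

    def copy(self) -> "Atom":
        c = None if self.coords is None else np.array(self.coords, dtype=float)
        return replace(self, coords=c)


@dataclass
class Bond:
    a: int
    b: int
    order: int = 1
    is_aromatic: bool = False
    rotatable: bool = False
    in_small_ring: bool = False

    @property
    def key(self) -> tuple[int, int]:
        """Canonical (min, max) atom-index pair identifying the bond."""
        return (self.a, self.b) if self.a < self.b else (self.b, self.a)

    def copy(self) -> "Bond":
        return replace(self)


@dataclass
class StereoCenter:
    """Tetrahedral centre with parity referenced to a fixed neighbour order.

    ``parity`` is the CIP-style label when RDKit could assign one, else
    ``"+"``/``"-"``. ``volume_sign`` is the sign of the signed volume of the
    first three neighbours in ``neighbor_order`` relative to the centre at the
    coordinates the parity was derived from; re-evaluating that sign on new
    coordinates (same neighbour order) tells whether the configuration was
    preserved.
    """

    atom: int
    parity: str
    neighbor_order: tuple[int, ...]
    volume_sign: int = 0


@dataclass
class Molecule:
    atoms: list[Atom] = field(default_factory=list)
    bonds: list[Bond] = field(default_factory=list)
    stereocenters: list[StereoCenter] = field(default_factory=list)
    name: str = ""

    # -- basic graph accessors -------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def has_coords(self) -> bool:
        return bool(self.atoms) and all(a.coords is not None for a in self.atoms)

    def coords_array(self) -> np.ndarray:
        if not self.has_coords():
            raise MoleculeError("molecule has no 3D coordinates")
        return np.array([a.coords for a in self.atoms], dtype=float)

    def set_coords(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (self.n_atoms, 3):
            raise MoleculeError(f"coordinate array shape {xyz.shape} != ({self.n_atoms}, 3)")
        for atom, row in zip(self.atoms, xyz):
            atom.coords = row.copy()

    def neighbors(self, i: int) -> list[int]:
        out = []
        for b in self.bonds:
            if b.a == i:
                out.append(b.b)
            elif b.b == i:
                out.append(b.a)
        return out

    def bond_between(self, i: int, j: int) -> Optional[Bond]:
        for b in self.bonds:
            if {b.a, b.b} == {i, j}:
                return b
        return None

    def adjacency(self) -> dict[int, list[int]]:
        adj: dict[int, list[int]] = {a.index: [] for a in self.atoms}
        for b in self.bonds:
            adj[b.a].append(b.b)
            adj[b.b].append(b.a)
        return adj

    def heavy_degree(self, i: int) -> int:
        return sum(1 for j in self.neighbors(i) if self.atoms[j].element != "H")

    def copy(self) -> "Molecule":
        return Molecule(
            atoms=[a.copy() for a in self.atoms],
            bonds=[b.copy() for b in self.bonds],
            stereocenters=list(self.stereocenters),
            name=self.name,
        )

    def validate(self) -> None:
        n = self.n_atoms
        for i, a in enumerate(self.atoms):
            if a.index != i:
                raise MoleculeError(f"atom index {a.index} at position {i}")
        seen: set[tuple[int, int]] = set()
        for b in self.bonds:
            if b.a == b.b or not (0 <= b.a < n and 0 <= b.b < n):
                raise MoleculeError(f"bad bond {b.a}-{b.b}")
            if b.key in seen:
                raise MoleculeError(f"duplicate bond {b.key}")
            seen.add(b.key)
        if self.bonds and not _is_connected(self.adjacency()):
            raise MoleculeError("molecule graph is not connected")

    # -- rings (local, graph-level) -------------------------------------------

    def ring_bond_keys(self) -> set[tuple[int, int]]:
        """Bonds that lie on at least one cycle (i.e. are not bridges)."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n_atoms))
        g.add_edges_from(b.key for b in self.bonds)
        bridges = {tuple(sorted(e)) for e in nx.bridges(g)}
        return {b.key for b in self.bonds if b.key not in bridges}


def _is_connected(adj: dict[int, list[int]]) -> bool:
    if not adj:
        return True
    start = next(iter(adj))
    seen = {start}
    stack = [start]
    while stack:
        for j in adj[stack.pop()]:
            if j not in seen:
                seen.add(j)
                stack.append(j)
    return len(seen) == len(adj)


# ---------------------------------------------------------------------------
# RDKit conversion
# ---------------------------------------------------------------------------

_BOND_ORDER = {
    Chem.BondType.SINGLE: 1,
    Chem.BondType.DOUBLE: 2,
    Chem.BondType.TRIPLE: 3,
    Chem.BondType.AROMATIC: 1,
}
_ORDER_BOND = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE, 3: Chem.BondType.TRIPLE}


def from_rdkit(rdmol: Chem.Mol, name: str = "") -> Molecule:
    """Convert an RDKit molecule (sanitised) into a :class:`Molecule`."""
    conf = rdmol.GetConformer() if rdmol.GetNumConformers() else None
    mol = Molecule(name=name or (rdmol.GetProp("_Name") if rdmol.HasProp("_Name") else ""))
    for at in rdmol.GetAtoms():
        coords = None
        if conf is not None:
            p = conf.GetAtomPosition(at.GetIdx())
            coords = np.array([p.x, p.y, p.z], dtype=float)
        mol.atoms.append(
            Atom(
                index=at.GetIdx(),
                element=at.GetSymbol(),
                is_aromatic=at.GetIsAromatic(),
                formal_charge=at.GetFormalCharge(),
                coords=coords,
                chiral_tag=int(at.GetChiralTag()),
            )
        )
    for bd in rdmol.GetBonds():
        mol.bonds.append(
            Bond(
                a=bd.GetBeginAtomIdx(),
                b=bd.GetEndAtomIdx(),
                order=_BOND_ORDER.get(bd.GetBondType(), 1),
                is_aromatic=bd.GetIsAromatic(),
            )
        )
    _perceive_stereocenters(mol, rdmol)
    return mol


def to_rdkit(mol: Molecule, with_coords: bool = True) -> Chem.Mol:
    """Rebuild an RDKit molecule; merged hydrogens become explicit H counts."""
    rw = Chem.RWMol()
    for a in mol.atoms:
        at = Chem.Atom(a.element)
        at.SetFormalCharge(a.formal_charge)
        at.SetIsAromatic(a.is_aromatic)
        if a.chiral_tag:
            at.SetChiralTag(Chem.ChiralType.values[a.chiral_tag])
        if a.merged_h_count:
            at.SetNumExplicitHs(a.merged_h_count)
            at.SetNoImplicit(True)
        rw.AddAtom(at)
    for b in mol.bonds:
        bt = Chem.BondType.AROMATIC if b.is_aromatic else _ORDER_BOND[b.order]
        rw.AddBond(b.a, b.b, bt)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    if with_coords and mol.has_coords():
        conf = Chem.Conformer(mol.n_atoms)
        for a in mol.atoms:
            conf.SetAtomPosition(a.index, [float(x) for x in a.coords])
        out.AddConformer(conf, assignId=True)
    return out


def _cip_ranks(rdmol: Chem.Mol) -> list[int]:
    Chem.AssignStereochemistry(rdmol, cleanIt=False, force=True)
    return [int(a.GetPropsAsDict().get("_CIPRank", a.GetIdx())) for a in rdmol.GetAtoms()]


def _perceive_stereocenters(mol: Molecule, rdmol: Chem.Mol) -> None:
    """Record tetrahedral centres with parity referenced to CIP-ranked neighbours.

    When 3D coordinates are present the parity sign is the signed volume of the
    three highest-ranked neighbours about the centre; otherwise it is derived
    from the RDKit chiral tag.
    """
    try:
        if rdmol.GetNumConformers():
            Chem.AssignStereochemistryFrom3D(rdmol)
        centers = Chem.FindMolChiralCenters(rdmol, includeUnassigned=False, useLegacyImplementation=False)
    except Exception:
        centers = []
    if not centers:
        mol.stereocenters = []
        return
    ranks = _cip_ranks(rdmol)
    out: list[StereoCenter] = []
    for idx, label in centers:
        nbrs = sorted(
            (n.GetIdx() for n in rdmol.GetAtomWithIdx(idx).GetNeighbors()),
            key=lambda j: (-ranks[j], j),
        )
        order = tuple(nbrs)
        sign = 0
        if mol.has_coords() and len(order) >= 3:
            sign = signed_volume_sign(mol.coords_array(), idx, order[:3])
        out.append(StereoCenter(atom=idx, parity=str(label), neighbor_order=order, volume_sign=sign))
    mol.stereocenters = out


def signed_volume_sign(xyz: np.ndarray, center: int, neighbors: Sequence[int]) -> int:
    """Sign of the signed volume spanned by three neighbours about a centre."""
    v = [xyz[j] - xyz[center] for j in neighbors[:3]]
    vol = float(np.dot(np.cross(v[0], v[1]), v[2]))
    return int(np.sign(vol))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _looks_like_path(source: str) -> bool:
    return ("\n" not in source) and (os.path.sep in source or os.path.exists(source))


def read_molecule(source: str, format: str = "smiles", name: str = "") -> Molecule:
    """Read a molecule from a SMILES string or an SDF/MOL/PDB file or block.

    ``source`` may be a path or the literal text of the record. Aromaticity and
    stereochemistry are perceived by RDKit; 3D coordinates are populated iff
    the format carries them. Multi-fragment inputs are rejected.
    """
    fmt = format.lower()
    if fmt == "smiles":
        rdmol = Chem.MolFromSmiles(source)
        if rdmol is None:
            raise ParseError(f"could not parse SMILES: {source!r}")
    elif fmt in ("sdf", "mol"):
        if _looks_like_path(source):
            rdmol = Chem.MolFromMolFile(source, removeHs=False)
        else:
            rdmol = Chem.MolFromMolBlock(source, removeHs=False)
        if rdmol is None:
            raise ParseError(f"could not parse {fmt.upper()} input")
    elif fmt == "pdb":
        block = open(source).read() if _looks_like_path(source) else source
        block = _extract_hetatm_ligand(block)
        rdmol = Chem.MolFromPDBBlock(block, removeHs=False)
        if rdmol is None:
            raise ParseError("could not parse PDB input")
    else:
        raise ParseError(f"unknown format {format!r}")
    frags = Chem.GetMolFrags(rdmol)
    if len(frags) > 1:
        raise MoleculeError(
            f"input contains {len(frags)} fragments; a single connected ligand is required"
        )
    mol = from_rdkit(rdmol, name=name)
    mol.validate()
    return mol


def _extract_hetatm_ligand(block: str) -> str:
    """Keep HETATM records (minus waters) if any exist, else the whole block."""
    het = [
        ln
        for ln in block.splitlines()
        if ln.startswith("HETATM") and ln[17:20].strip() not in ("HOH", "WAT")
    ]
    if het:
        return "\n".join(het + ["END"])
    return block


def write_sdf(mol: Molecule, path: Optional[str] = None) -> str:
    """Write the molecule (with coordinates, if present) as an SDF record."""
    rdmol = to_rdkit(mol, with_coords=True)
    if mol.name:
        rdmol.SetProp("_Name", mol.name)
    block = Chem.MolToMolBlock(rdmol) + "$$$$\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(block)
    return block


# ---------------------------------------------------------------------------
# Hydrogen merging and rotatable bonds
# ---------------------------------------------------------------------------

def merge_nonpolar_hydrogens(mol: Molecule) -> Molecule:
    """Fold hydrogens bonded to carbon into their parent's ``merged_h_count``.

    Hydrogens on N/O/S (and any other heteroatom) are polar and stay explicit.
    For inputs whose hydrogens are implicit (e.g. parsed SMILES), the implicit
    counts are materialised into ``merged_h_count`` via RDKit first.
    """
    rd = to_rdkit(mol, with_coords=mol.has_coords())
    rd = Chem.AddHs(rd, addCoords=mol.has_coords())
    # Protect polar hydrogens with an isotope label: RDKit's RemoveHs skips
    # isotopically labelled hydrogens and correctly adjusts stereo parities
    # for the ones it removes.
    for at in rd.GetAtoms():
        if at.GetSymbol() == "H" and at.GetNeighbors()[0].GetSymbol() != "C":
            at.SetIsotope(1)
    rd = Chem.RemoveHs(rd)
    for at in rd.GetAtoms():
        if at.GetSymbol() == "H":
            at.SetIsotope(0)
    out = from_rdkit(rd, name=mol.name)
    for i, at in enumerate(rd.GetAtoms()):
        if at.GetSymbol() == "C":
            out.atoms[i].merged_h_count = int(at.GetTotalNumHs())
    out.validate()
    return out


def _is_amide_cn(mol: Molecule, i: int, j: int) -> bool:
    """C-N single bond where the carbon carries a double bond to O."""
    for c, n in ((i, j), (j, i)):
        if mol.atoms[c].element == "C" and mol.atoms[n].element == "N":
            for k in mol.neighbors(c):
                b = mol.bond_between(c, k)
                if b is not None and b.order == 2 and mol.atoms[k].element == "O":
                    return True
    return False


def _is_conjugated_cc(mol: Molecule, i: int, j: int) -> bool:
    """Single bond between two carbons that each bear a double bond
    (the C=C-C=A pattern), in either orientation."""

    def has_double(atom: int, partner_must_be_c: bool) -> bool:
        for k in mol.neighbors(atom):
            b = mol.bond_between(atom, k)
            if b is not None and b.order == 2 and not b.is_aromatic:
                if not partner_must_be_c or mol.atoms[k].element == "C":
                    return True
        return False

    if mol.atoms[i].element != "C" or mol.atoms[j].element != "C":
        return False
    return (has_double(i, True) and has_double(j, False)) or (
        has_double(j, True) and has_double(i, False)
    )


def define_rotatable_bonds(mol: Molecule, disable_conjugated: bool = True) -> Molecule:
    """Flag rotatable bonds on a hydrogen-merged molecule (in place, returned).

    A bond rotates iff it is a single, non-aromatic, acyclic bond whose two
    ends each have at least two heavy neighbours, and it is not an amide C-N
    bond. With ``disable_conjugated`` (default, matching the preparation
    protocol this package models) the single bond of a C=C-C=A motif is frozen
    as well.
    """
    ring_keys = mol.ring_bond_keys()
    for b in mol.bonds:
        rot = (
            b.order == 1
            and not b.is_aromatic
            and b.key not in ring_keys
            and mol.heavy_degree(b.a) >= 2
            and mol.heavy_degree(b.b) >= 2
            and not _is_amide_cn(mol, b.a, b.b)
        )
        if rot and disable_conjugated and _is_conjugated_cc(mol, b.a, b.b):
            rot = False
        b.rotatable = rot
    return mol


def generate_conformer(mol: Molecule, seed: int = 0) -> Molecule:
    """Embed a 3D conformer with ETKDG; deterministic for a fixed seed."""
    rd = to_rdkit(mol, with_coords=False)
    rd = Chem.AddHs(rd)  # appended after the original atoms, indices preserved
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    params.useRandomCoords = False
    if AllChem.EmbedMolecule(rd, params) != 0:
        raise MoleculeError(f"conformer embedding failed for {mol.name or 'molecule'} (seed {seed})")
    AllChem.MMFFOptimizeMolecule(rd, maxIters=500)
    out = mol.copy()
    conf = rd.GetConformer()
    for a in out.atoms:
        p = conf.GetAtomPosition(a.index)
        a.coords = np.array([p.x, p.y, p.z], dtype=float)
    # refresh stereo parities from the new coordinates
    _perceive_stereocenters(out, to_rdkit(out, with_coords=True))
    return out
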