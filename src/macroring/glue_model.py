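"""Glue atoms, the anisotropic closure potential, and PDBQT emission.

Opening a macrocycle removes one bond ``a-b``. Both atoms keep their chemistry
but are retyped ``CGn`` (``n`` numbers the pair, starting at 1), and each
receives a massless, charge-zero pseudoatom ``Gn``: ``g_a`` hangs off ``a``
and is placed at the input position of ``b``, and vice versa. Because each
pseudoatom is bonded into its parent's rigid frame, pulling ``g_a`` onto ``b``
(and ``g_b`` onto ``a``) restores not just the bond length but the valence
angles and chirality around the broken bond — the restoring force is
*anisotropic* even though each individual G↔CG term depends only on distance.

The closure penalty is linear in distance with a slope of 50 kcal/mol/Å and
sums both cross terms of every pair:

    E_closure = k * Σ_n [ |g_a - b| + |g_b - a| ]

The PDBQT writer emits the AutoDock ligand dialect: a rigid ROOT block,
nested BRANCH records mirroring the torsion tree, CGn/Gn atom types, and a
trailing TORSDOF count. Bond connectivity and glue ideal lengths are carried
in REMARK lines so a written file reads back losslessly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .molgraph import Atom, Bond, Molecule, MoleculeError
from .ring_breaking import BreakPlan, TorsionTree, build_torsion_tree
from .ring_perception import BondKey, _edge

__all__ = [
    "GluePair",
    "ClosureParams",
    "OpenedMolecule",
    "PDBQTError",
    "open_rings",
    "closure_energy",
    "write_pdbqt",
    "read_pdbqt",
]


class PDBQTError(MoleculeError):
    pass


@dataclass
class GluePair:
    n: int  # 1-based pair index
    a: int  # CGn atom
    b: int  # CGn atom
    g_a: int  # Gn pseudoatom riding a, target is b
    g_b: int  # Gn pseudoatom riding b, target is a
    ideal_length: float  # original a-b bond length, Å


@dataclass
class ClosureParams:
    """Linear closure penalty; ``k`` in kcal/mol per Å of glue separation."""

    k: float = 50.0

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("penalty slope k must be positive")


@dataclass
class OpenedMolecule:
    """Acyclic-ised ligand: base graph (pseudoatoms appended) plus glue pairs.

    ``base`` holds original atoms 0..N-1 followed by pseudoatom records
    (element ``"G"``); pseudoatom bonds are part of ``base.bonds``. Removing
    the pseudoatoms and re-adding ``plan.removed_bonds`` reproduces the input
    graph exactly.
    """

    base: Molecule
    glue_pairs: list[GluePair]
    plan: BreakPlan
    n_real_atoms: int

    @property
    def tree(self) -> TorsionTree:
        return self.plan.tree

    def pseudoatom_indices(self) -> list[int]:
        # appended at the end by open_rings, but interleaved in emission order
        # when the molecule came from a PDBQT file
        return [a.index for a in self.base.atoms if a.element == "G"]

    def glue_type_of(self, index: int) -> Optional[str]:
        for gp in self.glue_pairs:
            if index in (gp.a, gp.b):
                return f"CG{gp.n}"
            if index in (gp.g_a, gp.g_b):
                return f"G{gp.n}"
        return None


def open_rings(mol: Molecule, plan: BreakPlan) -> OpenedMolecule:
    """Open the molecule along a break plan and attach glue pseudoatoms.

    For each removed bond ``(a, b)`` (in sorted order, numbering the pairs
    1, 2, ...): the bond is deleted, ``g_a`` is appended at the input position
    of ``b`` bonded to ``a``, then ``g_b`` at the position of ``a`` bonded to
    ``b``. The torsion tree in ``plan`` already accounts for the pseudoatoms.
    """
    if not mol.has_coords():
        raise MoleculeError("open_rings requires 3D coordinates")
    removed = sorted(plan.removed_bonds)
    keys = {b.key for b in mol.bonds}
    for e in removed:
        if e not in keys:
            raise MoleculeError(f"break plan bond {e} not present in molecule")
    base = Molecule(name=mol.name)
    base.atoms = [a.copy() for a in mol.atoms]
    base.bonds = [b.copy() for b in mol.bonds if b.key not in plan.removed_bonds]
    base.stereocenters = list(mol.stereocenters)
    n_real = len(base.atoms)
    pairs: list[GluePair] = []
    for n, (a, b) in enumerate(removed, start=1):
        ideal = float(np.linalg.norm(mol.atoms[a].coords - mol.atoms[b].coords))
        g_a = len(base.atoms)
        base.atoms.append(
            Atom(index=g_a, element="G", coords=mol.atoms[b].coords.copy(), partial_charge=0.0)
        )
        base.bonds.append(Bond(a=a, b=g_a, order=1))
        g_b = len(base.atoms)
        base.atoms.append(
            Atom(index=g_b, element="G", coords=mol.atoms[a].coords.copy(), partial_charge=0.0)
        )
        base.bonds.append(Bond(a=b, b=g_b, order=1))
        pairs.append(GluePair(n=n, a=a, b=b, g_a=g_a, g_b=g_b, ideal_length=ideal))
    om = OpenedMolecule(base=base, glue_pairs=pairs, plan=plan, n_real_atoms=n_real)
    _check_tree_covers(om)
    return om


def _check_tree_covers(om: OpenedMolecule) -> None:
    if om.plan.tree.all_atoms() != set(range(om.base.n_atoms)):
        raise MoleculeError("torsion tree does not span the opened molecule")


def closure_energy(
    om: OpenedMolecule,
    params: ClosureParams | None = None,
    coords: Optional[np.ndarray] = None,
) -> float:
    """Linear glue penalty, kcal/mol: ``k * Σ [|g_a−b| + |g_b−a|]``.

    Zero iff every pseudoatom coincides with its target glue atom. ``coords``
    overrides the coordinates stored on the molecule (used by the sampler).
    """
    params = params or ClosureParams()
    xyz = coords if coords is not None else om.base.coords_array()
    total = 0.0
    for gp in om.glue_pairs:
        total += float(np.linalg.norm(xyz[gp.g_a] - xyz[gp.b]))
        total += float(np.linalg.norm(xyz[gp.g_b] - xyz[gp.a]))
    return params.k * total


def glue_distances(om: OpenedMolecule, coords: Optional[np.ndarray] = None) -> dict[int, tuple[float, float]]:
    """Per-pair (|g_a−b|, |g_b−a|) distances in Å."""
    xyz = coords if coords is not None else om.base.coords_array()
    return {
        gp.n: (
            float(np.linalg.norm(xyz[gp.g_a] - xyz[gp.b])),
            float(np.linalg.norm(xyz[gp.g_b] - xyz[gp.a])),
        )
        for gp in om.glue_pairs
    }


# ---------------------------------------------------------------------------
# PDBQT
# ---------------------------------------------------------------------------

#: AutoDock atom types by element (ligand defaults; aromatic carbon is "A",
#: polar hydrogen "HD", O and S default to acceptor types)
_AD_TYPES = {"C": "C", "N": "N", "O": "OA", "S": "SA", "H": "HD", "P": "P", "F": "F", "Cl": "Cl", "Br": "Br", "I": "I"}


def _atom_type(om: OpenedMolecule, idx: int) -> str:
    t = om.glue_type_of(idx)
    if t:
        return t
    a = om.base.atoms[idx]
    if a.element == "C" and a.is_aromatic:
        return "A"
    return _AD_TYPES.get(a.element, a.element)


def _atom_line(serial: int, name: str, idx: int, om: OpenedMolecule) -> str:
    a = om.base.atoms[idx]
    x, y, z = (float(v) for v in a.coords)
    q = a.partial_charge or 0.0
    t = _atom_type(om, idx)
    return (
        f"ATOM  {serial:>5d} {name:<4s} LIG A   1    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}    {q:+6.3f} {t:<2s}"
    ).rstrip()


def write_pdbqt(om: OpenedMolecule) -> str:
    """Serialise the opened ligand in the AutoDock PDBQT ligand dialect.

    Atoms are numbered in emission order: the rigid ROOT group first (by base
    index), then each BRANCH depth-first. REMARK lines carry the full bond
    list and glue ideal lengths so :func:`read_pdbqt` can reconstruct the
    molecule losslessly; write→read→write is byte-identical.
    """
    if not om.base.has_coords():
        raise PDBQTError("cannot write PDBQT without coordinates")
    tree = om.plan.tree
    _check_tree_covers(om)

    serial_of: dict[int, int] = {}
    lines: list[str] = []
    counter = {"n": 0}

    def emit_atom(idx: int) -> None:
        counter["n"] += 1
        serial_of[idx] = counter["n"]
        el = om.base.atoms[idx].element
        name = ("G" if el == "G" else el) + str(counter["n"])
        lines.append(_atom_line(counter["n"], name[:4], idx, om))

    def emit_group(key: int) -> None:
        for idx in sorted(tree.groups[key]):
            emit_atom(idx)

    def emit_branches(key: int) -> None:
        for (a, b), child in tree.children[key]:
            parent_atom = a if a in tree.groups[key] else b
            child_atom = b if parent_atom == a else a
            lines.append(f"BRANCH {serial_of[parent_atom]:>3d} {len(serial_of) + 1:>3d}")
            # child_atom is emitted first within its group
            group = tree.groups[child]
            order = [child_atom] + sorted(set(group) - {child_atom})
            for idx in order:
                emit_atom(idx)
            emit_branches(child)
            lines.append(f"ENDBRANCH {serial_of[parent_atom]:>3d} {serial_of[child_atom]:>3d}")

    header: list[str] = [f"REMARK  Name = {om.base.name}" if om.base.name else "REMARK  Name ="]
    lines.append("ROOT")
    emit_group(tree.root_key)
    lines.append("ENDROOT")
    emit_branches(tree.root_key)
    torsdof = len(tree.rotatable_bonds)
    lines.append(f"TORSDOF {torsdof}")

    # connectivity + glue metadata (serial-based, after serials are known)
    for b in sorted(om.base.bonds, key=lambda b: tuple(sorted((serial_of[b.a], serial_of[b.b])))):
        i, j = sorted((serial_of[b.a], serial_of[b.b]))
        header.append(f"REMARK  BOND {i} {j} {b.order}{' aromatic' if b.is_aromatic else ''}")
    for gp in om.glue_pairs:
        header.append(f"REMARK  GLUE {gp.n} ideal {gp.ideal_length:.4f}")
    return "\n".join(header + lines) + "\n"


_ATOM_RE = re.compile(r"^(ATOM|HETATM)")


def read_pdbqt(text: str) -> OpenedMolecule:
    """Parse a ligand PDBQT back into an :class:`OpenedMolecule`.

    Glue pairs are recovered by matching ``CGn``/``Gn`` types: each ``Gn``
    pseudoatom must be bonded to one of the two ``CGn`` atoms, and its target
    is the other. Files without glue types parse to zero pairs. Bonds come
    from ``REMARK BOND`` lines when present, else from a covalent-distance
    heuristic over non-pseudo atoms.
    """
    atoms: list[tuple[int, str, float, float, float, float, str]] = []
    bonds_remark: list[tuple[int, int, int, bool]] = []
    glue_ideal: dict[int, float] = {}
    name = ""
    root_seen = False

    # structural parse: groups of atom serials plus the branch bonds linking
    # them, taken from the ROOT/BRANCH nesting itself
    @dataclass
    class _Grp:
        atoms: list[int]
        children: list[tuple[tuple[int, int], "_Grp"]]

    root_group = _Grp([], [])
    group_stack: list[_Grp] = [root_group]
    branch_stack: list[tuple[int, int]] = []
    for raw in text.splitlines():
        line = raw.rstrip()
        if line.startswith("REMARK  Name ="):
            name = line.split("=", 1)[1].strip()
        elif line.startswith("REMARK  BOND "):
            parts = line.split()
            bonds_remark.append((int(parts[2]), int(parts[3]), int(parts[4]), "aromatic" in parts))
        elif line.startswith("REMARK  GLUE "):
            parts = line.split()
            glue_ideal[int(parts[2])] = float(parts[4])
        elif line == "ROOT":
            root_seen = True
        elif line.startswith("BRANCH"):
            _, i, j = line.split()
            child = _Grp([], [])
            group_stack[-1].children.append(((int(i), int(j)), child))
            group_stack.append(child)
            branch_stack.append((int(i), int(j)))
        elif line.startswith("ENDBRANCH"):
            _, i, j = line.split()
            if not branch_stack or branch_stack[-1] != (int(i), int(j)):
                raise PDBQTError(f"unbalanced BRANCH/ENDBRANCH at: {line}")
            branch_stack.pop()
            group_stack.pop()
        elif _ATOM_RE.match(line):
            serial = int(line[6:11])
            x, y, z = float(line[30:38]), float(line[38:46]), float(line[46:54])
            charge = float(line[70:76])
            adtype = line[77:].strip()
            atoms.append((serial, line[12:16].strip(), x, y, z, charge, adtype))
            group_stack[-1].atoms.append(serial)
    if branch_stack:
        raise PDBQTError(f"unterminated BRANCH {branch_stack[-1]}")
    if not root_seen:
        raise PDBQTError("missing ROOT record")

    serial_to_idx = {serial: i for i, (serial, *_rest) in enumerate(atoms)}
    mol = Molecule(name=name)
    glue_cg: dict[int, list[int]] = {}
    glue_g: dict[int, list[int]] = {}
    for i, (serial, aname, x, y, z, q, adtype) in enumerate(atoms):
        m_cg = re.fullmatch(r"CG(\d+)", adtype)
        m_g = re.fullmatch(r"G(\d+)", adtype)
        if m_g:
            element = "G"
            glue_g.setdefault(int(m_g.group(1)), []).append(i)
        elif m_cg:
            element = "C"
            glue_cg.setdefault(int(m_cg.group(1)), []).append(i)
        else:
            element = _element_from_type(adtype)
        mol.atoms.append(
            Atom(
                index=i,
                element=element,
                is_aromatic=(adtype == "A"),
                coords=np.array([x, y, z]),
                partial_charge=q,
            )
        )
    if bonds_remark:
        for i, j, order, arom in bonds_remark:
            mol.bonds.append(Bond(a=serial_to_idx[i], b=serial_to_idx[j], order=order, is_aromatic=arom))
    else:
        _infer_bonds(mol)

    # glue pairs
    pairs: list[GluePair] = []
    for n in sorted(set(glue_cg) | set(glue_g)):
        cg = glue_cg.get(n, [])
        g = glue_g.get(n, [])
        if len(cg) != 2 or len(g) != 2:
            raise PDBQTError(
                f"unpaired pseudoatom: glue index {n} has {len(cg)} CG and {len(g)} G atoms"
            )
        a, b = sorted(cg)
        g_of = {}
        for gi in g:
            parent = [x for x in mol.neighbors(gi) if x in (a, b)]
            if len(parent) != 1:
                raise PDBQTError(f"dangling pseudoatom G{n} (atom {gi}) not bonded to a CG{n}")
            g_of[parent[0]] = gi
        if set(g_of) != {a, b}:
            raise PDBQTError(f"pseudoatoms of pair {n} attached to the same CG atom")
        pairs.append(
            GluePair(n=n, a=a, b=b, g_a=g_of[a], g_b=g_of[b], ideal_length=glue_ideal.get(n, 1.54))
        )

    n_real = sum(1 for a in mol.atoms if a.element != "G")
    removed = frozenset(_edge(gp.a, gp.b) for gp in pairs)

    # materialise the torsion tree straight from the parsed nesting
    groups: dict[int, frozenset[int]] = {}
    children: dict[int, list[tuple[BondKey, int]]] = {}
    rotatable: list[BondKey] = []

    def walk(grp: "_Grp") -> tuple[int, int]:
        """Returns (group key, subtree depth)."""
        members = frozenset(serial_to_idx[s] for s in grp.atoms)
        if not members:
            raise PDBQTError("empty ROOT/BRANCH group")
        key = min(members)
        groups[key] = members
        children[key] = []
        deepest = 0
        for (si, sj), sub in grp.children:
            bond = _edge(serial_to_idx[si], serial_to_idx[sj])
            rotatable.append(bond)
            ck, cd = walk(sub)
            children[key].append((bond, ck))
            deepest = max(deepest, cd + 1)
        return key, deepest

    root_key, depth = walk(root_group)
    tree = TorsionTree(
        root=groups[root_key],
        groups=groups,
        children=children,
        rotatable_bonds=sorted(rotatable),
        depth=depth,
    )
    plan = BreakPlan(removed_bonds=removed, tree=tree, depth=depth, n_macrocycles=len(pairs))
    om = OpenedMolecule(base=mol, glue_pairs=pairs, plan=plan, n_real_atoms=n_real)
    _check_tree_covers(om)
    return om


def _element_from_type(adtype: str) -> str:
    rev = {"A": "C", "OA": "O", "NA": "N", "SA": "S", "HD": "H"}
    if adtype in rev:
        return rev[adtype]
    if adtype in _AD_TYPES.values() or adtype in _AD_TYPES:
        return adtype
    raise PDBQTError(f"unknown atom type {adtype!r}")


_COVALENT_CUTOFF = 1.9  # Å, generous single-bond heuristic for heavy atoms


def _infer_bonds(mol: Molecule) -> None:
    xyz = mol.coords_array()
    n = mol.n_atoms
    for i in range(n):
        for j in range(i + 1, n):
            if mol.atoms[i].element == "G" or mol.atoms[j].element == "G":
                continue
            cutoff = 1.2 if "H" in (mol.atoms[i].element, mol.atoms[j].element) else _COVALENT_CUTOFF
            if float(np.linalg.norm(xyz[i] - xyz[j])) < cutoff:
                mol.bonds.append(Bond(a=i, b=j, order=1))
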