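"""Break-bond selection and torsion-tree construction.

Given the breakable macrocycles, the planner removes exactly one bond per
macrocycle so that the opened molecular graph is free of large rings, choosing
— by exhaustive search over all candidate combinations — the set whose torsion
tree has the shallowest deepest branch. Depth is counted in rotatable bonds
from the rigid root group to the farthest leaf; shallow trees keep the
conformational consequences of a single torsional move small, which is what
a torsional search engine needs.

A bond shared between two macrocycles can serve both, so a plan may remove
fewer bonds than there are macrocycles.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence
import warnings

from .molgraph import Bond, Molecule, MoleculeError, define_rotatable_bonds
from .ring_perception import BondKey, Ring, RingSet, _edge

__all__ = [
    "BreakCandidate",
    "TorsionTree",
    "BreakPlan",
    "BreakPlanError",
    "candidate_bonds",
    "enumerate_break_sets",
    "build_torsion_tree",
    "choose_break_plan",
]

MAX_BREAK_COMBINATIONS = 100_000


class BreakPlanError(MoleculeError):
    pass


@dataclass(frozen=True)
class BreakCandidate:
    bond: BondKey
    rings_covered: frozenset[int]  # indices into the macrocycle list


@dataclass
class TorsionTree:
    """Rigid root group plus nested branches, one per rotatable bond.

    ``groups`` are the rigid fragments left after cutting every rotatable
    bond, keyed by their smallest atom index; ``children`` maps a group key to
    ``(bond, child_group_key)`` pairs. ``depth`` is the number of rotatable
    bonds on the deepest root-to-leaf path.
    """

    root: frozenset[int]
    groups: dict[int, frozenset[int]]
    children: dict[int, list[tuple[BondKey, int]]]
    rotatable_bonds: list[BondKey]
    depth: int

    @property
    def root_key(self) -> int:
        return min(self.root)

    def all_atoms(self) -> set[int]:
        out: set[int] = set()
        for g in self.groups.values():
            out |= g
        return out


@dataclass
class BreakPlan:
    removed_bonds: frozenset[BondKey]
    tree: TorsionTree
    depth: int
    n_macrocycles: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "removed_bonds": sorted(map(list, self.removed_bonds)),
                "root": sorted(self.tree.root),
                "depth": self.depth,
                "n_macrocycles": self.n_macrocycles,
            }
        )


# ---------------------------------------------------------------------------
# Candidates
# ---------------------------------------------------------------------------

def candidate_bonds(mol: Molecule, macrocycle: Ring) -> list[BreakCandidate]:
    """Single non-aromatic C-C bonds of the macrocycle outside small rings."""
    out = []
    for a, b in sorted(macrocycle.bonds):
        bond = mol.bond_between(a, b)
        if bond is None:
            raise BreakPlanError(f"macrocycle bond {a}-{b} missing from molecule")
        if (
            bond.order == 1
            and not bond.is_aromatic
            and not bond.in_small_ring
            and mol.atoms[a].element == "C"
            and mol.atoms[b].element == "C"
        ):
            out.append(BreakCandidate(bond=_edge(a, b), rings_covered=frozenset()))
    return out


def enumerate_break_sets(
    candidates_per_ring: Sequence[Sequence[BreakCandidate]],
    cap: int = MAX_BREAK_COMBINATIONS,
) -> list[frozenset[BondKey]]:
    """All distinct bond sets choosing one candidate per macrocycle.

    Sets where one shared bond serves several macrocycles collapse to fewer
    bonds than rings, and duplicates are removed.
    """
    total = 1
    for cands in candidates_per_ring:
        total *= max(len(cands), 1)
        if total > cap:
            raise BreakPlanError(
                f"break-set enumeration exceeds cap ({total} > {cap})"
            )
    seen: set[frozenset[BondKey]] = set()
    out: list[frozenset[BondKey]] = []
    for combo in itertools.product(*[c or [None] for c in candidates_per_ring]):
        bonds = frozenset(c.bond for c in combo if c is not None)
        if bonds and bonds not in seen:
            seen.add(bonds)
            out.append(bonds)
    return out


# ---------------------------------------------------------------------------
# Torsion tree
# ---------------------------------------------------------------------------

def _rigid_groups(
    n_atoms: int, bonds: Iterable[BondKey], rotatable: set[BondKey]
) -> tuple[dict[int, frozenset[int]], dict[int, int]]:
    """Connected components after cutting rotatable bonds, keyed by min atom."""
    adj: dict[int, list[int]] = {i: [] for i in range(n_atoms)}
    for a, b in bonds:
        if _edge(a, b) not in rotatable:
            adj[a].append(b)
            adj[b].append(a)
    seen: set[int] = set()
    groups: dict[int, frozenset[int]] = {}
    atom_group: dict[int, int] = {}
    for start in range(n_atoms):
        if start in seen:
            continue
        comp = {start}
        stack = [start]
        seen.add(start)
        while stack:
            for j in adj[stack.pop()]:
                if j not in seen:
                    seen.add(j)
                    comp.add(j)
                    stack.append(j)
        key = min(comp)
        groups[key] = frozenset(comp)
        for at in comp:
            atom_group[at] = key
    return groups, atom_group


def build_torsion_tree(
    mol: Molecule,
    removed: frozenset[BondKey] | set[BondKey] = frozenset(),
    with_pseudoatoms: bool = True,
    disable_conjugated: bool = True,
) -> TorsionTree:
    """Torsion tree of the molecule with ``removed`` bonds deleted.

    Rotatable bonds are re-perceived on the opened graph (a formerly cyclic
    bond may become rotatable once its ring is opened). With
    ``with_pseudoatoms`` (the default) each end of a removed bond gets a
    terminal G placeholder appended — pseudoatoms ride their parent's rigid
    frame, and their presence makes the last ring bond at each glue atom a
    genuine rotor, exactly as in the emitted ligand. Placeholders are appended
    in sorted removed-bond order, ``g_a`` before ``g_b``, matching the atom
    numbering of :func:`macroring.glue_model.open_rings`. The root is the
    rigid group whose worst branch is shallowest; ties go to the smallest
    atom index.
    """
    removed = frozenset(_edge(*e) for e in removed)
    opened = Molecule(name=mol.name)
    opened.atoms = [a.copy() for a in mol.atoms]
    opened.bonds = [b.copy() for b in mol.bonds if b.key not in removed]
    if len(opened.bonds) != len(mol.bonds) - len(removed):
        raise BreakPlanError("removed bond not present in molecule")
    if with_pseudoatoms:
        from .molgraph import Atom

        for a, b in sorted(removed):
            for parent in (a, b):
                g = len(opened.atoms)
                opened.atoms.append(Atom(index=g, element="G"))
                opened.bonds.append(Bond(a=parent, b=g, order=1))
    if removed:
        # a deliberate opening must not leave any large ring behind; rings
        # kept rigid on purpose enter with removed == {} and skip this check
        import networkx as nx

        g = nx.Graph(b.key for b in opened.bonds if opened.atoms[b.a].element != "G" and opened.atoms[b.b].element != "G")
        for cyc in nx.minimum_cycle_basis(g):
            if len(cyc) >= 7:
                raise BreakPlanError(
                    f"residual macrocycle of size {len(cyc)} after removing {sorted(removed)}"
                )
    define_rotatable_bonds(opened, disable_conjugated=disable_conjugated)
    rotatable = {b.key for b in opened.bonds if b.rotatable}
    bond_keys = [b.key for b in opened.bonds]
    n_atoms = len(opened.atoms)
    groups, atom_group = _rigid_groups(n_atoms, bond_keys, rotatable)

    # group-level tree: nodes = group keys, edges = rotatable bonds
    gadj: dict[int, list[tuple[BondKey, int]]] = {k: [] for k in groups}
    for a, b in sorted(rotatable):
        ga, gb = atom_group[a], atom_group[b]
        if ga == gb:
            raise BreakPlanError(
                f"rotatable bond {a}-{b} closes a residual ring in the opened graph"
            )
        gadj[ga].append(((a, b), gb))
        gadj[gb].append(((a, b), ga))

    if len(groups) != len(rotatable) + 1:
        raise BreakPlanError("opened graph is not a tree of rigid groups")

    def eccentricity(root_key: int) -> int:
        depth = {root_key: 0}
        stack = [root_key]
        worst = 0
        while stack:
            g = stack.pop()
            for _, h in gadj[g]:
                if h not in depth:
                    depth[h] = depth[g] + 1
                    worst = max(worst, depth[h])
                    stack.append(h)
        return worst

    best_key = min(groups, key=lambda k: (eccentricity(k), k))
    depth = eccentricity(best_key)

    children: dict[int, list[tuple[BondKey, int]]] = {k: [] for k in groups}
    seen = {best_key}
    stack = [best_key]
    while stack:
        g = stack.pop()
        for bond, h in sorted(gadj[g], key=lambda t: t[1]):
            if h not in seen:
                seen.add(h)
                children[g].append((bond, h))
                stack.append(h)
    return TorsionTree(
        root=groups[best_key],
        groups=groups,
        children=children,
        rotatable_bonds=sorted(rotatable),
        depth=depth,
    )


# ---------------------------------------------------------------------------
# Plan selection
# ---------------------------------------------------------------------------

def _breaks_all_large_rings(
    removed: frozenset[BondKey], large_rings: Sequence[Ring]
) -> bool:
    return all(r.bonds & removed for r in large_rings)


def choose_break_plan(
    mol: Molecule,
    macrocycles: RingSet,
    disable_conjugated: bool = True,
    min_large: int = 7,
) -> BreakPlan:
    """Exhaustively pick the break set minimising torsion-tree depth.

    Exactly one bond is removed per breakable macrocycle; a set is feasible
    only if every enumerated ring of at least ``min_large`` atoms (kept or
    filtered) loses a bond, so no large ring survives in the opened graph.
    Ties break on fewer removed bonds, then the lexicographically smallest
    sorted bond tuple.
    """
    kept = macrocycles.kept
    large_rings = [r for r in macrocycles.rings if r.size >= min_large]
    per_ring: list[list[BreakCandidate]] = []
    usable: list[Ring] = []
    for i, ring in enumerate(kept):
        cands = candidate_bonds(mol, ring)
        if not cands:
            warnings.warn(
                f"macrocycle {sorted(ring.atoms)} has no breakable bond; left rigid",
                stacklevel=2,
            )
            continue
        per_ring.append([BreakCandidate(c.bond, frozenset({i})) for c in cands])
        usable.append(ring)
    if not per_ring:
        tree = build_torsion_tree(mol, frozenset(), disable_conjugated=disable_conjugated)
        return BreakPlan(frozenset(), tree, tree.depth, 0)

    best: Optional[tuple[tuple, frozenset[BondKey], TorsionTree]] = None
    for removed in enumerate_break_sets(per_ring):
        if not _breaks_all_large_rings(removed, large_rings):
            continue
        try:
            tree = build_torsion_tree(mol, removed, disable_conjugated=disable_conjugated)
        except BreakPlanError:
            continue
        key = (tree.depth, len(removed), tuple(sorted(removed)))
        if best is None or key < best[0]:
            best = (key, removed, tree)
    if best is None:
        warnings.warn("no feasible break set; all macrocycles left rigid", stacklevel=2)
        tree = build_torsion_tree(mol, frozenset(), disable_conjugated=disable_conjugated)
        return BreakPlan(frozenset(), tree, tree.depth, 0)
    _, removed, tree = best
    return BreakPlan(removed, tree, tree.depth, len(usable))
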