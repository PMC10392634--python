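"""Exhaustive ring perception and macrocycle selection.

Rings are enumerated with the Hanser–Jauffret–Kaufmann (HJK) algorithm, which
returns the *complete* set of simple cycles of the molecular graph — not a
minimal basis like SSSR — by progressively collapsing vertices of a path
graph whose edges remember the simple path they represent. The complete set
is then filtered:

* **chorded** rings have an external shortcut between two of their atoms that
  is strictly shorter than the shorter in-ring arc;
* **equivalent** rings are same-size rings that share at least one bond with a
  common neighbour ring and are identical outside that neighbour — one
  representative is kept per class;
* a size window (default 7–33 atoms) selects the rings worth opening for
  flexible docking: smaller rings have a handful of well-known conformers and
  stay rigid, larger ones would overwhelm a torsional search.

The surviving rings are the breakable macrocycles handed to the break
planner.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .molgraph import Molecule, MoleculeError

__all__ = [
    "Ring",
    "RingSet",
    "RingSelectionConfig",
    "RingEnumerationError",
    "enumerate_all_rings",
    "remove_chorded",
    "remove_equivalent",
    "select_breakable",
    "perceive_rings",
]

BondKey = tuple[int, int]


class RingEnumerationError(MoleculeError):
    """Cycle enumeration exceeded the configured safety cap."""


def _edge(a: int, b: int) -> BondKey:
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class Ring:
    """A simple cycle, stored as the ordered atom sequence of the cycle."""

    atoms: tuple[int, ...]

    @property
    def size(self) -> int:
        return len(self.atoms)

    @property
    def bonds(self) -> frozenset[BondKey]:
        n = len(self.atoms)
        return frozenset(_edge(self.atoms[i], self.atoms[(i + 1) % n]) for i in range(n))

    def canonical(self) -> "Ring":
        """Rotate/reflect so the atom tuple starts at the smallest index with
        the smaller second element — a unique representative per cycle."""
        atoms = self.atoms
        n = len(atoms)
        start = atoms.index(min(atoms))
        fwd = tuple(atoms[(start + i) % n] for i in range(n))
        rev = tuple(atoms[(start - i) % n] for i in range(n))
        return Ring(min(fwd, rev))

    def arc_length(self, u: int, v: int) -> int:
        """Number of bonds on the shorter in-ring arc between two ring atoms."""
        i, j = self.atoms.index(u), self.atoms.index(v)
        d = abs(i - j)
        return min(d, self.size - d)


#: provenance tags applied by the perception pipeline
TAGS = ("kept", "chorded", "equivalent", "too_small", "too_large")


@dataclass
class RingSet:
    rings: list[Ring] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)  # parallel to rings

    def __post_init__(self) -> None:
        if not self.provenance:
            self.provenance = ["kept"] * len(self.rings)

    @property
    def kept(self) -> list[Ring]:
        return [r for r, t in zip(self.rings, self.provenance) if t == "kept"]

    def tagged(self, tag: str) -> list[Ring]:
        return [r for r, t in zip(self.rings, self.provenance) if t == tag]

    def tag(self, ring: Ring, tag: str) -> None:
        if tag not in TAGS:
            raise ValueError(f"unknown provenance tag {tag!r}")
        self.provenance[self.rings.index(ring)] = tag

    def to_json(self) -> str:
        return json.dumps(
            [
                {"atoms": list(r.atoms), "size": r.size, "status": t}
                for r, t in zip(self.rings, self.provenance)
            ],
            indent=1,
        )


@dataclass
class RingSelectionConfig:
    min_size: int = 7
    max_size: int = 33
    enumeration_cap: int = 10_000

    def __post_init__(self) -> None:
        if not (3 <= self.min_size <= self.max_size):
            raise ValueError("require 3 <= min_size <= max_size")


# ---------------------------------------------------------------------------
# HJK enumeration
# ---------------------------------------------------------------------------

def enumerate_all_rings(mol: Molecule, cap: int = 10_000) -> RingSet:
    """All simple cycles of the molecular graph via HJK vertex collapse.

    The path graph starts with one edge per bond, labelled with the two-atom
    path. Vertices are removed one at a time (smallest degree first); removing
    vertex ``v`` concatenates every pair of paths meeting at ``v`` whose
    interiors are disjoint, emitting a cycle whenever the concatenation closes
    on itself. The result is independent of the elimination order.
    """
    # path edges: list of atom tuples; parallel edges are expected
    paths: list[tuple[int, ...]] = [(b.a, b.b) for b in mol.bonds]
    vertices = {a.index for a in mol.atoms}
    cycles: set[tuple[int, ...]] = set()

    def degree(v: int) -> int:
        return sum(1 for p in paths if p[0] == v or p[-1] == v)

    while vertices:
        v = min(vertices, key=degree)
        incident = [p for p in paths if p[0] == v or p[-1] == v]
        paths = [p for p in paths if p[0] != v and p[-1] != v]
        # orient every incident path to start at v
        oriented = [p if p[0] == v else p[::-1] for p in incident]
        for p1, p2 in itertools.combinations(oriented, 2):
            # interiors (everything but the shared endpoint v) must be disjoint
            set1, set2 = set(p1[1:]), set(p2[1:])
            if p1[-1] == p2[-1]:
                # paths share both endpoints: they close into a cycle through v
                if len(set1 & set2) == 1 and len(p1) + len(p2) >= 5:
                    cyc = Ring(tuple(p1) + tuple(p2[::-1][1:-1])).canonical()
                    cycles.add(cyc.atoms)
            else:
                if not (set1 & set2):
                    merged = tuple(p1[::-1]) + tuple(p2[1:])
                    paths.append(merged)
                    if len(paths) + len(cycles) > cap:
                        raise RingEnumerationError(
                            f"ring enumeration exceeded cap of {cap} "
                            "(pathologically fused ring system?)"
                        )
        vertices.remove(v)
    rings = sorted((Ring(c) for c in cycles), key=lambda r: (r.size, r.atoms))
    return RingSet(rings=rings)


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def _shortest_outside_path(mol: Molecule, ring: Ring, u: int, v: int) -> Optional[int]:
    """BFS distance from u to v using no bond of *ring*; None if unreachable."""
    banned = ring.bonds
    adj: dict[int, list[int]] = {a.index: [] for a in mol.atoms}
    for b in mol.bonds:
        if b.key not in banned:
            adj[b.a].append(b.b)
            adj[b.b].append(b.a)
    from collections import deque

    dist = {u: 0}
    q = deque([u])
    while q:
        x = q.popleft()
        if x == v:
            return dist[x]
        for y in adj[x]:
            if y not in dist:
                dist[y] = dist[x] + 1
                q.append(y)
    return None


def is_chorded(mol: Molecule, ring: Ring) -> bool:
    """True if some atom pair of the ring has an external shortcut strictly
    shorter than the shorter in-ring arc between them."""
    for u, v in itertools.combinations(ring.atoms, 2):
        short = _shortest_outside_path(mol, ring, u, v)
        if short is not None and short < ring.arc_length(u, v):
            return True
    return False


def remove_chorded(rings: RingSet, mol: Molecule) -> RingSet:
    for r, t in zip(rings.rings, rings.provenance):
        if t == "kept" and is_chorded(mol, r):
            rings.tag(r, "chorded")
    return rings


def remove_equivalent(rings: RingSet, mol: Molecule) -> RingSet:
    """Collapse classes of equivalent rings to one representative.

    Two kept rings of identical size are equivalent when some third kept ring
    (the common neighbour) shares at least one bond with each, and the two
    rings' bonds outside that neighbour coincide. Per class the ring with the
    lexicographically smallest sorted atom tuple survives.
    """
    kept = rings.kept
    parent = {r.atoms: r.atoms for r in kept}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    for r1, r2 in itertools.combinations(kept, 2):
        if r1.size != r2.size:
            continue
        b1, b2 = r1.bonds, r2.bonds
        for nb in kept:
            if nb is r1 or nb is r2:
                continue
            nbb = nb.bonds
            if (b1 & nbb) and (b2 & nbb) and (b1 - nbb) == (b2 - nbb):
                union(r1.atoms, r2.atoms)
                break
    classes: dict[tuple, list[Ring]] = {}
    for r in kept:
        classes.setdefault(find(r.atoms), []).append(r)
    for members in classes.values():
        if len(members) > 1:
            members.sort(key=lambda r: tuple(sorted(r.atoms)))
            for loser in members[1:]:
                rings.tag(loser, "equivalent")
    return rings


def select_breakable(rings: RingSet, cfg: RingSelectionConfig | None = None) -> RingSet:
    cfg = cfg or RingSelectionConfig()
    for r, t in zip(rings.rings, rings.provenance):
        if t != "kept":
            continue
        if r.size < cfg.min_size:
            rings.tag(r, "too_small")
        elif r.size > cfg.max_size:
            rings.tag(r, "too_large")
    return rings


def small_ring_bonds(rings: RingSet, max_size: int = 6) -> set[BondKey]:
    """Bonds belonging to any enumerated ring of at most ``max_size`` atoms."""
    out: set[BondKey] = set()
    for r in rings.rings:
        if r.size <= max_size:
            out |= r.bonds
    return out


def perceive_rings(mol: Molecule, cfg: RingSelectionConfig | None = None) -> RingSet:
    """Full pipeline: enumerate → drop chorded → drop equivalent → size window.

    Side effect: flags ``in_small_ring`` on bonds of the molecule that belong
    to any ring of at most 6 atoms (these are never break candidates).
    """
    cfg = cfg or RingSelectionConfig()
    rs = enumerate_all_rings(mol, cap=cfg.enumeration_cap)
    rs = remove_chorded(rs, mol)
    rs = remove_equivalent(rs, mol)
    rs = select_breakable(rs, cfg)
    small = small_ring_bonds(rs, max_size=cfg.min_size - 1)
    for b in mol.bonds:
        b.in_small_ring = b.key in small
    return rs
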