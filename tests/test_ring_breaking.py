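"""Break-candidate rules, exhaustive plan search, torsion-tree depth."""

import itertools

import pytest

from macroring import (
    build_torsion_tree,
    candidate_bonds,
    choose_break_plan,
    enumerate_break_sets,
    merge_nonpolar_hydrogens,
    perceive_rings,
    read_molecule,
)
from macroring.ring_breaking import BreakCandidate, BreakPlanError


def prep(smiles):
    mol = merge_nonpolar_hydrogens(read_molecule(smiles))
    rings = perceive_rings(mol)
    return mol, rings


class TestCandidates:
    def test_cyclononane_all_bonds(self):
        mol, rings = prep("C1CCCCCCCC1")
        assert len(candidate_bonds(mol, rings.kept[0])) == 9

    def test_lactone_excludes_heteroatom_bonds(self):
        mol, rings = prep("O=C1CCCCCCCCCCO1")  # 12-ring with one ester oxygen
        assert rings.kept[0].size == 12
        assert len(candidate_bonds(mol, rings.kept[0])) == 10

    def test_fused_aromatic_bond_excluded(self):
        mol, rings = prep("c1ccc2c(c1)CCCCCCCC2")
        ring = rings.kept[0]
        cands = {c.bond for c in candidate_bonds(mol, ring)}
        aromatic = {b.key for b in mol.bonds if b.is_aromatic}
        assert not cands & aromatic

    def test_small_ring_bonds_excluded(self):
        # 10-ring sharing an edge with a cyclohexane: the shared and all
        # six-ring bonds are off limits
        mol, rings = prep("C1CCC2CCCCCCCC2C1")
        ring = next(r for r in rings.kept if r.size >= 7)
        small = {b.key for b in mol.bonds if b.in_small_ring}
        assert small
        assert not {c.bond for c in candidate_bonds(mol, ring)} & small


class TestEnumerateBreakSets:
    def c(self, *bonds, ring=0):
        return [BreakCandidate(bond=b, rings_covered=frozenset({ring})) for b in bonds]

    def test_single_ring(self):
        sets = enumerate_break_sets([self.c((0, 1), (1, 2), (2, 3))])
        assert len(sets) == 3

    def test_independent_product(self):
        a = self.c(*[(i, i + 1) for i in range(5)])
        b = self.c(*[(10 + i, 11 + i) for i in range(4)], ring=1)
        assert len(enumerate_break_sets([a, b])) == 20

    def test_shared_bond_collapses(self):
        shared = (5, 6)
        a = self.c((0, 1), shared)
        b = self.c(shared, (7, 8), ring=1)
        sets = enumerate_break_sets([a, b])
        assert frozenset({shared}) in sets  # one bond can serve both rings

    def test_cap(self):
        huge = [self.c(*[(i, j) for j in range(1, 60)]) for i in range(3)]
        with pytest.raises(BreakPlanError):
            enumerate_break_sets(huge, cap=1000)


def brute_force_depth(mol, removed=frozenset()):
    """Oracle: minimal eccentricity over every rigid group as root."""
    tree = build_torsion_tree(mol, removed)
    # recompute eccentricities naively from the group adjacency
    import networkx as nx

    G = nx.Graph()
    for key, kids in tree.children.items():
        for _, child in kids:
            G.add_edge(key, child)
    if not G.nodes:
        return 0
    return min(max(d.values()) for d in (nx.shortest_path_length(G, s) for s in G.nodes))


class TestTorsionTree:
    def test_heptane_depth_via_oracle(self):
        mol = merge_nonpolar_hydrogens(read_molecule("CCCCCCC"))
        tree = build_torsion_tree(mol)
        assert len(tree.rotatable_bonds) == 4
        assert tree.depth == brute_force_depth(mol) == 2

    def test_butane_depth(self):
        mol = merge_nonpolar_hydrogens(read_molecule("CCCC"))
        assert build_torsion_tree(mol).depth == 1

    def test_opened_cyclononane(self):
        mol, rings = prep("C1CCCCCCCC1")
        removed = frozenset({(0, 1)})
        tree = build_torsion_tree(mol, removed)
        # all 8 surviving ring bonds rotate once the glue pseudoatoms are on
        assert len(tree.rotatable_bonds) == 8
        assert tree.depth <= 4
        assert tree.depth == brute_force_depth(mol, removed)

    def test_residual_ring_rejected(self):
        mol, _ = prep("C1CCCCCCCC1CC1CCCCCCC1")
        with pytest.raises(BreakPlanError):
            # only one ring broken: the other macrocycle's bonds become
            # "rotatable" but close a cycle
            build_torsion_tree(mol, frozenset({(0, 1)}))


class TestChooseBreakPlan:
    def test_cyclononane_tie_break_lowest_bond(self):
        mol, rings = prep("C1CCCCCCCC1")
        plan = choose_break_plan(mol, rings)
        assert plan.n_macrocycles == 1
        assert len(plan.removed_bonds) == 1
        # all 9 choices tie on depth by symmetry; smallest bond key wins
        assert sorted(plan.removed_bonds)[0] == (0, 1)

    @pytest.mark.parametrize(
        "smiles",
        [
            "C1CCCCCCCC1",  # plain 9-ring
            "C1CCCCCC1CCCC",  # 7-ring with a butyl tail
            "O=C1CCCCCCCCCCO1",  # 12-lactone
            "C1CCC2CCCCCCCC2C1",  # macrocycle fused to cyclohexane
        ],
    )
    def test_optimality_vs_exhaustive(self, smiles):
        mol, rings = prep(smiles)
        plan = choose_break_plan(mol, rings)
        per_ring = [candidate_bonds(mol, r) for r in rings.kept]
        depths = []
        for removed in enumerate_break_sets(per_ring):
            try:
                depths.append(build_torsion_tree(mol, removed).depth)
            except BreakPlanError:
                continue
        assert plan.depth == min(depths)

    def test_exactly_one_cover(self):
        mol, rings = prep("C1CCCCCCCC1CC1CCCCCCC1")
        plan = choose_break_plan(mol, rings)
        for ring in rings.kept:
            assert len(ring.bonds & plan.removed_bonds) == 1

    def test_unbreakable_macrocycle_warns(self):
        # 8-ring of alternating N/O: no C-C candidate at all
        mol, rings = prep("N1ONONONO1")
        assert rings.kept and not candidate_bonds(mol, rings.kept[0])
        with pytest.warns(UserWarning, match="no breakable bond"):
            plan = choose_break_plan(mol, rings)
        assert plan.removed_bonds == frozenset()

    def test_deterministic_across_atom_order(self):
        # same molecule entered with different atom orders gives the same
        # canonical plan signature (depth, number of removed bonds)
        a = prep("C1CCCCCC1CCCC")
        b = prep("CCCCC1CCCCCC1")
        plan_a = choose_break_plan(*a)
        plan_b = choose_break_plan(*b)
        assert (plan_a.depth, len(plan_a.removed_bonds)) == (plan_b.depth, len(plan_b.removed_bonds))
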