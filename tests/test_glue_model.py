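"""Glue construction, closure potential, PDBQT round-trip."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from macroring import (
    ClosureParams,
    closure_energy,
    open_rings,
    read_pdbqt,
    write_pdbqt,
)
from macroring.glue_model import PDBQTError, glue_distances
from macroring.molgraph import MoleculeError

from conftest import opened


class TestOpenRings:
    def test_pseudoatom_placement(self, opened_cyclononane):
        ref, om = opened_cyclononane
        assert om.base.n_atoms == 11  # 9 carbons + 2 pseudoatoms
        assert len(om.glue_pairs) == 1
        gp = om.glue_pairs[0]
        xyz = om.base.coords_array()
        assert np.linalg.norm(xyz[gp.g_a] - xyz[gp.b]) == 0.0
        assert np.linalg.norm(xyz[gp.g_b] - xyz[gp.a]) == 0.0
        assert 1.4 < gp.ideal_length < 1.7

    def test_graph_restores_exactly(self, opened_cyclononane):
        ref, om = opened_cyclononane
        pseudo = set(om.pseudoatom_indices())
        bonds = {b.key for b in om.base.bonds if b.a not in pseudo and b.b not in pseudo}
        bonds |= set(om.plan.removed_bonds)
        assert bonds == {b.key for b in ref.bonds}

    def test_chirality_untouched(self):
        ref, om = opened("O1[C@H](C)CCCCCCCC1", name="stereomacro")
        assert [s.parity for s in om.base.stereocenters] == [s.parity for s in ref.stereocenters]

    def test_triple_macrocycle_numbering(self):
        # three independent 8-rings in a chain: three glue pairs CG1..CG3
        smi = "C1CCCCCCC1CC1CCCCCC1CC1CCCCCCC1"
        ref, om = opened(smi, name="tricycle")
        assert [gp.n for gp in om.glue_pairs] == [1, 2, 3]
        text = write_pdbqt(om)
        for n in (1, 2, 3):
            assert sum(1 for ln in text.splitlines() if ln.endswith(f" G{n}")) == 2
            assert sum(1 for ln in text.splitlines() if ln.endswith(f" CG{n}")) == 2

    def test_requires_coords(self):
        from macroring import choose_break_plan, merge_nonpolar_hydrogens, perceive_rings, read_molecule

        mol = merge_nonpolar_hydrogens(read_molecule("C1CCCCCCCC1"))
        plan = choose_break_plan(mol, perceive_rings(mol))
        with pytest.raises(MoleculeError, match="coordinates"):
            open_rings(mol, plan)


class TestClosureEnergy:
    def test_zero_at_input_pose(self, opened_cyclononane):
        _, om = opened_cyclononane
        assert closure_energy(om) == 0.0

    def test_fifty_per_angstrom(self, opened_cyclononane):
        _, om = opened_cyclononane
        gp = om.glue_pairs[0]
        xyz = om.base.coords_array()
        xyz[gp.g_a] += np.array([0.0, 0.0, 1.0])
        assert closure_energy(om, coords=xyz) == pytest.approx(50.0)

    def test_linear_additivity_two_pairs(self):
        _, om = opened("C1CCCCCCCC1CC1CCCCCCC1", name="two-rings")
        assert len(om.glue_pairs) == 2
        xyz = om.base.coords_array()
        shifts = [0.5, 0.5, 0.25, 0.25]
        targets = []
        for gp in om.glue_pairs:
            targets += [gp.g_a, gp.g_b]
        for idx, s in zip(targets, shifts):
            direction = np.array([1.0, 0.0, 0.0])
            xyz[idx] += direction * s
        assert closure_energy(om, coords=xyz) == pytest.approx(50.0 * sum(shifts))

    def test_rigid_motion_invariance(self, opened_cyclononane):
        _, om = opened_cyclononane
        xyz = om.base.coords_array()
        xyz[om.glue_pairs[0].g_a] += 0.3
        e0 = closure_energy(om, coords=xyz)
        rot = Rotation.from_euler("xyz", [20, -40, 65], degrees=True)
        moved = rot.apply(xyz) + np.array([5.0, -3.0, 11.0])
        assert closure_energy(om, coords=moved) == pytest.approx(e0, rel=1e-9)

    def test_anisotropy(self, opened_cyclononane):
        # rotating a's frame moves g_a even though dist(a, b) is unchanged
        _, om = opened_cyclononane
        gp = om.glue_pairs[0]
        xyz = om.base.coords_array()
        neighbor = next(j for j in om.base.neighbors(gp.a) if j != gp.g_a)
        axis = xyz[gp.a] - xyz[neighbor]
        axis /= np.linalg.norm(axis)
        rot = Rotation.from_rotvec(axis * np.deg2rad(25))
        xyz2 = xyz.copy()
        xyz2[gp.g_a] = xyz[gp.a] + rot.apply(xyz[gp.g_a] - xyz[gp.a])
        d_ab = np.linalg.norm(xyz2[gp.a] - xyz2[gp.b])
        assert d_ab == pytest.approx(np.linalg.norm(xyz[gp.a] - xyz[gp.b]))
        assert closure_energy(om, coords=xyz2) > 1.0

    def test_invalid_slope(self):
        with pytest.raises(ValueError):
            ClosureParams(k=0.0)


class TestPDBQT:
    def test_writer_structure(self, opened_cyclononane):
        _, om = opened_cyclononane
        text = write_pdbqt(om)
        lines = text.splitlines()
        assert sum(1 for ln in lines if ln.endswith(" G1")) == 2
        n_branch = sum(1 for ln in lines if ln.startswith("BRANCH"))
        assert n_branch == len(om.plan.tree.rotatable_bonds) == 8
        assert lines[-1] == "TORSDOF 8"

    def test_rigid_ligand(self):
        ref, om = opened("c1ccccc1", name="benzene")
        text = write_pdbqt(om)
        assert "TORSDOF 0" in text
        assert text.count("BRANCH") == 0
        assert read_pdbqt(text).glue_pairs == []

    def test_round_trip_byte_identical(self, opened_cyclononane):
        _, om = opened_cyclononane
        text = write_pdbqt(om)
        om2 = read_pdbqt(text)
        assert write_pdbqt(om2) == text
        assert len(om2.glue_pairs) == 1
        assert om2.plan.depth == om.plan.depth
        assert om2.glue_pairs[0].ideal_length == pytest.approx(
            om.glue_pairs[0].ideal_length, abs=1e-4
        )

    def test_unpaired_pseudoatom_rejected(self, opened_cyclononane):
        _, om = opened_cyclononane
        text = write_pdbqt(om).replace(" G1", " G2")
        with pytest.raises(PDBQTError, match="unpaired"):
            read_pdbqt(text)

    def test_unbalanced_branch_rejected(self, opened_cyclononane):
        _, om = opened_cyclononane
        lines = [ln for ln in write_pdbqt(om).splitlines() if not ln.startswith("ENDBRANCH")]
        with pytest.raises(PDBQTError, match="BRANCH"):
            read_pdbqt("\n".join(lines))

    def test_unknown_atom_type_rejected(self, opened_cyclononane):
        _, om = opened_cyclononane
        text = write_pdbqt(om).replace(" C\n", " Xx\n", 1)
        with pytest.raises(PDBQTError, match="unknown atom type"):
            read_pdbqt(text)


class TestGlueDistances:
    def test_reports_per_pair_terms(self, opened_cyclononane):
        _, om = opened_cyclononane
        gp = om.glue_pairs[0]
        xyz = om.base.coords_array()
        xyz[gp.g_a] += np.array([0.6, 0.0, 0.0])
        gd = glue_distances(om, coords=xyz)
        assert gd[1][0] == pytest.approx(0.6)
        assert gd[1][1] == 0.0
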