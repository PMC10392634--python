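"""Torsional sampler: determinism, closure recovery, geometry audit."""

import numpy as np
import pytest

from macroring import (
    SamplerConfig,
    TorsionDriver,
    evaluate_closure,
    restore_bonds,
    sample_closure,
)
from macroring.glue_model import glue_distances
from macroring.molgraph import MoleculeError

from conftest import opened


FAST = SamplerConfig(n_steps=2500, n_restarts=3, seed=1)


class TestKinematics:
    def test_coords_pure_function_of_angles(self, opened_cyclononane):
        _, om = opened_cyclononane
        drv = TorsionDriver(om)
        angles = np.linspace(-90, 90, drv.n_torsions)
        assert np.array_equal(drv.coords(angles), drv.coords(angles))
        assert not np.allclose(drv.coords(angles), drv.coords(np.zeros(drv.n_torsions)))

    def test_rotation_preserves_bond_lengths(self, opened_cyclononane):
        _, om = opened_cyclononane
        drv = TorsionDriver(om)
        rng = np.random.default_rng(3)
        xyz = drv.coords(rng.uniform(-180, 180, drv.n_torsions))
        for b in om.base.bonds:
            before = np.linalg.norm(drv.x0[b.a] - drv.x0[b.b])
            after = np.linalg.norm(xyz[b.a] - xyz[b.b])
            assert after == pytest.approx(before, abs=1e-9)


class TestSampleClosure:
    def test_already_closed_returns_zero_energy(self, opened_cyclononane):
        _, om = opened_cyclononane
        poses = sample_closure(om, cfg=FAST)
        assert poses[0].energy == pytest.approx(0.0, abs=1e-9)

    def test_deterministic(self, opened_cyclononane):
        _, om = opened_cyclononane
        p1 = sample_closure(om, cfg=FAST)
        p2 = sample_closure(om, cfg=FAST)
        assert len(p1) == len(p2) == FAST.n_restarts
        for a, b in zip(p1, p2):
            assert a.energy == b.energy
            assert np.array_equal(a.coords, b.coords)

    def test_zero_torsion_molecule_passthrough(self):
        ref, om = opened("c1ccccc1", name="benzene")
        poses = sample_closure(om, cfg=FAST)
        assert len(poses) == 1
        assert np.array_equal(poses[0].coords, om.base.coords_array())

    def test_recovers_randomized_cycloheptane(self):
        ref, om = opened("C1CCCCCC1", name="cycloheptane")
        drv = TorsionDriver(om)
        rng = np.random.default_rng(11)
        om.base.set_coords(drv.coords(rng.uniform(-120, 120, drv.n_torsions)))
        poses = sample_closure(om, cfg=SamplerConfig(n_steps=4000, n_restarts=3, seed=1))
        gd = glue_distances(om, coords=poses[0].coords)
        assert max(max(v) for v in gd.values()) < 0.5

    def test_energy_audit(self, opened_cyclononane):
        _, om = opened_cyclononane
        drv = TorsionDriver(om)
        rng = np.random.default_rng(5)
        om.base.set_coords(drv.coords(rng.uniform(-120, 120, drv.n_torsions)))
        poses = sample_closure(om, cfg=FAST)
        drv2 = TorsionDriver(om)
        for p in poses:
            assert drv2.energy(p.coords) == pytest.approx(p.energy, rel=1e-9, abs=1e-12)


class TestRestoreBonds:
    def test_inverse_of_open(self, opened_cyclononane):
        ref, om = opened_cyclononane
        drv = TorsionDriver(om)
        closed = restore_bonds(om, drv.pose(np.zeros(drv.n_torsions)))
        assert closed.n_atoms == ref.n_atoms
        assert sorted(b.key for b in closed.bonds) == sorted(b.key for b in ref.bonds)

    def test_restored_bond_length_is_current_distance(self, opened_cyclononane):
        ref, om = opened_cyclononane
        drv = TorsionDriver(om)
        pose = drv.pose(np.full(drv.n_torsions, 15.0))
        closed = restore_bonds(om, pose)
        gp = om.glue_pairs[0]
        d_pose = np.linalg.norm(pose.coords[gp.a] - pose.coords[gp.b])
        d_closed = np.linalg.norm(closed.atoms[gp.a].coords - closed.atoms[gp.b].coords)
        assert d_closed == pytest.approx(d_pose)

    def test_triple_macrocycle_fully_restored(self):
        ref, om = opened("C1CCCCCCC1CC1CCCCCC1CC1CCCCCCC1", name="tricycle")
        drv = TorsionDriver(om)
        closed = restore_bonds(om, drv.pose(np.zeros(drv.n_torsions)))
        assert sorted(b.key for b in closed.bonds) == sorted(b.key for b in ref.bonds)
        assert all(a.element != "G" for a in closed.atoms)


class TestEvaluateClosure:
    def test_self_reference(self, cyclononane):
        rep = evaluate_closure(cyclononane, cyclononane)
        assert rep.ring_rmsd == pytest.approx(0.0, abs=1e-9)
        assert all(rep.chirality_ok.values())

    def test_translation_invariance(self, cyclononane):
        moved = cyclononane.copy()
        moved.set_coords(moved.coords_array() + np.array([1.0, 2.0, 3.0]))
        rep = evaluate_closure(moved, cyclononane)
        assert rep.ring_rmsd == pytest.approx(0.0, abs=1e-7)

    def test_single_displacement_closed_form(self, cyclononane):
        # one atom displaced by 1 Å, superposition off: RMSD = 1/sqrt(N)
        moved = cyclononane.copy()
        xyz = moved.coords_array()
        xyz[0] += np.array([1.0, 0.0, 0.0])
        moved.set_coords(xyz)
        rep = evaluate_closure(moved, cyclononane, superpose=False)
        assert rep.ring_rmsd == pytest.approx(1.0 / np.sqrt(9))

    def test_atom_count_mismatch(self, cyclononane):
        from macroring import read_molecule

        with pytest.raises(MoleculeError):
            evaluate_closure(cyclononane, read_molecule("CC"))

    def test_chirality_flip_detected(self):
        ref, om = opened("O1[C@H](C)CCCCCCCC1", name="stereomacro")
        assert ref.stereocenters
        mirrored = ref.copy()
        xyz = mirrored.coords_array()
        xyz[:, 2] *= -1  # reflection inverts every stereocentre
        mirrored.set_coords(xyz)
        rep = evaluate_closure(mirrored, ref)
        assert not all(rep.chirality_ok.values())


class TestMonotoneK:
    def test_stronger_glue_never_worse(self):
        from macroring import ClosureParams

        ref, om = opened("C1CCCCCCC1", name="cyclooctane")
        drv = TorsionDriver(om)
        rng = np.random.default_rng(9)
        om.base.set_coords(drv.coords(rng.uniform(-120, 120, drv.n_torsions)))
        cfg = SamplerConfig(n_steps=3000, n_restarts=2, seed=4)
        worst = {}
        for k in (50.0, 100.0):
            poses = sample_closure(om, params=ClosureParams(k=k), cfg=cfg)
            gd = glue_distances(om, coords=poses[0].coords)
            worst[k] = max(max(v) for v in gd.values())
        assert worst[100.0] <= worst[50.0] + 1e-6
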