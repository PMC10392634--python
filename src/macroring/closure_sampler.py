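"""Torsional sampler that drives ring closure and audits the result.

This is a desk-scale surrogate for a docking engine's conformational search:
a seeded Metropolis annealer over the ligand's torsion angles, minimising the
glue closure penalty plus a soft-sphere clash term, followed by a
deterministic coordinate-descent polish. Its job is to demonstrate that the
glue construction closes rings with correct bond geometry and chirality — not
to reproduce docking scores.

Coordinates are a pure function of the torsion-angle vector: angles are
applied as rotations of each branch's subtree about its rotatable bond, in
depth-first tree order starting from the rigid root.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .glue_model import ClosureParams, OpenedMolecule, closure_energy, glue_distances
from .molgraph import Bond, Molecule, MoleculeError, signed_volume_sign
from .ring_perception import _edge

__all__ = [
    "SamplerConfig",
    "Pose",
    "ClosureReport",
    "TorsionDriver",
    "sample_closure",
    "restore_bonds",
    "evaluate_closure",
]


@dataclass
class SamplerConfig:
    n_steps: int = 8000
    n_restarts: int = 8
    seed: int = 0
    temp_start: float = 5.0  # kcal/mol
    temp_end: float = 0.05
    max_torsion_step: float = 90.0  # degrees
    clash_k: float = 10.0  # kcal/mol/Å², soft-sphere half-harmonic
    clash_onset: float = 2.7  # Å
    success_glue_dist: float = 0.5  # Å
    polish_sweeps: int = 60

    def __post_init__(self) -> None:
        if self.n_steps <= 0:
            raise ValueError("n_steps must be positive")
        if self.success_glue_dist <= 0:
            raise ValueError("success_glue_dist must be positive")


@dataclass
class Pose:
    torsion_angles: np.ndarray  # degrees, aligned with TorsionDriver.edges
    coords: np.ndarray  # (n_atoms, 3)
    energy: float  # closure + clash, kcal/mol


@dataclass
class ClosureReport:
    best_pose: Pose
    glue_distances: dict[int, tuple[float, float]]
    restored_bond_error: dict[int, float]  # |current a-b| - ideal, per pair
    angle_errors: dict[int, float]  # worst valence-angle deviation (deg) per pair
    chirality_ok: dict[int, bool]  # per stereocentre atom index
    ring_rmsd: float
    success: bool

    def to_json(self) -> str:
        return json.dumps(
            {
                "energy": self.best_pose.energy,
                "glue_distances": {str(k): list(v) for k, v in self.glue_distances.items()},
                "restored_bond_error": {str(k): v for k, v in self.restored_bond_error.items()},
                "angle_errors": {str(k): v for k, v in self.angle_errors.items()},
                "chirality_ok": {str(k): v for k, v in self.chirality_ok.items()},
                "ring_rmsd": self.ring_rmsd,
                "success": self.success,
            },
            indent=1,
        )


class TorsionDriver:
    """Forward kinematics and energy for an opened ligand.

    ``edges`` lists the rotatable bonds in depth-first preorder as
    ``(pivot_atom, moved_atom, subtree_atoms)``; a pose's angle ``i`` rotates
    ``subtree_atoms`` about the pivot→moved axis. The clash term runs over
    heavy-atom pairs at least 4 bonds apart *in the closed graph* (so glue
    partners and their neighbourhoods are excluded, as they would be in a
    bonded force field) with pseudoatoms ignored.
    """

    def __init__(self, om: OpenedMolecule, params: ClosureParams | None = None, cfg: SamplerConfig | None = None):
        self.om = om
        self.params = params or ClosureParams()
        self.cfg = cfg or SamplerConfig()
        self.x0 = om.base.coords_array()
        tree = om.plan.tree
        self.edges: list[tuple[int, int, np.ndarray]] = []
        subtree_atoms: dict[int, set[int]] = {}

        def collect(key: int) -> set[int]:
            atoms = set(tree.groups[key])
            for _, child in tree.children[key]:
                atoms |= collect(child)
            subtree_atoms[key] = atoms
            return atoms

        collect(tree.root_key)

        def walk(key: int) -> None:
            for (a, b), child in tree.children[key]:
                pivot, moved = (a, b) if b in tree.groups[child] else (b, a)
                idx = np.fromiter(sorted(subtree_atoms[child]), dtype=int)
                self.edges.append((pivot, moved, idx))
                walk(child)

        walk(tree.root_key)
        self.n_torsions = len(self.edges)
        self._clash_pairs = self._build_clash_pairs()

    # -- clash exclusion over the closed graph ------------------------------

    def _build_clash_pairs(self) -> np.ndarray:
        om = self.om
        heavy = [
            a.index
            for a in om.base.atoms
            if a.element not in ("H", "G")
        ]
        adj: dict[int, list[int]] = {a.index: [] for a in om.base.atoms}
        for b in om.base.bonds:
            adj[b.a].append(b.b)
            adj[b.b].append(b.a)
        for gp in om.glue_pairs:  # restored bonds count for separation
            adj[gp.a].append(gp.b)
            adj[gp.b].append(gp.a)
        from collections import deque

        pairs = []
        for i in heavy:
            dist = {i: 0}
            q = deque([i])
            while q:
                x = q.popleft()
                if dist[x] >= 4:
                    continue
                for y in adj[x]:
                    if y not in dist:
                        dist[y] = dist[x] + 1
                        q.append(y)
            for j in heavy:
                if j > i and dist.get(j, 99) >= 4:
                    pairs.append((i, j))
        return np.array(pairs, dtype=int).reshape(-1, 2)

    # -- energies ------------------------------------------------------------

    def clash_energy(self, xyz: np.ndarray) -> float:
        if len(self._clash_pairs) == 0:
            return 0.0
        d = np.linalg.norm(xyz[self._clash_pairs[:, 0]] - xyz[self._clash_pairs[:, 1]], axis=1)
        overlap = np.clip(self.cfg.clash_onset - d, 0.0, None)
        return float(self.cfg.clash_k * np.sum(overlap**2))

    def energy(self, xyz: np.ndarray) -> float:
        return closure_energy(self.om, self.params, coords=xyz) + self.clash_energy(xyz)

    # -- kinematics ----------------------------------------------------------

    def coords(self, torsion_angles: Sequence[float]) -> np.ndarray:
        """Deterministic coordinates for a torsion-angle vector (degrees)."""
        if len(torsion_angles) != self.n_torsions:
            raise MoleculeError("torsion vector length mismatch")
        xyz = self.x0.copy()
        for (pivot, moved, idx), angle in zip(self.edges, torsion_angles):
            if angle == 0.0:
                continue
            self._rotate(xyz, pivot, moved, idx, float(angle))
        return xyz

    @staticmethod
    def _rotate(xyz: np.ndarray, pivot: int, moved: int, idx: np.ndarray, angle_deg: float) -> None:
        axis = xyz[moved] - xyz[pivot]
        norm = np.linalg.norm(axis)
        if norm < 1e-9:
            return
        rot = Rotation.from_rotvec(axis / norm * np.deg2rad(angle_deg))
        xyz[idx] = rot.apply(xyz[idx] - xyz[pivot]) + xyz[pivot]

    def pose(self, torsion_angles: Sequence[float]) -> Pose:
        angles = np.asarray(torsion_angles, dtype=float)
        xyz = self.coords(angles)
        return Pose(torsion_angles=angles, coords=xyz, energy=self.energy(xyz))


def sample_closure(
    om: OpenedMolecule,
    params: ClosureParams | None = None,
    cfg: SamplerConfig | None = None,
) -> list[Pose]:
    """Metropolis annealing over torsions; returns one best pose per restart.

    Each restart begins at the input conformation, anneals from
    ``temp_start`` to ``temp_end`` over ``n_steps`` proposals (one random
    torsion perturbed per step, amplitude shrinking with temperature), then
    polishes the best-seen angle vector by deterministic coordinate descent.
    Fully reproducible for a fixed ``cfg.seed``; the returned list is sorted
    by energy.
    """
    cfg = cfg or SamplerConfig()
    params = params or ClosureParams()
    driver = TorsionDriver(om, params, cfg)
    if driver.n_torsions == 0:
        return [driver.pose(np.zeros(0))]

    out: list[Pose] = []
    for r in range(cfg.n_restarts):
        rng = np.random.default_rng([cfg.seed, r])
        angles = np.zeros(driver.n_torsions)
        xyz = driver.coords(angles)
        e = driver.energy(xyz)
        best_angles, best_e = angles.copy(), e
        decay = (cfg.temp_end / cfg.temp_start) ** (1.0 / max(cfg.n_steps - 1, 1))
        temp = cfg.temp_start
        for _ in range(cfg.n_steps):
            i = int(rng.integers(driver.n_torsions))
            scale = max(temp / cfg.temp_start, 0.05)
            delta = float(rng.uniform(-1, 1)) * cfg.max_torsion_step * scale
            trial = angles.copy()
            trial[i] = (trial[i] + delta + 180.0) % 360.0 - 180.0
            pivot, moved, idx = driver.edges[i]
            trial_xyz = xyz.copy()
            TorsionDriver._rotate(trial_xyz, pivot, moved, idx, delta)
            e_trial = driver.energy(trial_xyz)
            if e_trial <= e or rng.random() < np.exp(-(e_trial - e) / temp):
                angles, xyz, e = trial, trial_xyz, e_trial
                if e < best_e:
                    best_angles, best_e = angles.copy(), e
            temp *= decay
        best_angles = _polish(driver, best_angles, cfg.polish_sweeps)
        out.append(driver.pose(best_angles))
    out.sort(key=lambda p: p.energy)
    return out


def _polish(driver: TorsionDriver, angles: np.ndarray, sweeps: int) -> np.ndarray:
    """Pattern-search refinement: per-torsion ± steps, halved when stuck."""
    angles = angles.copy()
    e = driver.energy(driver.coords(angles))
    step = 10.0
    for _ in range(sweeps):
        improved = False
        for i in range(driver.n_torsions):
            for sign in (1.0, -1.0):
                trial = angles.copy()
                trial[i] += sign * step
                e_t = driver.energy(driver.coords(trial))
                if e_t < e - 1e-12:
                    angles, e = trial, e_t
                    improved = True
                    break
        if not improved:
            step *= 0.5
            if step < 0.01:
                break
    return angles


def restore_bonds(om: OpenedMolecule, pose: Pose) -> Molecule:
    """Drop pseudoatoms and re-add the removed bonds at the pose coordinates."""
    pseudo = set(om.pseudoatom_indices())
    real = [a.index for a in om.base.atoms if a.index not in pseudo]
    remap = {old: new for new, old in enumerate(real)}
    closed = Molecule(name=om.base.name)
    for old in real:
        a = om.base.atoms[old].copy()
        a.index = remap[old]
        a.coords = pose.coords[old].copy()
        closed.atoms.append(a)
    for b in om.base.bonds:
        if b.a not in pseudo and b.b not in pseudo:
            nb = b.copy()
            nb.a, nb.b = remap[b.a], remap[b.b]
            closed.bonds.append(nb)
    for gp in om.glue_pairs:
        a, b = remap[gp.a], remap[gp.b]
        closed.bonds.append(Bond(a=min(a, b), b=max(a, b), order=1))
    # stereocentre indices survive only when pseudoatoms sat at the tail
    # (the open_rings layout); parsed PDBQT ligands carry no stereo records
    closed.stereocenters = [
        sc
        for sc in om.base.stereocenters
        if sc.atom in remap
        and remap[sc.atom] == sc.atom
        and all(remap.get(n) == n for n in sc.neighbor_order)
    ]
    closed.validate()
    return closed


def _kabsch_rmsd(p: np.ndarray, q: np.ndarray) -> float:
    """RMSD after optimal rigid superposition of p onto q."""
    pc, qc = p - p.mean(axis=0), q - q.mean(axis=0)
    rot, rssd = Rotation.align_vectors(qc, pc)
    return float(rssd / np.sqrt(len(p)))


def evaluate_closure(
    closed: Molecule,
    reference: Molecule,
    om: OpenedMolecule | None = None,
    ring_atoms: Optional[Sequence[int]] = None,
    success_glue_dist: float = 0.5,
    superpose: bool = True,
) -> ClosureReport:
    """Geometry/chirality audit of a closed pose against the input reference.

    ``ring_atoms`` selects the heavy atoms used for the RMSD (default: all
    heavy atoms). Glue distances, restored-bond and valence-angle errors are
    reported when the generating :class:`OpenedMolecule` is supplied.
    """
    if closed.n_atoms != reference.n_atoms:
        raise MoleculeError("closed and reference molecules differ in atom count")
    xyz_c, xyz_r = closed.coords_array(), reference.coords_array()
    sel = list(ring_atoms) if ring_atoms is not None else [
        a.index for a in reference.atoms if a.element != "H"
    ]
    if superpose:
        rmsd = _kabsch_rmsd(xyz_c[sel], xyz_r[sel])
    else:
        rmsd = float(np.sqrt(np.mean(np.sum((xyz_c[sel] - xyz_r[sel]) ** 2, axis=1))))

    chirality: dict[int, bool] = {}
    for sc in reference.stereocenters:
        if sc.volume_sign == 0 or len(sc.neighbor_order) < 3:
            continue
        sign = signed_volume_sign(xyz_c, sc.atom, sc.neighbor_order[:3])
        chirality[sc.atom] = sign == sc.volume_sign

    gd: dict[int, tuple[float, float]] = {}
    bond_err: dict[int, float] = {}
    ang_err: dict[int, float] = {}
    success = True
    if om is not None:
        # glue distances use the coordinates currently stored on om.base;
        # close_and_evaluate refreshes them to the best pose before calling
        gd = glue_distances(om) if om.base.has_coords() else {}
        pseudo = set(om.pseudoatom_indices())
        remap = {old: new for new, old in enumerate(i for i in range(om.base.n_atoms) if i not in pseudo)}
        for gp in om.glue_pairs:
            a, b = remap[gp.a], remap[gp.b]
            d = float(np.linalg.norm(xyz_c[a] - xyz_c[b]))
            bond_err[gp.n] = d - gp.ideal_length
            ang_err[gp.n] = _worst_angle_error(closed, reference, a, b)
        success = all(max(v) < success_glue_dist for v in gd.values()) if gd else True
    success = success and all(chirality.values())

    best = Pose(torsion_angles=np.zeros(0), coords=xyz_c, energy=0.0)
    return ClosureReport(
        best_pose=best,
        glue_distances=gd,
        restored_bond_error=bond_err,
        angle_errors=ang_err,
        chirality_ok=chirality,
        ring_rmsd=rmsd,
        success=success,
    )


def _angle(xyz: np.ndarray, i: int, j: int, k: int) -> float:
    u, v = xyz[i] - xyz[j], xyz[k] - xyz[j]
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def _worst_angle_error(closed: Molecule, reference: Molecule, a: int, b: int) -> float:
    """Largest deviation of valence angles n-a-b and n-b-a vs the reference."""
    xc, xr = closed.coords_array(), reference.coords_array()
    worst = 0.0
    for center, partner in ((a, b), (b, a)):
        for n in closed.neighbors(center):
            if n == partner:
                continue
            worst = max(worst, abs(_angle(xc, n, center, partner) - _angle(xr, n, center, partner)))
    return worst


def close_and_evaluate(
    om: OpenedMolecule,
    reference: Molecule,
    params: ClosureParams | None = None,
    cfg: SamplerConfig | None = None,
    ring_atoms: Optional[Sequence[int]] = None,
) -> ClosureReport:
    """Sample, take the best pose, restore bonds, and audit the closure."""
    cfg = cfg or SamplerConfig()
    poses = sample_closure(om, params, cfg)
    best = poses[0]
    om.base.set_coords(best.coords)
    closed = restore_bonds(om, best)
    report = evaluate_closure(
        closed, reference, om=om, ring_atoms=ring_atoms, success_glue_dist=cfg.success_glue_dist
    )
    report.best_pose = best
    return report
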