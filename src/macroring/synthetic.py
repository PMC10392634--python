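"""Deterministic synthetic macrocycles for development and validation.

Real macrocyclic ligands come with crystallographic coordinates; the
generator builds stand-ins from scratch: a single macrocyclic ring of a
requested size (7–33 atoms), optionally decorated with ring heteroatoms
(O/N), a fused cyclohexane, methyl substituents that create genuine
stereocentres, and an exocyclic tail — then embeds a 3D conformer with a
seeded distance-geometry run. Everything is a pure function of its
arguments, so fixtures regenerate identically everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

from rdkit import Chem

from .molgraph import (
    Molecule,
    generate_conformer,
    merge_nonpolar_hydrogens,
    read_molecule,
)

__all__ = ["MacrocycleSpec", "make_macrocycle", "closure_benchmark", "BENCHMARK_SPECS"]


@dataclass(frozen=True)
class MacrocycleSpec:
    ring_size: int
    n_hetero: int = 0  # ring oxygens replacing carbons, evenly spaced
    fused_cyclohexane: bool = False  # cis-fused six-ring on two adjacent ring atoms
    n_stereo_methyls: int = 0  # methyl substituents adjacent to ring oxygens
    tail_length: int = 0  # exocyclic -(CH2)n- tail
    seed: int = 1
    name: str = ""

    def __post_init__(self) -> None:
        if not (7 <= self.ring_size <= 33):
            raise ValueError("ring_size must be within 7..33")
        if self.n_hetero > self.ring_size // 3:
            raise ValueError("too many ring heteroatoms")


def _ring_smiles(spec: MacrocycleSpec) -> str:
    """Assemble the SMILES: ring atoms listed in order with decorations.

    Stereo-bearing carbons are written ``[C@H](C)`` right after a ring oxygen
    — the O/C asymmetry around them makes the centre genuine; RDKit is the
    arbiter of whether a centre survives (checked by the caller).
    """
    size = spec.ring_size
    symbols = ["C"] * size
    if spec.n_hetero:
        stride = size // spec.n_hetero
        for k in range(spec.n_hetero):
            symbols[(k * stride) % size] = "O"
    tail_pos = -1
    if spec.tail_length:
        tail_pos = next(i for i in range(size // 2, size - 2) if symbols[i] == "C")
    parts: list[str] = []
    placed_stereo = 0
    for i, sym in enumerate(symbols):
        token = sym
        if (
            sym == "C"
            and placed_stereo < spec.n_stereo_methyls
            and i > 0
            and symbols[i - 1] == "O"
        ):
            token = "[C@H](C)" if placed_stereo % 2 == 0 else "[C@@H](C)"
            placed_stereo += 1
        if i == 0:
            token += "1"
        if spec.fused_cyclohexane and sym == "C" and i == size - 2:
            # open the fused six-ring across atoms size-2 and size-1
            token += "2"
        if i == size - 1:
            if spec.fused_cyclohexane:
                token += "1CCCC2"  # closes macro ring then the fused ring
                parts.append(token)
                break
            token += "1"
        if i == tail_pos:
            token += "(" + "C" * spec.tail_length + ")"
        parts.append(token)
    return "".join(parts)


def make_macrocycle(spec: MacrocycleSpec) -> Molecule:
    """Build, hydrogen-merge and embed one synthetic macrocycle."""
    smi = _ring_smiles(spec)
    mol = read_molecule(smi, format="smiles", name=spec.name or f"macro{spec.ring_size}")
    mol = merge_nonpolar_hydrogens(mol)
    mol = generate_conformer(mol, seed=spec.seed)
    return mol


#: The ten benchmark macrocycles used for closure validation: ring sizes 7–16,
#: zero to two stereocentres, with and without a fused cyclohexane and tails.
BENCHMARK_SPECS: tuple[MacrocycleSpec, ...] = (
    MacrocycleSpec(ring_size=7, name="m07"),
    MacrocycleSpec(ring_size=8, n_hetero=1, name="m08o"),
    MacrocycleSpec(ring_size=9, name="m09"),
    MacrocycleSpec(ring_size=10, n_hetero=1, n_stereo_methyls=1, name="m10s1"),
    MacrocycleSpec(ring_size=11, tail_length=2, name="m11t"),
    MacrocycleSpec(ring_size=12, n_hetero=2, n_stereo_methyls=2, name="m12s2"),
    MacrocycleSpec(ring_size=13, fused_cyclohexane=True, name="m13f"),
    MacrocycleSpec(ring_size=14, n_hetero=1, name="m14o"),
    MacrocycleSpec(ring_size=15, n_hetero=2, n_stereo_methyls=1, tail_length=1, name="m15s1t"),
    MacrocycleSpec(ring_size=16, fused_cyclohexane=True, n_hetero=1, name="m16f"),
)


def closure_benchmark() -> list[Molecule]:
    """The embedded benchmark set (deterministic; specs are frozen)."""
    return [make_macrocycle(s) for s in BENCHMARK_SPECS]
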