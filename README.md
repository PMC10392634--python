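# macroring

Preparation of flexible macrocyclic ligands for torsional docking, plus a
desk-scale sampler that closes the opened rings and audits the result.

Macrocycles — non-aromatic rings of seven or more atoms — are awkward for
docking engines that sample bond rotations independently: the ring couples
its torsions, so the cyclic structure cannot be explored one bond at a time.
`macroring` takes the ring-opening route: delete one ring bond, dock the now
acyclic molecule, and let a restraint pull the ring shut again. The broken
bond's two carbons are retyped `CGn` and each carries a massless, charge-free
pseudoatom `Gn` placed at the partner's original position. The closure
penalty is linear in the glue separations,

```
E_closure = k · Σ_n ( |g_aₙ − bₙ| + |g_bₙ − aₙ| ),      k = 50 kcal/mol/Å
```

and is zero exactly when both pseudoatoms sit on their targets. Because each
pseudoatom is bonded into its parent's rigid frame, the restraint is
*anisotropic*: it restores the original bond length, valence angles and
chirality, not merely the a–b distance.

The pipeline:

1. **Ring perception** — every simple cycle of the molecular graph is
   enumerated with the Hanser–Jauffret–Kaufmann (HJK) path-graph collapse
   (not an SSSR basis), then *chorded* rings (those with an external shortcut
   shorter than their own arc) and *equivalent* rings (same-size rings
   differing only inside a common neighbour ring) are filtered out, and a
   7–33-atom size window selects the rings worth opening.
2. **Ring breaking** — among all single non-aromatic C–C ring bonds outside
   small rings, an exhaustive search picks one bond per macrocycle (a shared
   bond may serve two rings) minimising the depth of the deepest rotatable-
   bond branch of the resulting torsion tree.
3. **Glue construction & emission** — pseudoatoms are attached and the
   ligand is written as an AutoDock-style PDBQT (ROOT/BRANCH tree, `CGn`/`Gn`
   types, TORSDOF).
4. **Closure sampling** — a seeded Metropolis annealer over the torsion
   angles (closure penalty + soft-sphere clash term) closes the ring; the
   report covers glue distances, restored bond length, valence-angle errors,
   per-stereocentre parity and ring RMSD.

A curation module screens SMILES dictionaries (metal-containing, carbon-free
and valence-broken entries rejected; macrocycles flagged; largest-SSSR-ring
histogram), and a synthetic generator builds deterministic benchmark
macrocycles (ring sizes 7–33, heteroatoms, fused rings, stereocentres,
tails) with embedded 3D conformers.

## Worked example

```sh
$ macroring prepare "C1CCCCCCCC1" -o c9.pdbqt --seed 1
C1CCCCCCCC1: 1 macrocycle(s), 1 bond(s) removed, torsion-tree depth 4, TORSDOF 8 -> c9.pdbqt

$ macroring close c9.pdbqt -o c9_closed.sdf --steps 3000 --restarts 3 --seed 1 --report report.json
best energy 0.000 kcal/mol, worst glue distance 0.000 Å, closure succeeded -> c9_closed.sdf
```

Cyclononane's single 9-ring is opened at one C–C bond: the 8 surviving ring
bonds all become rotatable (TORSDOF 8) and the depth-minimising root leaves
no branch deeper than 4 rotatable bonds. Starting from the already-closed
input, the sampler keeps the zero-energy pose, so the worst glue distance is
0 Å and the closure audit succeeds. The same objects are available as a
library:

```python
from macroring import (read_molecule, merge_nonpolar_hydrogens, generate_conformer,
                       perceive_rings, choose_break_plan, open_rings, closure_energy)

mol = generate_conformer(merge_nonpolar_hydrogens(read_molecule("C1CCCCCCCC1")), seed=1)
plan = choose_break_plan(mol, perceive_rings(mol))
om = open_rings(mol, plan)          # 9 C + 2 pseudoatoms, 1 glue pair
closure_energy(om)                  # 0.0 at the input pose
```

Curation of a SMILES list:

```sh
$ macroring curate ligands.smi -o report.json --histogram hist.tsv
{"kept": 3, "rejected_metal": 1, "rejected_no_carbon": 1, "rejected_valence": 1}  macrocycle fraction 0.333
```

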