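# Methods

## Molecular model

The working representation is a lightweight attributed graph: heavy atoms
plus polar hydrogens, bond orders and aromaticity flags, optional Cartesian
coordinates in Å, and tetrahedral stereocentres. RDKit performs all chemical
perception (parsing, sanitisation, aromaticity, stereo assignment, ETKDG
conformer embedding followed by a short MMFF relaxation); everything
downstream operates on the plain graph. Atom indices are 0-based internally
and become 1-based serials in PDBQT output.

Non-polar hydrogens (those on carbon) are folded into a per-carbon
`merged_h_count`; hydrogens on heteroatoms stay explicit. A bond is
rotatable iff it is single, non-aromatic, acyclic, both ends have ≥ 2 heavy
neighbours, and it is not an amide C–N bond; optionally (default on) the
single bond of a C=C–C=A motif is frozen too, mirroring the standard
conjugated-bond treatment in docking preparation. Glue pseudoatoms count as
heavy neighbours for this rule — that is what makes the terminal ring bond
at each glue atom a genuine rotor in the opened ligand.

Stereocentres are stored as a CIP-ranked neighbour tuple plus the sign of
the signed volume of the three top-ranked neighbours about the centre,
evaluated at the input coordinates. Re-evaluating that sign on any later
coordinates (same neighbour order) tells whether a pose preserved the
configuration without re-entering a chemistry toolkit; this is how the
closure audit checks chirality.

## Ring perception

All simple cycles are enumerated with the Hanser–Jauffret–Kaufmann
path-graph collapse: edges carry the simple path they represent, vertices
are eliminated smallest-degree-first, and two paths meeting at the removed
vertex are concatenated when their interiors are disjoint (closing into a
recorded cycle when they share both endpoints). The result is the complete
cycle set, independent of elimination order; a configurable cap (default
10,000) aborts on pathologically fused systems rather than truncating
silently.

Filters run in a fixed order — chorded, equivalent, size window:

* A ring is **chorded** when some atom pair has an external path (using no
  ring bond) strictly shorter than the shorter in-ring arc. The comparison
  is strict: an equal-length alternative path does not chord a ring, which
  is precisely what lets mirror-image large rings around a small ring
  survive to be handled by the equivalence filter instead.
* Two kept rings of identical size are **equivalent** when a third kept ring
  shares at least one bond with both and the two rings coincide outside that
  neighbour. Classes are collapsed via union–find; the representative with
  the lexicographically smallest sorted atom tuple survives, making the
  choice independent of input atom order.
* The **size window** keeps rings of 7–33 atoms for breaking. Below seven a
  ring's conformer set is small and well known (chairs, boats) and it stays
  rigid; above 33 the opened form's torsional complexity outgrows what a
  torsional search can handle, so such rings also stay rigid.

Bonds in any ring of ≤ 6 atoms are flagged as small-ring context and are
never break candidates.

## Ring breaking

Candidates per macrocycle are its single, non-aromatic C–C bonds outside
small rings. Double bonds are excluded even though they connect carbons:
breaking one would discard geometry the closure potential cannot encode.
The planner enumerates every way of choosing one candidate per macrocycle
(duplicate bond sets collapse — a bond shared by two fused macrocycles can
open both, giving fewer removed bonds than rings), rejects sets that leave
any large ring intact (checked against the full enumerated cycle set and a
minimum-cycle-basis audit of the opened graph), and scores each survivor by
the depth of its torsion tree.

The torsion tree contracts rigid fragments (components left after cutting
rotatable bonds) into nodes; its depth is the number of rotatable bonds on
the deepest root-to-leaf path, and the root is chosen per break set as the
fragment with minimal eccentricity (ties to the smallest atom index). The
plan with minimal depth wins; ties break on fewer removed bonds, then the
smallest sorted bond tuple. Exhaustive search is bounded at 10⁵
combinations — macrocyclic ligands sit far below this; exceeding it is an
error, not a silent fallback.

## Glue model and closure potential

Opening bond (a, b) retypes both atoms `CGn` and appends two pseudoatoms:
`g_a` bonded to a at the input position of b, and `g_b` bonded to b at the
position of a. Pseudoatoms are charge-zero, excluded from steric terms, and
pair-matched: `Gn` only ever attracts its own `CGn` partner. The closure
energy sums both cross terms per pair,
`E = k·Σ(|g_a−b| + |g_b−a|)` with `k = 50 kcal/mol/Å`,
so either fragment feels a restoring force; the two-term symmetric form is a
deliberate design choice where a single-term variant would leave one
fragment's frame unconstrained. The potential is zero exactly at perfect
closure, invariant under rigid motion of the whole molecule, and
anisotropic in effect because each pseudoatom rides its parent's frame.

PDBQT emission follows the AutoDock ligand dialect: ROOT block, nested
BRANCH records mirroring the torsion tree, `CGn`/`Gn` type columns and a
TORSDOF count equal to the active torsions. Because the format itself does
not record intra-fragment connectivity, the writer adds `REMARK BOND` and
`REMARK GLUE` lines; the reader uses them when present (falling back to a
covalent-distance heuristic otherwise) and rebuilds the tree from the
BRANCH nesting, so write → read → write is byte-identical.

## Closure sampler

The sampler is a stand-in for a docking engine's search, built to validate
the closure construction, not to reproduce docking scores. It anneals the
torsion vector with Metropolis acceptance: one uniformly chosen torsion is
perturbed per step (amplitude scaled with temperature, cap 90°), the
temperature decays geometrically from 5 to 0.05 kcal/mol over the run, and
the best angles seen are refined by a deterministic pattern search (per-
torsion ± steps, halved when no move improves, down to 0.01°). Coordinates
are a pure function of the torsion vector — rotations applied in depth-first
tree order from the rigid root — so identical seeds give identical poses
bit-for-bit.

The objective adds a soft-sphere clash term to the closure energy: a
half-harmonic penalty (10 kcal/mol/Å², onset 2.7 Å) over heavy-atom pairs
at least four bonds apart *in the closed graph*, so glue partners and their
1-3/1-4 neighbourhoods are excluded exactly as bonded atoms would be in a
force field; pseudoatoms are ignored. Without this term the linear glue
potential happily threads chains through each other.

The closure audit reports per-pair glue distances, the restored bond's
deviation from its ideal length (the original bond length), the worst
valence-angle change at either glue atom, per-stereocentre parity, and the
heavy-atom RMSD after Kabsch superposition (scipy's `align_vectors`). A
closure counts as successful when every glue term is below 0.5 Å — an
artifact-level threshold chosen well inside the 2 Å pose-RMSD convention
used to judge docked poses.

## Synthetic benchmark

The generator assembles macrocycle SMILES from a frozen specification (ring
size 7–33, evenly spaced ring oxygens, an optionally cis-fused cyclohexane,
methyl-bearing stereocentres placed next to ring oxygens so the centres are
genuine, an exocyclic tail) and embeds a conformer with a seeded ETKDG run;
everything is a pure function of the spec, so fixtures regenerate
identically on any machine. The validation set is ten such macrocycles with
ring sizes 7–16, zero to two stereocentres and up to one fused cyclohexane —
ring sizes below 15 are where ring-opening methods are expected to work
best, and 7–16 spans that regime plus a margin while staying cheap enough to
sample thoroughly.

What the benchmark shows: that the glue construction closes rings to
sub-0.5 Å glue distances with correct bond lengths and chirality from
randomized torsions, under a pure torsional search. What it does not show:
docking accuracy against receptors (no intermolecular scoring is present),
performance on crystallographic ligands with charged groups, amide-rich
peptide backbones, or rings above 16 atoms, and robustness to the
conformational strain of fused polycyclic natural products.

## Numerical and validation choices

* Closure-recovery runs use 6,000 annealing steps and 5 restarts per
  molecule with fixed seeds — enough for every benchmark member to close
  reproducibly while keeping the whole suite interactive.
* Starting torsions for recovery runs are drawn uniformly from ±120° with a
  per-molecule fixed seed; ±180° would occasionally create knotted starts
  whose escape tests the annealer rather than the closure model.
* Ring enumeration and break-set search are exact with hard caps (10⁴
  cycles, 10⁵ combinations); both raise diagnostics instead of degrading.
* Degenerate inputs: molecules with no rings pass through unchanged; a
  macrocycle with no C–C candidate (e.g. an all-heteroatom ring) is left
  rigid with a warning; multi-fragment inputs are rejected at parse time.
* The equivalence filter interprets "neighbour ring" as any other kept ring
  sharing at least one bond with both candidates — the narrowest reading
  that resolves the mirror-arc case the filter exists for.
* Per-break-set re-rooting of the torsion tree is used when comparing break
  sets (a single global root could only give equal or deeper trees).

## Known limitations

* PDBQT charges default to zero; a Gasteiger hook exists at the model level
  but no charge model is applied during preparation.
* The rotatable-bond ruleset covers amides and simple conjugation; corner
  cases (thioamides, conjugated esters) follow the generic rules rather
  than bespoke patterns.
* The sampler's clash term is deliberately crude (no attractive dispersion,
  no electrostatics); it prevents collapse but does not rank conformers by
  physical energy.
* Equivalence filtering compares rings pairwise through one neighbour ring;
  exotic multi-ring redundancies beyond that pattern are not collapsed.
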