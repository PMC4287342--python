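# Methods

## The geometric model

An aromatic cage is modelled purely geometrically: a cluster of Phe/Tyr/Trp
side chains whose ring faces enclose a ligand moiety. The primitives are

- *MC*<sub>SC</sub> — the mass centre of one residue's side-chain heavy
  atoms (backbone N, CA, C, O, OXT excluded; hydrogens excluded
  everywhere). Mass weighting uses standard atomic masses; a
  `mass_weighted=False` switch selects the plain centroid, which differs
  negligibly for aromatic side chains but is provided because the original
  convention for the mass centre is not recoverable.
- *MC*<sub>ALL</sub> — the mass centre over the union of side-chain heavy
  atoms of the candidate residue set. Ligand atoms never contribute.
  Because each residue's *MC*<sub>SC</sub> is its own side-chain mass
  centre, *MC*<sub>ALL</sub> is exactly the mass-weighted mean of the
  per-residue *MC*<sub>SC</sub> values — the property the synthetic
  generator exploits to plant cages with closed-form geometry.
- the ring normal — the smallest-singular-direction of the centred
  ring-atom coordinates (a least-squares plane). Trp uses all nine indole
  atoms: for a planar indole the fitted normal is indistinguishable from
  either individual ring's, and the nine-atom fit is the natural reading of
  "the aromatic ring" for a fused system. Normals are axial (sign-free);
  the criterion angle is min(θ, 180° − θ), so every angle lies in [0°, 90°]
  and a sign flip of the normal cannot change any decision.

Detection thresholds (defaults; all configurable): aromatic residues with a
heavy atom < 6.0 Å from a ligand heavy atom are candidates; a same-chain
set of ≥ 3 candidates is accepted when all pairwise *MC*<sub>SC</sub>
distances are < 10.0 Å, at least three member angles are < 60°, and ≥ 2
ligand heavy atoms lie < 3.0 Å from *MC*<sub>ALL</sub>. The residue–ligand
distance is the minimum heavy-atom–heavy-atom distance — the permissive,
standard reading of a residue-to-ligand distance.

## Candidate-set semantics

The all-pairs condition makes candidate sets cliques of the
*MC*<sub>SC</sub>-distance graph (built per chain; cages never span
chains). Reporting every qualifying subset would duplicate each cage
combinatorially, so the detector reports **inclusion-maximal accepted
sets**: maximal cliques are evaluated first, and a clique that fails the
angle or contact criterion is descended into its sub-cliques until
acceptance. The descent matters because *MC*<sub>ALL</sub> moves with the
residue set — a large clique can fail criterion (b) or (c) while a subset
passes — and it guarantees the equivalence that the test suite checks
literally: every subset accepted by a brute-force enumeration of the
criteria is contained in some reported cage, and every reported cage passes
the criteria itself. The literal exponential enumeration remains available
(`mode="all-subsets"`, CLI `--sets all-subsets`) for oracle testing.
Accepted cages keep all their members, each annotated with its angle;
acceptance needs only three satisfying residues.

Deduplication treats two cages as identical when the sorted multiset of
(residue name, residue number) pairs matches and the ligand is the same
chemical component; the first occurrence wins, so the operation is
idempotent and acts within each ligand group.

## Strict thresholds and floating point

All comparisons implement strict "less than". Exact threshold equality is
not representable after general rigid motions in floating point, so a value
within a guard band of the cutoff (10⁻⁹ Å for distances, 10⁻⁵ degrees for
angles — orders of magnitude below the 10⁻³ Å precision of PDB coordinates)
counts as *at* the cutoff and is rejected. This makes the boundary fixtures
(a ring normal at exactly 60°, an *MC*<sub>SC</sub> pair at exactly 10.0 Å,
a nearest contact at exactly 6.0 Å) deterministic without affecting any
physically distinguishable configuration.

## Ligand chemistry

PDB HETATM groups carry neither connectivity nor formal charges. Bonds are
inferred from interatomic distances against single-bond covalent radii
(C 0.77, N 0.75, O 0.73, S 1.02 Å, …) plus a 0.45 Å tolerance — the
standard rule for PDB-derived small molecules. Rings are a minimum cycle
basis (smallest set of smallest rings) of the bond graph.

The classified object is the **moiety inside the cage**, not the whole
ligand: atoms within 4.0 Å of *MC*<sub>ALL</sub> (wider than the 3.0 Å
contact criterion, so the inserted group is captured whole), expanded to
complete rings plus their directly bonded substituents whenever a ring atom
is hit. Acyclic seeds are not expanded — a chain dangling into the cage is
classified by what actually inserts, which is why a free leucine bound
through its isobutyl tip is a hydrocarbon chain even though the zwitterionic
head carries N and O. The decision ladder gives cations precedence
(trimethyllysine is both an N-containing chain and a cation; it belongs
with the cations), then heterocycles, carbocycles, hetero-chains, plain
chains: cation detection is topological (N with ≥ 3 carbon neighbours, or a
guanidinium carbon bonded to three N), the only choice available without
formal charges.

## Superposition and internal symmetry

Rigid superposition is the closed-form least-squares (Kabsch) fit; the
implementation delegates the rotation to `scipy`'s `align_vectors` and
recomputes the residual from the transformed coordinates (the library's
reported residual loses precision near zero). Degenerate inputs — fewer
than three points, or collinear sets, detected by a singular-value ratio
below 10⁻⁸ — are errors.

Core superposition iterates {fit on the current pairs; drop pairs deviating
by more than 3.5 Å; re-fit} to a fixed point, starting from a seed pairing
supplied by the caller or derived from a global sequence alignment of the
Cα traces (BLOSUM62, affine gap penalties 11/1). Trimming only ever removes
pairs, so the core shrinks monotonically; fewer than 10 surviving pairs is
"no superimposable core". The 3.5 Å cutoff is a conventional choice for
discarding flexible loops while keeping genuinely equivalent positions;
published core RMSDs measured with unknown protocols are compared at
±0.2 Å in the spot-check tests for this reason.

Internal two-fold symmetry of a domain built from two sequence-consecutive
halves (for instance two four-stranded β-meanders) is measured by sliding
one half against the other over every sequence register with at least 15
overlapping residues, running the trimmed-core superposition at each
register, and keeping the register with the largest core (ties: lowest
RMSD). The split point is supplied by the caller; automatic sheet detection
is out of scope.

## The synthetic generator

Fixtures emulate the geometry the detector is designed for, with every
criterion controllable in closed form: residues are placed with their
*MC*<sub>SC</sub> evenly spaced on a circle of chosen radius (pairwise
distances are exact chords), ring normals make an exact chosen angle with
the vector to the closed-form *MC*<sub>ALL</sub>, and the ligand is placed
with a chosen number of atoms at the centre. The spin of each side chain
about its own ring normal changes no criterion and is searched
deterministically (30° steps) to avoid steric clashes; ligand orientation
is likewise searched with a seeded generator, so the same seed yields
byte-identical PDB output. Backbone atoms are stubs placed away from the
cage: they enter no mass centre and cannot perturb any criterion.

The validation sweep covers 3–5 residues × {0°, 30°, 59°} tilt ×
{4, 5, 6} Å radius. Chord arithmetic makes some of those 27 combinations
incapable of satisfying the pairwise criterion — three residues at radius
6 Å sit 10.39 Å apart, four at radius 5 Å have diagonals at exactly 10.0 Å
— so each spec computes its own expected detectability from the
construction values, and the tests demand exact recovery on the realisable
specs (15 of 27) and silence on the rest. This is a property of circle
geometry, not of the detector; fixtures are not moved to make tests pass.

What the generator does **not** emulate: real backbone conformations,
crystallographic disorder, solvent, multiple binding modes, and the
long-tailed variety of real ligand chemistry. Passing the synthetic suite
therefore demonstrates the correctness of the geometry and the decision
logic, not survey-level recall on the PDB; the spot checks on real entries
(see `tests/reference/`) cover the latter when coordinate files are
available.

Synthetic Cα traces serve the superposition tests the same way: a
two-meander domain whose halves are related by an exact rigid motion
(optionally with Gaussian noise on one half) for internal symmetry, and
helix-like traces related by a random rigid motion plus noise and displaced
loop residues for core trimming. Ground truth is known by construction in
both cases.

## Numerical and interface choices

- Alternate locations collapse to the highest-occupancy conformer per atom
  name (ties: first encountered). Multi-model files are analysed on model 1
  by default (CLI `--model`).
- Water (HOH, WAT, DOD) is never a ligand; every other HETATM residue
  group is, including modified residues inside polymer chains
  (methylated lysines are ligands of their reader domains).
- Het-group identity is the (component, chain, number, insertion code)
  tuple; multi-residue ligands are not merged by connectivity.
- Output ordering is deterministic everywhere: cages sort by (ligand,
  chain, residue numbers), report rows by their columns; report statistics
  are invariant to file processing order.
- The scan unit is one PDB file; batch behaviour (skip-and-warn on
  unreadable files, exit code 3 when files were skipped) is designed for
  large corpora. Tests and the acceptance script use small generated
  corpora and 50-structure randomised sweeps — sizes chosen to exercise
  every code path with exhaustible oracles (the brute-force subset
  enumeration is exponential and is kept to ≤ 12 aromatic residues per
  structure).
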