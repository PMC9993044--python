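# Methods

## Scope and model

`kinetomt` rebuilds, as a reusable and tested pipeline, the geometric
construction behind a composite structural model of the budding-yeast
kinetochore–microtubule interface: a 13-protofilament microtubule (MT) whose
plus end curls into "ram's horn" geometry, a single Ndc80 complex (Ndc80c)
attached end-on through its calponin-homology head domains, and a 17-member
DASH/Dam1c heterodecamer ring encircling the MT, positioned so that the
Spc19:Spc34 protrusion can reach the Ndc80:Nuf2 coiled-coil (the contact
usually labelled "interaction C").  The pipeline operates on coarse-grained
synthetic structures by default and on PDB/mmCIF inputs when provided; the
construction itself — lattice symmetry, pose transplantation, hinge setting,
ring expansion and constraint placement — is identical in either case.

## Conventions

* Tube axis = +z, plus end toward +z.  All angles are degrees at public
  interfaces, radians internally.
* Rotations follow the right-hand rule about the axis direction.  A negative
  inter-protofilament twist therefore winds clockwise when viewed from the
  plus end.  This fixes the sign of the −27.6° lattice parameter, which is
  meaningful only relative to a stated handedness convention.
* Residue numbering is 1-based; ranges are inclusive on both ends
  ("252–270" covers 19 residues).

## Helical lattice

A lattice site (p, d) — protofilament p, dimer d — receives the symmetry
operator: rotation about +z by `p·twist_pf + d·twist_dimer` and translation
along +z by `p·rise_pf + d·rise_dimer`.  Defaults are the yeast MT values:
rise 83.3 Å and twist 0.43° between consecutive dimers within a
protofilament; rise 9.65 Å and twist −27.6° between adjacent protofilaments;
13 protofilaments.  `closure_count` returns `round(360/|twist_pf|)`, the
protofilament number at which the accumulated inter-protofilament rotation
closes the tube (13 for 27.6°).

The tubulin dimer template must carry a *body frame* annotation (origin +
axes); the frame is mapped to (radius, 0, 0) with its z axis along the tube.
Deposited structures carry no canonical frame, so for real inputs this is a
one-time annotation step (the CLI defaults to centroid + lab axes).  The
frame radius default, 105 Å, is a modelling choice derived from canonical MT
wall geometry (≈250 Å outer diameter, ~50 Å lateral dimer spacing over 13
protofilaments); it scales the tube but cancels out of the four helical
parameters.

`estimate_lattice_params` inverts the construction independently: dimer
centroids are grouped by lattice site, and rises/twists are averaged over
all consecutive site pairs (axial offsets and azimuth increments about +z,
wrapped to (−180°, 180°]).  On noiseless generated lattices this reproduces
the generating values to ≈1e-6; with 0.1 Å coordinate jitter the estimates
stay within 0.5 %.

## Plus-end flaring

Kinetochore MT plus ends are modelled with a constant per-dimer outward bend:
dimers beyond `flare_start` rotate in their protofilament's radial–axial
plane about a hinge at the preceding dimer's distal end, so the k-th flared
dimer sits at `k·per_dimer_bend` to the tube axis.  Because every step is a
rigid rotation about the shared junction point, intra-dimer geometry is
exactly rigid and the curled path preserves junction continuity to <1e-6 Å.
The tomographic curvature underlying the published figure is not stated
numerically anywhere we could anchor to, and curved-protofilament crystal
structures span a range of per-dimer angles; the default of 22° over the
last two dimers is an explicit stand-in, configurable per run, and no test
or reported number depends on its particular value.

## Docking by pose transplantation

`transplant_pose` reproduces shared-template docking: superpose the
template's receptor part (tubulin of a head-bound reference complex) onto an
equivalent site of the target lattice (Kabsch/SVD with reflection
correction; CA atoms matched by chain + residue number), carry the
template's ligand pose along, then superpose the free ligand onto that
carried pose.  The operation is exactly equivariant: moving the target site
by a rigid motion moves the docked pose by the same motion.  Missing
receptor residues raise a match error listing the unmatched keys rather than
silently shrinking the fit.

`set_hinge` sets the rod's bend at the Ndc80-412/Nuf2-245 junction: the
distal segment rotates about the junction centroid, within the plane spanned
by its principal axis (SVD of centered coordinates, oriented away from the
hinge) and the reference axis, until the requested angle is met (tolerance
0.1°).  "Approximately parallel to the MT axis" is the 0° default.  The
junction gap is validated (≤2 Å) after placement; segment-internal
coordinates are never altered.  Loop rebuilding at the hinge is out of
scope — the junction is a geometric pivot, not a stereochemical model.

## Ring assembly and placement

`expand_ring` produces copy k by rotating the protomer `k·360/n` about the
axis (n = 17 by default) and applies a whole-ring (phi, z) motion.
`place_ring` finds (phi, z) minimizing a weighted squared deviation of
minimum inter-selection distances from their targets, over a deterministic
grid (0.5° × 0.5 Å, z ∈ [−60, 60] Å by default) with lexicographic
tie-breaking on (phi, z), followed by Nelder–Mead refinement that is only
accepted if it strictly improves the grid optimum.  Only the
constraint-bearing protomer copy is scored against the single docked Ndc80c,
matching the one-complex depiction of the published figure.

The "juxtaposed" Spc34-Thr199/Ndc80-583 proximity has no published distance;
the default constraint target is 10 Å between representative atoms (CA or
pseudo-atom) and is a documented modelling choice.  Note that one
min-distance constraint leaves a one-parameter family of exact solutions and
two constraints can still admit a second discrete solution; unique pose
recovery needs three well-separated anchors (the test suite plants poses
accordingly).

`detect_clashes` reports all inter-model atom pairs under a cutoff (default
2.4 Å, the conventional heavy-atom hard-sphere overlap) using a KD-tree;
results are identical to the exhaustive O(n²) comparison, which the tests
verify against an independent brute-force oracle.

## Interface analysis

Contacts are residue pairs whose minimum heavy-atom distance is within a
cutoff (default 4 Å).  Salt bridges pair basic (Arg CZ, Lys NZ, His NE2;
histidine included by default, configurable) with acidic charged-group
references (Asp/Glu carboxylate oxygen midpoints), within 4 Å; pseudo-atom
chains fall back to CA.  Phospho-site classification mirrors the interface's
regulatory logic: a Ser/Thr with an acidic charged group within 6 Å of its
hydroxyl is flagged *repulsive* (phosphorylation predicted to weaken the
contact, as for Dam1 Ser257 opposite Ndc80 Glu276); a site with no partner
atoms within 8 Å is *exposed* (sterically free, as for Ser292); anything
else is *buried*.  The 6 Å reach (phosphate extends beyond the hydroxyl) and
8 Å exposure radius are geometric heuristics, not energies; no electrostatic
scoring is attempted.

## Synthetic fixtures

The generators emit one CA-named pseudo-atom (element "X") per residue, with
yeast residue numbering at every landmark so selections read like the
biology.  Landmark positions are deterministic; only decorative cluster
beads receive seeded jitter, so calibrated distances hold for any seed
(default seed 20230308).

* *Pseudo-tubulin*: two 30-bead lobes (α/β chains), 80 Å along z, body frame
  at the centroid.
* *Ndc80c rod*: head tip at 0, hinge residues (Ndc80 412 / Nuf2 245) at
  160 Å, loop landmark (Ndc80 490) at 240 Å, far-end landmark (Spc24 213) at
  600 Å; Glu276/Asp295 pseudo-residues near the head base; the
  interaction-C landmark Ndc80 583 on the distal segment.
* *DASH/Dam1c protomer*: ten chains (Ask1, Dad1–4, Dam1, Duo1, Hsk3, Spc19,
  Spc34) spanning exactly 360/17° of azimuth at ring radius 160 Å (so 17
  copies close the ring), with the Spc34 protrusion carrying Thr199, Spc19
  residues 128–165 alongside it, and the Dam1 C-terminal arm as one bead per
  residue 252–305 (Ser257/265/292, Arg299 named).
* *Toy interface*: Ser257 4 Å from Glu276, Arg299 3 Å from Asp295, Ser292
  >8 Å from every partner atom — the published contact pattern by
  construction.

What the fixtures do *not* emulate: side-chain chemistry, sequence-accurate
chains beyond landmark residues, monomer-level (α/β) lateral lattice
contacts, the lattice seam's A/B distinction, nucleotide state, and any
energetics.  Tests passing on these fixtures demonstrate that the geometric
operations are correct and self-consistent, not that the composite model of
the real proteins is thermodynamically or evolutionarily right.

## Numerical choices and problem sizes

Superposition requires ≥3 non-collinear points (rank check at 1e-8 relative
tolerance); rotations are validated proper-orthogonal to 1e-6.  File round
trips are exact for mmCIF text fields and 0.001 Å for PDB coordinates; PDB
output relabels multi-character chain ids deterministically (A–Z, a–z, 0–9)
and splits >62-chain assemblies across MODEL records, returning the chain
map.  The default analysis sizes — 13 pf × 3 dimers (39 dimers, ~2 300
atoms), 17 × 128-atom ring protomers, 500-atom oracle clouds — were chosen
so every operation is exercised at full fidelity while the whole suite runs
in seconds on one CPU; all operations scale to full-atom inputs by the same
code paths.

## Known limitations

* The flare profile is a constant-curvature stand-in; fitting tomographic
  curvature is explicitly out of scope.
* Ring placement optimizes a rigid 2-DOF (phi, z) motion only; protomer
  internal flexibility and ring ellipticity are not modelled.
* Interface flags are geometric predictions; they say nothing about
  phosphorylation kinetics or cooperativity between sites beyond exposure.
* Insertion codes and alternate locations beyond the first are not
  supported in coordinate input.
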