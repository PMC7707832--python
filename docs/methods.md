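# Methods

This note documents the models, conventions and numerical choices behind
`igageom`, and what the synthetic-data tests do and do not demonstrate about
real coordinate models.

## Coordinate model and selections

Structures are ordered atom lists (chain, author residue number + insertion
code, residue name, atom name, element, Å coordinates, occupancy) read from
PDB or mmCIF via gemmi. Author numbering is used for all selections because
the measurements of interest are defined on author-numbered residues
(e.g. the Fc range 237–445, SC Cys470, heavy-chain Cys306); mmCIF
`label_seq` is ignored. Alternate locations are resolved to the
highest-occupancy conformer, ties broken by altloc identifier order. Waters
are excluded by default; hydrogens are kept but flagged, and all geometry
(axes, planes, contacts, clashes, SASA) operates on heavy atoms. Residue
ranges are inclusive on both ends.

The shipped domain map (`igageom/data/domains_siga.yaml`) encodes the
SIgA/dIgA nomenclature — heavy chains A–D, Fc_AB/Fc_CD with their C_H2/C_H3
halves, tailpieces, JC, SC D1–D5 — with chain IDs A–D/J/S and approximate
SC domain boundaries. The deposited files' chain naming cannot be assumed;
the config is a default to be verified against local copies and overridden
where needed.

## Bend and tilt

Each Fc selection (Cα of residues 237–445 on both heavy chains) is fitted
with:

* a **directed centroid axis**: centroid + first principal component of the
  centered Cα coordinates. The PCA line is sign-ambiguous, while the
  measured bends (97–98°) exceed 90°, so the sign is fixed by requiring a
  positive projection onto the C_H2-half → C_H3-half centroid vector. Fits
  are unweighted and Cα-only — the standard convention for domain axes; the
  ±3° tolerance used for deposit-based checks absorbs residual differences
  from other tools' fitting conventions.
* a **least-squares plane**: centroid + smallest-variance principal
  component as normal.

Bend = arccos of the dot product of the two directed axes (0–180°, not
folded); tilt = arccos of |normal·normal| (acute dihedral, 0–90°). Both are
invariant under common rigid motions by construction (verified by property
tests to 1e-6°). Degenerate selections (coincident atoms for axes,
collinear clouds for planes, orienting vector perpendicular to the axis)
raise errors rather than returning arbitrary directions.

Superposition is the least-squares rigid fit (Kabsch, via scipy's
`align_vectors`; reflections never produced), paired strictly by atom order,
with a Cα-by-residue-number wrapper that drops unmatched residues
symmetrically and logs the count. An independent Horn-quaternion
implementation in the test suite agrees to 1e-8 Å.

## Fab conformational search

A Fab is reduced to the vector from its pivot atom — the backbone N of the
amino-terminal residue of C_H2, the point where the Fab arm joins the Fc —
to the centre of mass of its CDR atoms. Placements are pure rotations about
the fixed pivot (the sphere radius is implicitly the input Fab-vector
length; no translation is applied):

1. 1000 directions from a Fibonacci spherical lattice (golden-angle spiral:
   point i has z = 1 − (2i+1)/n, azimuth i·π(3−√5)); deterministic,
   quasi-uniform, minimum pairwise separation 5.6° at n = 1000.
2. For each direction d, the minimal rotation mapping the unit Fab vector
   onto d (axis = v₀×d, angle = arccos v₀·d; the antipodal case uses a
   deterministic perpendicular axis built from the least-aligned coordinate
   basis vector).
3. Eight axial spins about d in γ = 45° steps, giving 8000 placements.

**Clash rule.** A placement is rejected when at least 8 non-linker Fab atoms
have any environment atom (Fc, JC, SC) within 1.0 Å. The threshold is
*reject at count ≥ 8*: eight heavy atoms is about one amino acid, i.e. the
rule rejects a placement once roughly a residue's worth of atoms collides; a
strict-greater variant is available (`--clash-strict-gt`), as is a
residue-level alternative. The linker is excluded as flexible. Counting
uses a KD-tree but is contractually identical to the all-pairs search
(verified exactly on 200 random placements plus planted scenarios with
k ∈ {0,5,7,8,10}). Hydrogens are excluded; modelled carbohydrates are part
of the environment by default (`--no-glycans`-style exclusion is a config
choice via the domain map).

**φ statistic.** For accepted placements, φ is the angle between the placed
Fab vector and a reference axis parallel to the Fc_AB plane through the
Fc+JC centre of mass. The in-plane direction of that reference is not fully
determined by the verbal definition; we construct it as the Fc_AB centroid
axis projected onto the Fc_AB plane, and expose the axis as an explicit
input so any other in-plane convention can be substituted. Consequently
φ histograms are comparable only up to that convention; the robust,
convention-independent statement is the *dominance* of φ < 90° (placements
concentrating on the concave face), which is what the tests assert.
Histograms normalise the tallest bin to 1 by default (`density` mode
available) over fixed 10° bins spanning [0°, 180°].

## Interfaces and accessibility

* **Contacts**: residue pairs with any heavy-atom pair within 7 Å
  (KD-tree, identical to brute force), reporting the minimal atom pair.
* **Interaction typing** within a 4 Å shell, heavy-atom distance criteria
  only: disulfide Cys Sγ–Sγ ≤ 2.3 Å; salt bridge Lys NZ / Arg NH1,NH2,NE /
  His ND1,NE2 to Asp OD1,OD2 / Glu OE1,OE2 / OXT ≤ 4.0 Å; hydrogen bond
  N/O–N/O ≤ 3.5 Å with no angle term (deposited cryo-EM models carry no
  hydrogens, so angle-aware criteria would be model-dependent); otherwise
  nonspecific ≤ 4.0 Å. Reports label hydrogen bonds as distance-only.
* **SASA**: Shrake–Rupley with the same golden-spiral construction used for
  the lattice (960 points per atom by default; bit-deterministic), probe
  1.4 Å, Bondi (1964) van der Waals radii (set name recorded in results;
  unknown elements raise unless a fallback radius is given). Closed-form
  checks: a lone sphere is exact; two intersecting spheres match the
  analytic cap formula to <1% at 2000 points.
* **Interface area**: PISA convention on the isolated pair,
  ½(SASA(A)+SASA(B)−SASA(A∪B)), symmetric and clamped at ≥0. Published
  areas from PISA carry unknown parameterisation; comparisons use ±15%.
* **Occlusion fraction**: (SASA(core alone) − SASA(core with occluder)) /
  SASA(core alone). The published "~16% of the core occluded by SC" does
  not specify whether carbohydrates or Fab stubs counted as core, so this
  is treated as a soft check only.
* **Sequon scan**: N-X-S/T with X≠P, overlapping matches reported, as a
  deliberate approximation to neural-network glycosylation predictors —
  it finds *potential* sites only.

## Synthetic ground truth

`make_pseudo_domain` builds an elongated, transversely anisotropic Cα cloud
realigned to its own principal frame, so its empirical axis is exactly +z
and its plane normal exactly +x; residue numbering (237–445 by default)
increases along +z, making the directed-axis convention exercisable.
`make_bent_assembly` places a second copy under R = R_spin·R_bend, where
R_bend rotates about the shared normal by the requested bend (moving the
axis, not the normal) and R_spin rotates about the new axis by the
requested tilt (moving the normal, not the axis); the two angles are
therefore independent and exact by construction, with optional isotropic
coordinate noise (0.2 Å in the sweep tests) on top. `make_toy_fab` is a
helical rod (guaranteed ≥ ~1.5 Å atom separation) with pivot at the origin
and CDR centre of mass at exactly the arm length; `plant_clash` drops probe
atoms 0.45·cutoff from chosen Fab atoms and verifies the exact planted
count by an all-pairs search before returning. The hemisphere-wall
environment is a dense slab whose top sits 3 Å below the pivot; the
geometric prediction (accepted iff lattice direction z > −3/arm) agrees
with the filter on ≥95% of placements, the residual disagreement being the
thin boundary cone where the rod grazes the slab.

These clouds are geometric stand-ins, not proteins: they have no secondary
structure, stereochemistry, side chains or glycans. Passing the synthetic
tests demonstrates the correctness of the geometry — axis/plane fitting,
rotation composition, clash counting, area integration — not that the
shipped domain config matches any particular deposition, nor that
convention-dependent quantities (φ histograms, PISA-parameterised areas)
will agree with other software beyond the stated tolerances. Deposit-based
checks run only when the user provides local coordinate files.

## Problem sizes and defaults

The package defaults are the study conditions: lattice n = 1000, γ = 45°
(8000 conformers per Fab), clash cutoff 1.0 Å at 8 atoms, contact cutoff
7 Å, interaction shell 4 Å, probe 1.4 Å. Test assemblies use 209 residues
per pseudo-Fc (matching the 237–445 selection) and an 80-atom, 40 Å toy
Fab; the full 8000-conformer scan against the ~137k-atom wall runs in
seconds. All generators take explicit seeds; the analysis pipeline itself
has no randomness.
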