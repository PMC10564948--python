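# Methods

## Data model and conventions

A particle pose is a centre (Å, right-handed, 0-based continuous
coordinates in the tomogram frame) and a proper rotation matrix mapping
the reference nucleosome frame into the tomogram frame.  The reference
frame places the disc in the x–y plane: ẑ is the superhelical
(disc-normal) axis, x̂ the dyad direction, and the H1 / linker entry–exit
side points along −x̂ (H1 binds at the dyad on the linker side).  The H1
reference direction is configurable because it is defined only
pictorially by map-back renderings of the averaged density.

Tables are read and written in two dialects: a single-block STAR loop
(RELION-style column names) and CSV with a header line.  Euler angles are
intrinsic, in degrees, ZYZ by default with ZXZ as an option; refinement
packages differ in convention, and the convention used for any given
table is generally not recoverable from the file itself, so it is an
explicit I/O parameter.  Conversion happens only at the boundary — all
internal code uses rotation matrices (scipy `Rotation`).  Coordinates
stored in pixels are converted as `(coordinate − origin offset) × pixel
size`.  Tomogram volumes come from MRC2014 headers (parsed directly,
little-endian, with the MAP magic checked) or JSON/YAML sidecars; a
sidecar or explicit value overrides the header.

## Neighbour census

Pair statistics never cross tomogram boundaries.

**Duplicate removal.** Within a tomogram, picks closer than the threshold
(default 60 Å, strict inequality: a pair at exactly 60 Å survives) are
conflicts.  Removal is greedy in ascending particle id: a particle is
dropped iff it conflicts with an already-retained particle.  In typical
refinement tables rows are ordered by template-matching score, so the
later (lower-scoring) pick of a duplicate pair is the one removed.  The
operation is idempotent and order-stable.

**Nearest neighbours.** Directed: each particle reports its single
nearest other particle in the same tomogram (k-d tree, verified against
an O(n²) scan in the tests).  A `mutual` option restricts to mutual
pairs.  The pair angle is the acute angle between disc axes,
arccos(|a·b|), folded to [0°, 90°] because the disc has a near-two-fold
ambiguity at intermediate resolution; an unfolded [0°, 180°] option
exists for sensitivity analysis.  Whether published neighbour angles were
computed between disc normals, dyad axes, or as full rotation angles is
generally underdetermined — the folded disc-axis angle is this package's
definition, not a claim about anyone else's script.

**Summary.** Pooled median distance and angle, fixed-width histograms
from 0 (defaults 10 Å and 5°, matching the granularity of published
distributions; both configurable), per-tomogram medians alongside the
pooled value, and the count bookkeeping n_input = n_removed + n_retained.

**Subpopulations.** Half-open bins [lo, hi).  Published bin labels
(60–80, 80–100 Å …) overlap at their endpoints, which forces a
convention; half-open intervals make the presets tile [60, 120) and
[0°, 60°) exactly.

**Stacking motifs.** A gated pair (defaults 55 ≤ d < 100 Å, disc-axis
angle < 25°) is type I when the centre offset is mostly along the mean
disc axis (face-to-face) and type II when mostly in-plane (lateral).
Gates were calibrated on constructed ideal stacks and are configuration,
not measured values.  With extension enabled, connected chains of gated
links with ≥ 3 members merge into one call: `tetra` for exactly four
members, `poly` otherwise (a three-member chain is reported as `poly`,
the catch-all for merged chains that are not tetranucleosomes).

## Compact fibre models

Three deterministic builders emit particle sets through the same table
formats as everything else, so the census code path is identical.

- *One-start solenoid*: consecutive nucleosomes on a single helix,
  defaults 8 per turn, centre radius 110 Å, pitch 110 Å; disc axes
  tangential to the helical path (face-to-face along the gyre), with a
  radial-axis option.  Consecutive-centre distance is the closed-form
  chord √((2r sin(π/8))² + (pitch/8)²) ≈ 85.3 Å.
- *Two-start crossed-linker zigzag*: two face-to-face stacks 190 Å
  apart, stacking rise 60 Å, sequence neighbours alternating stacks at
  half-rise offset; the nearest neighbour of any interior nucleosome is
  its same-stack partner at exactly the rise.
- *EM-based compact two-start zigzag*: the same arrangement with a global
  left-handed twist (default −15° per stack step), giving a same-stack
  chord of ≈ 64.9 Å.

Defaults are engineering choices guided by the fibre-model literature;
the load-bearing property, pinned by tests, is that all three defaults
place their median neighbour distance inside the 60–90 Å band expected of
compact fibres.  Parameter sets that bring any two centres below 55 Å
(disc clash) are rejected.  Models are built exactly; their interior
neighbour distances have zero variance, and the census runs without the
duplicate-removal stage (they are constructions, not noisy picks).

## Synthetic scenes

The generator emulates the statistical structure the analysis assumes:
chains of nucleosomes connected by straight linkers in a relaxed,
variable zigzag, confined to a thin slab.

Each fibre is a 3D walk.  Step lengths are log-normal (gamma optional),
parameterised by the median; successive step directions alternate by
±(zigzag/2 + jitter) about a fibre axis that meanders by a small random
rotation per step (defaults: zigzag 90°, jitter 15°, meander 5°).  Disc
axes are set perpendicular to the local pair of linker directions (the
zigzag plane normal), the H1 side faces the bisector of the two linkers,
and an isotropic orientation noise (default 15°) is composed on top.
Chains reflect at the slab and field boundaries; reflection is applied to
the step *direction* before the step is taken, so step lengths — the
quantity the census estimates — are never shortened by the wall.

**Spacing variance split.** The in-fibre spacing sd (default 10 Å at a
120 Å median) is split so 95% of the log-variance lives at the fibre
level (`fiber_level_fraction`): repeat length varies more between fibres
than between adjacent linkers.  This matters because the census assigns
each particle the *shorter* of its two flanking steps; with i.i.d.
per-step lengths of spread σ the recovered median is biased low by a
factor exp(−0.545 σ).  Putting the variance at the fibre level keeps the
census median an essentially unbiased estimate of the spacing parameter
(recovered 116.7–118.6 Å across seeds at n ≈ 6000), which is the
generator's stated parameter-recovery property.

**Excluded volume.** Nucleosome discs cannot interpenetrate.  Any two
particles that are not chain-adjacent must be at least `exclusion_A`
apart (default 110 Å, one disc diameter).  Steps violating this are
redrawn: first within the zigzag cone, then — because with zero jitter
the redraw would be deterministic — with the zigzag plane twisted about
the fibre axis, and as a last resort at walls and corners with a fully
random direction (a chain defect that preserves step length).  Without
excluded volume, fibres pass freely through one another and produce
sub-spacing cross-fibre neighbour pairs that no real specimen could
contain, corrupting the census.  In the noise-free limit the invariant
"every chain neighbour is the nearest neighbour" additionally requires
the self-avoidance distance to exceed the spacing itself (tests use
130 Å > 120 Å); at the default 110 Å, rare non-adjacent approaches in the
110–120 Å band are legitimate geometry.

**Field and density.** Defaults put ~1400 real nucleosomes in a
12000 Å × 12000 Å × 850 Å slab — the particle count per tomogram and the
field of a K3-class detector at ~2.2 Å/px, i.e. the per-volume particle
density of a thin-lamella acquisition.  Density is the physical
condition: scenes of other sizes should scale the field with √n.  At
several times this density an excluded-volume fibre gas jams and the
census degrades; that is a property of the specimen model, not of the
analysis.

**Artefact model.** Duplicates are copies of randomly chosen particles
displaced by exactly `duplicate_offset_A` (default 30 Å; the direction is
redrawn near walls so the displacement is never shortened) with ~5° of
rotation noise, appended after all real particles so ascending-id greedy
removal preferentially drops them.  Decoys are uniform random poses.
Ground truth records fibre membership, chain order, true step lengths and
the duplicate/decoy flags, and the evaluation op reports duplicate-removal
sensitivity/specificity, spacing-recovery bias and the fraction of
neighbour pairs joining chain-adjacent particles.

**What the generator does not model.** Missing-wedge anisotropy, CTF
effects, per-particle alignment error beyond isotropic orientation noise,
heterochromatin clustering (fibre starts are uniform), nucleosome-free
DNA, and inter-fibre contacts closer than the exclusion distance.
Passing tests demonstrate that the pipeline recovers the statistics of
this model faithfully; they do not show that real chromatin satisfies the
model.

## DNA paths and concentration

Each pose defines two anchor points at the DNA-gyre radius (default
55 Å) on its H1 side, split by ±25° about the disc axis — the gyre
opening at the dyad, a pictorially-derived default.  Candidate links
between particles score by the anchor-to-anchor gap (shortest of the four
anchor pairings, must be < 250 Å); the bend at each junction — the angle
between the gap segment and that disc's plane, i.e. how steeply the
linker would pitch out of the plane its DNA wraps in — must stay below
`max_turn_deg` (default 90°, permissive; tighten to enforce coplanar
linkers).  Links are accepted greedily in ascending gap order; each
anchor serves at most one link, bounding in- and out-degree by one, and
union-find rejects cycles, so paths are vertex-disjoint chains by
construction.  On noise-free scenes the recovered chains reproduce the
ground-truth chain order with purity 1.0.  Path prediction is a
reproducible formalisation of what is otherwise done by eye on map-back
renderings; the greedy-with-gates rule is the design choice, and all
gates are exposed.

Concentration: c = n · bp · m / N_A / V, with n retained nucleosomes,
bp the nucleosome repeat length (default 200 = 147 bp core + nominal
linker), m the double-stranded DNA mass per base pair (default
650 g/mol), V the tomogram volume from its header, converted to mg/ml
(1 Å³ = 10⁻²⁴ ml).  The defaults are assumptions, reported alongside the
result in the audit record; hand-checked oracle: one 200-bp nucleosome in
10⁶ Å³ gives 215.9 mg/ml.

## Numerical choices and problem sizes

Rotations are validated orthonormal (det +1) to 1e-6 on construction;
table round-trips preserve centres to 1e-6 Å and matrices to 1e-9 (8 and
10 decimal digits written, respectively).  Euler decompositions at gimbal
lock are non-unique but round-trip exactly as matrices.  Greedy
tie-breaks (duplicate removal by ascending id, path links by (gap,
id-pair)) make every pipeline stage deterministic under a fixed seed and
invariant to input row order.  Tests and the acceptance script use scenes
of ~1500–6000 particles (112 fibres × 50 nucleosomes at matched density
for the ≥5000-particle recovery check) and fibre models of 24–48
nucleosomes; these sizes give sub-Ångström stochastic scatter on the
recovered medians.

## Known limitations

Class labels are carried through but never interpreted; no spatial-
randomness statistic for label placement is included.  Paths never link
across tomogram boundaries.  The concentration estimate counts DNA mass
only, not protein.  The census treats all retained picks equally — there
is no weighting by alignment confidence.  Boundary-truncation bias in the
distance census (particles near the field edge missing their true
neighbour) is not corrected; at the default scene scale its effect on the
median is below the stochastic scatter.
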