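# Methods

## The ligand-local frame and its sign conventions

The orientation of a bound nitrite ion is measured in a frame anchored on
the ligand: origin at the mass-weighted centre of mass (COM) of the three
nitrite atoms, X axis toward the nitrogen, Z axis along the normal of the
nitrite plane, Y completing a right-handed set. Because the two oxygens of
nitrite are chemically equivalent, the sign of the plane normal carries no
physics; Z is therefore chosen so that the copper ion has a non-negative Z
component, and when the copper lies exactly in the nitrite plane the sign
is fixed instead by requiring a non-negative Y component. The altitudinal
angle is θ = atan2(|z|, x) and the azimuthal angle ψ = atan2(|y|, x) of the
copper in this frame, both mapped to [0°, 180°]. Using |y| (rather than
signed y) makes ψ invariant under relabelling O1 ↔ O2, and using signed x
gives the monotone progression N-bound (0°) → side-on (90°) → top-hat
(180°) for θ. Both angles are undefined when the relevant projection of
the copper vanishes (copper on the Y axis for θ, on the Z axis for ψ);
these degenerate poles raise errors rather than returning arbitrary
values.

## Orientation classification

Class windows (degrees, inclusive unless noted):

| altitudinal | θ | azimuthal | ψ |
|---|---|---|---|
| N-bound | 0–20 | symmetrical | 0–10 |
| | | l-shaped | (10)–30 |
| top-hat | 160–180 | bidentate | 170–180 |
| | | monodentate | 140–(170) |
| side-on | 70–110 | n/a | |

θ outside every window is reported as `borderline` and ψ outside the
windows of its altitudinal class as `unclassified`; nothing is ever
force-assigned, because structures genuinely do fall between top-hat and
side-on (θ ≈ 145–155°) or at unusual azimuths (the nitrite-bound D97N
crystal structure has ψ ≈ 45°, outside every azimuthal window). The shared
boundaries ψ = 10° and ψ = 170° belong to the symmetrical and bidentate
classes respectively (closed upper bound of the first-listed range). All
windows are a dataclass (`ClassificationThresholds`) and can be overridden,
including from the CLI.

A separate asymmetry descriptor marks the two Cu–O distances as
inequivalent when they differ by more than 0.3 Å, the conventional
separation between bidentate-like and monodentate-like top-hat contacts.

## Coordination twist φ

φ is the angle between the normal of the plane through N(NO₂⁻), Cu and the
axial His nitrogen and the normal of the plane through the two equatorial
His nitrogens. The axial His is the one subtending the largest
N(NO₂⁻)–Cu–N(His) angle; a tie within 1e-6° is resolved toward the lower
residue number with a warning. The equatorial pair is ordered by residue
number, which fixes the normal orientation and hence the fold of φ within
[0°, 180°]; the tetragonal/trigonal windows are symmetric under
φ → 180° − φ, so the labels do not depend on that ordering. Shape windows:
tetragonal for φ ≤ 30° or φ ≥ 150°, trigonal for 60° ≤ φ ≤ 120°,
intermediate otherwise — symmetric brackets around the ideal anchors
(0°/180° tetragonal, 90° trigonal), configurable like the classification
windows. φ is defined only for the 3-His + nitrite core; additional
ligands such as a coordinated water in penta-coordinate sites are outside
its construction.

## Structure input

PDB parsing is delegated to gemmi; single- and multi-model (trajectory)
files are supported. Alternate locations are resolved by keeping, per
(model, chain, residue, atom name), the copy with the highest occupancy,
ties broken by lowest B-factor, then altloc character; removal of
partial-occupancy waters is an explicit flag, waters are otherwise kept.
The coordinating nitrogen of each histidine is whichever of ND1/NE2 is
closer to the copper, which is robust to tautomer naming. Nitrite atoms
are mapped by element (exactly one N, two O required). Sidechain centres
of mass are mass-weighted over heavy atoms from Cβ onward (backbone N, CA,
C, O and hydrogens excluded) so that crystal structures without hydrogens
and MD snapshots give comparable values; an `include_hydrogens` option
exists for H-containing models. The package consumes an already-assembled
biological unit; symmetry expansion and hydrogen placement are upstream
preprocessing, and mmCIF is not parsed.

## Synthetic-site construction

`make_site` is the deterministic inverse of the analysis. The nitrite is
built in the canonical frame (ideal free-ion geometry by default: N–O
1.25 Å, O–N–O 115°; both configurable — no reported quantity depends on
them). The copper direction is solved from (θ, ψ): with the frame
conventions the copper must have non-negative y and z components, so a
direction exists only when cos θ and cos ψ agree in sign; infeasible pairs
(for example θ = 5°, ψ = 120°) are rejected with an error. The histidine
shell is solved in closed form in the copper-centred basis whose first
axis e₁ points at the nitrite nitrogen: the axial His sits at polar angle
160°, and the equatorial pair at polar angle ω with azimuths μ ± λ obeys

    cos φ = −cos ω · sin μ / sqrt(sin²ω cos²λ + cos²ω).

Near-trigonal targets fix λ = 60° and solve for μ; strongly twisted
(near-tetragonal) targets fix μ = 90° and solve for λ, which drives the
equatorial pair toward the mutually-trans arrangement that tetragonal
geometry actually requires. ω is 80° for φ > 90° and 100° otherwise, which
keeps the axial assignment unambiguous (160° > ω always). With zero noise
the full analysis recovers the targets to ~1e-12°; Gaussian coordinate
noise of configurable σ is added after the exact construction, and a
seeded random rigid motion is applied by default so nothing is tested in a
privileged pose.

## Synthetic trajectories and energy tables

The trajectory generator emulates the statistical structure of
resting-state active-site dynamics, not the physics: per frame, each metric
is drawn i.i.d. from a Gaussian regime and the frame's coordinates are then
constructed to realise the drawn value exactly (sidechain templates
translated so their heavy-atom COM sits at the drawn distance from Cu; the
phenolic H placed at the drawn distance from the nearer carboxylate
oxygen). Defaults are the conditions of the deprotonated-Asp97 system,
chain A: Tyr323–Cu 7.37 ± 0.19 Å switching to 9.83 ± 0.49 Å at the 69 ns
displacement event, Asp97–Cu 4.45 ± 0.18 Å, and a hydrogen bond of
1.8 ± 0.15 Å with transient breaks (probability 0.2 per pre-break frame,
break regime 4.5 ± 0.4 Å — chosen as a realistic rupture distance and
frequency for a frequently-disrupted interaction; the occupancy statistics
only require that break values clear the 2.5 Å cutoff). Values are floored
at 0.1 Å to keep distances physical; with the default parameters the floor
is never reached in practice. What the generator deliberately lacks:
temporal autocorrelation, covalent consistency of the placed hydrogen with
the Tyr geometry, rotameric realism, and any force-field energetics — so
passing tests demonstrate correct measurement and bookkeeping on data with
the right first- and second-order statistics, not fidelity to real MD.

The energy-table generator draws ΔE per conformer pair from configured
Normal distributions — defaults are the study conditions per system and
oxidation state: D97 (−0.27 ± 2.96, 8.66 ± 6.39), D97p (0.24 ± 2.73,
4.64 ± 7.66), D97N (−1.22 ± 4.29, 5.17 ± 4.87) kcal/mol for Cu(II)/Cu(I)
with 6/7/9 pairs respectively — and adds a large arbitrary offset
(σ = 10⁴ kcal/mol by default) to both members of each pair, mimicking
QM/MM total energies whose absolute values are not comparable across
snapshots. The analysis only ever differences within a pair key, which the
gauge-invariance tests verify.

## Statistical conventions

Trajectory summaries use the population standard deviation (frames are a
dense sample of one trajectory); ΔE summaries use the sample (n−1)
standard deviation (a handful of independent conformer pairs). Both have
flags to switch. Uncertainties on trajectory means are treated as the std
of frames, not block-averaged errors. Splitting a series at an event time
assigns t < t_split to the "before" segment and t ≥ t_split to "after".

## Problem sizes and tolerances

The test suite and acceptance script use 500 sites for round-trip checks
(tolerances 1e-6° for θ/ψ, 1e-3° for φ), 1000 sites against the
brute-force oracles (1e-6 agreement), 100 rigid motions plus oxygen
relabellings (1e-6°), and 20 seeded replicates of 400-frame trajectories
and full energy tables for statistical recovery, judged at three pooled
standard errors. Internal degeneracy tolerances are 1e-9 (zero-length
vectors, in-plane copper, undefined projections). Sizes were chosen so the
whole pipeline, including statistics, runs in seconds while leaving the
statistical checks comfortably powered.

## Known limitations

* The twist-angle construction assumes exactly three His ligands plus
  nitrite; other coordination motifs need their own plane definitions.
* Binding-mode classes are windows on (θ, ψ) only; electronic structure
  (copper oxidation state) is user metadata and never inferred.
* The classifier is specific to bent triatomic ligands; nothing
  generalises automatically to other anions.
* Crystal-structure checks against deposited entries require the user to
  supply the PDB files (and the assembled biological unit where relevant);
  the package does not download or symmetry-expand structures.
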