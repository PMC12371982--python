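# Methods

`knobdyn` quantifies the motion of a distal, quasi-rigid protein domain (a
"knob") relative to a stable core to which it is tethered by a flexible
two-stranded linker (a "stalk"). The geometry is that of bovine antibodies
with ultralong CDRH3 loops, where a disulfide-stabilized knob minidomain
sits at the end of a β-ribbon stalk protruding from the Fv core, but the
machinery applies to any hinged two-domain architecture. Inputs are a
reference structure, one or more trajectories (multi-model PDB), and an
explicit domain partition; outputs are per-frame series and run-averaged
summaries.

## Domain partition

Four disjoint residue sets are declared in a YAML document: `core_heavy`
and `core_light` (together the rigid *core*), and the heavy-chain segments
`stalk_n`, `knob`, `stalk_c`, which must be consecutive in chain order
(the knob lies between the two stalk strands). Residue identifiers are
opaque strings ordered by file appearance — antibody structures use Kabat
numbering with insertion codes such as `100F`, so identifiers are never
parsed numerically. Boundaries are taken from configuration, not detected:
in practice they come from a curated structure-based alignment.

Atom subsets: `backbone` is {N, CA, C} (O excluded — the minimal set that
fixes a rigid frame per residue), `heavy` excludes hydrogens, `all` is
everything. Fits and RMSDs use the backbone subset by default; energies
and contacts use heavy atoms.

## Superposition and the two-step knob fit

Rigid-body fits use the SVD form of the Kabsch algorithm, unweighted, with
the usual sign correction on the smallest singular value so that a proper
rotation (det +1) is always returned; near-collinear point sets are
rejected as degenerate. The rotation magnitude of a transform satisfies
cos θ = (tr R − 1)/2; it is evaluated as atan2 of the norm of the
antisymmetric part against the trace form rather than by a bare arccos,
because arccos amplifies matrix round-off by a square root near 0° and
180° (≈3·10⁻⁶ deg error at 180°) while the atan2 form is accurate at both
endpoints (≤10⁻⁹ deg, verified against constructed axis–angle rotations).

Per frame, three readouts are computed against the reference structure
(the simulation starting structure — by default the crystal/model
coordinates, configurable):

* **core RMSD** — fit on the core backbone, RMSD over the same selection;
* **entire RMSD** — fit on the core backbone, RMSD over the entire
  declared backbone, so knob excursions register instead of being
  averaged away by the fit;
* **knob offsets** (two-step fit) — (1) superpose the frame onto the
  reference on the core backbone and apply the transform to the whole
  frame; (2) superpose the core-aligned knob onto the reference knob. The
  *translational offset* is the knob-centroid displacement (Å) after step
  1; the *rotational offset* is the rotation magnitude (deg, [0, 180]) of
  the step-2 fit. For a rigid body the fitted translation equals the
  centroid shift, so the centroid convention is adopted; note that the
  "translation component" of a rigid transform is origin-dependent, so
  any comparison with other implementations must match conventions.

Summaries are time means over *all* frames (no equilibration discard),
then unweighted means across replicate runs. Full-precision per-frame CSVs
are retained; summary tables are formatted to two decimals at write time
only, so every summary number is exactly recomputable from the retained
series (the test suite audits this).

## Torsion-angle fluctuations and hinge mapping

Backbone dihedrals follow the IUPAC convention (cis = 0°, trans = 180°,
range (−180°, 180°]), with φᵢ = C(i−1)–N(i)–CA(i)–C(i) and
ψᵢ = N(i)–CA(i)–C(i)–N(i+1); chain-terminal angles are undefined and
carried as such rather than failing.

The torsion-angle fluctuation (TAF) of an angle over a trajectory is the
circular variance

TAF = 1 − R, R = |(mean cos θ, mean sin θ)|,

a dimensionless dispersion in [0, 1]: 0 for a rigid angle, 1 for two
equally populated values 180° apart. For von Mises-distributed angles with
concentration κ the population value is 1 − I₁(κ)/I₀(κ), which the
implementation reproduces within sampling error (tested at
κ ∈ {8, 4, 2, 1}, n = 10⁴). Angles are centered on the first sample before
summation — the statistic is rotation-invariant, and this keeps a constant
series at exactly zero. The formula lives behind a single function so an
alternative dispersion statistic (e.g., rescaled circular standard
deviation) could be swapped; thresholds would then need recalibration.

A residue is flagged as a **hinge** if its φ- or ψ-TAF strictly exceeds a
threshold, default 0.6. The default analysis scope is the stalk plus the
single knob residue adjacent to each stalk strand (configurable via
`knob_flank`). Ramachandran evolution output is the raw per-frame
(time, φ, ψ) triples with no binning, for time-colored scatter plots.
Note that biologically relevant bending can also arise from coordinated
sub-threshold φ/ψ shifts; no quantitative sub-threshold criterion is
implemented.

## Interaction energy and contacts

The energetic readout between two atom groups (knob vs. light chain, knob
vs. heavy-chain core) is the 12-6 Lennard-Jones sum over in-cutoff pairs,

E = Σ ε_ij [(r_min,ij/r_ij)¹² − 2 (r_min,ij/r_ij)⁶],

with AMBER-convention parameters (r_min/2, ε) combined by
r_min,ij = r_min/2,i + r_min/2,j and ε_ij = √(ε_i ε_j). Being
short-ranged, favorable values indicate direct contact, which is why the
vdW term alone is the headline readout; electrostatics is deliberately
omitted. Defaults: 12 Å cutoff, no long-range correction (this is an
interaction energy, not a total energy). When both groups share a chain,
pairs within three bonds are excluded using a bond graph inferred from
heavy-atom distances (< 1.9 Å); cross-chain pairs need no exclusions. The
two groups are ordered canonically before summation so E(A,B) = E(B,A)
holds bit-exactly.

Parameters ship as an editable table
(`residue_name  atom_name  type  r_min_half_A  epsilon_kcal`). The bundled
`ff14sb_lj` table maps the heavy atoms of the 20 standard residues to
standard AMBER-convention type constants exactly; hydrogens are covered by
name-pattern fallback rules whose types are approximate (hydrogen well
depths are ≤0.016 kcal/mol and contribute little to a heavy-atom-dominated
vdW readout). `toy_lj` is a one-row united-atom table for tests. Exact
(residue, atom) rows take precedence over wildcard rows, which apply in
file order; unmapped atoms are a hard error listing the offenders.

**Local minima** of an energy time course are found on a centered
running-mean smooth (default 11 frames): a frame qualifies if it is
strictly lower than every frame within ±`min_separation` and the full
window lies inside the series (so a monotone series has no minima);
results are ordered most-favorable first. `min_separation` should exceed
the expected dwell time of a contact episode if one representative frame
per episode is wanted.

**Contacts**: a knob/partner residue pair is reported if any heavy-atom
pair is within 4.5 Å; it is *polar* if additionally some N/O–N/O pair is
within 3.5 Å (a canonical hydrogen-bond heavy-atom distance), else
*nonpolar*. These are conventional cutoffs; no angular hydrogen-bond
criterion is applied.

## Synthetic benchmark systems

Because microsecond explicit-solvent trajectories cannot be regenerated at
desk scale, correctness is established on synthetic systems with exact
ground truth (`knobdyn.synthetic_data`):

* A poly-alanine-like backbone (N, CA, C, O; idealized bond lengths and
  angles, built by natural-extension-reference-frame construction) with
  the four domains. Core pieces and the light chain are compact bundles of
  parallel 10-residue helical rods — a single long helix is a 60 Å rod,
  not a globular domain. The chain breaks between bundle segments are
  nonphysical, but the segments move rigidly and their internal torsions
  are never analyzed.
* Default sizes: 40 + 40 core residues, 6 + 6 stalk, 20 knob
  (448 atoms) — the residue-count scale of an antibody Fv with an
  ultralong CDRH3. Default frame spacing 1 ns.
* The hinge is a rotation of everything C-terminal of a designated stalk
  residue's CA about that residue's CA→C bond. Two exact consequences
  make ground truth trivial: the hinge residue's ψ changes by exactly the
  applied angle and no other backbone torsion changes (a single known
  hinge positive), and the knob moves rigidly, so the applied angle and
  the noiseless backbone-centroid displacement are exact targets for the
  offset analysis.
* Motion schedules: rigid, sinusoidal (default amplitude 40°, 3 periods),
  or two-state basin flipping (default 0°/150° in 25-frame blocks; the
  150° separation puts the hinge ψ-TAF at 1 − cos 75° ≈ 0.74, safely
  above the 0.6 flag threshold, while all rigid residues stay near 0).
* Contact episodes override the schedule with a fixed bent angle (150°)
  during chosen frame intervals. The light chain is placed once,
  deterministically, at a minimum heavy-atom distance of 3.5 Å from the
  bent knob — just inside the C–C LJ minimum, still attractive — and
  backed off from everything else to ≥ 2.8 Å. Ground-truth contact pairs
  are recorded at ≤ 3.9 Å so that coordinate noise cannot push a planted
  pair beyond the 4.5 Å detection cutoff. In the extended pose the knob
  sits beyond the 12 Å cutoff from the light chain, so the energy is
  exactly zero outside episodes.
* Isotropic Gaussian coordinate noise (per atom, per frame, per axis) is
  added after the rigid motion from a single `numpy.random.default_rng`
  stream; a fixed seed gives bit-identical trajectories.

What the generator does *not* emulate: solvent and friction, correlated
thermal motion, side chains, internal knob/core flexibility, force-field
dynamics of any kind, or the gradual conformational drift of real
proteins. Passing the synthetic benchmarks therefore demonstrates that the
*measurement pipeline* is correct and well-calibrated at realistic noise
amplitudes — not that any particular biological system behaves this way.

Under the benchmark conditions (fixed in the test suite): a 1000-frame
sinusoidal schedule of amplitude 40° with σ = 0.3 Å noise is recovered
with rotational RMSE < 2° and translational RMSE < 0.5 Å; a fully rigid
system with σ = 0.1 Å shows mean offsets below 0.5 Å / 2° and mean core
RMSD below 0.3 Å with zero hinge flags; planted contact episodes are
recovered as one energy minimum each, with their contact pairs, and
bottom-decile energies coincide with significantly larger translational
offsets (one-sided Mann–Whitney).

## Numerical choices and degenerate inputs

* Kabsch fits require ≥ 3 non-collinear points; collinearity is detected
  via the second singular value of the centered coordinates (≤ 10⁻⁸
  relative).
* Rotation matrices are validated to orthonormality and det +1 within
  10⁻⁹; the fit re-orthonormalizes its product against round-off.
* Dihedrals are undefined (error) when three consecutive points are
  collinear within 10⁻⁹ of the bond scale; chain-boundary φ/ψ are carried
  as undefined values, contributing only defined frames to TAF.
* Atom pairs closer than 0.1 Å trigger a near-singularity warning naming
  the pair (the r⁻¹² term makes such energies meaningless).
* Multi-model files must have identical atom lists across models; frame
  times must be strictly increasing.
* Summary rounding is presentation-only (two decimals, matching the
  precision conventional for Å/deg/kcal·mol⁻¹ tables); all statistics are
  computed at full precision.

## Limitations

* The translational offset is centroid-based; tools that report the raw
  translation vector of the second fit in a different origin convention
  will disagree by construction.
* The TAF normalization is one of several circular-dispersion statistics
  in use; the 0.6 hinge threshold is tied to this normalization.
* The LJ hydrogen-type assignment is pattern-based and approximate; for
  hydrogen-sensitive energetics supply an explicit table.
* No solvation, electrostatics, or free-energy estimates: the energy
  readout ranks direct-contact propensity, nothing more.
* Binary trajectory formats are out of scope; convert to multi-model PDB
  (a plugin seam exists in `structure_io` for adding readers).
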