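# Methods

`bundlecv` measures and drives the collective rigid-body motions of
four-helix bundles of the HAMP type — two monomers, each contributing an
N-terminal and a C-terminal helix, packed as a parallel bundle.  Signal
relay through such bundles has been rationalised by three competing motion
models: axial **piston** shifts of individual helices, concerted axial
**rotation** (the "gearbox" picture, a switch between complementary x-da
and canonical knobs-into-holes core packing), and changes of the
**tilt** between helices or monomers.  The package provides these three
motions as differentiable collective variables (CVs), trajectory-level
quality analyses, a piston-state classifier, and a well-tempered
metadynamics engine that can bias the CVs on toy systems and post-process
hill records.

## Collective variables

Each helix is reduced to a vector.  `H` and `T` are the unweighted centers
of mass of four consecutive C-alpha atoms at the helix head and tail (four
residues = one helical turn, so the group center sits near the axis), `V =
H − T`, and `M = (H + T)/2`.  "Head" is the C-terminal turn by convention;
the choice fixes all signs and is recorded in each result's metadata.

- **Piston** (Å): `Z = (M − M₀′) · V̂` — the midpoint displacement
  projected on the *current* helix axis, with `M₀′` the reference midpoint
  after the reference structure is rigid-body aligned onto the current
  frame (Kabsch, unweighted, over the helical C-alpha selection).
  Positive piston moves the helix toward its head.
- **Rotation** (deg): the rotational reference group `R` (C-alpha atoms
  spaced four residues apart, off the axis) defines an offset `r = R − M`.
  The angle between `r` and the aligned reference offset `r₀`, both
  projected onto the plane normal to `V`, measured by
  `atan2(V̂·(r₀⊥ × r⊥), r⊥·r₀⊥)` — signed by the right-hand rule about
  `V̂` and robust near ±180°.  By default `r₀ = R₀′ − M` uses the current
  midpoint; `R₀′ − M₀′` is available as an option.  The current-midpoint
  variant couples weakly to translations of the helix (its reference
  offset moves with `M`); only the reference-midpoint variant is exactly
  translation invariant, which is why the gradient-cancellation property
  test uses that variant.
- **Tilt** (deg): `arccos(V₁·V₂ / |V₁||V₂|)` between two helix vectors, or
  between monomer vectors built from the pooled head/tail atoms of both
  helices of each monomer.  No reference is involved, so tilt is invariant
  to global rigid motion by construction.

**Gradients.** All three CVs carry analytic gradients with respect to the
contributing atoms (chain rule through the group centers of mass; each
atom receives 1/n of its group's gradient).  The aligned reference pose is
treated as constant — the optimal rotation is not differentiated through
the Kabsch solution.  This is the approximation engines make when a
reference-based CV is biased, and it is enforced consistently: the
finite-difference validator (`numeric_gradient_check`, central differences
with steps of 1e-6–1e-3 Å) freezes the alignment during differencing.
On random perturbed bundles the discrepancy is below 1e-9 per Å for all
three CVs, against a tolerance of 1e-4.

The tilt gradient is undefined at exactly 0° or 180° (the value is fine);
the implementation returns zero gradients there rather than NaN.  The
rotation CV refuses configurations whose rotational reference projects
onto the axis.

## Bundle analyses

- **Helical RMSD**: C-alpha RMSD after superposition over the helical
  selection only (defaults 282–296 and 312–326 per chain — the residues
  with persistent helical structure; termini and the inter-helix connector
  are excluded so the number reflects helix geometry, not loop motion).
- **Helical hydrogen bonds**: a pair (i, i+4) counts when the O(i)–N(i+4)
  distance is < 3.5 Å and the acceptor–donor–hydrogen angle at the donor
  nitrogen is < 30° (the standard backbone criterion; the angle threshold
  is configurable).  When no amide hydrogen is present it is reconstructed
  on the bisector opposite the N–CA and N–C(i−1) bonds at 1.01 Å.  Missing
  backbone atoms skip the pair with a logged warning, never silently.
- **Crick angle**: per residue, the signed in-plane angle between the
  direction from the helix axis to the residue's C-alpha and the direction
  from the helix axis to the bundle axis.  The helix axis direction is
  estimated from cross products of consecutive second differences of the
  C-alpha trace — exact for a regular helix, where a plain principal
  component is biased by the correlation between azimuth and axial
  position — and the axis position from a least-squares circle fit in the
  normal plane.  The bundle axis is the mean of the four helix axes.  The
  deviation subtracts an ideal knobs-into-holes ladder (position `a` at
  +19.5°, advancing 720/7° per residue); the ladder and the heptad
  register are configuration, not hard-coded, since ideal values depend on
  the packing convention adopted.
- **Piston states**: the diagonal pairs (N1, C2) and (N2, C1) move
  together.  With threshold `t = 0.5 Å` (midway between the observed P00
  fluctuation scale of ~0.16 Å and the 1–1.5 Å shifts of the piston
  states): P00 if all four |z| < t; P10 if N1 > +t, C2 < −t and the other
  pair stays within t; P01 mirrored; P11 if both pairs shifted; otherwise
  OTHER.  Any |z| ≥ 3 Å additionally sets an out-of-register flag — a
  register slip of the hydrophobic layers (≈ 4–5 Å shift) is treated as
  misfolding, not as a functional state.
- **Probability surfaces**: 1D/2D histograms (default 50 bins over the
  observed range padded 5%), normalised, −ln p in kT with empty bins
  masked and the minimum shifted to zero; optional per-frame weights
  connect to the reweighting machinery.

## Well-tempered metadynamics

The engine deposits Gaussian hills every `pace` (default 2 ps) with widths
σ per CV (default 0.2 Å for piston-like CVs) and heights

    h = h₀ · exp(−V(s, t) / (k_B ΔT)),   ΔT = (γ − 1) T,

where `V(s,t)` is the accumulated hills bias and γ the bias factor
(γ = (T + ΔT)/T).  At convergence the bias estimates the free energy as
`F(s) = −(T + ΔT)/ΔT · V(s, t→∞)`, which is how `free_energy_from_bias`
converts a hill record (the surface is shifted so its minimum is zero).
Defaults follow the bundle-simulation conventions: h₀ = 0.25 kJ/mol,
γ = 10, T = 298 K.

Half-sided polynomial **walls** `κ((s−s₀)/r)^e` (e = 4 even, so the
potential is C¹ at the bound and exactly zero inside) confine the CVs;
angle CVs are treated as non-periodic inside their walls.  The class
default κ = 500 kJ/mol with r ~ 0.1 Å matches the stiff confinement used
for protein-scale piston CVs; the built-in toy runs use much softer walls
(κ = 20 kJ/mol, r = 0.3 Å) because a stiff quartic makes thermal wall
penetrations numerically unstable at the toy time step of 0.01 ps.

The **bias offset** `c(t)` is evaluated on the same grid as the recovered
free energy, once per deposition:

    c(t) = (1/β) ln [ ∫ exp(βγ/(γ−1) V(s,t)) ds / ∫ exp(β/(γ−1) V(s,t)) ds ],

computed with a max-shift for numerical stability (the grid volume element
cancels).  For a bias that is constant over the grid, c equals that
constant — a closed-form identity the tests exercise.  Per-frame weights
`w ∝ exp(+β [V(s_t, t) − c(t)])` then reweight any unbiased observable;
`c(t)` is interpolated as a step function over depositions and is zero
before the first hill.  Static walls are not part of the reweighting
factor, so observables should be evaluated inside the wall window.

**Replay identity.** The in-run grid bias is maintained by adding each
hill with the same accumulation routine used to replay a HILLS record, and
HILLS files are written with 17 significant digits (exact float
round-trip).  Recomputing the free energy from an emitted HILLS file is
therefore bit-identical to the in-run bias, not merely close.

**Dynamics.** The toy backend is a BAOAB-discretised Langevin integrator
(positions in Å, time in ps, energies in kJ/mol, mass in amu; default
friction 5 ps⁻¹, dt 0.01 ps, with a guard requiring dt·friction < 0.1).
The CVs of a toy run are the coordinates themselves, 1–4 dimensions.  A
single integer seed fans out (via `numpy` seed spawning) into independent
streams for velocity initialisation and thermostat noise, so runs are
bit-reproducible.

**Problem sizes.** The double-well validation (`U(x) = 5(x²−1)² kJ/mol`,
barrier 5 kJ/mol ≈ 2 kT at 298 K) uses 400 000 steps (4 ns, 2000 hills)
per seed and five seeds; this converges the recovered barrier to
5.0 ± 0.4 kJ/mol across seeds and the seed average to within 0.5 kJ/mol
of the analytic value.  The unbiased Boltzmann reference is a 10⁶-step
trajectory; the comparison of reweighted and reference profiles uses
5-block standard errors per histogram bin over the thermally relevant
region (within 6 kJ/mol of the minimum).

## Synthetic bundles

The fixture generator builds ideal α-helices on an exact cylindrical
parametrisation of the C-alpha trace (rise 1.5 Å, twist 100°/residue,
radius 2.3 Å by default).  Backbone N, C and O sit at fixed cylindrical
offsets derived from ideal internal coordinates (φ = −57.8°, ψ = −47°);
the resulting O(i)–N(i+4) distance is ~3.05 Å, so an n-residue helix shows
exactly n−4 hydrogen bonds under the 3.5 Å / 30° criterion, and none after
a 1.3× axial stretch.

Four helices (N1, C1 of monomer 1; N2, C2 of monomer 2; N helices on one
square diagonal) are placed 10.1 Å apart, all chains running N→C along +z
as in the parallel HAMP architecture, and the two monomers are tilted
toward each other about the C-terminal tip by the cone half-angle (default
9°, giving the 18° inter-monomer tilt observed for the equilibrated wild
type bundle).  Helix phases are set so that the heptad `a` positions face
the core at the ideal Crick angle, which makes knobs-into-holes fixtures
meaningful.

Default helices are 22 residues long: with 100°/residue twist the head and
tail four-residue groups are then phase-commensurate (18 × 100° = 5
turns), their center-of-mass offsets cancel, and the helix vector `V` is
exactly axial — injected motions are recovered by the CVs to machine
precision rather than within a fraction of a degree.

`inject_motion` applies, in order: monomer tilt (rigid rotation about the
axis through the bundle tip perpendicular to the plane of the two monomer
axes, split symmetrically), per-helix piston (translation along the
current head–tail axis) and per-helix rotation (about the head–tail axis
through the midpoint, so `H` and `T` are fixed points and rotation leaves
the piston untouched), then i.i.d. Gaussian coordinate noise under a seed.
Because the fixtures live in the reference coordinate frame, recovery
tests evaluate the reference-based CVs with alignment disabled; alignment
behaviour is validated separately by applying global rigid motions.  For
combined random motions, piston and rotation are measured against a
tilt-matched reference, since a monomer tilt moves helix midpoints and
both CVs are defined relative to a reference structure.

`generate_trajectory` interpolates per-helix rigid transforms (rotation
slerp, linear translation) between two conformations and adds noise —
enough to emulate relaxation events such as the P00 → P10 transition for
classifier and pipeline tests.

### What the generator does and does not emulate

It reproduces the geometry the CVs and analyses are defined on: bundle
architecture, helix register, rigid collective motions, thermal coordinate
noise.  It does **not** emulate side chains, sequence, solvent, helix
bending or fraying, anharmonic couplings between motions, or realistic
kinetics.  Passing tests therefore certify the *measurement machinery* —
that the CVs read out exactly the motion that was put in, with correct
derivatives — and the *sampling machinery* on analytic potentials; they do
not certify biological conclusions about any particular protein, which
require real trajectories as input.

## Numerical choices and limitations

- Superposition is unweighted over the selection (the C-alpha-only RMSD
  convention); reflections are excluded by sign-correcting the smallest
  singular value; collinear selections are rejected with a specific error.
- Coordinates are treated as unwrapped; trajectory readers must deliver
  whole molecules (no periodic-image handling in the geometry layer).
- Hills are evaluated exactly (vectorised over all hills, no cutoff) at
  the hill counts these run lengths produce; the grid accumulation is the
  single shared code path for in-run bias and replay.
- Angles are reported in degrees everywhere; radians are internal only.
- The classifier's thresholds (0.5 Å state threshold, 3 Å out-of-register
  cut) are arguments, not constants.
- Output files (COLVAR, HILLS, surfaces, PDB fixtures) begin with
  `#! FIELDS` plus provenance lines (tool version, config hash, seed) and
  are byte-reproducible under a fixed seed.
- The metadynamics engine couples only to the built-in Langevin toys; the
  CV gradients are engine-ready but coupling to a real MD engine is out of
  scope, as are replica exchange, multiple walkers and adaptive hills.
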