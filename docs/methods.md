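# Methods

## Scope and model

`clampdyn` analyses and emulates the conformational behaviour of DNA sliding
clamps — toroidal processivity factors with pseudo six-fold symmetry
(bacterial Pol III β: homodimer with three clamp domains per protomer;
gp45/PCNA: homotrimers with two domains per protomer). The package works at
the level of the clamp-domain centres of mass (COMs): six points whose
distances, vertex angles and signed torsions describe ring closure, in-plane
opening and spiral (helical) distortion.

### Domain decomposition

Domains are configuration data: chain identifiers plus inclusive
author-numbered residue ranges, carried in YAML topology files. The shipped
topologies for the clamp crystal structures (1OK7, 1PLQ, 1B77, 1JQL) are a
**reconstruction**: coordinate depositions do not record domain boundaries,
so the ranges were chosen as the approximately equal sequential thirds
(β, 366 residues → 1–125 / 126–252 / 253–366) or halves (PCNA 258 →
1–117 / 118–258; gp45 228 → 1–110 / 111–228) of each protomer. They are
meant to be edited when better boundaries are available; all crystal-derived
angle checks carry a ±2° tolerance to absorb this ambiguity.

COMs are mass-weighted over non-hydrogen atoms by default (crystal
structures lack hydrogens); a `mode="ca"` flag switches to the unweighted
Cα mean for robustness comparisons. Whether published COM analyses of
clamps used mass weighting is generally unstated; the difference is far
below the ±2° tolerance for these ~100-residue domains.

## Geometric descriptors

* **Distance / angle / torsion** between COM points. Dihedrals use the
  IUPAC right-handed sign convention: rotating the fourth point by +x°
  about the 2→3 axis (right-hand rule) adds +x°; planar-cis is 0°.
* **Handedness sum**: the sum of the three signed COM torsions of the three
  consecutive 4-domain windows that avoid the designated opening interface
  (for β opened at A3/B1 these are B1-B2-B3-A1, B2-B3-A1-A2, B3-A1-A2-A3).
  Positive = right-handed spiral, negative = left-handed, 0 = planar. The
  orientation is regression-locked by a constructed right-handed-spiral
  test. Note that signed *inter-domain rotation* values reported for PCNA
  in the literature can follow the opposite sign convention from the
  handedness sum (a right-handed spiral described with negative rotations);
  the two conventions are documented here and deliberately not forced to
  agree.
* **Kabsch superposition** (SVD with the determinant correction) provides
  least-squares body rotations; weighted, proper (det = +1).
* **RMSD100** = RMSD / (1 + ln(N/100)) normalises fluctuation amplitudes to
  a 100-residue equivalent so assemblies of different size are comparable.
  Whether published RMSD100 traces for clamps used Cα or all atoms is
  unstated; this package defaults to Cα.
* **Inter-domain rotation**: from per-domain Kabsch rotations `R_i`, `R_j`
  (reference → current frame), the relative transform `R_rel = R_j R_iᵀ`
  gives angle `arccos((tr R_rel − 1)/2)`; the sign is the sign of the
  rotation axis projected on the reference i→j COM axis. This exact
  construction is our own (the quantity is usually reported without its
  formula); the synthetic-recovery tests make the pipeline self-consistent.
* **Series summaries** discard a pre-equilibration window (default
  10 ns = 10 000 ps in frame time; when frames carry no times an explicit
  discard must be supplied), unwrap angular series by nearest-image
  continuation (±360° to minimise frame-to-frame jumps, so steering sweeps
  across ±180° do not bias averages), and report sample mean ± SD
  (n−1 denominator).

## Coarse-grained simulator

One bead per clamp domain (position = COM, mass = domain aggregate mass,
~1.3×10⁴ amu for real clamp domains; the synthetic rings use their cloud
masses). Beads are joined along the ring path that avoids the opening
interface by harmonic bonds, angles and torsions; the terms crossing the
opening interface are the excluded *broken* set. Equilibrium values are
read off the built conformation, so the built state has zero energy and
zero force — rebuilding from any later frame re-zeroes the reference.

* **Units**: Å, ps, amu, kcal/mol; k_B = 0.0019872041 kcal mol⁻¹ K⁻¹;
  1 kcal/mol = 418.4 amu Å² ps⁻² (exactly, since 1 amu Å²/ps² = 10 J/mol).
  Degree-based force constants are converted internally to rad⁻²
  (× (180/π)²).
* **Stiffness defaults**: bonds 10 kcal mol⁻¹ Å⁻², angles and torsions
  30 kcal mol⁻¹ rad⁻². At 310 K these give thermal COM-geometry
  fluctuations of a few degrees, comparable to the ±3–6° SDs seen in
  all-atom equilibrium clamp simulations. Exposed via `StiffnessProfile`.
* **Restraints**: U = (k/2)(ξ − ξ₀(t))² with linearly moving targets
  ξ₀(t) = ξ₀(0) + v·min(t, duration). The ½ convention is fixed here and
  documented; collective-variable engines differ on it, and every check in
  this package (target tracking, equipartition) is convention-consistent
  once fixed. Angular differences are wrapped to (−180°, 180°]. Torsion
  targets move linearly like distance targets (the linear schedule for
  torsions is an assumption, stated as such).
* **Steering protocols**: type 1 pulls the opening-interface COM distance
  at constant velocity 2.0 Å ns⁻¹ with k = 500 kcal mol⁻¹ Å⁻² for 10 ns
  (net +20 Å); types 2/3 drive the three interface torsions by −20°/+20°
  over 10 ns with k = 50 kcal mol⁻¹ deg⁻², producing left-/right-handed
  spirals. After steering, restraints are dropped; the free phase defaults
  to 10 ns (the package's desk-scale choice; longer schedules, e.g. 140 ns,
  are plain configuration). CG time is nominal — no mapping to all-atom
  nanoseconds is claimed.
* **Integrator**: BAOAB-splitting Langevin dynamics, timestep 10 fs,
  damping 5 ps⁻¹, 310 K. BAOAB was chosen for its near-exact configurational
  statistics for stiff harmonic systems at large steps; at zero damping it
  reduces to velocity Verlet (used for the energy-conservation check).
  Trajectories are bitwise reproducible given the seed. The force kernel is
  numba-compiled; analytic gradients are verified against central finite
  differences to <10⁻⁵ relative error.
* **Numerical guards**: the 1/sin² factors in angle/torsion gradients are
  capped (floor 10⁻⁸ on sin²) so near-collinear geometry yields finite
  forces; ring geometries never approach collinearity in normal operation.
  Divergence at T = 0 (energy blow-up) raises an integration error advising
  a smaller step.

## Synthetic generator

The generator stands in for all-atom MD output, producing data whose ground
truth is exact by construction:

* **Ideal ring**: COMs exactly on a circle (default radius 35 Å, the scale
  of real clamp COM rings) in the z = 0 plane; each domain is a rigid,
  anisotropic random cloud (axis scales 1 : 0.6 : 0.35 of the 6 Å spread)
  so inertia tensors are non-degenerate and Kabsch fits unique.
* **Deformations** are rigid per-domain transforms. Spiral modes rotate the
  downstream arc of the ring about each interface COM axis in sequence, so
  each designated torsion changes by exactly the requested twist (rotations
  about an axis through two COMs alter only that window's torsion, making
  the construction exact and exactly invertible — applying the negated
  magnitude in the same window order restores the input). `planar_open`
  translates the two rigid half-rings apart along the interface axis
  (clamshell-style, gap exact, handedness stays 0); `in_plane_angle`
  rotates the third domain of a COM triple (and the arc beyond it) in the
  ring plane by an exact increment. Real all-atom deformations are
  emergent, not constructed; the construction is the desk-scale surrogate.
* **Trajectories**: per frame, the rotated domain of each designated
  interface is rigidly turned about the i→j COM axis through its own COM by
  an i.i.d. draw from Normal(mean, sd²) (defaults 13.9°, 4.4° — the
  distribution reported for inter-domain rotations of the gp45 monomer),
  plus optional isotropic Gaussian coordinate noise. COMs are preserved, so
  the drawn angle is exactly the relative body rotation the pipeline should
  recover.
* **Coordinate noise default is 0 Å.** Kabsch-recovered rotation
  *magnitudes* are positively biased under coordinate noise (the fitted
  noise rotation composes with the true one in quadrature; ≈ +1° at 0.5 Å
  noise on the default clouds). Recovery tests therefore run the noise-free
  generator, whose only error is the sampling error of the draws; noise
  robustness is exercised separately at 0.1 Å, where the bias (≈0.03°) is
  negligible. What passing recovery tests show is that the pipeline is
  exact for rigid-body data; they do not show robustness to the internal
  flexibility, solvent noise or drift of real MD data.

## Spheres and arrows

Each domain is drawn as a sphere at its COM plus an arrow fixed in the
domain's body frame: at the reference frame the arrow is the vector from
the sphere to the system COM; in later frames it is rotated by the domain's
fitted Kabsch rotation (Cα atoms when present, all atoms otherwise — the
fitting set is a package choice). Arrow lengths are conserved exactly. For
bead-only CG trajectories there are no internal atoms, so orientation is
propagated from a local ring frame built from the neighbouring beads and
the ring centroid (documented as a distinct construction). Output is CSV or
a BILD-dialect graphics script (one `.sphere` + one `.arrow` per domain).

## Problem sizes and tolerances used by the shipped checks

* Steered runs: 10 ns steering at 10 fs = 10⁶ steps, six beads; end-of-
  steering targets are met within ±0.5 Å / ±0.5° (thermal colvar
  fluctuation under the stiff restraints is ~0.04 Å / ~0.1°).
* Equipartition: a 10-ns run with one static torsion restraint
  (50 kcal mol⁻¹ deg⁻²); the stationary variance matches
  k_BT/k_eff = 0.0123 deg² within 20% (k_eff includes the ring's own 30
  kcal mol⁻¹ rad⁻² torsion term).
* Recovery: 1000-frame trajectories; the post-discard mean of the recovered
  rotations lies within 3 standard errors (±0.42°) of the generating mean.
* Exact-construction checks (spiral torsions, gaps, angle increments,
  inversions) use 10⁻⁶–10⁻⁹ tolerances; metric oracles (dihedral vs
  plane-projection formula, Kabsch vs quaternion method) agree to 10⁻⁹ over
  1000 random instances.

## Known limitations

* Crystal-geometry checks need the deposited PDB files (1OK7, 1PLQ, 1JQL)
  downloaded into `data/structures/`; they are not redistributed with the
  package.
* The CG model has no excluded volume, no electrostatics and no solvent;
  re-closure kinetics and interface re-association chemistry are outside
  its reach. Its free relaxation converges to whatever handedness its
  bonded reference geometry encodes — a mechanistic mirror of the
  β-recloses / gp45-stays-open contrast, enforced rather than predicted.
* mmCIF input, automatic domain-boundary detection, RMSF/PCA analyses and
  binary trajectory formats are out of scope; multi-model PDB is the
  trajectory dialect.
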