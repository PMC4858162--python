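# clampdyn

Geometry, handedness and coarse-grained ring-opening dynamics of DNA
sliding clamps.

Sliding clamps (bacterial Pol III β, bacteriophage gp45, eukaryotic PCNA)
are ring-shaped proteins that encircle double-stranded DNA and tether
polymerases and repair enzymes. All of them are built from six "clamp
domains" with pseudo six-fold symmetry, and they must open — in-plane or as
left-/right-handed spirals — to be loaded onto DNA by clamp loaders.
`clampdyn` provides the quantitative toolkit for studying those open and
closed conformations from structures and trajectories, plus a desk-scale
coarse-grained simulator of the steered opening protocols themselves.

## What it computes

For clamp domains with centres of mass (COMs) **r**₁…**r**₆ arranged
around the ring:

* COM distances, vertex angles and signed torsions (IUPAC right-handed
  convention);
* the **handedness sum** — the sum of the three signed COM torsions
  spanning the opening interface (for β opened at A3/B1:
  φ(B1-B2-B3-A1) + φ(B2-B3-A1-A2) + φ(B3-A1-A2-A3)); positive values are
  right-handed spirals, negative left-handed, zero planar;
* size-normalised RMSD, RMSD₁₀₀ = RMSD / (1 + ln(N/100)), with Kabsch
  least-squares superposition;
* signed **inter-domain rotations** from relative Kabsch body frames,
  with post-discard mean ± SD time-series summaries;
* the "spheres and arrows" representation: one sphere per domain COM plus a
  body-fixed arrow reporting domain orientation over a trajectory.

The coarse-grained simulator (one bead per domain, harmonic ring terms,
BAOAB Langevin dynamics at 310 K) implements three steered opening
protocols with moving harmonic restraints U = (k/2)(ξ − ξ₀(t))²:

| type | collective variable(s) | schedule |
|------|------------------------|----------|
| 1 | interface COM distance | +20 Å at 2.0 Å/ns, k = 500 kcal mol⁻¹ Å⁻² |
| 2 | three interface torsions | −20° each over 10 ns, k = 50 kcal mol⁻¹ deg⁻² (left-handed spiral) |
| 3 | three interface torsions | +20° each over 10 ns (right-handed spiral) |

followed by free relaxation. A synthetic generator builds ideal rings,
exact spiral/planar/hinge deformations and stochastic trajectories with
known ground truth, standing in for all-atom MD output. See
`docs/methods.md` for model details and assumptions.

## Worked example

Generate a synthetic six-domain clamp, twist it into a right-handed spiral
(+20° at each of the three interface torsions), and analyse it:

```sh
clampdyn synth -o syn --mode rh_spiral --twist-deg 20 --n-frames 5 --seed 3
clampdyn analyze syn/deformed.pdb -t syn/topology.yaml \
    -m handedness -m angle:A1-A2-A3 -m distance:A6-A1 -o ana
cat ana/metrics.csv
```

```
frame,time_ps,metric,value,unit
0,,handedness,60.00028126226779,deg
0,,angle:A1-A2-A3,119.99972584105436,deg
0,,distance:A6-A1,56.12854305375482,A
```

The handedness sum is +60° (three +20° torsions; positive = right-handed
spiral) to PDB coordinate precision; the A1-A2-A3 COM angle is the ideal
hexagon's 120°; and the A6–A1 opening-interface COM distance has grown
from the closed ring's 35 Å (the hexagon edge) to 56.1 Å as the spiral
separates the interface. A steered CG run produces the same end state
dynamically:

```sh
clampdyn simulate --model-type 3 --seed 1 --post-steering-ps 0 -o sim
# INFO clampdyn: final colvar torsion:A1-A2-A3-A4 = 19.936 (target 20.000)
# INFO clampdyn: final colvar torsion:A2-A3-A4-A5 = 20.054 (target 20.000)
# INFO clampdyn: final colvar torsion:A3-A4-A5-A6 = 20.003 (target 20.000)
```

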