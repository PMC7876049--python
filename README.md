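# helixhop

Infer how a motor-propelled cargo steps on the microtubule surface lattice
from nothing but its 3D trajectory.

Kinesin-coated beads moving along a microtubule suspended away from the
coverslip are free to travel all around the tube, and many motors (for
example the kinesin-6 MKLP1 and the centralspindlin complex) drive them on
left-handed helical paths: the motors occasionally switch protofilament
sideways while stepping forward. `helixhop` turns time-stamped 3D bead
positions sampled at ~0.1 s into the microscopic quantities behind that
motion: the total lattice hopping rate *k* and the preferences
*p*₁…*p*₈ for hopping to each of the 8 neighboring tubulin dimer sites.

It is a library for people analyzing single-particle tracking data of
helical motor motion — plus a synthetic-trajectory generator that emulates
every statistical feature the analysis assumes (biased lattice hopping,
transient trapping, supertwist geometry, localization noise), so the whole
chain is testable against known ground truth.

## The model

The bead hops on the surface lattice of a 13- or 14-protofilament
microtubule (dimer spacing *d* = 8 nm, lateral rise *r* = 0.82 nm,
left-handed supertwist pitch *P*_MT ≈ 8 µm for 14 protofilaments).
Measured coordinates (X µm along the axis, Y cumulative revolutions,
left-handed positive) map linearly to lattice coordinates (z, w):

    X_nm  = z·d + w·r        Y_rev = w/n + X_nm/P_MT

Hops go to the 8 nearest sites at rates *k*₁…*k*₈ (a continuous-time
Markov jump process). For such a process every joint cumulant of the
displacement grows linearly in time, with rate Σᵢ kᵢ·dzᵢᵃ·dwᵢᵇ, giving an
exact, invertible linear system

    (v_x, v_y, 2D_x, 2D_y, A, B, C, E)ᵀ = M (k₁ … k₈)ᵀ

where v are velocities, D diffusion coefficients, and A, B, C, E the
per-time coefficients of the joint cumulants κ₁₁, κ₂₁, κ₁₂, κ₂₂ — the
higher-order covariances that discriminate hopping patterns with identical
velocities and diffusion. The pipeline:

1. **Unwrap** raw (t, x, y, z) tracks into (X, Y) cylindrical coordinates
   and apply quality filters (run > 1 µm, helix radius ≤ 250 nm).
2. **Segment** each track into mobile and transiently trapped (immobile)
   stretches with a two-state Gaussian hidden Markov model on windowed,
   normalized displacements; excise the immobile runs.
3. **Estimate** the 8 macroscopic parameters per track with drift-adjusted
   covariance-based estimators (CVE) that cancel localization-noise bias
   using the anticorrelation of adjacent displacements.
4. **Infer** *k* and the preference simplex by MCMC under the physical
   constraints kᵢ ≥ 0, modeling each track's observed parameter vector as
   Gaussian around the theoretical one.

## Worked example

`examples/05_infer_hopping.py` simulates 36 tracks × 30 s of a strongly
forward/left-biased walk (k = 45 s⁻¹, forward preference 0.8), runs the
full segmentation → estimation → inference chain, and prints:

```
total hopping rate k = 45.4 +/- 1.4 /s (truth 45.0)
preference   truth  posterior
  fwd-left   0.10   0.102 +/- 0.011
  forward    0.80   0.792 +/- 0.011
  fwd-right  0.01   0.010 +/- 0.005
  left       0.05   0.042 +/- 0.014
  right      0.01   0.010 +/- 0.007
  bwd-left   0.01   0.007 +/- 0.006
  backward   0.01   0.029 +/- 0.014
  bwd-right  0.01   0.008 +/- 0.005
```

Every preference is recovered within its posterior spread from half a
minute of (noisy, intermittently trapped) observation per bead. The other
examples cover the geometry transforms (`01`), simulation and 3D
unwrapping (`02`), mode segmentation (`03`), the CVE vs MSD comparison
(`04`), and the one-call pipeline (`06`). A thin CLI mirrors the stages:
`helixhop simulate | unwrap | filter | segment | estimate | infer | run`.

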