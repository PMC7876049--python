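# Methods

## Lattice geometry and coordinate systems

The microtubule surface is modeled as a skewed 2D lattice: `n` ∈ {13, 14}
protofilaments, dimer spacing `d = 8 nm` along a protofilament, lateral
rise `r = 0.82 nm` between adjacent protofilaments, and — for n = 14 — a
left-handed supertwist of pitch `P_MT = 8 µm` (protofilament tilt
θ ≈ 0.73°, stored as an informational constant only; the transform is
parametrized by pitch, since θ and the tube perimeter are mutually
redundant). The composite linear map is implemented directly as

    X_nm = z·d + w·r,    Y_rev = w/n + X_nm/P_MT,

with the supertwist term dropped when `P_MT` is infinite (n = 13).
Left-handed rotation is the positive Y direction. Lattice coordinates are
real-valued throughout: the inference operates on displacement moments,
not on discrete site calls, so nothing is snapped to integer sites. The
seam — the one lateral contact with mismatched α/β registry — is ignored;
only ~1/13 of lateral contacts cross it, and the covariance estimators use
only single-interval displacements, so any seam effect stays local.

Two printed lattice constants are mutually inconsistent: a per-contact
rise of 0.82 nm and a 13-rise seam closure of 12 nm (13 × 0.82 = 10.66).
Both are kept (`rise_r` in the transform, `SEAM_CLOSURE_NM` as a
constant); the discrepancy is documented rather than resolved because no
measurement in this package can distinguish them.

The supertwist pitch correction assumes a preparation that is a mixture of
13-protofilament (fraction α, default 5/8) and 14-protofilament
microtubules; on the latter the observed bead pitch obeys
1/P_obs = 1/P_motor + 1/P_MT. The mixture-averaged observed pitch gives a
quadratic in P_motor whose positive root is returned; a residual check of
the mixture equation is part of the test suite.

## Cylindrical unwrapping

The per-frame rotation angle is the atan2 of the (y, z) position relative
to the rotation center, accumulated with smallest-angle increments —
valid because the fastest relevant rotation (~0.4 rev/s at 0.1 s
sampling) moves ≲0.04 rev per frame. The rotation center is a
least-squares (Kåsa) circle fit to the (y, z) cloud rather than its
centroid: the centroid of a partial arc is badly biased (a quarter-circle
arc would read ~0.58 rev instead of 0.25), while the circle fit is exact
for noise-free arcs of any extent and agrees with the centroid for
full-coverage data. When no axis is supplied, the longitudinal direction
is the principal direction of the 3D point cloud; a straight suspended
microtubule is assumed (curvature is out of scope). Note the principal
direction acquires a tilt of order the radius-to-length ratio on tracks
shorter than ~2 turns; the resulting pitch error is second order in the
tilt and negligible for tracks passing the 1 µm run filter.

Quality control keeps trajectories with net longitudinal run > 1 µm and
median per-frame helix radius ≤ 250 nm (~twice the microtubule + bead
radius). The median is used because transient outliers should not reject
an otherwise clean track.

## Mobile/immobile segmentation

Beads intermittently stall at a lattice site; in that state the apparent
motion is localization noise plus tether fluctuation and would dilute the
transport estimators. Each time point is scored by the look-ahead
displacement magnitude s = ‖(ΔX/σ_X, ΔY/σ_Y)‖ over a fixed window
(per-construct default: the expected time to travel ~0.1 µm along the
axis; 0.3/0.5/0.4 s for the three presets), with σ computed per
trajectory at that window. Windows slide from every time point; the
induced autocorrelation of s is a known caveat accepted for temporal
resolution.

A two-state Gaussian hidden Markov model is fitted to s by
expectation-maximization with ≥5 seeded restarts — a maximum-a-posteriori
fit: the immobile-state emission mean carries a normal prior centered at
0 (weight equivalent to ~30 observations). The anchor matters because the
mobile-mode distance distribution is skewed, and an unpenalized ML fit
occasionally splits the mobile bulk into two states instead of isolating
the small near-zero immobile mass (observed on synthetic cohorts: ~20%
of points called immobile versus 8% truth; with the anchor, accuracy is
~98% and the immobile fraction is recovered within ~1 percentage point).
States are relabeled after fitting so the larger-mean state is "mobile";
decoding thresholds the forward–backward posterior at 0.5. Degenerate
(zero-variance) input returns a flagged single-mode result.

Mobile runs shorter than 5 frames are dropped (they contribute no usable
adjacent-displacement pairs and would contaminate the covariance
estimators); the virtual trajectory concatenates only within-segment
displacements — no displacement ever spans an excised gap.

## Macroscopic estimators

Velocities are the pooled mean displacement per frame. The remaining six
parameters use drift-adjusted displacements (Z = X − v_x t, W = Y − v_y t)
and the covariance-based forms that combine same-index products with
adjacent-index products; for independent additive localization noise the
adjacent-displacement covariance is −σ², which exactly cancels the +2σ²
inflation of the displacement variance (and the analogous higher-order
noise terms in A, B, C, E). Expectations are sample means over all
adjacent-index pairs lying within one mobile segment, pooled across
segments weighted by pair count. Estimates are reported as computed —
negative variance-like values are legitimate sampling outcomes at this
layer and are clamped nowhere; positivity enters only through the
Bayesian inversion.

MSD analysis is provided as the cross-check route: per-track MSD over
τ = 0.1…1.0 s from all within-segment pairs, averaged across tracks
(mean ± SE), fitted with MSD = y₀ + 2Dτ + v²τ² by inverse-variance
weighted least squares with all three parameters bounded below by 0. The
model is linear in (y₀, 2D, v²), so the bounded fit is solved exactly by
non-negative least squares; an active bound sets a flag. The gliding-assay
corkscrew pitch is a least-squares sine fit y = a·sin(2πx/pitch + φ) + c
with the initial pitch from the dominant FFT frequency; it requires at
least one full period and rejects flat traces.

## Hopping inference

For a Markov jump process the displacement over time t is compound
Poisson, so all joint cumulants are linear in t with coefficients
Σᵢ kᵢ dzᵢᵃ dwᵢᵇ. The rows of the 8×8 moment matrix are exactly these
direction moments for orders (1,0), (0,1), (2,0), (0,2), (1,1), (2,1),
(1,2), (2,2); the matrix is well conditioned and the exact linear solve is
provided for diagnostics, with negative entries flagged rather than
hidden.

The Bayesian model treats each trajectory's observed 8-vector as Gaussian
around the theoretical vector, independently per parameter, with one free
noise scale σ_m per macroscopic parameter shared across trajectories
(per-parameter sampling noise spans orders of magnitude across moment
orders, so a single scale would be badly misspecified). Priors: flat on
each rate over [0, k_max] with k_max = 200 s⁻¹ — roughly an order of
magnitude above motor ATPase turnover, a prior-support statement rather
than a physical claim — and half-normal on each σ_m scaled to twice the
empirical cross-trajectory spread. The sampler works directly on the 8
non-negative rates plus the 8 scales (16 dimensions); the reported
quantities are k = Σkᵢ and pᵢ = kᵢ/k, so every posterior draw satisfies
the simplex constraint exactly and kᵢ ≥ 0 by construction. Sampling uses
an affine-invariant ensemble sampler: 4 independent ensembles of 48
walkers × 2000 steps by default (first half discarded), initialized near
the clipped exact linear solution. Split-R̂ is computed across the 4
ensembles for k and p₁…p₈; any R̂ ≥ 1.01 raises a warning and flags the
posterior as unconverged (the default budget is usually marginal at
cohort size ~36; 4000 steps is comfortably converged and is what the
acceptance checks use).

Posterior summaries include a 3×3 compass grid of preference means/SDs
(forward on top, left on the left, center empty). Inference is
equivariant under the lattice mirror w → −w with preferences permuted
(1↔3, 4↔5, 6↔8) up to Monte-Carlo error.

## Synthetic data

The generator is the package's definition of the study conditions. Each
track is a Gillespie simulation: exponential waiting times at total rate
Σkᵢ, directions drawn ∝ kᵢ, with an independent alternating-renewal
trapped state that suppresses hopping entirely while leaving localization
noise unchanged. The sampled lattice path passes through the geometry
transform and acquires independent Gaussian noise per frame: 3 nm SD
longitudinally and 6° SD rotationally (midpoint of the measured 5–7.5°
precision range), at the 0.10028 s observation cycle. An optional 3D
embedding on a 0.1225 µm cylinder (microtubule + bead radii) exercises
the unwrapping stage.

Construct presets (M2 dimer, M2C2 heterotetramer, M1 monomer; 36/47/47
tracks, 30 s each) are stored as config files holding the total rate,
symmetric background allocations, and the target cohort velocities; the
preference vector is solved in closed form at load so that the noise-free
expected longitudinal velocity (sites/s × 8 nm) and rotational velocity
(lateral sites/s ÷ n) match the targets (0.30 µm/s and 0.37 rev/s for
M2, 0.19/0.12 for M2C2, 0.24/0.11 for M1). Trap switching rates are only
constrained by occupancy in the source data (~5–10%); the defaults
(on 1/11.5 s⁻¹, off 1.0 s⁻¹ → 8% occupancy, mean trapped dwell 1 s) are
otherwise arbitrary and flagged as such — the 1 s dwell is chosen so a
trapped interval spans several frames and is resolvable by the HMM.

What the generator does *not* emulate: multiple-motor load sharing and
detachment, jumps beyond nearest-neighbor sites, microtubule flexural
dynamics, seam irregularity, obstacle geometry, and stage drift. Passing
tests therefore certify the statistical machinery under the stated model,
not the fidelity of that model to any particular experiment.

## Problem sizes and numerics

The validation suite runs the moment-map oracle at ≥10⁵ jumps per rate
vector (block-based Monte-Carlo standard errors, 20 blocks), the noise
benchmark at 50 tracks × 1000 frames, and parameter recovery at 36 tracks
× 30 s — the full study-scale cohort. EM convergence tolerance is 1e−8
over at most 500 iterations; geometry round trips are exact to machine
precision; all randomness flows from explicit seeds through
`numpy.random.SeedSequence` spawning, so identical seed and config give
bit-identical cohorts and reports.

## Known limitations

- The per-trajectory Gaussian likelihood ignores correlations between the
  eight estimated parameters within a track (they share displacements).
- The E estimator has heavy-tailed sampling error; at 36 tracks its
  per-track values are dominated by noise, and it contributes mainly
  through pooling.
- Axis estimation assumes a straight microtubule; curved or fluctuating
  filaments must be rejected upstream.
- The HMM emission model is a Gaussian on a non-negative distance;
  truncation at 0 is ignored because both state means sit well inside the
  support at the default windows.
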