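# Methods

## Model

A trial of an in-place motor task is summarized by its execution variables
`u` — the few movement quantities at the moment of execution that fully
determine the outcome.  The goal function is a two-stage map: the execution
mapping `S(u, x_e1)` turns the movement into a change of virtual-object
state, and the environment mapping `V(x_e2, p)` propagates the object
through the virtual physics to a scalar, nonnegative error.  The *solution
manifold* is the zero-error set in execution space; redundancy makes it a
curve or surface for the 3-variable tasks and a single point for the
2-variable bow task (both the yaw and the flight-time residual must vanish).

Coordinate frame: right-handed, +y up, −z forward (away from the subject),
+x toward the dominant side, origin at the mid-stance ground point.  SI
units internally (m, m/s, rad); degrees only at I/O boundaries and for the
punching-bag error, which is conventionally reported in degrees.

### Bow-and-arrow (BA)

`u = (chest excursion / baseline lateral chest limit, string draw /
upper-limb length)`.  The bow yaws linearly with normalized lean,
`θ_bow = (x_chest / x_max) · 15°`, clamped to `[0°, 15°]` (over-leaning
cannot push the bow past its physical range; the clamp is switchable).  The
arrow leaves the bow centre at speed `k · draw` along the yawed forward
direction.  The target plane is vertical and perpendicular to the *optimal*
arrow path; ground-plane kinematics are straight lines under gravity, so
the time of flight is `t = d_target / (|v| cos(θ* − θ))` and gravity enters
only the vertical hit coordinate (`g t² / 2` drop).  The error is the
radial distance from the bullseye in the target plane, including the
vertical component (a ground-plane-only variant is available).

A draw is classified *misfired* if the grip hand leaves the bow grip by
more than 0.08 m during the draw, *fired* once the dominant hand leaves the
draw plane by more than 0.14 m, *held* otherwise; whichever threshold is
crossed first in sample order decides.

### Reach-and-strike (RS)

`u = (vx, vy, vz)` hand velocity at ball impact; ball velocity is `k u`
(k = 1 by default — the ball inherits the hand velocity).  Projectile
motion to the vertical plane 4 m in front of the ball; the bullseye sits
1 m above the launch height; error is the planar distance from the
bullseye.  A non-forward launch (vz ≥ 0) is a gross miss.

### Punching bag (PB)

`u = (vx, vz, d)`: ground-plane hand velocity and the vertical hit height,
which must lie within the bag's vertical extent (the VR engine handled 3-D
contact; here the execution variables already encode the hit).  The bag's
initial angular speed is `ω = k · d · √(vx² + vz²)` and its swing azimuth
is the quadrant-correct `atan2(vz, vx)` (the one-argument arctangent is
singular at vx = 0 and identifies opposite directions).  The peak amplitude
comes from the point-mass energy balance `θ_max = arccos(1 − L ω² / 2g)`
(mass cancels; energy above the inversion limit is a gross miss), and the
small-angle swing is `θ(t) = θ_max cos(ω_n t + phase)` with natural
frequency `ω_n = √(g/L)` — distinct from the initial angular speed ω.  The
error is the axis-angle magnitude (degrees) of the rotation between the
observed and desired peak bag-axis orientations, computed as
`atan2(|a_obs × a_des|, a_obs · a_des)` for conditioning near 0° and 180°.
It decomposes into a height component (amplitude mismatch, degrees) and a
signed direction component (azimuth mismatch at the desired amplitude,
positive toward the lateral axis); the components recombine in quadrature
for small angles.

We note the hit-height variable enters ω as a direct factor.  A lever-arm
reading (pivot-to-impact distance) would reverse the monotonicity in hit
height; the velocity scale k absorbs the overall magnitude either way, and
the direct-factor form is the package's contract.

### Placement and calibration

Objects are placed from the lean/reach star test: BA bow at 90 % of
upper-limb length forward and 65/80/95 % of the lateral chest limit; RS
ball and PB bag at the neutral HMD height, 50 % of forward reach, and
65/80/95 % of the lateral hand limit (dominant side for BA/RS,
non-dominant for PB).

Constants with no canonical value are required configuration with shipped
defaults fixed by a deterministic calibration routine, not hand-tuned
numbers:

| constant | default | how it is fixed |
|---|---|---|
| BA velocity scale `k` | 20 m/s per unit draw | a full draw is a ~13 m/s arrow; keeps draws inside the search grid |
| BA target distance `d_target` | 6 m | desk-scale archery; drop stays above ground for the default subject |
| BA target radius | 0.5 m | consistent with miss distances of a few tenths of a metre |
| BA bullseye | derived | placed exactly where the optimal shot (condition lean, draw = 0.65) lands — the calibration invariant |
| RS velocity scale `k` | 1 | hand speeds are already in the task's operating range |
| RS target radius | 1.0 m | the printed 2.0 m target diameter |
| PB desired amplitude `θ_des` | 30° | a visibly large but sub-inversion swing |
| PB desired azimuth `φ_des` | 30° toward the dominant side | task definition |
| PB velocity scale `k` | derived | `calibrate_pb_k`: a 4 m/s reference punch at bag-centre height reaches `θ_des` exactly |
| PB target radius | 10° | the error threshold used for the bag task |

Under these defaults every task has an exact zero-error execution
(documented optimum), which the tests assert to 1e-9.

## TNC-cost

Each cost is `mean e(U) − mean e(U*)` for an optimized set `U*`:

* **T-cost** translates the cloud's centroid to every point of a
  rectangular grid.  The reference search limits are shipped verbatim as
  `SearchGrid.default(task)`; because search limits are setup-specific
  (they depend on where objects were placed for a given subject),
  `SearchGrid.for_environment(gf)` re-anchors a grid to the constructed
  environment's feasible bounds, which is what analyses of synthetic data
  use.  Exact exhaustive scanning is used up to 5·10⁵ lattice points;
  beyond that a stride-8 coarse scan with full-resolution local refinement
  is used (it matches the exact mode on small grids, which is tested).
* **N-cost** scales the centred cloud by 1.00, 0.99, …, 0.00 and keeps the
  best factor; ties resolve toward the least manipulation (largest factor).
  The per-variable variant scales a single coordinate.
* **C-cost** greedily swaps values of the second (and third) execution
  variable between trial pairs, accepting a swap only if the set's mean
  error strictly decreases, until a full batch accepts nothing.  Iteration
  order is fixed (row, partner, variable-2 before variable-3) for
  determinism; a seeded randomized order is available.  We read the batch
  description as independent per-variable exchanges rather than joint
  (v2, v3) swaps; marginal distributions are preserved exactly either way.
  Against a factorial brute-force oracle on small 2-variable instances the
  greedy result attains the global optimum on well over 90 % of random
  instances and is never better (it cannot be).

Gross-miss trials (infinite error) are excluded from all TNC means and
counted in the diagnostics; one infinite error would otherwise poison every
candidate comparison.

Costs are nonnegative up to numerical tolerance *plus grid resolution*: the
observed centroid is generally not a lattice point, so T can be a hair
negative on coarse grids.

## Task adjustment

Computed from one prior block and applied forward (the steps can also be
layered over successive blocks):

1. **Velocity scaling.**  The smallest scalar `kv ≥ 1` bringing the
   centroid of the velocity-based execution variables into the operating
   region `v_min`, with comparisons oriented by each bound's sign (a
   negative forward-velocity bound means *at least as negative*; zero
   bounds are inactive).  A scalar preserves the velocity direction
   structure; "never slow a subject down" is the `kv ≥ 1` floor.  A
   centroid of zero or of the wrong sign on an active axis is infeasible
   and reported as such.
2. **Target resizing.**  Centroid bias is first removed with the T-cost
   algorithm (assuming bias is learnable), then the N-cost of the
   T-adjusted set measures irreducible noise and the radius becomes
   `max(r0, N / e_max)`.  `e_max` is dimensionless — an error-to-radius
   ratio — so the same threshold applies to metre-valued and degree-valued
   tasks.  The returned radius satisfies `N / rt ≤ e_max` (the closure of
   the strict inequality: any strictly larger radius would not be the
   smallest).  Errors here do not depend on the radius, so N needs no
   recomputation per candidate.
3. **Visual error modification.**  Each trial splits into its nearest
   zero-error execution `u*` (Euclidean projection onto the solution
   manifold; optional per-variable standardization for mixed-unit tasks)
   and the fluctuation `d = u − u*`.  The displayed execution is
   `u_r = u* + c ⊙ d`; `c = 1` is the identity, `c = 0` displays a perfect
   trial, components may differ to shrink selected error axes only.  The
   vector `c` is chosen by a largest-first grid search (step 0.05) over the
   policy family (uniform, single-axis, magnitude-preserving) for the
   largest `c` with mean displayed error ≤ `e_max · rt`; single-axis
   policies can be infeasible when the untouched axes carry an error floor,
   and this is reported rather than raised.

The **magnitude-preserving variant** rescales the shrunken execution back
to the observed movement magnitude.  For the punching bag with
`c = (c₁, c₁, 1)` the rescaling is applied to the velocity components,
restoring the observed hand speed with the hit height untouched: this
preserves both `‖u‖` and — because the swing amplitude depends only on
`d · |v|` — the bag swing height *exactly*, while shrinking the direction
error.  Rescaling the full vector instead (available as `mode="full"`)
would trade a small amount of hit-height change against speed change and
preserve the swing height only approximately; the velocity-block form is
the one that actually delivers the variant's stated purpose (shift
attention to hit direction while keeping the bag's apparent inertia).

Projection uses SLSQP on `min ‖x − u‖²` subject to the task's smooth 2-D
residual vanishing, multi-started from the observed point and the most
promising points of a coarse lattice; results are accepted only below
`1e-6 ×` target radius error and verified against a dense-lattice distance
bound in the tests.

## Metrics and filters

MRE (mean distance from bullseye), BVE (RMS distance from the hit
centroid), and centroid bias (distance from bullseye to hit centroid)
separate accuracy from consistency.  With MRE a mean of norms,
`MRE² = bias² + BVE²` does **not** hold; `MRE ≤ bias + BVE` does, and the
RMS-of-norms variant (provided as `rmse`) satisfies the exact Pythagorean
split.  Execution-space centroid bias is the observed centroid minus the
T-cost argmin centroid, per variable.

Trial filters run in a fixed order: gross misses and errors above 15 × the
target radius first (projectile tasks only — falling short produces huge
distances), then errors more than 3 sample SDs from the mean of the
surviving trials.  Flags are recomputed deterministically from the error
cache, so the filter is idempotent.  Note the outlier inflates the SD it is
judged against: in a 20-trial block a 4-SD-of-base outlier is typically
*not* flagged (its included z-score drops below 3); around 40 trials it is.
Flagged trials are never dropped from the data, only marked.

Trajectory windows are evaluated on the sampled grid with no interpolation
(tracker data is discrete): on-target time is the longest contiguous run of
samples ending at the strike whose instantaneous velocities map to errors
below the target radius (position-based variables frozen at the trial's
values; a run of only the strike sample counts one sample period), and the
pre-execution lateral speed is averaged over the contiguous run with speed
above 20 % of strike speed.  Both the signed mean and the mean magnitude of
the lateral velocity are reported, since both conventions are in use.

## Synthetic data

Trial-to-trial scatter is a truncated multivariate normal around a strategy
point — the standard unstructured-motor-noise assumption; rows outside the
physical domain (e.g. hit heights off the bag) are redrawn.  Practice is
geometric decay of the centroid's offset from the optimum (bias decay) and
of the noise SD (noise decay) across blocks.  Presets place 25 (BA) or 30
(RS, PB) trials per condition — the reference block sizes — with BA bias
(+0.076 normalized chest, +0.104 normalized draw) and SDs (0.074, 0.14)
taken from the reference cohort's near-lean values; RS and PB spreads are
not published and were chosen once as realistic (RS σ = (0.35, 0.35, 0.60)
m/s; PB σ = (0.25, 0.25, 0.05)).  All randomness flows from
`numpy.random.Generator` (PCG64) streams derived from a single integer
seed via `SeedSequence([seed, block_index])`, so identical seeds give
identical data across platforms.

Generated trajectories hold the lateral velocity component constant at its
strike value through the approach (striking movements build forward and
vertical speed while keeping a steady lateral drift), which gives window
statistics exact ground truth; the default profile then holds the strike
velocity through the final second, with a bell-shaped overshoot-and-settle
variant for more lifelike speed histories and a step-profile helper for
constructing exact on-target suffixes.

What passing tests on synthetic data do **not** show: the generator has no
biomechanics (no joint limits, no elbow-singularity effects near maximal
reach, no speed–accuracy coupling), no temporal structure within a block
(trials are exchangeable), and Gaussian noise where real execution
distributions can be skewed.  Results about *recovering planted structure*
transfer to real data; results about the *size* of effects do not.

## Numerical choices and edge cases

* Gross misses are `+inf` error plus a flag, never silently dropped;
  filtering is the metrics module's decision.
* Scalar PB evaluation raises an input error for a hit height off the bag
  (no contact), but the goal function's error path reports a gross miss
  instead of raising, and the vectorized batch path scores such rows `+inf`
  so grid searches degrade gracefully.
* N-cost shrink factors stop at 0 (no expansion beyond the observed
  spread); ties resolve to the largest factor.
* C-cost accepts only strict improvements, guaranteeing termination.
* Angle errors use `atan2`-based magnitudes, well conditioned where
  `arccos` of a dot product loses half the working precision.
* CSV round trips are bit-exact (full-precision serialization,
  `float_precision="round_trip"` parsing).

## Known limitations

* The T-cost exact mode on the full reference RS grid (~2.6 M lattice
  points) is exhaustive by design and costs minutes; the coarse-to-fine
  mode is the practical default above 5·10⁵ points and is exact only up to
  the refinement neighbourhood.
* Manifold projection is a local-search method; pathological error
  surfaces with distant disconnected manifold branches could defeat the
  multi-start seeding.  All three shipped tasks have well-behaved residuals.
* Expected T-cost under pure bias decay is not guaranteed monotone when
  the noise spans strongly asymmetric parts of the error surface (the bow
  task's short-draw branch is steep); the monotone-recovery tests use
  noise scales small against the surface curvature.
* Error *amplification* (`c > 1`) works mechanically but is untested
  against any empirical claim.
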