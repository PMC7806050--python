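# Methods

This note documents the models and numerical choices behind `armreach`:
what is computed, under which assumptions, and why the defaults are what
they are.

## Arm model

The arm is two rigid segments with three degrees of freedom: shoulder
pitch `q1` (positive = downward rotation), shoulder yaw `q2` (positive =
toward the body midline/board) and elbow flexion `q3` (zero = fully
extended).  Shoulder roll is deliberately absent: point-to-point reaches
barely use it, and dropping it makes the inverse problem far cheaper.
The frame is shoulder-centered and right-handed: `+x` along the fully
stretched zero-posture arm (lateral), `+y` the facing direction (the
reaching board lies in a plane of constant y), `+z` up.

Dynamics follow the Euler-Lagrange equations
`tau = M(q) q̈ + C(q, q̇) q̇ + G(q)`, with `C` assembled from Christoffel
symbols so that `Ṁ − 2C` is skew-symmetric.  The closed-form expressions
are derived symbolically (sympy) once per process and compiled to
vectorized numpy callables; `M`, `G` and `∂M/∂q` are evaluated in a
single fused call because they share almost all trigonometric
subexpressions (this matters: dynamics evaluation dominates the optimal
control runtime).  Correctness is checked against an independent
finite-difference Euler-Lagrange oracle (numeric differentiation of
kinetic and potential energy).

Segments are modelled as thin solid cylinders rather than ideal slender
rods.  An ideal rod has zero axial inertia, and at `q2 = 90°, q3 = 0`
the pitch axis aligns with the arm axis, which would make `M(q)`
singular; a 4 cm segment radius keeps `M` positive definite over the
whole admissible box.  Default anthropometry (upper arm 0.30 m / 2.1 kg,
forearm 0.33 m / 1.65 kg, centers of mass at 45% of segment length) is
mid-range adult; every value is per-subject configurable, and results
that depend on them are configuration-sensitive by nature.

Joint limits default to `q1 ∈ [−90°, 90°]`, `q2 ∈ [−10°, 120°]`,
`q3 ∈ [0°, 150°]`.  All twelve tabulated starting postures are interior
points of this box.

Marker-to-angle conversion inverts the forward kinematics of the
shoulder→elbow and elbow→wrist directions; rotation of the forearm plane
about the upper-arm axis (the neglected roll) is discarded.  Because the
upper-arm direction determines `(q1, q2)` only up to the branch swap
`(q1 ± π, ±π − q2)`, the branch with `|q1| ≤ 90°` is selected — the
pitch limit makes it the only admissible one.  Angles are radians
internally and degrees at every file/CLI boundary.

## Cost library

Five basic cost functionals are evaluated on sampled trajectories:
squared Cartesian wrist jerk (HJ), squared joint jerk (JJ), squared
torque rate (TC), the kinetic-metric path length `∫ sqrt(q̇ᵀ M q̇) dt`
(Geo), and absolute mechanical work `∫ Σ|q̇ᵢ τᵢ| dt` (Enr).  Integrals
use trapezoidal quadrature on the trajectory grid.  Derivatives not
supplied by the caller are taken with a 7-point moving quintic
(Savitzky-Golay) filter rather than repeated central differences:
repeated `gradient` calls lose two orders of accuracy at the interval
ends, exactly where the jerk of a reach peaks, and misestimate the hand
jerk of a quintic reach by ~20%; the local quintic fit is exact there.

The composite cost is `J = Σ S_i α_i J_i`.  The scalar factors `S`
balance the five costs — whose native units differ by many orders of
magnitude — into a common range.  For a given task the five single-cost
optimal trajectories are computed, `J_i,max` is the largest value of
cost `i` across them, and `S_i = J_JJ,max / J_i,max` with the joint-jerk
factor anchored at 1, so each balanced cost `S_i J_i` spans
`[0, J_JJ,max]`.  (The anchoring at joint jerk reflects that it has the
largest raw range.)  Without this balancing, the geodesic and energy
weights are numerically invisible (`S·J` ratios of 1e−7) and cannot be
identified.  Factors are recalibrated whenever either boundary
configuration changes.

Inside gradient-based trajectory optimization the absolute value in the
energy integrand is smoothed as `sqrt(x² + ε²) − ε` with `ε = 1e−6`, and
the geodesic square root as `sqrt(· + 1e−16)`; evaluation for reporting
keeps the exact forms.

## Optimal control transcription

The reach OCP asks for joint trajectories from a start to an end
configuration in time `T` minimizing the balanced composite, subject to
the arm dynamics and joint-angle box limits, with rest-to-rest boundary
conditions (a free-end-rate variant is available by flag).  The arm is
fully actuated, so the dynamics never constrain the reachable paths:
any C³ joint trajectory is realizable, with torques given by inverse
dynamics (differential flatness).  The transcription therefore
parametrizes each joint trajectory directly — a quintic rest-to-rest
interpolant plus corrections in the bump-polynomial basis
`s³(1−s)³ P_k(2s−1)` (`P_k` shifted Legendre), which vanish with their
first two derivatives at both ends — and minimizes the composite as a
smooth unconstrained function of the 3×K coefficients (L-BFGS-B,
deterministic start at the quintic interpolant, i.e. zero coefficients).
Basis columns are rescaled to unit jerk RMS; without this
preconditioning the smoothness costs are badly conditioned and the
optimizer stalls millimeters away from the optimum.  Joint limits enter
as a smooth quadratic hinge penalty (weight 1e7); in practice reaching
solutions are interior and the penalty is inactive.

Dynamics residuals are zero by construction; the reported solution
quality criteria are boundary-condition satisfaction and the
grid-refinement stability of the optimal cost.  The Cartesian jerk
needed by the hand-jerk cost is evaluated exactly through a
symbolically derived chain rule (third time derivative of the forward
kinematics); numeric third differentiation of the wrist path biases the
optimum by several millimeters.

Defaults: 50 grid nodes, 6 basis corrections per joint, duration taken
from the observation being explained (1 s for synthetic tasks) — time
alignment in the fitting metric absorbs speed differences anyway.

## Trajectory distance

Classic symmetric dynamic time warping over pointwise Euclidean
distances in 3D, no window, unit step weights; both the raw accumulated
distance and the per-step normalized value are reported, and the
fitting objective uses the raw value.  A brute-force enumeration over
all admissible warping paths serves as the test oracle.  Observed
reaches are compared as *relative end-effector trajectories*: observed
joint angles re-projected through the model's own kinematics, which
removes arm-length mismatch and torso translation.

## Inverse optimal control

The weight vector is recovered by bi-level optimization: the upper
level searches `α` (joint-jerk component fixed at 1, the other four in
[0, 1]); each evaluation solves the OCP and measures DTW to the
observation.  The search method is COBYQA — a deterministic
derivative-free quadratic-model trust-region method of the Powell
family — run three times from `(0.5, 1, 0.5, 0.5, 0.5)` with initial
trust radii 0.15, 0.3 and 0.45; the best run wins and the result is
normalized to the simplex.  If a component exceeds one, the run is
restarted with that component fixed to one and the joint-jerk weight
freed (when two exceed one simultaneously, the larger is fixed).  "One
iteration" is one trust-region step; the `2n+1` evaluations that build
the initial quadratic model are not counted against the iteration
budget.  OCP solutions are memoized on `α` rounded to 1e−4, and every
lower-level solve after the first is warm-started from the *first*
evaluation's optimal coefficients — a fixed start, so the rollout
remains a well-defined deterministic function of `α` (warm-starting
from the previous candidate would make the search objective
path-dependent and measurably misleads the trust-region model), while
roughly halving the fit time.

The *search* objective is DTW with squared local distances.  The
Euclidean-DTW surface is piecewise linear (V-shaped) along its valley
floor, which stalls quadratic interpolation models well away from the
minimizer; the squared variant is locally quadratic with the same
perfect-match minimizer, and recovers planted weights several times
more accurately at the same budget.  All *reported* distances remain
plain Euclidean DTW.

Only local optimality is claimed: the bi-level landscape is non-convex
and partially flat (weight combinations trading off against each other
within sub-millimeter trajectory differences), so recovery is judged by
tolerance.  Identifiability varies across tasks; recovery experiments
use reaching tasks from the experiment design (posture-to-board
reaches), where the five models' predictions genuinely differ.

## Movement primitives

Wrist trajectories (the only predicted marker) are encoded per axis as
`y(z) = φ(z)ᵀ ω` over a linear time-to-phase map `z ∈ [0, 1]`, with 15
normalized Gaussian radial bases per axis (width `2/(n−1)`), and a
Gaussian `N(μ_ω, Σ_ω)` over weights representing trial-to-trial motor
variability; axes are independent blocks.  Fitting is per-trajectory
ridge regression (`λ = 1e−3`) followed by the sample mean and
covariance; the covariance receives diagonal shrinkage of 0.1 times its
mean eigenvalue.  The shrinkage matters: with fewer demonstrations than
bases the sample covariance is singular, conditioning becomes
overconfident, and divergences between successive refits blow up by
orders of magnitude.  With one demonstration (the model-based
initialization) the covariance is the configured large prior `100² I`.
Observation noise is per-axis, estimated from fit residuals, floored at
1e−6.

The marginal at any phase is `N(Φᵀμ_ω, ΦᵀΣ_ωΦ + Σ_y)`; prediction from
a partial observation conditions the weight posterior on the observed
prefix (placed on phases `[0, f]`, default f = 0.3) in closed form and
rolls out the full phase axis with pointwise variance.  Updates append
the observation to the storage and refit; the KL divergence between
successive weight distributions monitors convergence.  The convergence
statistic is the KL *per weight dimension*: the raw KL between refits
scales with the dimension (45 here) and concentrates around `d/2n²`
from sampling alone, so a dimension-free threshold (0.01, three
consecutive updates) is used.

Weight vectors themselves are not identifiable from trajectories — the
normalized RBF design matrix has condition number ~5e5, so distinct
weights encode visually identical paths.  Recovery tests therefore
compare fitted distributions in trajectory space (mean and covariance
functions through the basis), which is the identifiable content.

## Weight map and hybrid loop

A Gaussian process per weight component maps the stacked boundary
configuration `(q_s, q_e) ∈ R⁶` (raw radians, standardized) to the
fitted weights: anisotropic squared-exponential kernel plus a noise
term, hyperparameters by marginal likelihood from a fixed start.
Predictions use the mean only (the variance is a diagnostic — too little
training data to trust it), clipped to [0, 1] and renormalized to the
simplex.  Per-subject adaptation appends the subject's fitted weight
vector and refits a copy; the population model is never mutated.

The hybrid session initializes a single-demonstration ProMP from the
OCP rollout under the predicted weights (wide prior), predicts each
incoming reach from its first 30% with the pre-update model (honest
forecasting), then absorbs the observation.  No correction for shoulder
drift or arm-length mismatch is applied at initialization — the first
prediction is allowed to be wrong, and the update loop absorbs the
error within a few observations.  Predictions are rolled out at the
incoming observation's own sampling — comparing point sets of different
resolutions would floor the DTW error at the coarser spacing regardless
of accuracy.  When observations arrive as full marker frames, the
session also stores each reach's *relative* end-effector trajectory;
after convergence the mean of that relative distribution (sampled at
the task's node count, again for resolution-matched comparison) is
fitted by inverse optimal control and the per-subject weight map
updated.  Fitting the lab-frame mean instead would launder the
arm-length and drift mismatch into the recovered weights.  The report
includes the DTW errors of the before/after rollouts against the
converged mean.  The update runs
synchronously; callers wanting a live session during the (expensive)
IOC job should dispatch it to a worker process.

## Discomfort analysis

The discomfort of a task combines, in degrees, the starting shoulder
pitch (90° = most comfortable, fully stretched down), the starting yaw,
and the pitch change: `Dis = (90 − q1_S)/180 + β1 q2_S/180 + β2
q1_Change/180`.  The weights `(β1, β2)` maximize the R² of a linear
regression of the dynamics-related contribution `C = α_TC + α_Enr` on
`Dis`, by exhaustive grid search over `[−1, 1]²` at resolution 0.005.
Because the one-regressor R² equals the squared correlation and `Dis`
is affine in `β`, every grid cell is evaluated exactly from second
moments — the search is exhaustive without per-cell regressions.  Ties
break toward the smallest `‖β‖`.  "Kinematics-related" means
`α_HJ + α_JJ`; the geodesic weight is reported separately (it mixes
kinematic and dynamic character), so the two contributions need not sum
to one.

## Synthetic subjects

No public recordings exist for the experiments this package models, so
recovery studies run on synthetic subjects built from the package's own
rollouts under a planted weight vector, corrupted by the uncertainty
sources a real pipeline faces: per-reach weight jitter on the simplex
(sd 0.02, planning-level motor variability), additive iid Gaussian
marker noise (sd 2 mm — mocap-scale; the signal-dependent motor noise
of the physiology literature is deliberately not modelled, since the
pipeline treats variance only through the primitive distribution), an
arm-length scale factor (default 1, up to ~8% in mismatch experiments),
and slow sinusoidal shoulder drift (amplitude 1 cm, 0.3 Hz torso sway).
Markers are written at 250 Hz in the mocap TSV dialect; a JSON manifest
records every planted truth and seed, and a fixed seed reproduces files
bit for bit.

The task grid crosses the twelve tabulated starting postures with nine
board targets (3×3, 12.5 cm spacing, board at 80% arm length).  Target
columns sit half a spacing toward the arm side: without a roll degree
of freedom, targets exactly in the reference-point column require
`|q1| = 90°`, the edge of the pitch limit.  The pick-and-place template
repeats 4 targets × 4 placements × 10 times (160 reaches, 40 per
target).

Passing tests on these subjects show that the estimators recover what
generated the data under the modelled uncertainty sources; they cannot
show robustness to what is not modelled (signal-dependent noise,
marker occlusions and relabeling, soft-tissue artifacts, fatigue
drift).

## Problem sizes in the shipped tests

The test and acceptance runs scale the study down to desk scale: OCPs
use 30 grid nodes and 5 basis corrections inside inverse-optimal-control
fits (50 nodes and 6-8 corrections for single solves), the upper level
runs 30 trust-region iterations per radius, recovery uses five planted
weight vectors on one posture-to-board task, and the online experiment
streams 40 synthetic reaches of one pick-and-place task.  These sizes
reproduce the qualitative findings (composite beats singles, error
stabilization within ~5 updates, distribution convergence within ~10)
while keeping a full run in minutes.

## Known limitations

- Local optima in both levels; three radii cover the weight box but
  certify nothing global.
- Weight identifiability depends on the task; near-degenerate reaches
  (tiny amplitude, single-joint motions) leave some weights
  ill-determined, mirrored in flat DTW valleys.
- The discomfort metric is a proof-of-concept linear form; the
  procedure, not any particular fitted `β`, is the reproducible object.
- Anthropometric defaults are population-level; per-subject dynamics
  (masses, inertias) are not estimated from data.
- The ProMP phase map is linear in time; strongly non-uniform movement
  speeds are absorbed only by the DTW-based evaluation, not the model.
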