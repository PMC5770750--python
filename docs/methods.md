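# Methods

## Model overview

`reachopt` simulates goal-directed planar arm reaching as a stochastic
optimal control problem.  A two-joint (shoulder, elbow), six-muscle arm
moves in the horizontal plane; the hand must cross a wall line
(y = 0.6175 m, 95% of arm length straight ahead of the shoulder) inside a
target interval of width W centered at x = 0.  The controller maximizes
the *expected utility*

    J = E[ exp(-MT / gamma) * rho * [hit]  -  upsilon * ∫ ||u_t||^2 dt
           -  w_perp * v_x(crossing)^2 ],

the probability-weighted average over noisy repetitions of a temporally
discounted reward for hitting, minus the muscular effort, minus a penalty
on the endpoint-velocity component parallel to the wall (so that hits tend
to arrive perpendicular to the target surface).  Because motor noise is
signal-dependent, faster movements disperse more and miss small targets
more often; the expected-utility objective therefore couples the
cost-benefit trade-off (discounted reward vs. effort) with the
speed-accuracy trade-off (Fitts' law) in a single criterion.

## Plant

Rigid-body dynamics `q'' = M(q)^-1 (tau - C(q,q') - B q')` with

* inertia `M = [[k1 + 2 k2 cos q2, k3 + k2 cos q2], [k3 + k2 cos q2, k3]]`,
  `k1 = I1 + I2 + m2 l1^2 = 0.169`, `k2 = m2 l1 s2 = 0.0528`, `k3 = I2 = 0.045`
  (masses 1.4/1.1 kg, lengths 0.30/0.35 m, inertias 0.025/0.045 kg m^2,
  COM offsets 0.11/0.16 m);
* Coriolis vector `C = [-q2'(2 q1' + q2'); q1'^2] k2 sin q2`;
* damping `B = [[0.05, 0.025], [0.025, 0.05]]` N m s (all unmodelled
  dissipation); gravity is absent (horizontal plane).

Muscle activations `u ∈ [0,1]^6` are corrupted multiplicatively,
`u~ = u (1 + kappa N(0, I))` with `kappa = 0.3`, clamped back to the unit
box (the declared range of an activation; the raw noise formula alone can
leave it), then mapped to torque `tau = A^T (f_max ⊙ u~)` through the
constant moment-arm matrix `A` (rows 0.04/-0.04 shoulder, 0.025/-0.025
elbow, ±0.028/0.035 bi-articular) and maximum tensions
`f_max = (700, 382, 572, 445, 159, 318)` N.

Integration is semi-implicit Euler (velocity first, then position with the
new velocity) at `dt = 0.002` s; the semi-implicit variant was chosen for
its stability at this step size.  Joint limits
(q1 ∈ [-0.6, 2.6], q2 ∈ [-0.2, 3.0] rad) are enforced by clamping with the
violating joint's velocity zeroed.  Angle convention: q1 from the +x axis
at the shoulder (origin), q2 relative elbow flexion — this puts the target
(0, 0.6175) straight ahead and reachable.

Degenerate inputs: a non-finite state raises immediately; activations
outside the unit box are rejected rather than silently clipped, so
controller bugs surface at the interface.

## State estimation

Feedback of the true state arrives `delay = 10` steps (20 ms) late.  The
estimator blends an open-loop term (previous open-loop estimate propagated
by the noise-free forward model with the efference copy — the pre-noise
command) and a closed-loop term (the delayed true state rolled forward
through the `delay` buffered efference copies):
`x~ = (k1 x~1 + k2 x~2)/(k1 + k2)` with `k1 = 0.2, k2 = 1.0`.  Sensory
noise is neglected, which keeps the estimator simpler than a Kalman
filter; with a noise-free plant the estimate is exact.  During the first
`delay` steps no delayed observation exists; the closed-loop term then
rolls the (exactly known) initial state forward through all commands
issued so far.  The open-loop term evolves independently for the whole
movement and is never re-anchored to the combined estimate.  The
`delay`-fold forward-model iteration is computed exactly at every step;
no learned surrogate approximates it.

## Controller and policy search

One feed-forward network per (start point, target width): 4 inputs
(joint angles mapped affinely onto [-1, 1] by the joint limits; joint
velocities divided by a fixed 20 rad/s scale), `N_h = 10` tanh hidden
units, 6 logistic outputs — activations are in [0,1]^6 by construction,
with no clipping.  116 parameters, initialized uniformly on [0, 0.1].
Activation functions and input scaling are the package's own choices
(tanh/logistic keep the action box exact; the scaling keeps units in the
squashers' sensitive range and makes parameter vectors transferable).

Parameters are searched by an in-package (mu/mu_w, lambda)-CMA-ES
(weighted recombination of the best half, cumulative step-size adaptation,
rank-one + rank-mu covariance updates).  Published operating point:
`sigma0 = 0.01`, popsize 30, up to 5000 iterations, `repet = 50` rollouts
per candidate evaluation.  Candidates are ranked by their `repet`-rollout
mean utility; no re-averaging across iterations, no common random numbers
across candidates (plain independent seeding keeps the estimator
unbiased), and stopping is by iteration count only.  The returned policy
is the best evaluated candidate, making the best-so-far objective
non-decreasing by construction.  Seeding is counter-based: the master
seed fans out to per-(iteration, candidate) rollout streams, so runs are
reproducible and a candidate's stream does not depend on the population
size.

## Task and rollout

15 start points on three arcs centered on the target at 15%, 37.5% and
60% of arm length (0.0975, 0.24375, 0.39 m), holding 3, 5 and 7 points
evenly spread over ±45° about the target-to-shoulder axis; four target
widths (5, 10, 20, 40 mm).  Rollouts start at rest exactly at a start
point (within-circle variability of the physical task is not simulated)
and stop at the first crossing of the wall line, located by linear
interpolation within the crossing step (position, time and endpoint
velocity are all interpolated), or at a 4 s timeout — the underlying
formulation is infinite-horizon, so the horizon is a numerical cutoff
chosen long enough that optimized policies never reach it.  A timed-out
rollout scores no reward and keeps its full effort.  Effort is computed
from the raw commanded activations (the quantity the objective penalizes),
not the noisy applied ones, and is not discounted — only the reward term
carries the `exp(-t/gamma)` factor.  Because the movement stops at the
wall, the discounted-reward integral collapses to `rho exp(-MT/gamma)` on
a hit.  Cost weights: `gamma = 0.6` s, `rho = 3000`, `upsilon = 1`.  The
perpendicularity weight `w_perp = 1` makes that term the same order of
magnitude as the effort term for typical optimized movements
(tangential speeds of a few tenths of m/s); its exact form (squared
tangential velocity) keeps it sign-symmetric.

## Numerical implementation

The closed-loop control step costs `delay + 1` forward-model evaluations,
so a policy search executes ~10^7 forward-model steps.  The rollout loop
is compiled with numba; the pure-NumPy operations (`arm`, `estimator`,
`controller` modules) are the reference implementation and the test suite
asserts step-for-step agreement between kernel and reference on shared
noise draws.  All randomness flows through numpy Generators seeded from
explicit SeedSequence hierarchies.

## Synthetic-data scope

The simulator itself generates all data; there is no external input.  The
generator reproduces the study conditions (geometry, noise level, delays,
cost weights above).  It deliberately omits features of real reaching
data: sensory noise, muscle activation dynamics and fatigue, state-
dependent moment arms, the viscous load of a haptic manipulator,
within-start-circle variability, and trial-to-trial learning.  Passing
tests therefore show that the *model* reproduces the targeted phenomena,
not that it quantitatively matches any particular human dataset —
consistent with the model's purpose of explaining qualitative signatures
(Fitts linearity, dispersion scaling, velocity-profile shape).

## Analysis choices

* Fitts regression: ordinary least squares of per-(distance, width) mean
  MT on ID = log2(D/W); movement times of all wall-crossing movements
  (hits and misses) enter the cell means by default — misses still cross
  the wall and their exclusion is switchable (`include_misses=False`).
* Dispersion: 0.5 mm bins with an edge grid symmetric about the target
  center; Gaussian fitted to bin counts by least squares to mirror a
  histogram-based fit, with maximum likelihood on raw crossings as an
  option; the fitted SD is floored at the binning resolution
  (bin width / sqrt(12)) so degenerate samples keep a positive sigma.
* KL divergence between fitted Gaussians in closed form, direction
  KL(model ‖ reference).
* Velocity profiles: endpoint speed via the Jacobian at each stored
  state; a perfectly flat profile reports asymmetry 0.5 by convention.

## Problem sizes used by the test suite and acceptance script

The published campaign (60 optimizations × popsize 30 × up to 5000
iterations × 50 rollouts per candidate ≈ 4.5 × 10^8 rollouts) is the
package's `reproduce --scale full` path.  The test suite and the
acceptance script run a scaled-down campaign chosen as the package's
standard desk-scale configuration: all four target widths, one start per
distance arc (the three on-axis starts), popsize 20, 400 iterations, 10
rollouts per candidate, 100 evaluation rollouts per optimized policy.
Statistics measured at this scale are early points of a long optimization:
orderings that depend on fine endgame control (notably the tightening of
dispersion for the smallest targets and the early-peaked velocity
profiles) emerge late in policy search, and the desk-scale runs show the
optimizer still shortening movement times rather than shaping
deceleration.  See the limitations below.

## Known limitations

* At desk-scale search budgets the optimized policies are ballistic: the
  velocity peak sits near the end of the movement (asymmetry ratio ≈ 0.9)
  instead of early, and movement-time minimization still dominates over
  endgame precision for the far starts.  The early-peak/deceleration
  strategy documented for the full-budget model is a product of a search
  ~100× longer than a test suite can run.
* The best-evaluated-candidate rule under a noisy objective is optimistic
  (winner's curse): recorded best-so-far utilities exceed the re-evaluated
  utility of the returned policy by a Monte-Carlo margin that shrinks
  with `repet`.
* CMA-ES hyperparameters are the standard defaults; no restarts or
  noise-handling extensions (e.g. re-evaluation averaging) are used.
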