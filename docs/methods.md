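# Methods

## Model and units

The simulator integrates a four-state tumor–immune model of intravesical BCG
immunotherapy.  All quantities are dimensionless: cell populations are scaled
by 10⁶ cells, BCG by 10⁶ c.f.u, time in days.  The default rate constants are
the dimensionless estimates for the human parameterization
(μ₁=1, μ₂=0.41, p₁=1.25, p₂=0.285, p₃=1.1, p₄=0.12, p₅=0.003, α=0.52,
β=0.011, r=0.032); dimensional source values are treated as provenance
metadata only, since every downstream quantity in the package is defined on
the dimensionless model.  The default initial state [0.1, 0.1, 0, 0.8]
represents early-stage disease: few effector cells, no infected cells, and a
tumor burden well below the carrying capacity 1/β ≈ 91.

Instillations are impulsive: the dose is added to the BCG state
instantaneously.  The convention is impulse-then-integrate — the dose
scheduled at grid step k jumps B, the post-impulse state is stored as row k,
and RK4 advances to k+1.  The first dose of a regimen lands at t = 0.  A
single global step Δt = 0.01 day is used everywhere (integration, cost
accumulation, surrogate training, control); the step is small enough that
the RK4 error is far below every tolerance in the test suite (fourth-order
convergence is verified explicitly), and a single grid keeps regimen costs,
settling times and surrogate data mutually consistent.

Numerical choices:

* Small negative values from RK4 rounding are *not* clipped; tests assert a
  −10⁻⁹ floor instead, so an integrator bug cannot hide behind a projection.
* Settling time (first time Tu < 1% of its own initial value) is reported on
  the grid without interpolation, so it is quantized to one Δt
  (0.01 day) — negligible against the Monte-Carlo spreads it is compared to.
* A state that becomes non-finite aborts the run with the offending step
  index; randomized training draws that diverge are resampled and counted.
* The inner RK4 loops are compiled (numba); the Monte-Carlo and Sobol
  analyses run tens of thousands of 10⁴-step simulations in seconds, and the
  settling-time kernel exits early at the threshold crossing.

## Regimen cost

A regimen (d, g, N) is scored by
w₁·(Σₖ Tu(k)·Δt)/Tu* + λ·d·N + w_N·|N − round(N)| + w_t·Tu(k_t)/Tu*,
with defaults w₁ = 200, λ = 1, w_N = 10⁴, w_t = 10⁵.  Design choices:

* Tu* is the maximum of Tu over the 100-day horizon of the *untreated* run
  from the same initial state (untreated growth is monotone here, so this is
  the day-100 value, ≈ 16.0 from the default x₀).  Both the stage and the
  terminal term are normalized by it.
* The stage sum is the plain rectangle rule including both endpoints
  k = 0 and k = k_t, exactly as the cost is written.
* N is relaxed to a real number during search.  The *executed* impulse count
  is round(N) (half-up); the λ·d·N and w_N·|N − round(N)| terms use the raw
  N, so the relaxation penalty is continuous and piecewise linear with zeros
  exactly at the integers.
* The terminal tumor-free condition is enforced purely through the w_t
  penalty (a relaxed constraint, not a hard one).
* Treatments scheduled beyond the 100-day horizon are dropped with a
  warning; the dose term still charges the raw d·N, so pushing treatments
  off the horizon is never rewarded.

## Metaheuristics

All three optimizers are box-bounded, fully seeded, dimension-generic, and
budgeted at 200 iterations by default.

**PSO** follows the standard velocity/position updates with inertia
w = 0.5, cognitive and social weights c₁ = c₂ = 0.5, and a 100-particle
swarm; r₁, r₂ are drawn per particle, per dimension, per iteration.
Positions are clamped to the box (velocity left untouched), which lets the
swarm settle exactly on active bounds.  Velocities are initialized uniformly
in ±(upper − lower): with these strongly contracting coefficients a swarm
started at rest collapses before it has explored the basin structure, and
the measured best-cost distribution across seeds is markedly worse (see the
limitation note below).  One particle starts at the reference initial point
(2.2, 10, 3).

**Simulated annealing** runs an epoch of 20 Gaussian proposals per
temperature level (componentwise sd = 0.1 × range, reflected at the bounds),
Metropolis acceptance exp(−Δc/T), T₀ = 1 and geometric cooling 0.95 per
level.  With probability 0.3 a proposal replaces the treatment-count
component by an exact ±1 integer step from the current rounded count.  The
integrality penalty w_N = 10⁴ digs wells at integer N whose width is ~10⁻³
in N; isotropic Gaussian proposals essentially never land in a *different*
well, so a purely Gaussian chain freezes in whichever well it first touches.
The integer step is the natural neighborhood for a variable whose executed
value is an integer.

**ACO** discretizes each variable into a layer of levels (dose in 0.1
steps, gap and count at integers for the regimen box; 21-point grids for
generic problems), with selection probability ∝ pheromone^α · heuristic^β
(α = β = 1), evaporation 0.1, deposit Q/cost (Q = 1), 50 ants.  The prior
heuristics favor low dose (1/d), long gaps (g) and few treatments (1/N) —
a "cheap regimen" prior that the pheromone updates override where the cost
disagrees.  Costs are assumed positive (true for the regimen cost by
construction).

Known limitation: on the default box the cost landscape's global optimum sits
at (6.4, 5, 7) with cost ≈ 74, inside an integer-N needle.  ACO reaches it by
construction (integer grid) and the integer-step SA kernel reaches its 74–77
neighborhood reliably, but vanilla PSO — which has no mechanism to land on
an interior integer exactly — typically returns 80–88.  A comparison that
expects PSO to dominate the other two therefore does not hold when all three
are implemented at full strength; PSO's characteristic solutions have the
treatment count pinned at a *bound* (e.g. N = 10), where clamping makes
integrality free.

## Koopman surrogate and receding-horizon dosing

Training data are 100 randomized 100-day simulations: initial states with
B, E, Ti ~ U[0, 0.5] and Tu ~ U[0.1, 1], impulses every 5 days with doses
~ U[0, 6.4] — the operating envelope both controllers live in.  The extended
state [yₖ, yₖ₋₁, yₖ₋₂, uₖ₋₁, uₖ₋₂] (output = Tu, one delay unit) is lifted
with 10 thin-plate-spline RBFs ψ(r) = r²·log r (ψ(0) = 0 by limit) centered
at seeded k-means centroids of the pooled extended states; lifted dimension
5 + 10 = 15.  A_lift and B_lift solve the one-step least-squares problem on
all lifted sample pairs, and C_lift separately regresses the full four-state
vector on the lifted state (the controller's stage cost weights the state
vector, so the projection maps to all four states, not just the output).
Plain pseudo-inverse by default; a ridge (off by default) is available for
conditioning.  The first two steps of each trajectory lack full lag history
and are dropped.  Multi-step prediction iterates the lifted recursion
linearly — the dictionary is applied only to the initial condition.

The baseline for surrogate accuracy is a first-order Taylor model at the
trajectory's initial state, discretized with the *same* RK4 step (for an
affine system the RK4 step equals the degree-4 truncation of the matrix
exponential, precomputed once).  On a held-out randomized run the surrogate's
100-day output RMSE is ~0.05 versus ~0.7 for the Taylor model, which inherits
unsaturated exponential growth from the linearization point.

The controller solves, every 5 days, a condensed QP over the next impulse:
stage weight Q = diag(0, 0, 0, 1000) on the state error, input weight
R = 0.1, dose box [0, 6.4] (the lower bound deliberately lets the controller
skip treatments; the clinical per-treatment minimum 2.2 is available in
config), prediction horizon 5 days on the Δt grid, control horizon one move.
The tracking reference decays as Tu(0)·e^(−t) on the Tu channel from
treatment start.  The terminal weight solves the discrete-time algebraic
Riccati equation posed in lifted coordinates with Q_lift = CᵀQC, so the
equation is well-posed on (A_lift, B_lift); scipy's direct solver is tried
first, then fixed-point Riccati iteration, and on failure the controller
falls back to Q_lift with a warning.  Because only the first move in the
horizon is free (inputs are impulsive), the QP is condensed onto the move
variables; the box-constrained problem is solved by a dense primal
active-set method with a KKT-residual check (verified against a grid-search
oracle in tests).  Measurement history before t = 0 is padded with the
initial output and zero inputs.

## Uncertainty and sensitivity analysis

Both analyses treat a *fixed open-loop dose schedule* (by default the
weekly-style regimen (5.46, 5, 10)) as the treatment under study.

Monte-Carlo uncertainty (200 runs, seeded): parameter mode draws each rate
from Normal(μ, (0.1μ)²) with negative draws *resampled* (not clipped — rates
must stay positive, and clipping would pile probability mass at zero for the
small-μ rates); initial-condition mode draws each state component from
Uniform[x₀/1.1, x₀/0.9], the band implied by ~90%-accurate imaging.  The
output is the settling time; mean and sd are computed over settled runs,
non-settlers are counted separately and flag the result when they exceed
half the runs.  A pointwise mean ± 1.96·sd band of Tu(t) is also returned.

Sobol sensitivity: 11 factors (ten parameters plus a single scale factor on
the whole initial state, which captures measurement-scale uncertainty
without exploding the factor space), each Uniform(0.8×, 1.2× nominal).
Sampling is the Saltelli A/B/AB_i design on scrambled Sobol' sequences
(n_base = 1024 by default, a power of two for balance; cost
n_base × 13 runs).  Both indices use the Jansen estimators
(S_i = 1 − mean((f_B − f_ABi)²)/2V, S_Ti = mean((f_A − f_ABi)²)/2V), which on
this problem have bootstrap confidence intervals an order of magnitude
tighter than the plain correlation-form first-order estimator (±0.04 versus
±0.4 for the dominant factor at n = 1024).  Runs that never settle are
imputed at the 100-day horizon (keeping the design balanced) and counted.
Bootstrap 95% intervals are reported per factor.  The estimator is validated
against the closed-form Ishigami indices in the test suite.

## What the synthetic conditions do and do not show

All data in this package are generated by the model itself: the study
conditions are the dimensionless parameterization above, the default initial
state, and the stated perturbation laws.  Passing tests demonstrate that the
pipeline reproduces the model-implied quantities (costs, settling
statistics, sensitivities) under those conditions — they say nothing about
biological fidelity of the four-state model, about inter-patient variability
beyond the assumed 10%/±10% laws, or about dosing safety.  The Koopman
surrogate is trained and evaluated on the same operating envelope; its
accuracy degrades for initial states or dose patterns far outside it.

## Problem sizes

Defaults used throughout: 100-day horizon at Δt = 0.01 (10⁴ steps);
optimizer budgets 200 iterations (PSO 100 particles, SA 20 moves per
temperature, ACO 50 ants); 200 Monte-Carlo runs per uncertainty mode; Sobol
n_base = 1024 (13,312 model runs); 100 training trajectories for the
surrogate.  These match the study conditions; the test suite uses smaller
designs only where a property (not a reported value) is being checked.
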