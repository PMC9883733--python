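# Methods

## Model and observation layer

hieropt estimates parameters of ODE models

    xdot = f(x, theta, u),   x(0) = x0(theta, u)

observed through datapoints

    ybar_i = s_i * h_i + b_i + eps_i,   eps_i ~ N(0, sigma_i^2),
    h_i = T( g_{o(i)}(x(t_i), theta, u) )

where `g_o` is the unscaled observable formula of observable `o` (any
symbolic expression in states and parameters, e.g. a stoichiometric
combination `sum_l k_l x_l`), and `T` is an optional `log2`/`log10`
transformation applied before the statics.  Experimental conditions
override condition variables or pin model parameters to constants; each
condition is simulated independently and contributions are summed.  Model
time starts at 0 and measurement times are nonnegative; no steady-state
pre-equilibration or event handling is provided.

The objective is the Gaussian negative log-likelihood

    J = 1/2 sum_i [ log(2 pi sigma_i^2) + (ybar_i - (s_i h_i + b_i))^2 / sigma_i^2 ]

in nats.  A config flag (`omit_constant_terms`, default off) drops the
`log(2 pi sigma^2)` terms, which is only meaningful when all noise
parameters are fixed.

## Static-parameter groups and analytic validity

Each measurement names at most one scaling group, any number of additive
offset groups, and at most one noise group; a missing group means the
defaults s=1, b=0, sigma=1.  Each group is declared `analytic`, `numeric`
or `fixed`.  The validator decides *analytic eligibility* from the index
sets alone (never from measurement values):

- **A1** — an analytic scaling group and an analytic offset group that
  share any datapoint must cover exactly the same datapoints; they are then
  solved jointly.
- **A2** — if a scaling/offset group touches an analytically estimated
  noise parameter, all its datapoints must lie in that single noise group
  (the unknown sigma is then constant within the group and cancels from the
  formulas).
- **A3** — when every sigma in the group is already known (fixed, numeric,
  or the default), the sigma-weighted formulas apply as-is, so the group
  may span several known-noise groups.
- **A4** — within one kind, analytic groups must be disjoint: a datapoint
  carrying two analytic offsets is unidentifiable and is reported as a
  structural error.  Non-analytic offsets may stack freely; this is exactly
  the situation of median-centered proteomics data, which carries one
  per-protein and one per-cell-line offset per datapoint, of which only the
  per-protein layer (nested in the per-protein noise groups) can be
  analytic.

Requesting `analytic` for an ineligible group is an error; there is no
silent demotion.  Datapoints with missing measurement values are dropped at
load time (with a logged count), not imputed, since the index sets are
defined over observed datapoints only.

## Inner problem

Given the simulated `h` at fixed `theta`, stationarity of J in the statics
gives per group

    s_alpha   = ( sum h_i^2 w_i )^-1 sum (ybar_i - b_i) h_i w_i
    b_beta    = ( sum w_i )^-1       sum (ybar_i - s_i h_i) w_i
    sigma_g^2 = mean_i r_i^2,        w_i = 1 / sigma_i^2

with the coupled case (identical scaling/offset index sets) solved as a
sigma-weighted least-squares line fit.  The weighted coupled form is used
even when known sigma values differ within the group — a strict
generalization of the coincident-sigma case, and verified against a 2-D
numeric minimizer in the tests.  When the group's sigma is itself analytic
the weights are uniform (A2 guarantees a single unknown sigma, which
cancels).  Order of computation is fixed: scalings/offsets first, then
noise parameters from the fully resolved residuals; under the validity
assumptions no fixed-point iteration is needed.  With an offset fixed, the
coupled routine takes the reduced single-scaling code path, so the two
paths agree bitwise.

Degenerate groups (all `h_i` zero for a scaling; constant `h_i` for a
coupled fit; fewer than two points for a coupled fit) raise errors naming
the group rather than returning arbitrary values — they signal an
unidentifiable group the user must fix.

At a perfect fit the likelihood is unbounded in sigma; sigma is therefore
clipped from below at `sigma_floor` (default 1e-10, configurable) and the
clip recorded.  Every inner solve verifies stationarity of the analytic
coordinates (max |grad| <= 1e-8 (1+|J|)) and positive semidefiniteness of
the per-group inner Hessian blocks; cross-terms between the (s, b) blocks
and sigma vanish at stationarity, so the block check is exact there.

## Gradients

The reduced objective is `Jhat(theta) = J(theta, s(theta), b(theta),
sigma(theta))`.  Because the inner optimum is exactly stationary, dJhat/
dtheta equals the partial theta-gradient of J at fixed optimal statics
(envelope property); analytic sigma contributes no extra terms.
Numeric-mode statics are outer coordinates and receive their explicit
partials.  Three routes are provided:

- **forward** — the variational system for dx/dtheta is integrated jointly
  with the states; dh/dtheta follows by the chain rule through the
  observable formula and transformation (for log2, a factor 1/(g ln 2)).
- **adjoint** — after the inner solve, the adjoint ODE `pdot = -(df/dx)^T p`
  is integrated backward piecewise from the last measurement (p = 0
  beyond), with jumps `p += (dJ_i/dx)^T` at measurement times built from
  the residual weights of the *optimal* statics.  The gradient is the jump
  terms' explicit parts plus `int p^T (df/dtheta) dt + p(0)^T dx0/dtheta`.
  The quadrature runs over the dense interpolants of x and p (scipy
  `quad_vec`), so the backward ODE state is exactly `n_x`-dimensional —
  its cost does not scale with the parameter count.
- **finite differences** — central differences of the full outer objective,
  which re-solves the inner problem at each perturbation; agreement with
  the fixed-statics gradient is therefore a direct check of the envelope
  property, not merely of the integrator.

Sigma-clipped groups break the envelope property locally; the gradient then
treats sigma as a constant at the floor (one-sided validity) and the clip
is surfaced in the evaluation trace.

All model Jacobians (df/dx, df/dtheta, dh/dx, dh/dtheta, dx0/dtheta) are
derived symbolically with sympy at compile time, so the adjoint jump
conditions are exact.  The backward pass interpolates the stored forward
solution (dense output) rather than re-simulating from checkpoints; the
benchmark problems comfortably fit in memory, and the interface leaves room
for checkpointing.

## Numerical choices

- Integrator: scipy LSODA with analytic Jacobian; defaults rtol 1e-8,
  atol 1e-12 (gradient-accuracy checks in the tests tighten this to 1e-10 /
  1e-14, and long multistart runs may relax it via `OptimizerConfig`).
- A state-magnitude guard (1e120) aborts integration quickly near
  finite-time blow-up; any simulation failure maps to an infinite objective
  with a recorded reason so multi-start continues, rather than raising.
- Adjoint quadrature tolerance 1e-10 (absolute and relative) per segment.
- Central finite differences use steps around 1e-4 on the scaled
  coordinates: large enough to stay above the solver-noise floor, small
  enough to keep truncation error below the comparison tolerances.
- Optimization scales: dynamic parameters log10 by default (bounds declared
  in linear space), scalings and noise parameters log10, offsets linear.
  Statics without declared bounds use s in [1e-3, 1e3], b in [-10, 10],
  sigma in [1e-3, 1e2].
- Local optimizers: bounded gradient-based scipy methods behind a common
  adapter (L-BFGS-B, TNC, trust-constr), iteration cap 150 by default,
  gtol 1e-6, ftol 1e-10.  TNC's budget caps function evaluations, the
  closest control it exposes.  Failed evaluations inside a run feed a large
  finite objective with zero gradient to the optimizer; a start that ends
  there is reported as failed and the multistart continues.
- Start points are uniform on the declared scales, reproducible from
  (global seed, start id); the dynamic block of a start is identical across
  modes so standard-vs-hierarchical comparisons are paired.

## Synthetic benchmarks and what they show

The generator simulates a registered benchmark at its true parameters and
adds i.i.d. Gaussian noise: `y_i = s_i h_i + b_i + eps_i`, bit-reproducible
per seed, together with an absolute-data twin (same simulations, s=1, b=0)
for the information-loss comparison.  Noise levels default to roughly 10%
of the rescaled-signal spread of each benchmark.  Registered problems:

- `exp_decay` (1 state, 1 parameter, one analytic scaling) and
  `conversion_reaction` (closed-form solvable, no statics) for exact
  checks;
- `cascade3`, a three-state signaling cascade with 8 dynamic parameters, 3
  scalings, 2 offsets and 2 noise parameters (all analytic) over three
  input levels — the third observable carries a small cross-reactivity
  term (`x3 + 0.25 x2`) so that its free scaling cannot absorb a rate
  parameter exactly, keeping all directions identifiable;
- `dataset1_like` and `dataset2_like`, structural skeletons of a
  viability-style dataset (cell-line scalings, one shared noise parameter)
  and a median-centered proteomics dataset (log2 observables built as
  stoichiometric combinations with strictly positive coefficients and
  initial conditions, per-protein offsets and noise parameters, numeric
  per-cell-line offsets).

These benchmarks are deliberately small (at most 5 states) so the entire
suite runs in minutes on one core; the multistart comparisons use 20 paired
starts with the 150-iteration cap.  The generator draws i.i.d. Gaussian
noise only — no outliers, no replicate structure, no real normalization
pipelines — so passing tests certify the estimator's correctness and the
optimization behavior under the stated error model, not robustness to
misspecified noise or to the scale of thousand-state models.

## Known limitations

- Gaussian additive noise only; no Laplace or proportional-error inner
  solutions.
- One scaling and one noise group per datapoint (offsets may stack);
  arbitrary combinations of several scalings per datapoint are out of
  scope.
- No SBML import, unit handling, steady-state adjoints, dosing events or
  second-order derivatives.
- The hierarchical-vs-standard comparison is a stochastic property of
  optimizer trajectories; it is asserted at the median over paired starts,
  not per start.
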