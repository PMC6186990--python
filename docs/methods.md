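# Methods

This note documents the models, algorithms and numerical choices behind
`odeanalyzer`, and what the test suite does and does not establish.

## Problem setting

Integrate-and-fire neuron models are hybrid systems: continuous
sub-threshold dynamics given by ODEs, plus an algorithmic spike/reset rule
that is *not* part of the equations analyzed here. Synaptic input arrives
as discrete events on a fixed time grid of resolution h (the network
communication step); each event adds a stereotyped postsynaptic shape
ι(t − t_spike), scaled by the synaptic weight, to the total input current
or conductance. The package answers one question: given the ODEs, the
shapes and the parameter values, how should the system be evolved from one
grid point to the next?

## Shape canonicalization

A shape is admissible when it satisfies a linear homogeneous
constant-coefficient ODE,  (d/dt)ⁿ ι = Σ_{i<n} aᵢ (d/dt)ⁱ ι.

*Function form.* Order 1 is tested directly: a₀ = ι'(t*)/ι(t*) at the
smallest integer t* ≥ 1 with ι(t*) ≠ 0 (scanning 1, 2, 3, …; bound 100),
accepted iff ι' − a₀ι simplifies to zero identically. For n ≥ 2 the
candidate coefficients solve X·a = ((d/dt)ⁿι(t₁), …), where X is the n×n
matrix of derivatives 0..n−1 evaluated at t = (1, …, n); if X is singular
the whole window is shifted by one (budget: 10 shifts — if no window works,
the derivatives are linearly dependent as functions and a lower order would
have been found). The candidate is accepted only when the ODE residual is
identically zero, so the procedure is sound by construction; orders are
tried up to `max_order` (default 10, far above the published shape
families, which are ≤ order 3).

*ODE form.* The declared order is the number of initial values. Each
derivative's factor aᵢ = ∂rhs/∂ι⁽ⁱ⁾ is extracted; the shape is rejected if
any factor still contains a shape symbol or t (non-linearity /
time-varying coefficient) or if a nonzero residue remains after
subtracting Σ aᵢ ι⁽ⁱ⁾ (inhomogeneity). Only constant-coefficient shape
ODEs are accepted, matching the canonical form above.

*Zero-testing.* Symbolic checks use canonical simplification; where the
simplifier is inconclusive the expression is evaluated at deterministic
rational points with 50-digit arithmetic, treating any sample clearly away
from zero (> 1e−30) as a refutation. Double-precision rounding can
therefore never masquerade as a symbolic zero.

## Classification and routing

dV/dt = r(V, …) is linear constant coefficient iff ∂²r/∂V² ≡ 0 and ∂r/∂V
contains no time, state or shape symbol (parameters are fine). The
analytic branch additionally requires the right-hand side to decompose as
vf·V + Σ_s sf_s·s + b with parameter-only factors sf_s and a parameter-only
additive constant b: coupling to another *state* variable (as opposed to a
shape) routes the model to the numeric branch, as does any conductance
product g·(V − E). The pipeline makes one global choice — if any ODE fails,
the whole system is evolved numerically — and the analytic branch handles
the single-membrane-equation layout that current-based models use. Additive
constants (resting-potential and bias-current terms) do not block the
analytic branch; they are folded into the closed-form bias update below.

## Exact propagator scheme

For each shape of order n the joint state y with the membrane potential
obeys dy/dt = A·y. The companion form places a_{n−1} … a₀ in the first
row, a shifted identity below, and (sf, vf) in the last row; the exact
one-step map is the matrix exponential P(h) = e^{Ah}, computed
symbolically. For n = 1, and for n = 2 whenever the auxiliary root
x = −a₁/2 + √(a₁²/4 + a₀) is provably real, a lower triangular variant is
used (state y₁ = ι' + x·ι), which keeps the propagator entries compact;
the transform T mapping the plain derivative vector to y is stored with
the matrix. When the reality of x cannot be established symbolically the
companion form is used — both produce identical trajectories (pinned by a
regression test).

Spikes arriving at a grid point add w·T·(ι⁽ⁿ⁻¹⁾(0), …, ι(0), 0) to the
state, i.e. the shape's initial values scaled by the summed synaptic
weight w; multiple shapes superpose, each with its own propagator, and all
contribute additively to the V update. A constant bias b (units of dV/dt)
adds −(b/vf)(1 − e^{vf·h}) per step; a piecewise-constant bias uses the
same term with the level c_k of the current interval, and reduces exactly
to the constant formula when all levels agree.

The emitted `update_instructions` are strings "target = expression" with
*simultaneous* semantics: every right-hand side reads pre-step values, so
the instruction order cannot introduce bugs.

*Numerical execution.* `evolve_analytic` assembles the one-step update
matrix from matrix exponentials of the parameter-substituted system
matrices rather than by substituting numbers into the general symbolic
propagator entries: the general entries contain removable singularities at
degenerate parameter points (e.g. synaptic time constant equal to the
membrane time constant, where P picks up h·e^{−h/τ} terms), where direct
substitution is ill-defined while e^{Ah} itself is smooth. Exactness is
verified against a tightly-toleranced adaptive oracle (DOP853,
rtol 1e−12) to 1e−8 relative over 100 grid steps of Poisson input.

## Stiffness test

Models on the numeric branch are integrated grid interval by grid interval
over 5 independent trials of 20 time units each, driven by Poisson spike
trains of rate ν = 0.1 events per time unit snapped to the grid
(deterministic given the seed; weight 1.0 per event). Events increment the
shape states by the shape's initial values; models that declare no shapes
receive the weight on every state variable. Two integrations run on
identical inputs:

* **explicit** — scipy's embedded Runge–Kutta 4(5) pair;
* **implicit** — an in-repo semi-implicit midpoint extrapolation stepper
  (Bader–Deuflhard): substep sequence m = 2, 6, 10, 14, 22, polynomial
  extrapolation in the squared substep, error from the two highest
  extrapolation columns, Jacobian computed symbolically from the model and
  frozen per macro step. The method is A-stable at every order, so its
  accepted steps are accuracy- and interval-limited, never
  stability-limited — the contrast the test exploits.

Both use absolute error control at the requested accuracy (default 1e−3;
relative tolerance floored at 100·ε). The first trial step of a run is the
grid resolution h itself, and the controller's step proposal carries over
between intervals, capped by the interval length. Two pieces of step
bookkeeping matter: (i) a proposal inflated by the error estimate of a step
that was merely clipped at a grid boundary is discarded in favour of the
intended proposal, and (ii) sub-ulp "sliver" steps created when a clipped
step undershoots the boundary by one rounding unit are excluded from the
statistics — both are artifacts of finite precision, not controller
decisions, and the second would otherwise trip the machine-precision rule
on perfectly smooth models.

Each run yields the minimal (m) and average (s) accepted step; trials are
aggregated by min and mean. The recommendation follows a fixed tree with
ε the double-precision unit roundoff (≈ 2.22e−16):

| condition | recommendation |
|---|---|
| m_expl < 10ε and m_impl < 10ε | warning (no recommendation) |
| m_expl < 10ε ≤ m_impl | implicit |
| m_impl < 10ε ≤ m_expl | explicit |
| both ≥ 10ε and s_impl > β·s_expl | implicit |
| otherwise | explicit |

A run that aborts with a non-finite state counts as m < 10ε — the abort is
itself evidence of stiffness. β defaults to 6, the conservative end of the
ratio at which implicit and explicit run times break even on the
controlled stiff pair y₁' = a·y₁, y₂' = −2y₂ + y₁ (a = −100), whose exact
solution y₂ = −(1/98)e^{−100t} + (99/98)e^{−2t} mixes a fast and a slow
decay. On that pair the explicit average step is pinned near the stability
limit ≈ 3/|a| while the implicit average tracks the grid interval, so the
ratio s_impl/s_expl grows with both |a| and h; at accuracy 1e−5 the
implicit recommendation appears once the resolution is coarse relative to
the fast timescale (h = 0.2 for a = −100 in the tests), and the ratio is
monotone in |a| (checked over a ∈ {−10, −50, −100, −500}).

## Reference models

The fixture catalog spans the three routings: `iaf_psc_alpha` (analytic),
`iaf_cond_alpha` and `adex_cond_alpha` (numeric, non-stiff at defaults),
`fitzhugh_nagumo`, `morris_lecar` and `stiff_pair` (numeric, stiffness
parameter-dependent). Defaults follow common simulator practice
(τ = 10 ms, C = 250 pF, synaptic time constants 0.2/2 ms for the
integrate-and-fire models).

The FitzHugh–Nagumo fixture V' = V − V³/3 − W + 0.25,
W' = τ(V + 0.7 − 0.8W) exposes τ as its stiffness-controlling parameter;
the default τ = 125 places the recovery-variable rate −0.8τ at −100, the
same fast rate as the stiff benchmark pair, so the oscillator sits in the
regime where the explicit/implicit trade-off is visible within a realistic
sweep of grid resolutions. With that default and accuracy 1e−5 the
recommendation flips from explicit to implicit near h ≈ 0.18–0.19
(seed-dependent within ±0.01), which the acceptance script locates by
bisection. The Morris–Lecar fixture uses the dimensionless gating form
with its printed constants and exposes the rate scale α of the recovery
variable.

## What the synthetic inputs do and do not show

All test inputs are generated: Poisson spike trains emulate stationary
presynaptic bombardment with independent arrivals; they do not reproduce
temporally correlated or bursty input, synaptic depression, or
physiological weight distributions (weights are unit-valued by default).
Passing tests therefore establish the *mathematical* contracts — exactness
of the propagator scheme, soundness of shape detection, reproducibility
and direction of the stiffness verdict — not that a particular biological
parametrization is stiff or non-stiff; the verdict is, by design, a
function of the user's parameters and resolution.

## Known limitations

* Shapes must obey linear homogeneous constant-coefficient ODEs; sums of
  shifted arbitrary functions of time are out of scope.
* The analytic branch covers the single-state-equation layout of
  current-based models; linear multi-state systems with cross-coupling are
  evolved numerically rather than block-diagonalized.
* The stiffness verdict is empirical and seed-dependent near the decision
  boundary; it deliberately uses step-size statistics, not wall-clock time
  or Jacobian eigenvalue estimates.
* Threshold crossing, reset and refractoriness are outside the analyzed
  equations; exact handling of spikes *between* grid points is not
  attempted.
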