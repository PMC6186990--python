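# odeanalyzer

Solver selection and generation for the ODE systems of integrate-and-fire
neuron models.

Point-neuron models couple a membrane equation, e.g. the current-based form

    dV/dt = -V/τ + I(t)/C,

to *postsynaptic shapes* — the stereotyped current or conductance time
courses elicited by incoming spikes, such as the alpha function
ι(t) = (e/τ_s)·t·e^(−t/τ_s). Which integration scheme is appropriate for
such a system is rarely decided systematically: a linear constant-coefficient
system driven by shapes that satisfy a linear homogeneous ODE can be evolved
*exactly* on a fixed time grid, while conductance-based and nonlinear models
need a numeric solver whose type (explicit vs. implicit) depends on whether
the parametrization makes the system stiff. `odeanalyzer` automates that
decision:

1. **Shape analysis.** Each shape, given either as a function of time or as
   an ODE with initial values, is reduced symbolically to the canonical form
   (d/dt)ⁿ ι = Σᵢ aᵢ (d/dt)ⁱ ι. For function-form shapes the order n and the
   coefficients aᵢ are found constructively by solving a linear system built
   from the shape's derivatives at integer times and verifying the candidate
   ODE symbolically. Shapes that admit no such form are rejected with a
   diagnostic.
2. **Classification.** A state ODE dV/dt = r(V, …) is linear constant
   coefficient iff ∂²r/∂V² ≡ 0 and ∂r/∂V is free of time, state and shape
   symbols.
3. **Exact propagator scheme** (linear branch). The joint state
   y = ((d/dt)^{n−1}ι, …, ι, V) obeys dy/dt = A·y, so one symbolic matrix
   exponential P(h) = e^{Ah} per shape evolves the system exactly over a grid
   step h. Spikes enter as state increments (the shape's initial values times
   the synaptic weight), several shapes superpose additively, and a constant
   bias current I_E adds the closed-form term I_E·τ/C·(1 − e^{−h/τ}).
   For shapes of order 1 and 2 the matrix is written in lower triangular form
   for cheaper evaluation.
4. **Stiffness test** (numeric branch). The model is integrated under
   Poisson spike bombardment with an explicit embedded Runge–Kutta 4(5)
   stepper and with a semi-implicit midpoint extrapolation (Bader–Deuflhard)
   stepper, both adaptive. Comparing minimal accepted steps against 10·ε
   (machine precision) and average steps against the threshold ratio β = 6
   yields a recommendation: `numeric-explicit`, `numeric-implicit`, or a
   `warning` when both schemes collapse.

## Input format

A JSON document (or equivalent `dict`) with three sections — `odes`,
`shapes`, `parameters`:

```json
{
  "odes": [
    {"symbol": "V", "definition": "-V/Tau + I/C", "initial_values": {"V": "0"}}
  ],
  "shapes": [
    {"type": "function", "symbol": "I",
     "definition": "exp(1)/tau_syn * t * exp(-t/tau_syn)"}
  ],
  "parameters": {"Tau": "10", "C": "250", "tau_syn": "2"}
}
```

Shapes may instead be given as ODEs with initial conditions:

```json
{"type": "ode", "symbol": "g_ex",
 "definition": "-g_ex/tau_syn_ex**2 - 2*g_ex'/tau_syn_ex",
 "initial_values": {"g_ex": "0", "g_ex'": "exp(1)/tau_syn_ex"}}
```

Expressions use identifiers, `+ - * / **`, parentheses, the functions
`exp`, `log`, `sqrt`, `sinh`, `cosh`, `tanh`, the time symbol `t`, and
primes for derivatives. Euler's number is written `exp(1)`; every free
symbol must be declared in `parameters`. Numeric literals are parsed as
exact rationals so the symbolic zero-tests remain sound.

## Worked example

```python
>>> import json, odeanalyzer as oa
>>> model = oa.make_fixture("iaf_psc_alpha")   # alpha-current IaF neuron
>>> rec = oa.analyse(model, quiet=True)
>>> rec.scheme
'analytical'
>>> print(rec.propagator["update_instructions"][0])
I__x = I__x*exp(-h/tau_syn)
>>> json.loads(oa.write_output(rec))["shapes"][0]["coefficients"]
['-1/tau_syn**2', '-2/tau_syn']
```

The detected shape ODE is ι'' = −ι/τ_s² − 2ι'/τ_s (the alpha function is
order 2), and the emitted update instructions evolve the auxiliary state
`I__x = I' + I/τ_s`, the current `I` and the membrane potential `V` by one
grid step exactly. A conductance-based model routes to the numeric branch
instead:

```python
>>> rec = oa.analyse(oa.make_fixture("iaf_cond_alpha"), seed=1, quiet=True)
>>> rec.scheme
'numeric-explicit'
```

i.e. at the default parametrization the model is non-stiff and an explicit
scheme is the economical choice.

From the shell:

```sh
ode_analyzer model.json --output solver.json
ode_analyzer stiffness model.json --resolution 0.1 --accuracy 1e-3 --seed 1
```

The second form runs the stiffness tester stand-alone even for models that
would be solved analytically.

## Scope

No simulator code generation, no threshold/reset handling (spike detection
sits algorithmically on top of the sub-threshold dynamics analyzed here),
no stochastic or multi-compartment models, and no runtime solver switching.
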