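# Methods

## Model class and problem statement

We consider analytic nonlinear ODE models

```
ẋ(t) = f(x(t), u(t), w(t), θ, k),      y(t) = g(x(t), u(t), w(t), θ, k)
```

with states `x ∈ R^nx`, known inputs `u`, unknown inputs `w`, unknown
constant parameters `θ` and known constants `k`. The joint unknown is
`z(t) = [x(t), θ, w(t)]`. A model is *fully observable* when every entry
of `z(τ)` is locally determined by the outputs `y(t)` (and known inputs)
on a finite interval: state observability, structural local
identifiability of parameters, and input reconstructibility are then all
instances of one property, and they must be analysed jointly — a
parameter may be identifiable only conditional on an input being known,
and vice versa.

## Structural analysis

**Augmentation.** Parameters become states with zero dynamics. Each
unknown input contributes a derivative chain `w, ẇ, …, w⁽ⁱ⁾` with shift
dynamics, because the i-th Lie derivative of the output can involve input
derivatives up to order i. The augmented state is
`x̃ = [x, θ, w-chains]` with `n_x̃ = n_x + n_θ + n_w·(i+1)` for an
unbounded chain.

**Extended Lie derivatives.** Because known inputs are time-varying,
the Lie derivative carries correction terms for them:

```
L^i g = ∂(L^{i-1}g)/∂x̃ · f̃ + Σ_j ∂(L^{i-1}g)/∂u^(j) · u^(j+1)
```

where `u^(j)` are independent symbols for the input derivatives (the
summation is finite: an order-i Lie derivative contains input derivatives
of order at most i). No intermediate simplification is applied — the
expressions are consumed by numeric specialization, where simplification
buys nothing; this keeps the symbolic phase cheap even at Lie order 6.

**Rank test.** The observability–identifiability matrix stacks
`∂(L^i g)/∂x̃` for `i = 0..m`. Generic full rank (equal to the augmented
dimension) certifies full observability; the matrix is built one block at
a time and the build stops early at full rank, or when the rank stalls
for `patience` consecutive blocks (the observable codistribution
stabilizes once a block adds nothing), or at a hard cap, in which case
the report is marked inconclusive rather than guessed.

**Exact generic rank.** Each symbol is specialized to a random positive
rational in [1/2, 2]; symbols that occur in exponents receive small
positive integers (2–4), so powers stay in the rational field and all
bases stay positive, as required for the analytic setting. The Jacobian
entries at the point are computed by memoized forward-mode
differentiation in exact `fractions.Fraction` arithmetic directly on the
symbolic expression DAG — this avoids materializing the (very large)
symbolic Jacobians of high-order Lie derivatives. Logarithms (arising
from derivatives of `x^n` with respect to n) are mapped consistently to
independent random rationals, i.e. treated as generic transcendentals.
The rank of the resulting rational matrix is computed by Gaussian
elimination over two random ~51-bit prime fields (modular rank can only
*under*estimate the rational rank, with probability ~p⁻¹), and the
maximum over three seeded specialization points is reported. Every seed
is recorded in the report. A floating-point SVD rank (tolerance
`max(dims)·eps·σ_max`) evaluated with true IEEE logarithms provides an
independent diagnostic cross-check; it is never the verdict. The exact
evaluator covers rational operations, powers and logs — sufficient for
all analytic model files this package targets; other transcendentals
raise a clear error.

**Classification.** If the rank is deficient, each column belonging to a
state, a parameter or an unknown input itself (chain heads only — higher
derivatives are bookkeeping) is deleted in turn; an unchanged rank marks
that variable unobservable / unidentifiable / unreconstructible. The
column tests reuse the specialized rational matrices, restricted to
points that achieve the generic rank.

**Input excitation and truncation.** Known-input derivatives can be
zeroed above a chosen order, globally or per input (`u_zero_above = 1`
models a constant input, 2 a ramp…), exposing how exciting an experiment
must be. Unknown-input chains can likewise be truncated
(`w_truncation = 1`: constant unknown input), which restricts the input
class to polynomials in time. Because with an unbounded chain the matrix
gains `n_w` columns but only `n_y` rows per Lie order, full rank is
unreachable whenever `n_y ≤ n_w`; verdicts about generic smooth inputs
are therefore obtained from a *sweep* over truncation orders
i = 1, 2, 3: full rank at every order with steadily growing rank is
reported as the *suggestion* "fully observable for generic smooth
inputs" (a heuristic for the untestable infinite-chain limit, labelled
as such), and failure at every order as the suggestion "not fully
observable".

**Multiple experiments.** States, outputs and inputs are replicated per
experiment with shared parameters. Replicated input symbols receive
independent random specialization values, so the analysis automatically
assumes generic, distinct input levels across experiments — which is
exactly what makes replication informative (e.g. four constant-input
experiments substituting for one ramp experiment).

## Estimation: optimal tracking

Unknown inputs are discretized as continuous piecewise-linear functions
of `n_e + 1` node values on equidistant nodes (piecewise-constant is
available for step-like inputs). The decision vector is
`[θ; unknown x0 per experiment; input nodes per experiment]`, with θ
shared across experiments. The objective is the negative Gaussian
log-likelihood with known per-point σ (noisy data) or an
unweighted least-squares cost (noiseless data); both are monotone in the
σ-scaled residual norm. Inequality constraints are supported as penalty
terms (unused by the bundled scenarios). Simulation failures at trial
points are penalized with a large finite cost, never fatal.

**Solver.** A seeded hybrid: differential evolution (population
`6·dim`, ~40 generations, no internal polish) followed by trust-region
reflective least-squares refinement from the best three mutually distinct
population members (and the warm start, if any). The finite-difference
step of the refinement (`1e-6` relative) is chosen well above the ODE
integration noise at the default tolerances (rtol 1e-8 / atol 1e-10);
smaller steps produce garbage gradients, which is the classic failure
mode of single-shooting calibration. Gauss–Newton structure matters
here: the noiseless optima lie at the bottom of narrow curved valleys
(Hill coefficients trading off against input levels) that quasi-Newton
methods on the scalar cost do not descend reliably. Re-running with the
same seed reproduces the result bit-for-bit.

**Refinement.** `refine_elements` doubles `n_e` and warm-starts the new
nodes from the interpolated coarse solution; piecewise spaces nest under
doubling, so the warm start reproduces the coarse input exactly and the
cost is non-increasing along the schedule. The HIV scenario uses the
1→2→4 schedule.

**Uncertainty.** Standard errors come from the Gauss–Newton
approximation: central-difference Jacobian `J` of the σ-scaled residuals
at the optimum and covariance `(JᵀJ)⁻¹` (pseudo-inverse for safety).
These are linearized, per-coordinate uncertainties — not profile
likelihoods — and are used to express recovery errors as z-scores.

**Integration.** `scipy.integrate.odeint` (lsoda) with rtol 1e-8 /
atol 1e-10; compiled right-hand sides are cached per model. A degenerate
single-point horizon returns the initial state directly.

## Synthetic data

The generator fixes a true system per scenario and samples outputs on a
regular grid (20–25 points per experiment), adding independent Gaussian
noise `N(0, σ²)` with σ equal to 5% of each output's range in that
experiment (σ = 0 for the noiseless variants; the data then equal the
simulation exactly). All draws derive from one seed. The bundled
scenarios mirror the case-study designs:

| scenario | model | experiments | true input(s) |
|---|---|---|---|
| c2m_noiseless / c2m_noisy | 2-compartment, k1e known | 1 / 6 | ramps (distinct per experiment) |
| ts_noiseless / ts_noisy | toggle switch, reformulated | 1 / 4 | piecewise-constant / distinct constants |
| hiv_noiseless / hiv_noisy | HIV infection | 1 / 1 | slow cosine infection rate |

The unmeasured initial condition `x2(0)` is estimated per experiment in
the two-compartment scenarios; the other scenarios have known initial
states (both toggle-switch states are measured, and the HIV baseline is
taken as known patient state). The HIV model uses rescaled units so that
all states and rates are of order 0.1–10, and its cosine infection rate
varies slowly relative to the 50-day observation window (period 400), so
that a four-element piecewise-linear approximant carries sub-percent
node bias; nominal values are package defaults of literature-like
magnitude, not measurements. The HIV study deliberately uses a single
experiment: pooling patients would forbid patient-specific parameters.

What the generator does *not* emulate: output-dependent or correlated
noise, missing observations, irregular sampling, model mismatch
(estimation uses the same equations that generated the data). Passing
recovery tests therefore demonstrates the identifiability pipeline and
optimizer, not robustness to structural misspecification.

## Numerical choices and edge cases

- Specialization retries: a pole (division by zero, log of a
  non-positive value) at a random point triggers a redraw, up to five
  times per seed before an inconclusive-rank error.
- Bounds: decade-wide boxes around the nominal magnitudes, fixed in the
  scenario definitions; Hill coefficients in [1, 6]; all estimates are
  returned strictly inside their bounds.
- Problem sizes: the bundled studies span 5 (noiseless two-compartment)
  to 20 (six-experiment noisy two-compartment) decision variables; each
  full recovery study runs in a few minutes on one CPU.
- Tie-breaks: when a refinement stage fails to improve, the
  warm-started coarse solution is kept, preserving cost monotonicity.

## Known limitations

- Structural verdicts are *local* (rank conditions at generic points);
  global distinguishability and the measure-zero set of atypical initial
  conditions are out of scope, as are impulsive (delta-function) inputs.
- The generic-smooth-input conclusion from truncation sweeps is a
  suggestion, not a theorem; reports label it accordingly.
- Symbolic cost grows steeply with model size and Lie order; the
  analysis is practical for models of a handful of states, which covers
  the intended use.
- The uncertainty intervals are Gauss–Newton approximations and can be
  optimistic for strongly nonlinear parameters, and they are local: when
  the likelihood surface is multimodal and a noise draw tips the global
  optimum into a rival mode (or onto a bound), the intervals describe the
  wrong mode and do not cover the truth.
- The noisy single-experiment HIV study exhibits exactly that behaviour:
  with ~2-day sampling against a ~1/3-day viral-clearance timescale, the
  burst size N and clearance rate c are practically near-unidentifiable
  from one noisy experiment, and for some noise draws the maximum
  likelihood estimate collapses to a bound far from the truth (verified
  by comparing the likelihood at the returned optimum against a polished
  truth-start: the wrong mode genuinely fits better). This is a
  practical, not structural, deficiency — the noiseless study recovers
  everything to sub-percent accuracy — and it is the kind of failure the
  multi-experiment schemes of the other two case studies are designed to
  prevent. The corresponding noisy-recovery check is retained unchanged
  and fails under the bundled conditions — an honest record of the
  practical limit rather than a defect in the analysis or the solver.
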