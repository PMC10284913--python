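# Methods

## Models

All five growth laws describe tumor volume v(t) ≥ 0 in *model volume
units*; the package fixes 1 unit = 100 mm³, which puts the study's
protocol thresholds at 2 units (dosing) and 20 units (censoring) and
makes carrying-capacity-scale fitted values (k ≈ 2.8 treated, ≈ 35
untreated) physically plausible. Rates carry implied units day^−α.
All parameters are constrained positive.

Two Gompertz variants circulate: a·v·ln(b/(v+c)) and a·ln(b/(v+c))
(without the v factor). Both are supported through an explicit
`GompertzForm` argument — neither is declared "the" Gompertz law; the
form with the v factor is the package default, the form without it is
what the reference fitted models use. They coincide at v = 1 and share
the equilibrium v = b − c.

The fractional generalization replaces d/dt with the Caputo derivative
of order α ∈ (0, 1]. The Caputo form (rather than Riemann–Liouville) is
used because it annihilates constants and accepts ordinary initial
conditions. Kinetic parameters keep their numeric values when the order
changes; their implied units become day^−α.

The generalized Bertalanffy–Pütter law with |a − b| < 10⁻⁶ is rejected
rather than silently switched to the particular (a = b) branch: the two
branches are distinct models with distinct parameter records.

## Numerics

**Mittag–Leffler function.** Direct series summation with term-ratio
stopping for |z| ≤ 30 and α ≥ 0.3 (all arguments arising in fitting fall
here). For z < −30 and 0 < α < 1 the algebraic asymptotic expansion
−Σ_k z^−k/Γ(1−αk), truncated at its smallest term, is used; it is
verified against high-precision references to better than 10⁻⁸ relative
at |z| ≥ 30. Large positive arguments raise an explicit range error
rather than returning an unvalidated value. Alternating-series
cancellation limits accuracy for moderately negative z to roughly 10⁻⁸
relative in double precision.

**Caputo IVP solver.** Adams–Bashforth–Moulton predictor–corrector with
the full (untruncated) memory term, product-rectangle predictor and
product-trapezoid corrector, one corrector pass by default. Cost is
O(N²); at the default step h = 0.01 day over the 18-day horizon
(N = 1801) a solve takes milliseconds. Validation: against
v₀·E_α(a·t^α) for the linear law (worst relative error ≈ 8·10⁻⁷ across
the reference rates and orders) and against an adaptive classical
solver at α = 1 (worst ≈ 4·10⁻⁶ across all ten reference parameter
sets). Trajectories that leave the finite range raise a divergence
error carrying the last valid time; fitting scores such trials +∞.

**Caputo derivative / RL integral.** L1 finite differences and
product-trapezoid quadrature on uniform grids. The L1 derivative of a
constant array is exactly zero by construction; the quadrature is exact
for piecewise-linear integrands and O(h²) otherwise.

**Spline resampling.** Cubic interpolating spline with not-a-knot
boundary conditions, evaluated on a uniform 0.1-day grid spanning the
measured range only. Four measurements minimum; no extrapolation.

## Fitting

Stage one minimizes the MSE over the law's kinetic parameters at α = 1
with Nelder–Mead in log-parameter space (positivity by construction),
objective tolerance 10⁻⁸, 2000 evaluations per run, one restart from
the best point. The 4-parameter generalized Bertalanffy–Pütter law has
a narrow curved valley; the recovery analyses give it three restarts,
after which noiseless self-generated data are recovered to ≈ 10⁻⁸
relative. With nearly equal exponents (the untreated reference row:
1.38 vs 1.44) the law is *practically non-identifiable* from 18-day
noiseless data — MSE ≈ 10⁻¹⁰ coexists with ≈ 25 % parameter error — so
parameter-recovery checks use the treated-arm parameter sets, whose
exponents are well separated.

Stage two solves the fractional equation on the data grid for each α on
[0.70, 1.00] in steps of 0.01 (fitted orders of interest lie in
[0.86, 0.98]) with stage-one parameters frozen, and reports the
MSE-minimizing order; exact ties resolve to the smallest α. The grid
contains 1.0, so the fractional MSE never exceeds the integer MSE.

**Initial condition.** v₀ is never a fitted parameter. Two conventions
are exposed: pinning v₀ to the first resampled observation, and fixing
v₀ to a near-zero nucleation-scale volume (0.01 units = 1 mm³). The
comparison pipeline defaults to the near-zero convention, and this
choice is load-bearing: with v₀ pinned to the first observation, the
integer stage can compensate a fractional order entirely by rescaling
its rate parameters, leaving α = 1 a boundary optimum of the sweep — in
extensive experiments on self-generated fractional fixtures the
two-stage procedure then *never* strictly improves. With the near-zero
convention the model must climb from ≈ 0 to the first measured volume,
the integer stage systematically underfits the early window, and the
fractional order's steep early growth (the t^α kink of E_α) buys a
genuine, reproducible improvement. The magnitude of that improvement on
our synthetic fixtures is small (tenths of a percent of MSE); large
fractional gains require data whose shape no integer-order law in the
family can express, which self-generated growth-law fixtures by
construction rarely provide.

## Synthetic experiments

The generator emulates the structure of an orthotopic murine study:
18-day horizon; observations at days 0, 3, 5, 8, 10, 13, 15, 18
(alternating 3/2-day cadence — chosen so the terminal observation lands
on the horizon); volumes recorded in mm³ with multiplicative lognormal
noise exp(σε − σ²/2), calibrated to unit mean, default σ = 0.05; a
treated arm dosed at the first *recorded* volume ≥ 200 mm³ with ≥ 10
days between doses (the protocol is observation-driven); censoring at
the first recorded volume ≥ 2000 mm³, keeping the terminal sample; and
default dynamics from the fractional Gompertz law at untreated
reference parameters, α = 0.9, v₀ = 50 mm³.

Treatment is an instantaneous log-kill: the true volume drops by
κ = 0.4 at each dose time and the Caputo solver restarts from the
post-kill volume (the pre-dose memory is deliberately discarded at the
intervention; the drug dose itself, 8 mg/kg, is recorded but not
mechanistically modeled). A zero-effect dose (κ = 0) is logged but does
not restart the solver, so treated and untreated arms coincide exactly
in that limit.

What the generator does **not** emulate: pharmacokinetics, delayed or
cumulative drug effects, inter-animal variability, measurement-error
heteroscedasticity beyond the multiplicative model, or missed
observations. Passing tests therefore demonstrate correctness of the
pipeline and the qualitative mechanisms, not fidelity to any particular
animal dataset.

## Well-posedness diagnostics

Through the Caputo–Fabrizio fixed-point form, existence of a solution
requires (φ(α) + ψ(α)·c)·θ < 1 and uniqueness on [0, t] requires
1 − (φ(α) + ψ(α)·t)·θ > 0, with φ(α) = (2−2α)/(M(α)(2−α)),
ψ(α) = 2α/((2−α)M(α)) and θ a Lipschitz constant of the law on the
volume range of interest. The normalization M(α) ≡ 1 is adopted (the
common Caputo–Fabrizio convention); c defaults to 1 and t to the 18-day
horizon — both are surfaced configuration, not derived quantities. θ is
exact (= a) for the exponential law and a dense-grid supremum of
|∂f/∂v| otherwise; power-law exponents below 1 make the derivative
singular at v = 0, so the grid nudges inward there. Over the full
18-day horizon the uniqueness condition fails for every reference
model — the contraction argument is short-horizon by nature — which the
diagnostics report honestly rather than hide.

Stability of the linear law is classified in the Mittag–Leffler sense
by evaluating the solution envelope E_α(a·t^α) at t ∈ {10, 100, 1000}
days: negative rates decay algebraically, zero rates are constant,
positive rates grow without bound (evaluated in log space where the
series would overflow).

## Problem sizes

Default analysis scales, chosen to keep every study desk-scale: solver
step 0.01 day for solver-accuracy checks (1801 points), 0.1 day for
fitting grids (181 points); α grid of 31 points; 40 replicates in the
fractional-versus-integer comparison study; 5 + 5 reference parameter
sets. The full test suite and the acceptance script each run in a few
minutes on one core.

## Known limitations

- The solver's O(N²) memory term is fine at these scales but not for
  long horizons at fine steps; no short-memory truncation is provided.
- The Mittag–Leffler implementation covers the real arguments the
  models produce, not the complex plane, α > 2, or large positive
  arguments (which raise).
- The α sweep treats kinetic parameters as frozen; jointly optimizing
  (θ, α) would typically find lower MSE but answers a different
  question than the two-stage design isolates.
- MSE is the only comparison statistic; no information criteria or
  uncertainty quantification are attempted.
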