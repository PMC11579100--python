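# Methods

## Problem class

`optidose` computes optimal dose regimens for ODE-based pharmacokinetic/
pharmacodynamic (PK/PD) models.  A model is a parameterized system

    dy/dt = f(t, y, θ, u),    y(t0) = y0(θ),    t ∈ [t0, tf],

with θ estimated beforehand and held fixed.  Doses D = (D1, …, Dm) enter
through a fixed dosing scenario: IV boluses are instantaneous state jumps
y(s⁺) = y(s⁻) + amount·e_k, infusions contribute a zero-order rate
amount/duration to the input vector u while active.  The therapeutic goal is
split into a *top-priority* target, written as a state constraint
g(y(t, D)) ≤ 0 on a window [t1, t2], and a *secondary* target, written as a
cost functional J(D) (an integral or point value of a named observable).
The state-constrained optimal control problem is

    min J(D)   s.t.  the model ODE,  g(y(t,D)) ≤ 0 on [t1,t2],  D_min ≤ D ≤ D_max.

Four constraint kinds are supported, each normalized to g ≤ 0 internally
(lower bounds become `threshold − obs`, upper bounds `obs − threshold`):
pointwise-in-time (*path*), at a single time (*point*), on a window average
(*mean value*), and on the time an observable spends beyond a level
(*duration*).

## Penalty transformation and outer loops

Path violations are penalized by the quadratic (Moreau–Yosida) penalty

    P(D, ρ) = ρ/2 ∫ max{0, g(y(t,D))}² dt,

scalar constraints by ρ/2·max{0, g}².  The penalized objective
OFV = CFV + Σ PFV is minimized over the dose box for a strictly increasing
schedule of penalty parameters ρ (default ×10 per stage), warm-starting each
stage — solutions approach the constrained optimum as ρ → ∞, with the
residual violation of each stage shrinking like 1/ρ for point constraints.
PFV/ρ is reported per stage as a ρ-free violation measure.

The safeguarded augmented-Lagrangian mode replaces the quadratic penalty by
the Powell–Hestenes–Rockafellar function

    P_AL(D, λ, ρ) = 1/(2ρ) ∫ max{0, λ(t) + ρ g}² − λ(t)² dt,

with λ ≥ 0 piecewise linear on a node grid over the constraint window
(default 101 nodes) and the standard pointwise update
λ⁺ = min(max(0, λ + ρ g), λ_max), λ_max = 10⁶.  Scalar constraints carry a
scalar multiplier with the same update.  λ ≡ 0 recovers the quadratic
penalty exactly, and disabling updates makes the loop reproduce plain
continuation bitwise.  On the toy point-constraint problem the multiplier
iteration converges to the analytic KKT multiplier to ~5 digits within four
outer iterations.

## Evaluation of functionals

Cost and penalty integrals are evaluated as augmented quadrature states
integrated alongside the model (initialized at 0, read at tf), exactly like
an AUC.  Integration restarts at every administration, infusion end,
constraint-window endpoint and support time, so windowed integrands switch
exactly at their endpoints and bolus jumps are exact.  max{0, g}² is C¹, so
the penalty integrand is integrated directly without event detection.

The duration functional τ (time below a level) has a discontinuous
indicator right-hand side; by default it is evaluated *exactly* on the dense
solution by bracketing threshold crossings and refining them with Brent's
method.  A logistic surrogate `1/(1+exp((obs−thr)/ε))` (ε = 0.01 in
observable units) and an area-below-threshold alternative
∫max{0, thr − obs}dt are provided for optimizers that struggle with the
non-smoothness.

Default solver: LSODA with rtol 1e-10 / atol 1e-12, both config-exposed;
dense output is reported on ~200 grid points per horizon plus breakpoints.
The heavy end-to-end runs in the test suite and the acceptance script use
rtol 1e-8 / atol 1e-10, which changes the reported functionals only in the
7th significant digit.

## Inner solver

Each penalized problem is solved by projected quasi-Newton (L-BFGS-B) over
the dose box with central finite-difference gradients (per-coordinate step
1e-5·max(|D_i|, 1), one-sided at the box boundary).  Convergence: relative
OFV change below 1e-10 and small projected gradient.  Large penalty
parameters create near-wall curvature ~ρ·(dg/dD)² that can stall the
quasi-Newton line search; if the projected gradient at termination exceeds
1e-4·(1+|OFV|) a bounded derivative-free polish (Powell) is run from the
returned point and kept when it improves the objective.  Starting from
infeasible doses triggers a warning (large violations at large ρ
destabilize both the ODE solver and the line search); warm-started
continuation stages, which legitimately sit marginally infeasible, are
exempt.

For verification, a brute-force oracle evaluates the objective on an
explicit grid (1–2 parameters) and refines the best bracket by bounded
scalar minimization; on every bundled 1-D problem it agrees with the
quasi-Newton solver to well under 0.1 dose units.

## Dosing-interval optimization

Instead of dose amounts, the administration time of repeated fixed doses can
be optimized: all records sit at time 0 with a dose-number column, and the
record with dose number k is administered at θ·(k−1) — the lag-time
construction.  A single gap parameter is the default; per-dose gaps are a
trivial extension of the same expansion but are not enabled by default.

## Bundled example models

The three disease examples are reconstructions of canonical model families,
assembled and parameterized by this package; they are *not* transcriptions
of any published individual-patient parameter set.  Structural anchors
(neutrophil baseline 7×10⁹/L with safety threshold 1, biomarker target
level 10, twice-daily 1 h infusions with a mean-count threshold of 100
CFU/mL, the dosing windows and horizons) are the study conditions; rate
constants were chosen once to give realistic dynamics on those horizons and
an interior, constraint-active optimum, and are frozen in `models.py` with
per-line unit comments.

* **tumor_myelo** (days): 10 states.  One-compartment IV-bolus PK (V = 1,
  ke = 1.2/d) drives (i) a transit tumor-kill model — proliferating cells
  grow exponentially (λ0 = 0.30/d) switching smoothly (ψ = 20) to linear
  growth (λ1 = 0.80 mass/d), drug kills at k2·C and damaged cells pass
  through a 3-stage death chain (k1 = 0.5/d); tumor weight W is the sum of
  all tumor states — and (ii) the 5-state transit-feedback myelosuppression
  model: precursor proliferation inhibited linearly (slope·C), maturation
  chain with ktr = 1/d, feedback (Circ0/Circ)^γ with γ = 0.17,
  baseline Circ0 = 7.  Dosing: 16 daily IV boluses on days 12–27 grouped
  into 4 dose levels; horizon [0, 32] d.  The administration route follows
  the IV-bolus description of the optimal-solution figures.
* **biomarker_idr** (days): elevated biomarker at baseline kin/kout = 15;
  drug stimulates loss, dB/dt = kin − kout(1 + Emax·C/(EC50+C))B with
  Emax = 2, EC50 = 5; the healthy target B_tar = 10 is reachable since
  Emax > kin/(10·kout) − 1.  42 daily boluses, dose changes weekly (m = 6),
  horizon [0, 42] d, constraint B ≤ 10 on [14, 42].
* **antibiotic_ar** (hours): two-compartment PK per kg (V1 = 0.25, V2 =
  0.15 L/kg, CL = 0.1, Q = 0.05 L/h/kg); bacteria grow logistically
  (kg = 0.8/h, Smax = 10⁸, inoculum 10⁶ CFU/mL) and are killed saturably
  (kmax = 3/h, EC50 = 4 mg/L); an adaptive-resistance state R ∈ [0,1]
  builds with exposure (kon = 0.025 per mg/L·h, koff = 0.05/h) and shifts
  the kill EC50 by (1 + 6R).  Constraint: mean count over [6, 24] h below
  100 CFU/mL; cost: drug AUC over [0, 24] h.

Because the parameterizations are the package's own, the *numerical* optima
(doses, AUCs) are specific to these tables; what the tests assert — and what
passing them shows — are the structural outcomes of the method itself:
monotone approach of the constrained margin to its threshold as ρ grows,
cost monotonically increasing as the constraint tightens, constraint
activity at the optimum, ρ-independence and multi-start stability of the
solution, agreement with brute-force oracles, and exact recovery of
closed-form optima and multipliers on the toy problems.  They do not show
that any particular published dose table is reproduced, nor anything about
inter-individual variability, parameter uncertainty, or model misspecification.

## Synthetic test inputs

`fixtures` supplies (i) closed-form observables (constants, ramps, a curve
with exactly placed threshold crossings) wrapped in the trajectory contract,
used to pin every penalty formula to hand-computable values; (ii) random
band-limited observables (seed 20241008) for the penalty identities (PHR
with λ = 0 equals the quadratic penalty; PFV/ρ is ρ-free); and (iii) toy
one-compartment problems with analytic solutions: the active point
constraint gives D* = c·V·e^{ke·tf} with KKT multiplier
μ = (1−e^{−ke·tf})·e^{ke·tf}/ke, and the quadratic-penalty minimizer at
finite ρ sits at exactly D* − a/(ρb²) (a the AUC slope, b the constraint
slope) — both asserted in the tests.

## Numerical choices and limitations

* Tie-breaks: record expansion is order-preserving; simultaneous boluses
  accumulate.  A degenerate interval θ = 0 (both doses at once) is allowed
  and simply simulated.
* Quadrature cross-check: augmented states agree with trapezoidal
  integration of the dense output to 1e-4 relative for smooth integrands.
* Problem sizes: continuation runs are 2–4 box-constrained solves over ≤ 6
  parameters with ≤ 10-state ODE systems; a full tumor continuation takes
  about a minute on one CPU.
* Path-constraint penalized optima converge to the constrained optimum
  noticeably slower in ρ than point constraints (tangential constraint
  activity); the augmented-Lagrangian mode closes that gap faster.
* Not covered: parameter estimation, inter-individual variability,
  steady-state/ADDL dosing records, multi-subject files, delay or
  stochastic dynamics, simultaneous dose-and-interval optimization, and
  global optimality guarantees (multi-start dispersion is the diagnostic;
  the remedy — grouping doses to reduce degrees of freedom — is surfaced as
  advice, not automated).
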