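# Methods

## Model class

`rbmsim` simulates reaction-based models (RBMs): N molecular species
S₁…S_N and M irreversible reactions

    R_i :  Σ_j a_ij S_j  →^{k_i}  Σ_j b_ij S_j

with non-negative integer stoichiometric matrices **A** = (a_ij)
(reactants) and **B** = (b_ij) (products) and positive kinetic constants
k_i.  Under mass-action kinetics the concentration vector **X** obeys

    dX/dt = (B − A)ᵀ (K ∘ X^A),    (X^A)_i = Π_j x_j^{a_ij},

with ∘ the Hadamard product.  The analytic Jacobian follows by
differentiating each flux monomial:
J[p,q] = Σ_i (b_ip − a_ip) · k_i · a_iq · x_q^{a_iq−1} · Π_{j≠q} x_j^{a_ij}.

Conventions and assumptions:

- **0⁰ := 1** in X^A, so a species absent from a reaction never gates its
  flux and the right-hand side is well defined at zero concentrations.
- Transient negative concentrations produced by a solver are passed to
  the RHS unmodified.  Clamping would destroy the smoothness the
  error estimators rely on; tolerance control is responsible for keeping
  excursions within the error budget.
- The package is **unit-agnostic**: X may be molar concentrations or
  molecule counts as long as each k_i is expressed in the matching units
  for its reaction order.
- **A** and **B** are stored dense.  Generated models are sparse, but at
  the sizes this CPU implementation targets (≲ a few hundred species)
  dense BLAS evaluation of the RHS/Jacobian is faster than sparse
  indexing; dense semantics are normative.

## Integrators

Two adaptive Runge–Kutta methods of order 5, both following the designs
of Hairer & Wanner's reference codes.

**DOPRI5** — the 7-stage Dormand–Prince 5(4) pair with FSAL.  Standard
published coefficients, stored as exact rationals evaluated in double
precision.  Error control uses the scaled RMS norm

    err = sqrt( (1/N) Σ_i ( e_i / (ε_a + ε_r·max(|x_old,i|, |x_new,i|)) )² )

with defaults ε_a = 10⁻¹², ε_r = 10⁻⁶ and a 10⁴-step budget (the
settings deterministic simulators in this field conventionally run
with).  A step is accepted iff err ≤ 1; the controller uses safety 0.9,
h ← h·clip(0.9·err^(−1/5), 0.2, 10).  The initial step, when not given,
comes from the standard RHS-magnitude heuristic.  Stiffness detection
monitors h·ρ̃, where ρ̃ = ‖f(y_st7) − f(y_st6)‖/‖y_st7 − y_st6‖ is the
Lipschitz estimate from the two c = 1 stages; h·ρ̃ > 3.25 on 15
consecutive flagged accepted steps (with a 6-step clean run resetting
the counter) terminates with `stiffness_detected` and partial results.
These constants are those of the reference DOPRI5 code.

**RADAU5** — the 3-stage Radau IIA collocation method, order 5, A-, S-
and stiffly stable; the last stage is the step solution (stiff
accuracy).  Stage increments solve Z = h(A ⊗ I)F(y₀ + Z) by simplified
Newton with the Jacobian frozen at y₀: the Newton matrix I − h(A ⊗ J)
is LU-factorized **directly in its 3N×3N form** and reused across
iterations.  The classical real+complex transformation into three
N-sized solves is an optimization worth roughly a constant factor; at
the problem sizes this CPU code targets the direct factorization is
simpler and numerically identical, so it was chosen deliberately.
At most 7 Newton iterations per attempt; divergence (Θ ≥ 1) or
non-convergence halves the step and refreshes the Jacobian.  The
convergence test is Θ/(1−Θ)·‖ΔZ‖ < max(10·u/ε_r, min(0.03, √ε_r)).
The embedded order-3 error estimate e = f₀ + (d₁Z₁ + d₂Z₂ + d₃Z₃)/h is
filtered through (I/(hγ) − J)⁻¹ (γ the real eigenvalue of the RK
matrix), with the classical refined re-estimate on first/rejected
steps; h ← h·clip(0.9·(15/(14+it))·err^(−1/4), 0.2, 8).

**Dense output.**  Both solvers fill the requested grid by
interpolation — DOPRI5 with its quartic interpolant, RADAU5 with the
collocation cubic through (0, c₁, c₂, 1) — rather than forcing steps
onto output times, so the controller's step sequence is independent of
the output grid.  A grid consisting of the single time 0 returns the
initial state without integrating.

**Fixed-step mode** (`SolverSettings.fixed_step`) disables the
controller entirely; it exists for convergence-order studies (both
methods show the expected global O(h⁵) slope on dX/dt = −X) and is not
meant for production runs.

Linear invariants (c with (B−A)c = 0) are preserved to roundoff by
construction — Runge–Kutta methods conserve linear first integrals —
which the conservation tests confirm at ~10⁻¹⁶ relative drift.

## Dispatch

Stiffness is classified **per parameterization row**, not per model,
because the spectrum of J depends on both X₀ and K.  The dominant
eigenvalue of J(X₀) is estimated by power iteration (50 iterations,
10⁻³ relative convergence, seeded start vector); dominant complex pairs
make power iteration oscillate, in which case the estimate falls back
to a full dense eigen-decomposition rather than failing silently.  Rows
with |λ|_max < 500 (the default threshold, applied to the raw
magnitude) run DOPRI5, the rest RADAU5.  DOPRI5 failures — stiffness
detected mid-run (stiffness often develops only after a transient, as
in Robertson's problem, which looks non-stiff at t = 0), step-limit, or
underflow — are **re-executed from t = 0** with RADAU5.

Rows are independent; the optional joblib backend must (and does)
reproduce the sequential result exactly.  A row with invalid parameters
gets an `invalid_input` status instead of aborting the batch.  A batch
size of 512 rows is a convenient unit of work for chunked sweeps; on
CPU it is purely advisory.

## Synthetic model generation

The generator emulates the statistical shape of curated biochemical
networks:

| quantity | distribution | default range |
|---|---|---|
| initial concentrations | log-uniform | [10⁻⁴, 1) |
| kinetic constants | log-uniform | [10⁻⁶, 10] |
| reactant order | uniform on {0, 1, 2} | ≤ 2 molecules |
| product molecules | uniform on {0, 1, 2} | ≤ 2 molecules |

Log-uniform means exp(Uniform(ln lo, ln hi)): measured concentrations
and rate constants span several orders of magnitude, and a uniform
distribution in log space captures that dispersion.  Reactions of order
> 2 are excluded because simultaneous collisions of three molecules are
vanishingly rare (the integrators themselves accept any order).
Species are chosen uniformly with replacement, so 2A and A+B both
occur; empty reactions are resampled; duplicate reactions are allowed
(benign under mass action).  Zero-order (pure-source) reactions are
emitted by default and can be disabled.

What the generator does **not** emulate: modular/hub topology, flux
balance, time-scale separation structure, or thermodynamic consistency
of real pathways.  Passing tests on generated models therefore
demonstrate numerical correctness and robustness across a wide
parameter dispersion — not biological realism of any single trajectory.

Batches perturb each kinetic constant log-uniformly within ±25%:

    k′ = exp( ln(0.75k) + (ln(1.25k) − ln(0.75k))·rnd ),  rnd ~ U[0,1)

so k′ ∈ [0.75k, 1.25k) and ln k′ is uniform on that log-interval.

For batch experiments on generated models the package uses an output
grid of 100 points on [0, 5] time units; generated rate constants
concentrate most relaxation dynamics within a few time units, and this
horizon exercises both transient and near-equilibrium behaviour at
moderate cost.

## Model folder dialect

The plain-text folder layout (`left_side`, `right_side`, `c_vector`,
`M_0`, optional `MX_0`, `c_matrix`, `t_vector`, `cs_vector`,
`alphabet`) documented in `rbmsim/io.py` is **normative for this
package**.  Numbers are written with 17 significant digits so
write→read round-trips are exact.  `cs_vector` is 0-based on disk
(a deliberate choice, documented, since conventions differ between
simulators in this family).  The SBML importer accepts the irreversible
mass-action subset (reversible reactions whose law is a difference of
two mass-action monomials are split in two); the kinetic-law MathML is
converted to a symbolic expression and compared against the expected
monomial, so algebraically equivalent spellings are recognized and
anything else is rejected with the reaction named.  Export to SBML is
out of scope.

## Analysis workflows

**PSA-2D.**  Two axes (an initial concentration, or a set of kinetic
constants selected by a mask) define a Cartesian grid; a kinetic-mask
axis **assigns** the axis value to every selected constant (the swept
quantity *is* the constants' value, as in sweeps where one scaling
parameter controls thousands of constants).  Grid orientation: rows =
axis 1, columns = axis 2, row-major over the meshgrid.

**Oscillation amplitude.**  "Average oscillation amplitude" is defined
here as: drop the first half (default) of the output grid as transient,
find strict local maxima/minima, average (max − following min) over
consecutive pairs; fewer than two peaks, or a total range below
10⁻⁶·max(1, global max), scores 0 (non-oscillating).  The transient
fraction is a parameter because limit-cycle convergence times vary.

**Sobol SA.**  Saltelli's design built on a scrambled Sobol sequence of
dimension 2D (`scipy.stats.qmc`), n_base·(2D+2) rows with second-order
blocks, n_base·(D+2) without; the per-base-point row ordering (A,
AB₁…AB_D, BA₁…BA_D, B) is this package's documented convention.
Estimators: Saltelli-2010 for S1, Jansen for ST, the standard
normalization by Var(f(A)∪f(B)); these match common reference
implementations so tabulated outputs are comparable across tools.
Confidence half-widths come from a percentile bootstrap over base
points (default 1000 resamples, 95% level).  Zero output variance
yields all-zero indices with a degeneracy flag.  The SA template
statistic is the signed difference between a species' final
concentration and a reference value; factor ranges are sampled
uniformly (not log-uniformly) within their bounds.

**Parameter estimation.**  The fitness is the mean over target points
of |sim − target| / max(|target|, 10⁻¹²): non-negative, zero only at
exact match, invariant to species ordering, +∞ for failed trajectories
so minimizers penalize them.  The bundled optimizer is seeded
differential evolution over log₁₀(k) — a reference implementation for
recovery experiments, not a tuned estimation framework; any external
optimizer can consume the fitness directly.  Recovery experiments
should select free constants via `rank_kinetic_sensitivity`: a constant
whose doubling leaves the observed dynamics unchanged is
(structurally or practically) non-identifiable from that trajectory,
and no optimizer can recover it.

## Known limitations

- Mass-action kinetics only; Hill and Michaelis–Menten laws are not
  representable (the SBML importer rejects them explicitly).
- No event detection, root finding, or mass-matrix support; Radau order
  is fixed at 5 (no order variation).
- The stiffness classifier probes J at t = 0 only; stiffness that
  develops later is caught by the DOPRI5 monitor and handled by the
  RADAU5 re-run, at the cost of one wasted explicit attempt.
- Power iteration underestimates ρ when the two leading eigenvalues are
  close in magnitude; the 5%-accuracy contract is what the dispatch
  threshold needs, not a general-purpose eigensolver guarantee.
- The batch engine parallelizes over rows only (coarse-grained); no
  fine-grained parallelism within a single trajectory.
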