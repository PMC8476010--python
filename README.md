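# rbmsim

Deterministic simulation of biochemical reaction networks, for systems
biologists who need to run **many** simulations of one model —
parameter sweeps, variance-based sensitivity analysis, parameter
estimation — without hand-deriving ODEs or hand-picking a solver.

A reaction-based model (RBM) is a set of N species and M reactions

    R_i :  Σ_j a_ij S_j  →^{k_i}  Σ_j b_ij S_j,

encoded by stoichiometric matrices **A**, **B** ∈ ℕ^{M×N} and kinetic
constants **K** ∈ ℝ₊^M.  Under mass-action kinetics `rbmsim` converts
this automatically into the ODE system

    dX/dt = (B − A)ᵀ (K ∘ X^A),   (X^A)_i = Π_j x_j^{a_ij},

and integrates it with a stiffness-aware pair of order-5 Runge–Kutta
methods: the explicit Dormand–Prince pair (**DOPRI5**) for non-stiff
parameterizations and the implicit 3-stage Radau IIA method
(**RADAU5**) for stiff ones.  Each parameterization in a batch is
routed by the dominant eigenvalue of the Jacobian at the initial state
(|λ|_max < 500 → DOPRI5); runs on which DOPRI5 detects stiffness or
exhausts its step budget are automatically re-executed with RADAU5.
Default tolerances are ε_a = 10⁻¹², ε_r = 10⁻⁶ with at most 10⁴ steps.

The package also provides:

- a synthetic RBM generator (log-uniform X₀ in [10⁻⁴, 1), log-uniform K
  in [10⁻⁶, 10], reactions of order ≤ 2) and a ±25% log-uniform kinetic
  perturbation for building batches of parameterizations,
- bi-dimensional parameter sweeps (PSA-2D) with an
  oscillation-amplitude summary,
- Sobol sensitivity analysis via Saltelli sampling with first/total-order
  indices and bootstrap 95% confidence intervals,
- a relative-distance fitness for parameter estimation, with a seeded
  reference optimizer,
- plain-text model-folder I/O and a mass-action SBML importer.

## Worked example

Robertson's classic stiff kinetics as a mass-action RBM — at t = 0 the
system *looks* non-stiff (B = C = 0 silences the fast reactions), so
the dispatcher tries DOPRI5 first, which detects stiffness mid-run and
falls back to RADAU5:

```python
import numpy as np
from rbmsim import RBM, SolverSettings, ParameterizationSet, run_batch

rbm = RBM(
    species_names=["A", "B", "C"],
    A=[[1, 0, 0], [0, 1, 1], [0, 2, 0]],   # A->B; B+C->A+C; 2B->B+C
    B=[[0, 1, 0], [1, 0, 1], [0, 1, 1]],
    K=[0.04, 1e4, 3e7],
    X0=[1.0, 0.0, 0.0],
)
settings = SolverSettings(t_out=np.array([1.0, 1e2, 1e3]))
params = ParameterizationSet(X0_batch=rbm.X0[np.newaxis, :])
result = run_batch(rbm, params, settings)
traj = result.trajectories[0]
print("classified:", result.classification[0], f"(rho = {result.rho[0]:.3g})")
print("fallback to RADAU5:", bool(result.fallback_mask[0]))
print("solver used:", traj.solver_used, "| status:", traj.status.value)
for t, row in zip(traj.times, traj.states):
    print(f"t = {t:7.1f}   A = {row[0]:.6f}   B = {row[1]:.3e}   C = {row[2]:.6f}")
```

prints

```
classified: nonstiff (rho = 0.04)
fallback to RADAU5: True
solver used: RADAU5 | status: success
t =     1.0   A = 0.966460   B = 3.075e-05   C = 0.033510
t =   100.0   A = 0.617235   B = 6.154e-06   C = 0.382759
t =  1000.0   A = 0.336875   B = 2.014e-06   C = 0.663123
```

The three concentrations are the textbook Robertson solution (they
agree with a BDF reference at rtol 10⁻¹⁰ to better than 10⁻⁷ relative),
B passing through its ~3·10⁻⁵ quasi-steady-state maximum while A slowly
converts to C.

## Command line

```sh
rbmsim generate --n 64 --m 64 --seed 1 --out model/      # synthetic RBM
rbmsim simulate --model model/ --out dynamics/           # batch simulation
rbmsim convert  --sbml model.xml --out model/            # SBML import
rbmsim psa2d    --model model/ --axis1 k:0:0.5:2:50 \
                --axis2 x0:1:0:1:50 --summary amplitude --species 0 \
                --t-end 60 --out grid.tsv
rbmsim sobol    --model model/ --factors factors.tsv --species 3 \
                --n-base 512 --out indices.tsv
```

`simulate` reads a model folder (`left_side`, `right_side`, `c_vector`,
`M_0`, optional `MX_0`/`c_matrix`/`t_vector`/`cs_vector`/`alphabet` —
the dialect is documented in `rbmsim/io.py`), writes one TSV per
simulation plus a summary of per-row status, solver and stiffness
estimate, and exits non-zero if any row failed.

## Documentation

`docs/methods.md` describes the numerical methods (tableaux, step
controllers, stiffness detection, the simplified-Newton solver), the
synthetic-generator distributions and what they do and do not emulate,
the analysis-workflow definitions, and known limitations.
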