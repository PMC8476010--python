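"""Adaptive single-trajectory ODE integration.

Two Runge-Kutta methods of order 5, following the classical Hairer &
Wanner designs:

* DOPRI5 -- the 7-stage explicit Dormand-Prince 5(4) pair with FSAL,
  PI-free step control, quartic dense output, and the standard
  stiffness-detection monitor on ``h * rho_tilde`` (estimated from the
  last two stages).
* RADAU5 -- the 3-stage Radau IIA collocation method, order 5, stiffly
  accurate (the last stage IS the step solution).  Stage equations are
  solved by simplified Newton iteration; the Newton matrix
  ``I - h (A (x) J)`` is LU-factorized directly in its 3N x 3N form and
  the factorization is reused across iterations.

Both integrators fill the requested output grid by dense-output
interpolation (DOPRI5 quartic interpolant, RADAU5 collocation cubic)
rather than forcing steps onto the output times, so the step-size
controller behaves identically whatever grid is requested.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.linalg import lu_factor, lu_solve

__all__ = [
    "SolverSettings",
    "Trajectory",
    "ButcherTableau",
    "Status",
    "error_norm",
    "dopri5_integrate",
    "radau5_integrate",
    "DOPRI5_TABLEAU",
    "RADAU5_TABLEAU",
]

UROUND = np.finfo(float).eps


class Status(str, enum.Enum):
    SUCCESS = "success"
    STIFFNESS_DETECTED = "stiffness_detected"
    STEP_LIMIT_EXCEEDED = "step_limit_exceeded"
    STEP_SIZE_UNDERFLOW = "step_size_underflow"
    INVALID_INPUT = "invalid_input"


@dataclass
class SolverSettings:
    """Integration tolerances, output grid and step limits.

    Defaults follow the widely used deterministic-simulation settings:
    absolute tolerance 1e-12, relative tolerance 1e-6, at most 1e4
    steps.  ``stiffness_threshold`` is the dominant-eigenvalue bound
    used by the batch dispatcher (not by the integrators themselves).
    ``fixed_step`` disables the adaptive controller and forces constant
    step size (used for convergence-order studies).
    """

    eps_a: float = 1e-12
    eps_r: float = 1e-6
    max_steps: int = 10_000
    t_out: np.ndarray = field(default_factory=lambda: np.array([1.0]))
    h_init: Optional[float] = None
    stiffness_threshold: float = 500.0
    fixed_step: Optional[float] = None

    def __post_init__(self) -> None:
        self.t_out = np.asarray(self.t_out, dtype=float).ravel()
        self.validate()

    def validate(self) -> None:
        if not (self.eps_a > 0 and self.eps_r > 0):
            raise ValueError("eps_a and eps_r must be positive")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")
        if self.t_out.size == 0:
            raise ValueError("t_out must contain at least one time")
        if self.t_out.size > 1 and not np.all(np.diff(self.t_out) > 0):
            raise ValueError("t_out must be strictly increasing")
        if self.t_out[0] < 0:
            raise ValueError("output times must be non-negative")
        if self.fixed_step is not None and self.fixed_step <= 0:
            raise ValueError("fixed_step must be positive")


@dataclass
class Trajectory:
    """One simulated time course.

    ``states`` has one row per output time; rows past the reached time
    are NaN when the integration terminated early.  ``n_steps`` counts
    attempted steps and always equals ``n_accepted + n_rejected``.
    """

    times: np.ndarray
    states: np.ndarray
    solver_used: str
    status: Status
    n_steps: int = 0
    n_accepted: int = 0
    n_rejected: int = 0
    rho: Optional[float] = None

    @property
    def success(self) -> bool:
        return self.status == Status.SUCCESS


@dataclass
class ButcherTableau:
    """Runge-Kutta coefficient table with an embedded error estimate."""

    c: np.ndarray
    a: np.ndarray
    b: np.ndarray
    b_err: np.ndarray
    order: int

    def __post_init__(self) -> None:
        self.c = np.asarray(self.c, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.b_err = np.asarray(self.b_err, dtype=float)
        rowsum = self.a.sum(axis=1)
        if not np.allclose(rowsum, self.c, atol=1e-12, rtol=0):
            raise ValueError("tableau row sums do not match the abscissae")


# ---------------------------------------------------------------------------
# DOPRI5(4) coefficients (exact rationals evaluated in double precision)

_DP_C = np.array([0.0, 1 / 5, 3 / 10, 4 / 5, 8 / 9, 1.0, 1.0])
_DP_A = np.zeros((7, 7))
_DP_A[1, 0] = 1 / 5
_DP_A[2, :2] = (3 / 40, 9 / 40)
_DP_A[3, :3] = (44 / 45, -56 / 15, 32 / 9)
_DP_A[4, :4] = (19372 / 6561, -25360 / 2187, 64448 / 6561, -212 / 729)
_DP_A[5, :5] = (9017 / 3168, -355 / 33, 46732 / 5247, 49 / 176, -5103 / 18656)
_DP_A[6, :6] = (35 / 384, 0.0, 500 / 1113, 125 / 192, -2187 / 6784, 11 / 84)
_DP_B = _DP_A[6].copy()  # FSAL: 5th-order weights equal the last stage row
_DP_BHAT = np.array(
    [5179 / 57600, 0.0, 7571 / 16695, 393 / 640, -92097 / 339200, 187 / 2100, 1 / 40]
)
_DP_E = _DP_B - _DP_BHAT  # error-estimate weights

DOPRI5_TABLEAU = ButcherTableau(c=_DP_C, a=_DP_A, b=_DP_B, b_err=_DP_E, order=5)

# dense-output weights (Hairer's contd5)
_DP_D = np.array(
    [
        -12715105075 / 11282082432,
        0.0,
        87487479700 / 32700410799,
        -10690763975 / 1880347072,
        701980252875 / 199316789632,
        -1453857185 / 822651844,
        69997945 / 29380423,
    ]
)

# ---------------------------------------------------------------------------
# Radau IIA, s = 3, order 5

_SQ6 = np.sqrt(6.0)
_RA_C = np.array([(4 - _SQ6) / 10, (4 + _SQ6) / 10, 1.0])
_RA_A = np.array(
    [
        [(88 - 7 * _SQ6) / 360, (296 - 169 * _SQ6) / 1800, (-2 + 3 * _SQ6) / 225],
        [(296 + 169 * _SQ6) / 1800, (88 + 7 * _SQ6) / 360, (-2 - 3 * _SQ6) / 225],
        [(16 - _SQ6) / 36, (16 + _SQ6) / 36, 1 / 9],
    ]
)
_RA_B = _RA_A[2].copy()  # stiffly accurate
# weights of the order-3 embedded error estimate (Hairer & Wanner)
_RA_DD = np.array([-(13 + 7 * _SQ6) / 3, (-13 + 7 * _SQ6) / 3, -1 / 3])
# real eigenvalue of the RK matrix A (its reciprocal scales the Newton matrix)
_RA_GAMMA = float(np.real(sorted(np.linalg.eigvals(_RA_A), key=lambda z: abs(z.imag))[0]))

RADAU5_TABLEAU = ButcherTableau(c=_RA_C, a=_RA_A, b=_RA_B, b_err=_RA_DD, order=5)


# ---------------------------------------------------------------------------


def error_norm(
    x_old: np.ndarray, x_new: np.ndarray, err: np.ndarray, settings: SolverSettings
) -> float:
    """Scaled RMS norm of an error estimate.

    sqrt( mean( (err_i / (eps_a + eps_r * max(|x_old_i|, |x_new_i|)))^2 ) )
    """
    scale = settings.eps_a + settings.eps_r * np.maximum(np.abs(x_old), np.abs(x_new))
    return float(np.sqrt(np.mean((err / scale) ** 2)))


def _initial_step(
    rhs: Callable, x0: np.ndarray, f0: np.ndarray, t_end: float, settings: SolverSettings
) -> float:
    """Hairer's RHS-magnitude heuristic for the first step size."""
    scale = settings.eps_a + settings.eps_r * np.abs(x0)
    d0 = np.sqrt(np.mean((x0 / scale) ** 2))
    d1 = np.sqrt(np.mean((f0 / scale) ** 2))
    h0 = 1e-6 if d0 < 1e-5 or d1 < 1e-5 else 0.01 * d0 / d1
    h0 = min(h0, t_end) if t_end > 0 else h0
    x1 = x0 + h0 * f0
    f1 = np.asarray(rhs(x1), dtype=float)
    d2 = np.sqrt(np.mean(((f1 - f0) / scale) ** 2)) / h0
    dm = max(d1, d2)
    h1 = max(1e-6, h0 * 1e-3) if dm <= 1e-15 else (0.01 / dm) ** (1 / 5)
    h = min(100 * h0, h1)
    return min(h, t_end) if t_end > 0 else h


def _finish_degenerate(
    t_out: np.ndarray, x0: np.ndarray, solver: str
) -> Optional[Trajectory]:
    """Trajectory for grids that need no integration (single t = 0)."""
    if t_out.size == 1 and t_out[0] == 0.0:
        return Trajectory(
            times=t_out.copy(),
            states=x0[np.newaxis, :].copy(),
            solver_used=solver,
            status=Status.SUCCESS,
        )
    return None


def dopri5_integrate(
    rhs: Callable[[np.ndarray], np.ndarray],
    x0: np.ndarray,
    settings: SolverSettings,
) -> Trajectory:
    """Integrate dX/dt = rhs(X) from t = 0 with the Dormand-Prince 5(4) pair.

    A step is accepted when the scaled error norm is <= 1.  The
    stiffness monitor compares ``h * rho_tilde`` -- with ``rho_tilde``
    the Lipschitz estimate from the two c = 1 stages -- against 3.25;
    fifteen consecutive flagged accepted steps terminate the run with
    ``stiffness_detected`` and partial results, leaving the caller (the
    dispatcher) to re-run with the implicit solver.
    """
    settings.validate()
    x0 = np.asarray(x0, dtype=float).ravel()
    t_out = settings.t_out
    deg = _finish_degenerate(t_out, x0, "DOPRI5")
    if deg is not None:
        return deg
    t_end = float(t_out[-1])
    n = x0.size
    states = np.full((t_out.size, n), np.nan)
    i_out = 0
    if t_out[0] == 0.0:
        states[0] = x0
        i_out = 1

    f0 = np.asarray(rhs(x0), dtype=float)
    if not np.all(np.isfinite(f0)):
        return Trajectory(t_out.copy(), states, "DOPRI5", Status.STEP_SIZE_UNDERFLOW)

    fixed = settings.fixed_step is not None
    if fixed:
        h = float(settings.fixed_step)
    elif settings.h_init is not None:
        h = float(settings.h_init)
    else:
        h = _initial_step(rhs, x0, f0, t_end, settings)

    t, x, k1 = 0.0, x0.copy(), f0
    n_acc = n_rej = 0
    iastiff = nonsti = 0
    K = np.empty((7, n))
    status = Status.SUCCESS

    while t < t_end:
        if n_acc + n_rej >= settings.max_steps:
            status = Status.STEP_LIMIT_EXCEEDED
            break
        if t_end - t <= 8 * UROUND * max(abs(t_end), 1.0):
            break  # end reached within roundoff
        h = min(h, t_end - t)
        if h < 16 * UROUND * max(abs(t), 1.0):
            status = Status.STEP_SIZE_UNDERFLOW
            break
        K[0] = k1
        bad = False
        for s in range(1, 7):
            xs = x + h * (_DP_A[s, :s] @ K[:s])
            K[s] = rhs(xs)
            if not np.all(np.isfinite(K[s])):
                bad = True
                break
        if bad:
            if fixed:
                status = Status.STEP_SIZE_UNDERFLOW
                break
            h *= 0.25
            n_rej += 1
            continue
        x_new = x + h * (_DP_A[6] @ K)  # = stage 7 input; b == a[6]
        err_vec = h * (_DP_E @ K)
        err = error_norm(x, x_new, err_vec, settings)

        if fixed or err <= 1.0:
            n_acc += 1
            # stiffness monitor on the two c = 1 stages
            if not fixed:
                x_s6 = x + h * (_DP_A[5, :5] @ K[:5])
                den = float(np.sum((x_new - x_s6) ** 2))
                num = float(np.sum((K[6] - K[5]) ** 2))
                if den > 0:
                    hlamb = h * np.sqrt(num / den)
                    if hlamb > 3.25:
                        nonsti = 0
                        iastiff += 1
                        if iastiff >= 15:
                            status = Status.STIFFNESS_DETECTED
                    else:
                        nonsti += 1
                        if nonsti == 6:
                            iastiff = 0
            # dense output over (t, t + h]
            if i_out < t_out.size and t_out[i_out] <= t + h * (1 + 4 * UROUND):
                ydiff = x_new - x
                bspl = h * K[0] - ydiff
                cont = np.array(
                    [x, ydiff, bspl, ydiff - h * K[6] - bspl, h * (_DP_D @ K)]
                )
                while i_out < t_out.size and t_out[i_out] <= t + h * (1 + 4 * UROUND):
                    th = min(max((t_out[i_out] - t) / h, 0.0), 1.0)
                    th1 = 1.0 - th
                    states[i_out] = cont[0] + th * (
                        cont[1] + th1 * (cont[2] + th * (cont[3] + th1 * cont[4]))
                    )
                    i_out += 1
            t += h
            x = x_new
            k1 = K[6]  # FSAL
            if status == Status.STIFFNESS_DETECTED:
                break
            if not fixed:
                fac = 0.9 * err ** (-0.2) if err > 0 else 10.0
                h *= min(10.0, max(0.2, fac))
        else:
            n_rej += 1
            fac = 0.9 * err ** (-0.2)
            h *= min(1.0, max(0.2, fac))

    if status == Status.SUCCESS and i_out < t_out.size:
        # end reached within roundoff; fill trailing points with final state
        while i_out < t_out.size and t_out[i_out] <= t * (1 + 8 * UROUND):
            states[i_out] = x
            i_out += 1
        if i_out < t_out.size:
            status = Status.STEP_LIMIT_EXCEEDED
    return Trajectory(
        times=t_out.copy(),
        states=states,
        solver_used="DOPRI5",
        status=status,
        n_steps=n_acc + n_rej,
        n_accepted=n_acc,
        n_rejected=n_rej,
    )


def _collocation_eval(
    theta: float, y0: np.ndarray, Z: np.ndarray
) -> np.ndarray:
    """Evaluate the Radau collocation cubic at fraction ``theta`` of the step.

    Newton interpolation through (0, y0), (c1, y0+Z1), (c2, y0+Z2), (1, y0+Z3).
    """
    nodes = np.concatenate(([0.0], _RA_C))
    vals = np.vstack([y0, y0 + Z])
    # divided differences (vector-valued)
    dd = vals.copy()
    for order in range(1, 4):
        for i in range(3, order - 1, -1):
            dd[i] = (dd[i] - dd[i - 1]) / (nodes[i] - nodes[i - order])
    out = dd[3]
    for i in (2, 1, 0):
        out = dd[i] + (theta - nodes[i]) * out
    return out


def radau5_integrate(
    rhs: Callable[[np.ndarray], np.ndarray],
    jac: Callable[[np.ndarray], np.ndarray],
    x0: np.ndarray,
    settings: SolverSettings,
) -> Trajectory:
    """Integrate with the 3-stage Radau IIA collocation method (order 5).

    The stage increments Z solve  Z = h (A (x) I) F(y0 + Z);  a
    simplified Newton iteration with the Jacobian frozen at y0 is used,
    at most 7 iterations per attempt, halving the step on divergence.
    The embedded order-3 estimate is smoothed through
    ``(I/(h*gamma) - J)^{-1}`` as in the classical RADAU5 code.
    """
    settings.validate()
    x0 = np.asarray(x0, dtype=float).ravel()
    t_out = settings.t_out
    deg = _finish_degenerate(t_out, x0, "RADAU5")
    if deg is not None:
        return deg
    t_end = float(t_out[-1])
    n = x0.size
    states = np.full((t_out.size, n), np.nan)
    i_out = 0
    if t_out[0] == 0.0:
        states[0] = x0
        i_out = 1

    fixed = settings.fixed_step is not None
    f0 = np.asarray(rhs(x0), dtype=float)
    if not np.all(np.isfinite(f0)):
        return Trajectory(t_out.copy(), states, "RADAU5", Status.STEP_SIZE_UNDERFLOW)
    if fixed:
        h = float(settings.fixed_step)
    elif settings.h_init is not None:
        h = float(settings.h_init)
    else:
        h = _initial_step(rhs, x0, f0, t_end, settings)

    fnewt = max(10 * UROUND / settings.eps_r, min(0.03, settings.eps_r**0.5))
    kron_eye = np.eye(3)
    t, x = 0.0, x0.copy()
    n_acc = n_rej = 0
    status = Status.SUCCESS
    J = None
    lu3 = lu1 = None
    h_fact = None
    need_jac = True
    first_or_rejected = True

    while t < t_end:
        if n_acc + n_rej >= settings.max_steps:
            status = Status.STEP_LIMIT_EXCEEDED
            break
        if t_end - t <= 8 * UROUND * max(abs(t_end), 1.0):
            break  # end reached within roundoff
        h = min(h, t_end - t)
        if h < 16 * UROUND * max(abs(t), 1.0):
            status = Status.STEP_SIZE_UNDERFLOW
            break
        if need_jac or J is None:
            J = np.asarray(jac(x), dtype=float)
            need_jac = False
            h_fact = None
        if h_fact is None or abs(h - h_fact) > 1e-14 * h:
            # Newton matrix I - h (A (x) J), and the real shift for the
            # error filter (1/(h*gamma)) I - J
            M3 = np.kron(kron_eye, np.eye(n)) - h * np.kron(_RA_A, J)
            lu3 = lu_factor(M3)
            lu1 = lu_factor(np.eye(n) / (h * _RA_GAMMA) - J)
            h_fact = h

        f0 = np.asarray(rhs(x), dtype=float)
        scale = settings.eps_a + settings.eps_r * np.abs(x)
        Z = np.zeros((3, n))
        converged = False
        diverged = False
        theta = None
        dyno_prev = None
        for it in range(7):
            F = np.empty((3, n))
            ok = True
            for s in range(3):
                F[s] = rhs(x + Z[s])
                if not np.all(np.isfinite(F[s])):
                    ok = False
                    break
            if not ok:
                diverged = True
                break
            G = Z - h * (_RA_A @ F)
            dz = lu_solve(lu3, -G.reshape(-1)).reshape(3, n)
            Z += dz
            dyno = float(np.sqrt(np.mean((dz / scale[np.newaxis, :]) ** 2)))
            if dyno_prev is not None:
                theta = dyno / dyno_prev if dyno_prev > 0 else 0.0
                if theta >= 1.0:
                    diverged = True
                    break
                eta = theta / (1.0 - theta)
                if eta * dyno < fnewt:
                    converged = True
                    break
            if dyno == 0.0:
                converged = True
                break
            dyno_prev = dyno
        iters = it + 1

        if not converged or diverged:
            if fixed:
                status = Status.STEP_SIZE_UNDERFLOW
                break
            n_rej += 1
            h *= 0.5
            need_jac = True
            first_or_rejected = True
            continue

        x_new = x + Z[2]  # stiffly accurate: last stage is the solution
        if fixed:
            err = 0.0
        else:
            e_raw = f0 + (_RA_DD @ Z) / h
            err_vec = lu_solve(lu1, e_raw)
            err = max(error_norm(x, x_new, err_vec, settings), 1e-10)
            if err >= 1.0 and first_or_rejected:
                # refined estimate for the very first / freshly rejected step
                f_err = np.asarray(rhs(x + err_vec), dtype=float)
                if np.all(np.isfinite(f_err)):
                    err_vec = lu_solve(lu1, f_err + (_RA_DD @ Z) / h)
                    err = max(error_norm(x, x_new, err_vec, settings), 1e-10)

        if fixed or err < 1.0:
            n_acc += 1
            if i_out < t_out.size and t_out[i_out] <= t + h * (1 + 4 * UROUND):
                while i_out < t_out.size and t_out[i_out] <= t + h * (1 + 4 * UROUND):
                    th = min(max((t_out[i_out] - t) / h, 0.0), 1.0)
                    states[i_out] = _collocation_eval(th, x, Z)
                    i_out += 1
            t += h
            x = x_new
            first_or_rejected = False
            # refresh the Jacobian when Newton slowed down
            if theta is None or theta > 1e-3:
                need_jac = True
            if not fixed:
                fac = 0.9 * (2 * 7 + 1) / (2 * 7 + iters)
                h *= min(8.0, max(0.2, fac * err ** (-0.25)))
        else:
            n_rej += 1
            first_or_rejected = True
            fac = 0.9 * (2 * 7 + 1) / (2 * 7 + iters)
            h *= min(1.0, max(0.2, fac * err ** (-0.25)))
            need_jac = True

    if status == Status.SUCCESS and i_out < t_out.size:
        while i_out < t_out.size and t_out[i_out] <= t * (1 + 8 * UROUND):
            states[i_out] = x
            i_out += 1
        if i_out < t_out.size:
            status = Status.STEP_LIMIT_EXCEEDED
    return Trajectory(
        times=t_out.copy(),
        states=states,
        solver_used="RADAU5",
        status=status,
        n_steps=n_acc + n_rej,
        n_accepted=n_acc,
        n_rejected=n_rej,
    )
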