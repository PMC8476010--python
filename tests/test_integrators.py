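"""DOPRI5 and RADAU5: accuracy, step control, dense output, statuses."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from rbmsim import (
    ButcherTableau,
    SolverSettings,
    Status,
    dopri5_integrate,
    error_norm,
    radau5_integrate,
)
from rbmsim.integrators import DOPRI5_TABLEAU, RADAU5_TABLEAU


def settings(t_out, **kw):
    return SolverSettings(t_out=np.asarray(t_out, dtype=float), **kw)


class TestErrorNorm:
    def test_zero_error(self):
        s = settings([1.0])
        assert error_norm(np.ones(3), np.ones(3), np.zeros(3), s) == 0.0

    def test_absolute_scale_at_zero_state(self):
        s = settings([1.0])
        err = np.array([s.eps_a])
        assert error_norm(np.zeros(1), np.zeros(1), err, s) == pytest.approx(1.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(0)
        s = settings([1.0], eps_a=1e-9, eps_r=1e-4)
        xo, xn, e = rng.normal(size=(3, 6))
        scale = s.eps_a + s.eps_r * np.maximum(np.abs(xo), np.abs(xn))
        expected = np.sqrt(np.mean((e / scale) ** 2))
        assert error_norm(xo, xn, e, s) == pytest.approx(expected, rel=1e-14)


class TestTableaux:
    def test_row_sum_consistency_enforced(self):
        with pytest.raises(ValueError, match="row sums"):
            ButcherTableau(
                c=[0.0, 0.5], a=[[0.0, 0.0], [0.4, 0.0]], b=[0.5, 0.5],
                b_err=[0.0, 0.0], order=2,
            )

    def test_shipped_tableaux_are_consistent(self):
        for tab in (DOPRI5_TABLEAU, RADAU5_TABLEAU):
            np.testing.assert_allclose(tab.a.sum(axis=1), tab.c, atol=1e-12)
            assert tab.order == 5


def _solve(solver, rbm, s, x0=None):
    x0 = rbm.X0 if x0 is None else x0
    if solver == "dopri5":
        return dopri5_integrate(rbm.rhs, x0, s)
    return radau5_integrate(rbm.rhs, rbm.jacobian, x0, s)


@pytest.mark.parametrize("solver", ["dopri5", "radau5"])
def test_exponential_decay_closed_form(solver, decay):
    s = settings([1.0])
    traj = _solve(solver, decay, s)
    assert traj.status == Status.SUCCESS
    assert traj.states[-1, 0] == pytest.approx(np.exp(-1.0), rel=10 * s.eps_r)


def test_radau_fast_decay_closed_form(fast_decay):
    s = settings([0.01])
    traj = radau5_integrate(fast_decay.rhs, fast_decay.jacobian, fast_decay.X0, s)
    assert traj.status == Status.SUCCESS
    assert traj.states[-1, 0] == pytest.approx(np.exp(-10.0), rel=1e-4)


@pytest.mark.parametrize("solver", ["dopri5", "radau5"])
def test_symmetric_equilibrium(solver, reversible_pair):
    traj = _solve(solver, reversible_pair, settings([20.0]))
    assert traj.status == Status.SUCCESS
    np.testing.assert_allclose(traj.states[-1], [0.5, 0.5], atol=1e-6)


@pytest.mark.parametrize("solver", ["dopri5", "radau5"])
def test_dense_output_against_closed_form(solver, reversible_pair):
    """Interior grid points are interpolated, not stepped onto."""
    s = settings(np.linspace(0.0, 20.0, 41))
    traj = _solve(solver, reversible_pair, s)
    exact = 0.5 + 0.5 * np.exp(-2.0 * s.t_out)
    assert traj.status == Status.SUCCESS
    np.testing.assert_allclose(traj.states[:, 0], exact, atol=5e-6)


def test_dopri5_detects_stiffness_on_robertson(robertson):
    traj = dopri5_integrate(robertson.rhs, robertson.X0, settings([1e3]))
    assert traj.status in (Status.STIFFNESS_DETECTED, Status.STEP_LIMIT_EXCEEDED)
    assert traj.n_steps <= 10_000


def test_radau_matches_stiff_reference_on_robertson(robertson):
    """Independent oracle: BDF at eps_r = 1e-10 on the same mass-action RHS."""
    t_eval = [1.0, 1e2, 1e3]
    traj = radau5_integrate(
        robertson.rhs, robertson.jacobian, robertson.X0, settings(t_eval)
    )
    assert traj.status == Status.SUCCESS
    ref = solve_ivp(
        lambda t, x: robertson.rhs(x),
        (0.0, 1e3),
        robertson.X0,
        method="BDF",
        jac=lambda t, x: robertson.jacobian(x),
        rtol=1e-10,
        atol=1e-14,
        t_eval=t_eval,
    )
    np.testing.assert_allclose(traj.states, ref.y.T, rtol=1e-4)


@pytest.mark.parametrize("solver", ["dopri5", "radau5"])
def test_order_five_convergence_with_fixed_step(solver, decay):
    hs = [0.1, 0.05, 0.025, 0.0125]
    errs = []
    for h in hs:
        traj = _solve(solver, decay, settings([1.0], fixed_step=h))
        assert traj.status == Status.SUCCESS
        errs.append(abs(traj.states[-1, 0] - np.exp(-1.0)))
    slope = np.polyfit(np.log(hs), np.log(errs), 1)[0]
    assert slope == pytest.approx(5.0, abs=0.3)


@pytest.mark.parametrize("solver", ["dopri5", "radau5"])
def test_tolerance_monotonicity(solver, decay):
    """Tightening eps_r by 100x never worsens the final-state error."""
    errors = []
    for eps_r in (1e-4, 1e-6, 1e-8):
        traj = _solve(solver, decay, settings([1.0], eps_r=eps_r))
        errors.append(abs(traj.states[-1, 0] - np.exp(-1.0)))
    assert errors[1] <= errors[0] and errors[2] <= errors[1]


@pytest.mark.parametrize("solver", ["dopri5", "radau5"])
def test_linear_invariant_preserved(solver, reversible_pair, robertson):
    for rbm in (reversible_pair, robertson):
        total0 = rbm.X0.sum()
        traj = _solve(solver, rbm, settings(np.linspace(0.0, 10.0, 21)))
        if traj.status != Status.SUCCESS:
            continue  # explicit solver may bail out on the stiff model
        drift = np.max(np.abs(traj.states.sum(axis=1) - total0)) / total0
        assert drift < 1e-8


def test_radau_is_stiffly_accurate(decay):
    """The last collocation stage IS the step solution.

    The dense-output value at the end of a step must coincide with the
    state the integrator carries forward: a grid point landed on by
    interpolation at theta = 1 and the same point reached as the final
    step state agree to roundoff, and halving the step shrinks the
    single-step error by ~2^5.
    """
    one = radau5_integrate(
        decay.rhs, decay.jacobian, decay.X0, settings([0.5], fixed_step=0.5)
    )
    dense = radau5_integrate(
        decay.rhs, decay.jacobian, decay.X0,
        settings([0.25, 0.5], fixed_step=0.5),
    )
    assert abs(one.states[-1, 0] - dense.states[-1, 0]) < 1e-14
    half = radau5_integrate(
        decay.rhs, decay.jacobian, decay.X0, settings([0.5], fixed_step=0.25)
    )
    err_one = abs(one.states[-1, 0] - np.exp(-0.5))
    err_half = abs(half.states[-1, 0] - np.exp(-0.5))
    assert err_one < 1e-4
    assert err_one / err_half > 20.0


def test_step_limit_status(decay):
    s = settings([50.0], max_steps=3)
    traj = dopri5_integrate(decay.rhs, decay.X0, s)
    assert traj.status == Status.STEP_LIMIT_EXCEEDED
    assert traj.n_steps == traj.n_accepted + traj.n_rejected <= 3


def test_degenerate_single_zero_time(decay):
    for fn in (
        lambda: dopri5_integrate(decay.rhs, decay.X0, settings([0.0])),
        lambda: radau5_integrate(decay.rhs, decay.jacobian, decay.X0, settings([0.0])),
    ):
        traj = fn()
        assert traj.status == Status.SUCCESS
        np.testing.assert_array_equal(traj.states, [[1.0]])


def test_counters_consistent(reversible_pair):
    traj = dopri5_integrate(
        reversible_pair.rhs, reversible_pair.X0, settings([20.0], eps_r=1e-9)
    )
    assert traj.n_steps == traj.n_accepted + traj.n_rejected
    assert traj.n_accepted > 0 and traj.n_rejected >= 0


def test_invalid_settings_rejected():
    with pytest.raises(ValueError):
        SolverSettings(eps_a=-1.0, t_out=np.array([1.0]))
    with pytest.raises(ValueError):
        SolverSettings(t_out=np.array([1.0, 0.5]))
    with pytest.raises(ValueError):
        SolverSettings(t_out=np.array([]))
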