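"""ODE simulation, forward sensitivity analysis and the adjoint backward pass.

The model expressions are compiled symbolically once per model; the exact
Jacobians df/dx, df/dtheta, dh/dx, dh/dtheta and dx0/dtheta are derived with
sympy so that the adjoint jump conditions are exact.

The adjoint state ``p`` has dimension ``n_x`` (the number of model states),
independent of the number of parameters.  Between measurement times it obeys

    pdot = -(df/dx)^T p,     p == 0 after the last measurement,

with a jump ``p <- p + (dJ_i/dx)^T`` at each measurement time (applied by the
objective layer through ``jumps``).  The parameter gradient is assembled as

    dJ/dtheta = sum_i dJ_i/dtheta|_explicit
                + int_{t0}^{T} p^T (df/dtheta) dt + p(t0)^T dx0/dtheta,

where the quadrature is evaluated over the dense interpolants of x and p so
that the backward ODE state itself never grows with the parameter count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import sympy as sp
from scipy.integrate import quad_vec, solve_ivp

from .problem import Condition, OdeModel

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-12

_LN2 = math.log(2.0)
_LN10 = math.log(10.0)


def apply_transformation(raw, transformation):
    """Apply an observable transformation; returns (value, ok)."""
    raw = np.asarray(raw, dtype=float)
    if transformation == "identity":
        return raw, np.isfinite(raw)
    ok = np.isfinite(raw) & (raw > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        if transformation == "log2":
            return np.log2(raw), ok
        if transformation == "log10":
            return np.log10(raw), ok
    raise ValueError(f"unknown transformation '{transformation}'")


def transformation_chain_factor(raw, transformation):
    """d(transformed)/d(raw): 1, 1/(raw ln 2) or 1/(raw ln 10)."""
    if transformation == "identity":
        return np.ones_like(np.asarray(raw, dtype=float))
    if transformation == "log2":
        return 1.0 / (np.asarray(raw, dtype=float) * _LN2)
    if transformation == "log10":
        return 1.0 / (np.asarray(raw, dtype=float) * _LN10)
    raise ValueError(f"unknown transformation '{transformation}'")


class CompiledModel:
    """Symbolically compiled model: vector field, observables and their exact
    Jacobians as fast numpy callables with signature (t, x, theta, u)."""

    def __init__(self, model: OdeModel):
        self.model = model
        t = sp.Symbol("t")
        xs = sp.symbols([f"{s}" for s in model.state_ids]) if model.state_ids else []
        ps = (
            sp.symbols([f"{s}" for s in model.parameter_ids])
            if model.parameter_ids
            else []
        )
        us = (
            sp.symbols([f"{s}" for s in model.condition_variable_ids])
            if model.condition_variable_ids
            else []
        )
        if len(model.state_ids) == 1:
            xs = [xs] if not isinstance(xs, (list, tuple)) else list(xs)
        if len(model.parameter_ids) == 1:
            ps = [ps] if not isinstance(ps, (list, tuple)) else list(ps)
        if len(model.condition_variable_ids) == 1:
            us = [us] if not isinstance(us, (list, tuple)) else list(us)
        xs, ps, us = list(xs), list(ps), list(us)
        local = {str(s): s for s in [*xs, *ps, *us, t]}

        def parse(expr):
            return sp.sympify(expr, locals=local)

        f = sp.Matrix([parse(e) for e in model.rhs_expressions])
        x0 = sp.Matrix([parse(e) for e in model.initial_expressions])
        h = sp.Matrix([parse(o.formula) for o in model.observables]) if model.observables else sp.Matrix([])

        def jac(expr_matrix, wrt):
            if expr_matrix.rows == 0 or len(wrt) == 0:
                return sp.zeros(expr_matrix.rows, len(wrt))
            return expr_matrix.jacobian(sp.Matrix(wrt))

        args = (t, xs, ps, us)
        self._f = self._lambdify(args, f)
        self._dfdx = self._lambdify(args, jac(f, xs))
        self._dfdp = self._lambdify(args, jac(f, ps))
        args0 = (ps, us)
        self._x0 = self._lambdify0(args0, x0)
        self._dx0dp = self._lambdify0(args0, jac(x0, ps))
        self._h = self._lambdify(args, h)
        self._dhdx = self._lambdify(args, jac(h, xs))
        self._dhdp = self._lambdify(args, jac(h, ps))

        self.n_states = model.n_states
        self.n_parameters = model.n_parameters
        self.obs_index = {o.observable_id: k for k, o in enumerate(model.observables)}
        self.transformations = [o.transformation for o in model.observables]

    @staticmethod
    def _lambdify(args, mat):
        t, xs, ps, us = args
        fn = sp.lambdify((t, xs, ps, us), mat, modules="numpy")
        shape = (mat.rows, mat.cols)

        def call(tv, x, p, u):
            return np.asarray(fn(tv, list(x), list(p), list(u)), dtype=float).reshape(shape)

        return call

    @staticmethod
    def _lambdify0(args, mat):
        ps, us = args
        fn = sp.lambdify((ps, us), mat, modules="numpy")
        shape = (mat.rows, mat.cols)

        def call(p, u):
            return np.asarray(fn(list(p), list(u)), dtype=float).reshape(shape)

        return call

    # -- condition resolution ------------------------------------------------

    def resolve_condition(self, theta, condition: Condition | None):
        """Build (theta_eff, u, free_mask): overridden parameters become
        constants for this condition, so their sensitivity columns are zeroed."""
        theta_eff = np.array(theta, dtype=float)
        u = np.zeros(len(self.model.condition_variable_ids))
        free = np.ones(self.n_parameters, dtype=bool)
        if condition is not None:
            pidx = {p: i for i, p in enumerate(self.model.parameter_ids)}
            uidx = {v: i for i, v in enumerate(self.model.condition_variable_ids)}
            for target, value in condition.override_map.items():
                if target in uidx:
                    u[uidx[target]] = value
                else:
                    theta_eff[pidx[target]] = value
                    free[pidx[target]] = False
        return theta_eff, u, free

    def f(self, t, x, p, u):
        return self._f(t, x, p, u)[:, 0]

    def dfdx(self, t, x, p, u):
        return self._dfdx(t, x, p, u)

    def dfdp(self, t, x, p, u):
        return self._dfdp(t, x, p, u)

    def x0(self, p, u):
        return self._x0(p, u)[:, 0]

    def dx0dp(self, p, u):
        return self._dx0dp(p, u)

    def h_raw(self, t, x, p, u):
        return self._h(t, x, p, u)[:, 0]

    def dhdx(self, t, x, p, u):
        return self._dhdx(t, x, p, u)

    def dhdp(self, t, x, p, u):
        return self._dhdp(t, x, p, u)


@dataclass
class Trajectory:
    """Forward solution on a time grid, with a dense interpolant on [t0, T]."""

    times: np.ndarray
    states: np.ndarray  # (n_times, n_x)
    dense_interpolant: object  # OdeSolution or None (degenerate t0-only case)
    theta_eff: np.ndarray
    u: np.ndarray
    free_mask: np.ndarray
    success: bool = True
    message: str = ""
    t0: float = 0.0
    x0_value: np.ndarray | None = None

    def state_at(self, t):
        if self.dense_interpolant is None or t <= self.t0:
            return self.x0_value
        return np.asarray(self.dense_interpolant(t), dtype=float)


@dataclass
class ForwardSensitivities:
    """dx/dtheta at the trajectory's grid times; shape (n_times, n_x, n_theta)."""

    times: np.ndarray
    dx_dtheta: np.ndarray
    trajectory: Trajectory


@dataclass
class AdjointState:
    """Result of the backward pass: gradient pieces assembled from p."""

    quadrature: np.ndarray  # int p^T df/dtheta dt, shape (n_theta,)
    init_term: np.ndarray  # p(t0)^T dx0/dtheta
    p_t0: np.ndarray
    jump_times: np.ndarray
    backward_state_dimension: int
    success: bool = True
    message: str = ""


#: State-magnitude ceiling: beyond this the trajectory is treated as diverged
#: (LSODA can otherwise grind indefinitely near a finite-time blow-up).
BLOWUP_LIMIT = 1e120


class _IntegrationBlowUp(FloatingPointError):
    pass


def _guarded(fun):
    """Wrap an ODE right-hand side so divergence aborts integration quickly."""

    def wrapped(t, z):
        if not np.all(np.isfinite(z)) or np.max(np.abs(z)) > BLOWUP_LIMIT:
            raise _IntegrationBlowUp(f"state magnitude exceeded {BLOWUP_LIMIT:g}")
        with np.errstate(over="raise", invalid="raise"):
            try:
                return fun(t, z)
            except FloatingPointError as err:
                raise _IntegrationBlowUp(f"overflow in vector field: {err}") from err

    return wrapped


def _failed_trajectory(times, nx, theta_eff, u, free, message):
    return Trajectory(
        times=np.asarray(times, dtype=float),
        states=np.full((len(times), nx), np.nan),
        dense_interpolant=None,
        theta_eff=theta_eff,
        u=u,
        free_mask=free,
        success=False,
        message=message,
    )


def simulate(
    compiled: CompiledModel,
    theta,
    condition: Condition | None,
    times,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> Trajectory:
    """Integrate the model from t0=0 and return states at the requested times.

    Integration failure or a non-finite state yields a trajectory with
    ``success=False`` (the objective layer maps this to an infinite
    objective) rather than an exception.
    """
    times = np.asarray(sorted(set(float(t) for t in times)), dtype=float)
    theta_eff, u, free = compiled.resolve_condition(theta, condition)
    x0 = compiled.x0(theta_eff, u)
    if not np.all(np.isfinite(x0)):
        return _failed_trajectory(times, compiled.n_states, theta_eff, u, free,
                                  "non-finite initial state")
    t_end = float(times[-1]) if len(times) else 0.0
    if t_end <= 0.0:
        states = np.tile(x0, (len(times), 1))
        return Trajectory(times, states, None, theta_eff, u, free,
                          t0=0.0, x0_value=x0)
    try:
        sol = solve_ivp(
            _guarded(lambda t, x: compiled.f(t, x, theta_eff, u)),
            (0.0, t_end),
            x0,
            method="LSODA",
            jac=lambda t, x: compiled.dfdx(t, x, theta_eff, u),
            dense_output=True,
            rtol=rtol,
            atol=atol,
        )
    except (ValueError, FloatingPointError, OverflowError) as err:
        return _failed_trajectory(times, compiled.n_states, theta_eff, u, free, str(err))
    if not sol.success:
        return _failed_trajectory(times, compiled.n_states, theta_eff, u, free, sol.message)
    states = sol.sol(times).T
    if not np.all(np.isfinite(states)):
        return _failed_trajectory(times, compiled.n_states, theta_eff, u, free,
                                  "non-finite state in solution")
    return Trajectory(times, states, sol.sol, theta_eff, u, free,
                      t0=0.0, x0_value=x0)


def forward_sensitivities(
    compiled: CompiledModel,
    theta,
    condition: Condition | None,
    times,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> ForwardSensitivities:
    """Solve the augmented variational system for dx/dtheta.

    Columns belonging to parameters overridden by the condition are zero
    (those parameters are constants within the condition).
    """
    times = np.asarray(sorted(set(float(t) for t in times)), dtype=float)
    theta_eff, u, free = compiled.resolve_condition(theta, condition)
    nx, npar = compiled.n_states, compiled.n_parameters
    x0 = compiled.x0(theta_eff, u)
    S0 = compiled.dx0dp(theta_eff, u)
    S0[:, ~free] = 0.0
    z0 = np.concatenate([x0, S0.ravel()])

    def rhs(t, z):
        x = z[:nx]
        S = z[nx:].reshape(nx, npar)
        J = compiled.dfdx(t, x, theta_eff, u)
        Jp = compiled.dfdp(t, x, theta_eff, u)
        Jp[:, ~free] = 0.0
        return np.concatenate([compiled.f(t, x, theta_eff, u), (J @ S + Jp).ravel()])

    t_end = float(times[-1]) if len(times) else 0.0
    if not np.all(np.isfinite(x0)) or t_end <= 0.0:
        trajectory = simulate(compiled, theta, condition, times, rtol=rtol, atol=atol)
        S = np.tile(S0, (len(times), 1, 1))
        if not trajectory.success:
            S = np.full((len(times), nx, npar), np.nan)
        return ForwardSensitivities(times, S, trajectory)
    try:
        sol = solve_ivp(_guarded(rhs), (0.0, t_end), z0, method="LSODA",
                        dense_output=True, rtol=rtol, atol=atol)
    except (ValueError, FloatingPointError, OverflowError) as err:
        trajectory = _failed_trajectory(times, nx, theta_eff, u, free, str(err))
        return ForwardSensitivities(
            times, np.full((len(times), nx, npar), np.nan), trajectory
        )
    if not sol.success or not np.all(np.isfinite(sol.sol(times))):
        trajectory = _failed_trajectory(
            times, nx, theta_eff, u, free,
            f"sensitivity integration failed: {sol.message if not sol.success else 'non-finite state'}",
        )
        return ForwardSensitivities(
            times, np.full((len(times), nx, npar), np.nan), trajectory
        )
    Z = sol.sol(times).T
    S = Z[:, nx:].reshape(len(times), nx, npar)

    class _StateSlice:
        """Dense interpolant of x extracted from the augmented solution."""

        def __init__(self, dense, n):
            self._dense, self._n = dense, n

        def __call__(self, t):
            return np.asarray(self._dense(t), dtype=float)[: self._n]

    trajectory = Trajectory(
        times=times,
        states=Z[:, :nx],
        dense_interpolant=_StateSlice(sol.sol, nx),
        theta_eff=theta_eff,
        u=u,
        free_mask=free,
        t0=0.0,
        x0_value=x0,
    )
    return ForwardSensitivities(times, S, trajectory)


def adjoint_backward(
    compiled: CompiledModel,
    trajectory: Trajectory,
    jumps: list[tuple[float, np.ndarray]],
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    quad_tol: float = 1e-10,
) -> AdjointState:
    """Integrate the adjoint ODE backward with measurement-time jumps.

    ``jumps`` is a list of ``(time, dJ_i/dx)`` contributions computed by the
    objective layer *after* the inner static parameters are fixed; several
    jumps at the same time are summed.  Returns the quadrature and
    initial-condition pieces of the gradient (explicit dJ/dtheta terms are
    added by the caller).
    """
    nx, npar = compiled.n_states, compiled.n_parameters
    theta_eff, u, free = trajectory.theta_eff, trajectory.u, trajectory.free_mask

    by_time: dict[float, np.ndarray] = {}
    for t_i, contribution in jumps:
        key = float(t_i)
        by_time[key] = by_time.get(key, np.zeros(nx)) + np.asarray(contribution, float)
    jump_times = np.asarray(sorted(by_time), dtype=float)

    p = np.zeros(nx)  # p == 0 after the last measurement
    quadrature = np.zeros(npar)
    boundaries = sorted(set([trajectory.t0, *by_time.keys()]), reverse=True)

    def dfdp_free(t, x):
        Jp = compiled.dfdp(t, x, theta_eff, u)
        Jp[:, ~free] = 0.0
        return Jp

    for k, t_hi in enumerate(boundaries):
        if t_hi in by_time:
            p = p + by_time[t_hi]
        t_lo = boundaries[k + 1] if k + 1 < len(boundaries) else trajectory.t0
        if t_lo >= t_hi:
            continue
        if not np.any(p):
            continue  # p stays 0; quadrature contributes nothing
        try:
            sol = solve_ivp(
                _guarded(lambda t, pv: -compiled.dfdx(
                    t, trajectory.state_at(t), theta_eff, u
                ).T @ pv),
                (t_hi, t_lo),
                p,
                method="LSODA",
                dense_output=True,
                rtol=rtol,
                atol=atol,
            )
        except (ValueError, FloatingPointError, OverflowError) as err:
            return AdjointState(np.full(npar, np.nan), np.full(npar, np.nan),
                                p, jump_times, nx, success=False, message=str(err))
        if not sol.success:
            return AdjointState(np.full(npar, np.nan), np.full(npar, np.nan),
                                p, jump_times, nx, success=False, message=sol.message)

        def integrand(t, _sol=sol):
            x = trajectory.state_at(t)
            return _sol.sol(t) @ dfdp_free(t, x)

        segment, _ = quad_vec(integrand, t_lo, t_hi, epsabs=quad_tol, epsrel=quad_tol)
        quadrature += segment
        p = np.asarray(sol.sol(t_lo), dtype=float)

    dx0 = compiled.dx0dp(theta_eff, u)
    dx0[:, ~free] = 0.0
    init_term = p @ dx0
    return AdjointState(quadrature, init_term, p, jump_times, nx)
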