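"""Objective functions and gradients.

Two modes are supported:

- *standard*: the Gaussian negative log-likelihood J(theta, s, b, sigma)
  with all non-fixed static parameters as explicit outer coordinates;
- *hierarchical*: the reduced objective Jhat(theta) = J(theta, s(theta),
  b(theta), sigma(theta)) where the analytic statics are replaced by their
  closed-form conditional optima at every evaluation.

Because the inner solution is exactly stationary (grad_{s,b,sigma} J = 0),
the total gradient of Jhat equals the partial theta-gradient of J at the
fixed optimal statics (envelope property).  Both forward-sensitivity and
adjoint assembly of that gradient are provided and must agree; a central
finite-difference fallback re-solves the inner problem at each perturbation
and therefore checks the envelope property itself.

Noise groups clipped at the sigma floor break the envelope property locally;
their sigma is treated as a constant at the floor (the gradient is one-sided
there) and the clip is recorded in the evaluation trace.
"""

from __future__ import annotations

import math
import time as _time
from dataclasses import dataclass

import numpy as np

from .errors import SimulationError
from .inner import LOG_2PI, InnerSolution, solve_inner
from .ode import (
    CompiledModel,
    adjoint_backward,
    apply_transformation,
    forward_sensitivities,
    simulate,
    transformation_chain_factor,
)
from .problem import (
    DEFAULT_STATIC_BOUNDS,
    DEFAULT_STATIC_VALUES,
    STATIC_SCALES,
    Problem,
)

_LN10 = math.log(10.0)


@dataclass
class ObjectiveValue:
    value: float
    per_datapoint_contributions: np.ndarray | None = None
    failure_flag: bool = False
    failure_message: str = ""
    inner_solution: InnerSolution | None = None


@dataclass
class GradientResult:
    gradient: np.ndarray
    method: str
    parameter_names: tuple[str, ...] = ()
    failure_flag: bool = False

    @property
    def gradient_norm(self) -> float:
        return float(np.linalg.norm(self.gradient))


@dataclass
class GradientRatio:
    """E[|grad_s J|] / E[|grad_theta J|]; ``defined`` is False when the
    dynamic-gradient mean is zero."""

    ratio: float
    defined: bool
    mean_scaling: float = 0.0
    mean_dynamic: float = 0.0


class ParameterSpace:
    """Mapping between the optimizer's vector and (theta, statics).

    Coordinates are kept on their declared optimization scale: dynamic
    parameters per the problem's ``dynamic_parameter_scale`` (log10 by
    default), scalings and noise parameters on log10, offsets linear.  In
    hierarchical mode the outer vector holds theta plus numeric-mode
    statics; in standard mode also the analytic-mode statics (optimized
    numerically there).  Analytic statics never appear in the hierarchical
    outer vector.
    """

    def __init__(self, problem: Problem, mode: str):
        if mode not in ("standard", "hierarchical"):
            raise ValueError(f"unknown mode '{mode}'")
        self.problem = problem
        self.mode = mode
        scale_map = problem.scale_map
        bounds_map = problem.bounds_map
        self.entries: list[dict] = []
        for pid in problem.model.parameter_ids:
            self.entries.append(
                {
                    "name": pid,
                    "target": ("dynamic", pid),
                    "scale": scale_map[pid],
                    "bounds": tuple(bounds_map[pid]),
                }
            )
        include_modes = ("numeric",) if mode == "hierarchical" else ("numeric", "analytic")
        used = {
            g
            for kind in ("scaling", "offset", "noise")
            for g in problem.groups.groups(kind)
        }
        for spec in problem.groups.specs:
            if spec.mode not in include_modes or spec.group_id not in used:
                continue
            bounds = spec.bounds or DEFAULT_STATIC_BOUNDS[spec.kind]
            self.entries.append(
                {
                    "name": f"{spec.kind}:{spec.group_id}",
                    "target": (spec.kind, spec.group_id),
                    "scale": STATIC_SCALES[spec.kind],
                    "bounds": tuple(bounds),
                }
            )

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(e["name"] for e in self.entries)

    @property
    def n(self) -> int:
        return len(self.entries)

    @property
    def n_dynamic(self) -> int:
        return sum(1 for e in self.entries if e["target"][0] == "dynamic")

    def is_static(self, i: int, kind: str | None = None) -> bool:
        target = self.entries[i]["target"]
        return target[0] != "dynamic" and (kind is None or target[0] == kind)

    def internal_bounds(self) -> list[tuple[float, float]]:
        out = []
        for e in self.entries:
            lo, hi = e["bounds"]
            if e["scale"] == "log10":
                out.append((math.log10(lo), math.log10(hi)))
            else:
                out.append((lo, hi))
        return out

    def to_internal(self, values_lin: np.ndarray) -> np.ndarray:
        x = np.array(values_lin, dtype=float)
        for i, e in enumerate(self.entries):
            if e["scale"] == "log10":
                x[i] = math.log10(x[i])
        return x

    def to_linear(self, x: np.ndarray) -> np.ndarray:
        v = np.array(x, dtype=float)
        for i, e in enumerate(self.entries):
            if e["scale"] == "log10":
                v[i] = 10.0 ** v[i]
        return v

    def unpack(self, x: np.ndarray) -> tuple[np.ndarray, dict]:
        """Internal vector -> (theta on linear scale, statics {(kind, gid): value})."""
        v = self.to_linear(x)
        theta = np.empty(self.problem.model.n_parameters)
        statics = {}
        pidx = {p: i for i, p in enumerate(self.problem.model.parameter_ids)}
        for value, e in zip(v, self.entries):
            kind, target = e["target"]
            if kind == "dynamic":
                theta[pidx[target]] = value
            else:
                statics[(kind, target)] = value
        return theta, statics

    def grad_to_internal(self, grad_lin: np.ndarray, x: np.ndarray) -> np.ndarray:
        """Chain rule d/d(log10 v) = v ln(10) d/dv on log-scaled coordinates."""
        g = np.array(grad_lin, dtype=float)
        v = self.to_linear(x)
        for i, e in enumerate(self.entries):
            if e["scale"] == "log10":
                g[i] *= v[i] * _LN10
        return g


class Evaluator:
    """Compiles a problem once and evaluates objectives and gradients.

    Records a trace entry per evaluation: {iter, J, grad_norm, ratio,
    clipped_groups, wall_time}.
    """

    def __init__(
        self,
        problem: Problem,
        rtol: float = 1e-8,
        atol: float = 1e-12,
        omit_constant_terms: bool | None = None,
    ):
        self.problem = problem
        self.compiled = CompiledModel(problem.model)
        self.rtol = rtol
        self.atol = atol
        if omit_constant_terms is None:
            omit_constant_terms = bool(
                problem.config_map.get("omit_constant_terms", False)
            )
        self.omit_constant_terms = omit_constant_terms
        self.trace: list[dict] = []
        self._n_eval = 0
        self.n_simulation_failures = 0

        # measurement layout per condition
        self.by_condition = []
        measurements = problem.measurements
        for ci, cond in enumerate(problem.conditions):
            idx = [
                i for i, m in enumerate(measurements) if m.condition_id == cond.condition_id
            ]
            if not idx:
                continue
            times = sorted({measurements[i].time for i in idx})
            t_index = {t: k for k, t in enumerate(times)}
            rows = [
                (
                    i,
                    t_index[measurements[i].time],
                    self.compiled.obs_index[measurements[i].observable_id],
                )
                for i in idx
            ]
            self.by_condition.append(
                {"condition": cond, "times": np.asarray(times, float), "rows": rows}
            )
        self.n_measurements = len(measurements)
        self.y = np.array([m.value for m in measurements], dtype=float)

    # -- simulation of observables ------------------------------------------

    def observables(self, theta, with_sensitivities: bool = False):
        """Simulate all conditions; return transformed observables per
        measurement (and their theta-sensitivities), or a failure."""
        h = np.full(self.n_measurements, np.nan)
        dh = (
            np.zeros((self.n_measurements, self.compiled.n_parameters))
            if with_sensitivities
            else None
        )
        trajectories = []
        for block in self.by_condition:
            cond, times, rows = block["condition"], block["times"], block["rows"]
            if with_sensitivities:
                fs = forward_sensitivities(
                    self.compiled, theta, cond, times, rtol=self.rtol, atol=self.atol
                )
                trajectory = fs.trajectory
            else:
                trajectory = simulate(
                    self.compiled, theta, cond, times, rtol=self.rtol, atol=self.atol
                )
            if not trajectory.success:
                return None, None, trajectory.message
            trajectories.append((block, trajectory))
            theta_eff, u = trajectory.theta_eff, trajectory.u
            t_grid = trajectory.times
            raw_cache = {}
            for mi, ti, oi in rows:
                t = t_grid[ti]
                x = trajectory.states[ti]
                if ti not in raw_cache:
                    raw_cache[ti] = self.compiled.h_raw(t, x, theta_eff, u)
                raw = raw_cache[ti][oi]
                transformation = self.compiled.transformations[oi]
                value, ok = apply_transformation(raw, transformation)
                if not ok:
                    return None, None, (
                        f"observable '{self.problem.model.observable_ids[oi]}' "
                        f"non-positive under {transformation} at t={t}"
                    )
                h[mi] = float(value)
                if with_sensitivities:
                    dgdx = self.compiled.dhdx(t, x, theta_eff, u)[oi]
                    dgdp = self.compiled.dhdp(t, x, theta_eff, u)[oi].copy()
                    dgdp[~trajectory.free_mask] = 0.0
                    chain = float(transformation_chain_factor(raw, transformation))
                    dh[mi] = chain * (dgdx @ fs.dx_dtheta[ti] + dgdp)
        return h, (dh, trajectories), None

    # -- objective values ----------------------------------------------------

    def _nll_from_arrays(self, h, s_i, b_i, sigma_i) -> ObjectiveValue:
        r = self.y - (s_i * h + b_i)
        contributions = 0.5 * (r / sigma_i) ** 2
        if not self.omit_constant_terms:
            contributions = contributions + 0.5 * (LOG_2PI + 2.0 * np.log(sigma_i))
        return ObjectiveValue(
            value=float(np.sum(contributions)),
            per_datapoint_contributions=contributions,
        )

    def resolve_static_arrays(self, statics: dict | None):
        """Per-datapoint s, b, sigma from fixed specs, defaults and the given
        {(kind, gid): value} overrides (numeric current values or any
        explicitly supplied statics)."""
        statics = statics or {}
        n = self.n_measurements
        s_i = np.ones(n)
        b_i = np.zeros(n)
        sigma_i = np.ones(n)
        groups = self.problem.groups
        for kind, arr in (("scaling", s_i), ("offset", b_i), ("noise", sigma_i)):
            for gid, idx in groups.groups(kind).items():
                spec = groups.spec(gid)
                if (kind, gid) in statics:
                    value = float(statics[(kind, gid)])
                elif spec.mode == "fixed":
                    value = float(spec.fixed_value)
                else:
                    value = DEFAULT_STATIC_VALUES[kind]
                if kind == "offset":
                    arr[list(idx)] += value
                else:
                    arr[list(idx)] = value
        return s_i, b_i, sigma_i

    def standard_objective(self, theta, statics: dict | None = None) -> ObjectiveValue:
        """J(theta, s, b, sigma) with every static explicitly supplied
        (missing ones fall back to fixed values / defaults)."""
        h, _, err = self.observables(theta)
        if err is not None:
            self.n_simulation_failures += 1
            return ObjectiveValue(math.inf, failure_flag=True, failure_message=err)
        s_i, b_i, sigma_i = self.resolve_static_arrays(statics)
        return self._nll_from_arrays(h, s_i, b_i, sigma_i)

    def hierarchical_objective(
        self, theta, numeric_values: dict | None = None
    ) -> ObjectiveValue:
        """Jhat(theta): analytic statics at their closed-form optima."""
        h, _, err = self.observables(theta)
        if err is not None:
            self.n_simulation_failures += 1
            return ObjectiveValue(math.inf, failure_flag=True, failure_message=err)
        inner = solve_inner(
            h,
            list(self.problem.measurements),
            self.problem.groups,
            sigma_floor=self.problem.sigma_floor,
            numeric_values=numeric_values,
        )
        result = self._nll_from_arrays(h, inner.s_i, inner.b_i, inner.sigma_i)
        result.inner_solution = inner
        return result

    # -- gradients -----------------------------------------------------------

    def _residual_quantities(self, h, s_i, b_i, sigma_i):
        r = self.y - (s_i * h + b_i)
        v = -(r / sigma_i**2) * s_i  # dJ_i / dh_i at fixed statics
        return r, v

    def _static_partials(self, h, r, sigma_i, space: ParameterSpace):
        """Explicit partials of J w.r.t. outer static coordinates (linear scale)."""
        groups = self.problem.groups
        partials = {}
        for e in space.entries:
            kind, gid = e["target"]
            if kind == "dynamic":
                continue
            idx = list(groups.groups(kind)[gid])
            if kind == "scaling":
                partials[(kind, gid)] = -float(
                    np.sum(r[idx] * h[idx] / sigma_i[idx] ** 2)
                )
            elif kind == "offset":
                partials[(kind, gid)] = -float(np.sum(r[idx] / sigma_i[idx] ** 2))
            else:  # noise
                sig = sigma_i[idx]
                term = -(r[idx] ** 2) / sig**3
                if not self.omit_constant_terms:
                    term = term + 1.0 / sig
                partials[(kind, gid)] = float(np.sum(term))
        return partials

    def _theta_gradient_forward(self, theta, s_i, b_i, sigma_i):
        h, aux, err = self.observables(theta, with_sensitivities=True)
        if err is not None:
            return None, None, err
        dh = aux[0]
        _, v = self._residual_quantities(h, s_i, b_i, sigma_i)
        return h, v @ dh, None

    def _theta_gradient_adjoint(self, theta, h, s_i, b_i, sigma_i):
        """Assemble dJ/dtheta from the adjoint backward pass (Fig-1 style
        ordering: statics are already fixed when the adjoint is simulated)."""
        _, v = self._residual_quantities(h, s_i, b_i, sigma_i)
        gradient = np.zeros(self.compiled.n_parameters)
        for block in self.by_condition:
            cond, times, rows = block["condition"], block["times"], block["rows"]
            trajectory = simulate(
                self.compiled, theta, cond, times, rtol=self.rtol, atol=self.atol
            )
            if not trajectory.success:
                return None, trajectory.message
            theta_eff, u = trajectory.theta_eff, trajectory.u
            jumps = []
            raw_cache = {}
            for mi, ti, oi in rows:
                t = trajectory.times[ti]
                x = trajectory.states[ti]
                if ti not in raw_cache:
                    raw_cache[ti] = self.compiled.h_raw(t, x, theta_eff, u)
                raw = raw_cache[ti][oi]
                chain = float(
                    transformation_chain_factor(
                        raw, self.compiled.transformations[oi]
                    )
                )
                dgdx = self.compiled.dhdx(t, x, theta_eff, u)[oi]
                jumps.append((t, v[mi] * chain * dgdx))
                dgdp = self.compiled.dhdp(t, x, theta_eff, u)[oi].copy()
                dgdp[~trajectory.free_mask] = 0.0
                gradient += v[mi] * chain * dgdp  # explicit theta-dependence of h
            adj = adjoint_backward(
                self.compiled, trajectory, jumps, rtol=self.rtol, atol=self.atol
            )
            if not adj.success:
                return None, adj.message
            gradient += adj.quadrature + adj.init_term
        return gradient, None

    def objective_and_gradient(
        self,
        x: np.ndarray,
        space: ParameterSpace,
        method: str = "forward",
        record: bool = True,
    ) -> tuple[ObjectiveValue, GradientResult]:
        """Outer objective and gradient at the internal vector ``x``.

        Hierarchical mode solves the inner problem first; the gradient uses
        the envelope property (no terms for analytic statics; numeric
        statics receive their explicit partials, mapped to their
        optimization scale).
        """
        t_start = _time.perf_counter()
        theta, statics = space.unpack(x)
        if space.mode == "hierarchical":
            value = self.hierarchical_objective(theta, numeric_values=statics)
            inner = value.inner_solution
            if value.failure_flag:
                grad = GradientResult(
                    np.zeros(space.n), method, space.names, failure_flag=True
                )
                self._record(value, grad, None, t_start, record)
                return value, grad
            s_i, b_i, sigma_i = inner.s_i, inner.b_i, inner.sigma_i
        else:
            value = self.standard_objective(theta, statics)
            if value.failure_flag:
                grad = GradientResult(
                    np.zeros(space.n), method, space.names, failure_flag=True
                )
                self._record(value, grad, None, t_start, record)
                return value, grad
            s_i, b_i, sigma_i = self.resolve_static_arrays(statics)

        if method == "finite_difference":
            grad_internal = self._fd_gradient(x, space)
            grad = GradientResult(grad_internal, method, space.names)
            ratio = self._ratio_from_grad(grad_internal, space)
            self._record(value, grad, ratio, t_start, record)
            return value, grad

        if method == "forward":
            h, g_theta, err = self._theta_gradient_forward(theta, s_i, b_i, sigma_i)
        elif method == "adjoint":
            h, _, err = self.observables(theta)
            if err is None:
                g_theta, err = self._theta_gradient_adjoint(theta, h, s_i, b_i, sigma_i)
        else:
            raise ValueError(f"unknown gradient method '{method}'")
        if err is not None:
            grad = GradientResult(
                np.zeros(space.n), method, space.names, failure_flag=True
            )
            self._record(value, grad, None, t_start, record)
            return value, grad

        r = self.y - (s_i * h + b_i)
        static_partials = self._static_partials(h, r, sigma_i, space)
        grad_lin = np.zeros(space.n)
        pidx = {p: i for i, p in enumerate(self.problem.model.parameter_ids)}
        for i, e in enumerate(space.entries):
            kind, target = e["target"]
            if kind == "dynamic":
                grad_lin[i] = g_theta[pidx[target]]
            else:
                grad_lin[i] = static_partials[(kind, target)]
        grad_internal = space.grad_to_internal(grad_lin, x)
        grad = GradientResult(grad_internal, method, space.names)
        ratio = self._ratio_from_grad(grad_internal, space)
        self._record(value, grad, ratio, t_start, record)
        return value, grad

    def _fd_gradient(self, x, space: ParameterSpace, step: float = 1e-6) -> np.ndarray:
        """Central differences of the full outer objective (re-solves the
        inner problem at every perturbation in hierarchical mode)."""
        g = np.zeros(space.n)
        for i in range(space.n):
            for sign in (+1.0, -1.0):
                xs = np.array(x, dtype=float)
                xs[i] += sign * step
                theta, statics = space.unpack(xs)
                if space.mode == "hierarchical":
                    value = self.hierarchical_objective(theta, numeric_values=statics)
                else:
                    value = self.standard_objective(theta, statics)
                if value.failure_flag:
                    raise SimulationError(
                        f"simulation failed during finite differences: {value.failure_message}"
                    )
                g[i] += sign * value.value / (2.0 * step)
        return g

    def _ratio_from_grad(self, grad, space: ParameterSpace) -> GradientRatio | None:
        s_idx = [i for i in range(space.n) if space.is_static(i, "scaling")]
        d_idx = [i for i in range(space.n) if not space.is_static(i)]
        if not s_idx or not d_idx:
            return None
        mean_s = float(np.mean(np.abs(grad[s_idx])))
        mean_d = float(np.mean(np.abs(grad[d_idx])))
        if mean_d == 0.0:
            return GradientRatio(math.nan, False, mean_s, mean_d)
        return GradientRatio(mean_s / mean_d, True, mean_s, mean_d)

    def _record(self, value, grad, ratio, t_start, record):
        if not record:
            return
        self._n_eval += 1
        inner = value.inner_solution
        self.trace.append(
            {
                "iter": self._n_eval,
                "J": value.value if math.isfinite(value.value) else None,
                "grad_norm": None if grad.failure_flag else grad.gradient_norm,
                "ratio": None if ratio is None or not ratio.defined else ratio.ratio,
                "clipped_groups": list(inner.sigma_clipped_groups) if inner else [],
                "wall_time": _time.perf_counter() - t_start,
            }
        )


# -- module-level convenience API (constructs an Evaluator per call) ---------


def negative_log_likelihood(theta, s, b, sigma, problem: Problem, **kw) -> ObjectiveValue:
    """Standard objective (negative log-likelihood) with explicit statics.

    ``s``, ``b``, ``sigma`` map group ids to values; groups not mentioned
    fall back to their fixed values or the defaults s=1, b=0, sigma=1.
    """
    statics = {}
    for kind, mapping in (("scaling", s), ("offset", b), ("noise", sigma)):
        for gid, value in (mapping or {}).items():
            statics[(kind, gid)] = value
    return Evaluator(problem, **kw).standard_objective(theta, statics)


def hierarchical_objective(theta, problem: Problem, numeric_values=None, **kw) -> ObjectiveValue:
    """Reduced objective Jhat(theta) with analytic inner statics."""
    return Evaluator(problem, **kw).hierarchical_objective(theta, numeric_values)


def gradient(
    theta,
    problem: Problem,
    method: str = "forward",
    mode: str = "hierarchical",
    statics: dict | None = None,
    **kw,
) -> GradientResult:
    """Gradient of the outer objective w.r.t. the outer parameter vector.

    The vector is ordered as ``ParameterSpace(problem, mode).names``; theta
    components are reported on their declared optimization scale.
    """
    evaluator = Evaluator(problem, **kw)
    space = ParameterSpace(problem, mode)
    x = _internal_from_theta(space, theta, statics)
    _, grad = evaluator.objective_and_gradient(x, space, method=method, record=False)
    return grad


def _internal_from_theta(space: ParameterSpace, theta, statics: dict | None):
    statics = statics or {}
    pidx = {p: i for i, p in enumerate(space.problem.model.parameter_ids)}
    values_lin = np.empty(space.n)
    for i, e in enumerate(space.entries):
        kind, target = e["target"]
        if kind == "dynamic":
            values_lin[i] = np.asarray(theta, dtype=float)[pidx[target]]
        else:
            values_lin[i] = statics.get(
                (kind, target), DEFAULT_STATIC_VALUES[kind]
            )
    return space.to_internal(values_lin)


def gradient_ratio_from_components(grad_scaling, grad_dynamic) -> GradientRatio:
    """Ratio E[|grad_s J|]/E[|grad_theta J|] from explicit gradient blocks."""
    grad_scaling = np.asarray(grad_scaling, dtype=float)
    grad_dynamic = np.asarray(grad_dynamic, dtype=float)
    mean_s = float(np.mean(np.abs(grad_scaling))) if grad_scaling.size else 0.0
    mean_d = float(np.mean(np.abs(grad_dynamic))) if grad_dynamic.size else 0.0
    if mean_d == 0.0:
        return GradientRatio(math.nan, False, mean_s, mean_d)
    return GradientRatio(mean_s / mean_d, True, mean_s, mean_d)


def gradient_ratio_diagnostic(
    theta, problem: Problem, statics: dict | None = None, method: str = "forward", **kw
) -> GradientRatio:
    """Mean absolute gradient over scaling coordinates divided by the mean
    absolute gradient over dynamic coordinates, in standard mode."""
    evaluator = Evaluator(problem, **kw)
    space = ParameterSpace(problem, "standard")
    x = _internal_from_theta(space, theta, statics)
    _, grad = evaluator.objective_and_gradient(x, space, method=method, record=False)
    ratio = evaluator._ratio_from_grad(grad.gradient, space)
    if ratio is None:
        return GradientRatio(math.nan, False)
    return ratio
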