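"""Objective values, hierarchical reduction and gradient assembly."""

import math

import numpy as np
import pytest
from scipy import stats
from scipy.optimize import minimize

import hieropt as hp
from hieropt.objective import ParameterSpace, _internal_from_theta


def _static_problem(h_values, y_values, specs_and_groups=None):
    """A problem whose single 'state' is constant so the observable values
    are fully controlled: x' = 0, x(0) = 1, one observable per datapoint
    shape via condition overrides is unnecessary — instead each datapoint
    gets its own time with h pinned through a condition variable."""
    # h enters through the observable formula h = c * x with c a condition
    # variable; each datapoint lives in its own condition.
    model = hp.OdeModel(
        state_ids=("x",),
        parameter_ids=("k",),
        condition_variable_ids=("c",),
        rhs_expressions=("0*k",),
        initial_expressions=("1",),
        observables=(hp.Observable("obs", "c*x"),),
    )
    conditions, measurements = [], []
    for i, (hv, yv) in enumerate(zip(h_values, y_values)):
        cid = f"d{i}"
        conditions.append(hp.Condition(cid, {"c": float(hv)}))
        groups = specs_and_groups[1](i) if specs_and_groups else {}
        measurements.append(
            hp.Measurement("obs", cid, 1.0, float(yv), **groups)
        )
    specs = specs_and_groups[0] if specs_and_groups else []
    return hp.Problem(
        model=model,
        conditions=tuple(conditions),
        measurements=tuple(measurements),
        groups=hp.build_group_structure(measurements, specs),
        dynamic_parameter_scale={"k": "lin"},
        dynamic_bounds={"k": (0.1, 10.0)},
    )


class TestNegativeLogLikelihood:
    def test_perfect_fit_constant_term_only(self):
        problem = _static_problem([1.0], [1.0])
        value = hp.negative_log_likelihood([1.0], {}, {}, {}, problem)
        assert value.value == pytest.approx(0.5 * math.log(2 * math.pi), rel=1e-12)

    def test_unit_residual_adds_half(self):
        problem = _static_problem([1.0], [2.0])
        value = hp.negative_log_likelihood([1.0], {}, {}, {}, problem)
        assert value.value == pytest.approx(0.5 * math.log(2 * math.pi) + 0.5, rel=1e-12)

    def test_matches_gaussian_log_density_sum(self):
        """Independently coded oracle: negated sum of N(y | s h + b, sigma^2)
        log-densities over 5 seeded datapoints."""
        rng = np.random.default_rng(17)
        h = rng.uniform(0.5, 2.0, 5)
        y = rng.normal(1.0, 1.0, 5)
        specs = [
            hp.StaticParameterSpec("s", "scaling", "fixed", fixed_value=1.7),
            hp.StaticParameterSpec("b", "offset", "fixed", fixed_value=-0.3),
            hp.StaticParameterSpec("sig", "noise", "fixed", fixed_value=0.8),
        ]
        problem = _static_problem(
            h, y,
            (specs, lambda i: {"scaling_group": "s", "offset_groups": ("b",),
                               "noise_group": "sig"}),
        )
        value = hp.negative_log_likelihood([1.0], {}, {}, {}, problem)
        oracle = -float(np.sum(stats.norm.logpdf(y, loc=1.7 * h - 0.3, scale=0.8)))
        assert value.value == pytest.approx(oracle, rel=1e-12)
        assert np.sum(value.per_datapoint_contributions) == pytest.approx(value.value)

    def test_simulation_failure_maps_to_infinity(self):
        model = hp.OdeModel(
            state_ids=("x",), parameter_ids=("k",), condition_variable_ids=(),
            rhs_expressions=("k*x*x",), initial_expressions=("1",),
            observables=(hp.Observable("obs", "x"),),
        )
        measurements = [hp.Measurement("obs", "c0", 10.0, 1.0)]
        problem = hp.Problem(
            model=model, conditions=(hp.Condition("c0"),),
            measurements=tuple(measurements),
            groups=hp.build_group_structure(measurements, []),
            dynamic_parameter_scale={"k": "lin"}, dynamic_bounds={"k": (0.1, 10)},
        )
        value = hp.negative_log_likelihood([5.0], {}, {}, {}, problem)
        assert value.failure_flag and value.value == math.inf


class TestHierarchicalObjective:
    def test_exact_double_data_recovers_scaling(self):
        rng = np.random.default_rng(2)
        h = rng.uniform(0.5, 2.0, 6)
        specs = [
            hp.StaticParameterSpec("s_all", "scaling", "analytic"),
            hp.StaticParameterSpec("sig", "noise", "fixed", fixed_value=1.0),
        ]
        problem = _static_problem(
            h, 2.0 * h,
            (specs, lambda i: {"scaling_group": "s_all", "noise_group": "sig"}),
        )
        value = hp.hierarchical_objective([1.0], problem)
        n = len(h)
        assert value.inner_solution.s["s_all"] == pytest.approx(2.0, abs=1e-12)
        assert value.value == pytest.approx(n / 2 * math.log(2 * math.pi), rel=1e-12)

    def test_never_worse_than_any_static_draw(self, exp_decay_truth):
        problem = exp_decay_truth.problem
        theta = np.array([0.55])
        jhat = hp.hierarchical_objective(theta, problem).value
        rng = np.random.default_rng(8)
        for _ in range(100):
            j = hp.negative_log_likelihood(
                theta, {"s_all": float(rng.uniform(0.05, 8.0))}, {}, {}, problem
            ).value
            assert jhat <= j + 1e-12

    def test_matches_nested_numeric_minimization(self, cascade_truth):
        """Jhat(theta) equals min over the 7 statics of J(theta, .) computed
        by an independent nested minimization on the simulated observables."""
        problem = cascade_truth.problem
        theta = np.array([1.1, 0.75, 1.4, 0.65, 0.95, 0.45, 0.55, 0.28])
        ev = hp.Evaluator(problem)
        jhat = ev.hierarchical_objective(theta).value
        h, _, err = ev.observables(theta)
        assert err is None
        y = np.array([m.value for m in problem.measurements])
        groups = problem.groups

        def unpack(v):
            n = len(y)
            s_i, b_i, sigma_i = np.ones(n), np.zeros(n), np.ones(n)
            for value, gid in zip(v[:3], ("s_obs1", "s_obs2", "s_obs3")):
                s_i[list(groups.groups("scaling")[gid])] = value
            for value, gid in zip(v[3:5], ("b_obs2", "b_obs3")):
                b_i[list(groups.groups("offset")[gid])] = value
            for value, gid in zip(v[5:], ("sigma_12", "sigma_3")):
                sigma_i[list(groups.groups("noise")[gid])] = np.exp(value)
            return s_i, b_i, sigma_i

        def j_of(v):
            s_i, b_i, sigma_i = unpack(v)
            r = y - (s_i * h + b_i)
            return float(0.5 * np.sum(np.log(2 * np.pi * sigma_i**2) + (r / sigma_i) ** 2))

        rng = np.random.default_rng(9)
        best = math.inf
        for _ in range(8):  # multi-start oracle: 7-D landscape, NM can stall
            x0 = np.concatenate([rng.uniform(0.3, 3.0, 3), rng.normal(0, 1, 2),
                                 rng.normal(0, 1, 2)])
            stage1 = minimize(j_of, x0=x0, method="Nelder-Mead",
                              options={"maxiter": 20000, "maxfev": 20000,
                                       "xatol": 1e-11, "fatol": 1e-13})
            stage2 = minimize(j_of, x0=stage1.x, method="BFGS",
                              options={"gtol": 1e-10})
            best = min(best, stage1.fun, stage2.fun)
        assert jhat == pytest.approx(best, rel=1e-6)

    def test_reduces_to_standard_when_all_statics_fixed(self):
        bench = hp.make_benchmark("conversion_reaction")
        truth = hp.generate_data(bench.problem, bench.theta_true, bench.statics_true, seed=4)
        theta = np.array([0.9, 0.5])
        j_std = hp.negative_log_likelihood(theta, {}, {}, {}, truth.problem).value
        j_hier = hp.hierarchical_objective(theta, truth.problem).value
        assert j_hier == pytest.approx(j_std, rel=1e-14)


class TestGradient:
    def test_single_datapoint_closed_form(self):
        """Decay model, y=0 at t=1, statics at defaults: dJ/dk = -e^-2."""
        model = hp.OdeModel(
            state_ids=("x",), parameter_ids=("k",), condition_variable_ids=(),
            rhs_expressions=("-k*x",), initial_expressions=("1",),
            observables=(hp.Observable("obs", "x"),),
        )
        measurements = [hp.Measurement("obs", "c0", 1.0, 0.0)]
        problem = hp.Problem(
            model=model, conditions=(hp.Condition("c0"),),
            measurements=tuple(measurements),
            groups=hp.build_group_structure(measurements, []),
            dynamic_parameter_scale={"k": "lin"}, dynamic_bounds={"k": (0.01, 10)},
        )
        for method in ("forward", "adjoint", "finite_difference"):
            grad = hp.gradient([1.0], problem, method=method, mode="hierarchical")
            assert grad.gradient[0] == pytest.approx(-math.exp(-2.0), rel=1e-5)

    def test_perfect_fit_zero_gradient_all_methods(self, exp_decay):
        truth = hp.generate_data(
            exp_decay.problem, exp_decay.theta_true, exp_decay.statics_true,
            seed=0, noise_sd=0.0,
        )
        theta = exp_decay.theta_true_vector
        for method in ("forward", "adjoint", "finite_difference"):
            grad = hp.gradient(theta, truth.problem, method=method)
            assert np.all(np.abs(grad.gradient) < 1e-5)

    def test_envelope_property_fd_matches_fixed_statics_gradient(self, cascade_truth):
        """Central FD of Jhat implicitly re-solves the inner problem at each
        perturbation; equality with the fixed-statics analytic gradient is
        exactly the envelope property."""
        ev = hp.Evaluator(cascade_truth.problem, rtol=1e-10, atol=1e-14)
        space = ParameterSpace(cascade_truth.problem, "hierarchical")
        x = _internal_from_theta(space, np.array([1.3, 0.9, 1.2, 0.7, 1.0, 0.5, 0.45, 0.35]), None)
        _, g_fwd = ev.objective_and_gradient(x, space, method="forward")
        g_fd = ev._fd_gradient(x, space, step=1e-3)
        tol = np.maximum(1e-4 * np.abs(g_fwd.gradient), 1e-6)
        assert np.all(np.abs(g_fwd.gradient - g_fd) <= tol)

    def test_optimum_preservation_on_grid(self, exp_decay_truth):
        """Grid minimum of Jhat(theta) equals the (theta, s)-grid minimum of
        the standard objective within grid resolution."""
        problem = exp_decay_truth.problem
        ev = hp.Evaluator(problem)
        theta_grid = np.linspace(0.3, 1.6, 40)
        s_grid = np.linspace(0.5, 4.0, 120)
        jhat_min = min(ev.hierarchical_objective(np.array([t])).value for t in theta_grid)
        j_min = math.inf
        for t in theta_grid:
            h, _, err = ev.observables(np.array([t]))
            assert err is None
            y = np.array([m.value for m in problem.measurements])
            for s in s_grid:
                r = y - s * h
                j = 0.5 * np.sum(np.log(2 * np.pi) + r**2)
                j_min = min(j_min, float(j))
        grid_tol = (s_grid[1] - s_grid[0]) ** 2 * len(y)  # curvature x spacing^2
        assert jhat_min <= j_min
        assert abs(jhat_min - j_min) <= grid_tol


class TestGradientRatio:
    def test_zero_scaling_gradient_gives_zero_ratio(self):
        ratio = hp.gradient_ratio_from_components([0.0, 0.0], [1.0, 3.0])
        assert ratio.defined and ratio.ratio == 0.0

    def test_hand_built_components(self):
        ratio = hp.gradient_ratio_from_components([4.0], [1.0, 3.0])
        assert ratio.ratio == pytest.approx(2.0)

    def test_zero_dynamic_gradient_flagged_undefined(self):
        ratio = hp.gradient_ratio_from_components([1.0], [0.0, 0.0])
        assert not ratio.defined

    def test_matches_fd_gradient_ratio_on_benchmark(self, cascade_truth):
        """Standard-mode diagnostic vs a ratio computed from an independent
        central-FD gradient."""
        problem = cascade_truth.problem
        rng = np.random.default_rng(31)
        theta = cascade_truth.problem.model.parameter_ids
        theta = np.array([1.0, 0.8, 1.2, 0.7, 1.1, 0.5, 0.5, 0.3]) * rng.uniform(0.8, 1.2, 8)
        statics = {("scaling", g): 1.5 for g in ("s_obs1", "s_obs2", "s_obs3")}
        ratio = hp.gradient_ratio_diagnostic(
            theta, problem, statics=statics, rtol=1e-10, atol=1e-14
        )
        ev = hp.Evaluator(problem, rtol=1e-10, atol=1e-14)
        space = ParameterSpace(problem, "standard")
        x = _internal_from_theta(space, theta, statics)
        g_fd = ev._fd_gradient(x, space, step=1e-3)
        s_idx = [i for i in range(space.n) if space.is_static(i, "scaling")]
        d_idx = [i for i in range(space.n) if not space.is_static(i)]
        fd_ratio = np.mean(np.abs(g_fd[s_idx])) / np.mean(np.abs(g_fd[d_idx]))
        assert ratio.defined
        assert ratio.ratio == pytest.approx(fd_ratio, rel=1e-3)

    def test_trace_records_evaluations(self, exp_decay_truth):
        ev = hp.Evaluator(exp_decay_truth.problem)
        space = ParameterSpace(exp_decay_truth.problem, "hierarchical")
        x = _internal_from_theta(space, np.array([0.7]), None)
        ev.objective_and_gradient(x, space)
        assert len(ev.trace) == 1
        entry = ev.trace[0]
        assert set(entry) >= {"iter", "J", "grad_norm", "ratio", "clipped_groups", "wall_time"}
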