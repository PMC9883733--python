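"""Closed-form inner solutions vs independent numeric minimization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize, minimize_scalar

import hieropt as hp
from hieropt.inner import solve_inner

from conftest import random_inner_group, restricted_nll


class TestOptimalScaling:
    def test_exact_proportionality(self):
        assert hp.optimal_scaling([1, 2], [2, 4], 0.0, 1.0) == pytest.approx(2.0)

    def test_least_squares_average(self):
        assert hp.optimal_scaling([1, 1], [1, 3], 0.0, 1.0) == pytest.approx(2.0)

    def test_heteroscedastic_matches_scalar_minimizer(self):
        h, y, sigma = np.array([1.0, 2.0]), np.array([2.0, 2.0]), np.array([1.0, 2.0])
        s = hp.optimal_scaling(h, y, 0.0, sigma)
        assert s == pytest.approx(1.5)
        oracle = minimize_scalar(
            lambda sv: restricted_nll(h, y, sv, 0.0, sigma), bounds=(0, 10), method="bounded",
            options={"xatol": 1e-12},
        )
        assert s == pytest.approx(oracle.x, rel=1e-6)

    def test_all_zero_observables_degenerate(self):
        with pytest.raises(hp.DegenerateGroupError, match="grp"):
            hp.optimal_scaling([0.0, 0.0], [1.0, 2.0], 0.0, 1.0, group_id="grp")


class TestOptimalOffset:
    def test_mean_residual(self):
        assert hp.optimal_offset([1, 2], [2, 3], 1.0, 1.0) == pytest.approx(1.0)

    def test_perfect_fit_gives_zero_offset(self):
        h = np.array([0.5, 1.5, 2.5])
        assert hp.optimal_offset(h, 2.0 * h, 2.0, 1.0) == pytest.approx(0.0)

    def test_heteroscedastic_weighted_mean(self):
        b = hp.optimal_offset([0.0, 0.0], [1.0, 2.0], 1.0, [1.0, 2.0])
        assert b == pytest.approx(1.2)
        oracle = minimize_scalar(
            lambda bv: restricted_nll([0, 0], [1, 2], 1.0, bv, [1.0, 2.0]),
            bounds=(-10, 10), method="bounded", options={"xatol": 1e-12},
        )
        assert b == pytest.approx(oracle.x, rel=1e-6)

    def test_empty_group_is_error(self):
        with pytest.raises(hp.ValidationError):
            hp.optimal_offset([], [], 1.0, 1.0, group_id="empty")


class TestCoupledScalingOffset:
    def test_exact_affine_fit(self):
        s, b = hp.optimal_scaling_offset([1, 2, 3], [3, 5, 7], 1.0)
        assert (s, b) == (pytest.approx(2.0), pytest.approx(1.0))

    def test_two_points_interpolated(self):
        s, b = hp.optimal_scaling_offset([0, 1], [4, 9], 1.0)
        assert (s, b) == (pytest.approx(5.0), pytest.approx(4.0))

    def test_random_group_matches_2d_minimizer(self):
        rng = np.random.default_rng(42)
        h = rng.uniform(0.1, 3.0, 20)
        y = rng.normal(1.0, 2.0, 20)
        sigma = rng.uniform(0.5, 2.0, 20)
        s, b = hp.optimal_scaling_offset(h, y, sigma)
        oracle = minimize(
            lambda v: restricted_nll(h, y, v[0], v[1], sigma),
            x0=[1.0, 0.0], method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 5000},
        )
        assert s == pytest.approx(oracle.x[0], rel=1e-8)
        assert b == pytest.approx(oracle.x[1], rel=1e-8)

    def test_constant_observable_degenerate(self):
        with pytest.raises(hp.DegenerateGroupError):
            hp.optimal_scaling_offset([1.0, 1.0, 1.0], [1, 2, 3], 1.0)

    def test_single_point_group_error(self):
        with pytest.raises(hp.DegenerateGroupError):
            hp.optimal_scaling_offset([1.0], [2.0], 1.0)

    def test_b_fixed_reduces_to_single_scaling_bitwise(self):
        """With b fixed the coupled path must take the reduced code path and
        agree bit for bit with the single-scaling formula."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            h, y, sigma = random_inner_group(rng)
            s_coupled, b = hp.optimal_scaling_offset(h, y, sigma, b_fixed=0.0)
            s_single = hp.optimal_scaling(h, y, 0.0, sigma)
            assert b == 0.0
            assert s_coupled == s_single  # bitwise


class TestOptimalSigma:
    def test_mean_squared_residual(self):
        sigma, clipped = hp.optimal_sigma([1.0, -1.0], 1e-10)
        assert sigma**2 == pytest.approx(1.0) and not clipped

    def test_unbalanced_residuals(self):
        sigma, _ = hp.optimal_sigma([0.0, 0.0, 3.0], 1e-10)
        assert sigma**2 == pytest.approx(3.0)

    def test_perfect_fit_clipped_at_floor(self):
        sigma, clipped = hp.optimal_sigma([0.0, 0.0], 1e-10)
        assert sigma == 1e-10 and clipped

    def test_matches_scalar_minimizer(self):
        rng = np.random.default_rng(3)
        r = rng.normal(0, 1.5, 9)
        sigma, _ = hp.optimal_sigma(r, 1e-10)
        oracle = minimize_scalar(
            lambda lg: restricted_nll(np.zeros_like(r), r, 0.0, 0.0, np.exp(lg)),
            bounds=(-8, 3), method="bounded", options={"xatol": 1e-13},
        )
        assert sigma == pytest.approx(np.exp(oracle.x), rel=1e-6)


def _inner_problem_instance(seed, n_groups=(3, 2, 2), n_per=6):
    """Synthetic measurement list with analytic scaling/offset/noise groups:
    scalings and offsets pair up on identical index sets (coupled), the
    noise groups tile the datapoints."""
    rng = np.random.default_rng(seed)
    n_s, n_b, n_sigma = n_groups
    measurements = []
    h = []
    specs = []
    for g in range(n_s):
        for i in range(n_per):
            k = g * n_per + i
            measurements.append(
                hp.Measurement(
                    "obs", "c", float(k), float(rng.normal(1.0, 2.0)),
                    scaling_group=f"s{g}",
                    offset_groups=(f"b{g}",) if g < n_b else (),
                    noise_group=f"sig{g % n_sigma}" if n_sigma else None,
                )
            )
            h.append(rng.uniform(0.2, 3.0))
    for g in range(n_s):
        specs.append(hp.StaticParameterSpec(f"s{g}", "scaling", "analytic"))
    for g in range(n_b):
        specs.append(hp.StaticParameterSpec(f"b{g}", "offset", "analytic"))
    for g in range(n_sigma):
        specs.append(hp.StaticParameterSpec(f"sig{g}", "noise", "analytic"))
    groups = hp.build_group_structure(measurements, specs)
    return np.array(h), measurements, groups


def _total_nll(h, measurements, s_i, b_i, sigma_i):
    y = np.array([m.value for m in measurements])
    return restricted_nll(h, y, s_i, b_i, sigma_i)


class TestSolveInner:
    def test_exact_scaling_recovered(self):
        """Data generated as y = 2 h with one analytic scaling and sigma
        fixed at 1 gives s = 2 and vanishing stationarity norm."""
        rng = np.random.default_rng(0)
        h = rng.uniform(0.5, 2.0, 10)
        measurements = [
            hp.Measurement("obs", "c", float(i), 2.0 * hi, scaling_group="s0",
                           noise_group="sig0")
            for i, hi in enumerate(h)
        ]
        specs = [
            hp.StaticParameterSpec("s0", "scaling", "analytic"),
            hp.StaticParameterSpec("sig0", "noise", "fixed", fixed_value=1.0),
        ]
        groups = hp.build_group_structure(measurements, specs)
        solution = solve_inner(h, measurements, groups)
        assert solution.s["s0"] == pytest.approx(2.0, abs=1e-12)
        assert solution.stationarity_norm <= 1e-10

    def test_inner_solution_beats_random_statics(self):
        h, measurements, groups = _inner_problem_instance(seed=11)
        solution = solve_inner(h, measurements, groups, sigma_floor=1e-10)
        j_opt = _total_nll(h, measurements, solution.s_i, solution.b_i, solution.sigma_i)
        rng = np.random.default_rng(99)
        n = len(measurements)
        for _ in range(100):
            s_i = np.ones(n)
            b_i = np.zeros(n)
            sigma_i = np.ones(n)
            for gid, idx in groups.groups("scaling").items():
                s_i[list(idx)] = rng.uniform(0.1, 5.0)
            for gid, idx in groups.groups("offset").items():
                b_i[list(idx)] = rng.normal(0, 2.0)
            for gid, idx in groups.groups("noise").items():
                sigma_i[list(idx)] = rng.uniform(0.1, 4.0)
            assert j_opt <= _total_nll(h, measurements, s_i, b_i, sigma_i) + 1e-12

    def test_matches_joint_numeric_minimization(self):
        """3 scaling + 2 offset + 2 noise analytic groups: the closed forms
        match a joint 7-parameter numeric minimization to 1e-6 relative."""
        h, measurements, groups = _inner_problem_instance(seed=23)
        solution = solve_inner(h, measurements, groups, sigma_floor=1e-10)
        y = np.array([m.value for m in measurements])
        s_ids = sorted(groups.groups("scaling"))
        b_ids = sorted(groups.groups("offset"))
        sig_ids = sorted(groups.groups("noise"))

        def unpack(v):
            n = len(measurements)
            s_i, b_i, sigma_i = np.ones(n), np.zeros(n), np.ones(n)
            for gid, value in zip(s_ids, v[: len(s_ids)]):
                s_i[list(groups.groups("scaling")[gid])] = value
            for gid, value in zip(b_ids, v[len(s_ids): len(s_ids) + len(b_ids)]):
                b_i[list(groups.groups("offset")[gid])] = value
            for gid, value in zip(sig_ids, v[len(s_ids) + len(b_ids):]):
                sigma_i[list(groups.groups("noise")[gid])] = np.exp(value)
            return s_i, b_i, sigma_i

        oracle = minimize(
            lambda v: restricted_nll(h, y, *unpack(v)),
            x0=np.concatenate([np.ones(len(s_ids)), np.zeros(len(b_ids)), np.zeros(len(sig_ids))]),
            method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 40000, "maxfev": 40000},
        )
        j_analytic = _total_nll(h, measurements, solution.s_i, solution.b_i, solution.sigma_i)
        assert j_analytic == pytest.approx(oracle.fun, rel=1e-6)
        s_num, b_num, sig_num = unpack(oracle.x)
        assert np.allclose(solution.s_i, s_num, rtol=1e-4)
        assert np.allclose(solution.sigma_i, sig_num, rtol=1e-4)

    def test_no_ode_solves_inside_inner_module(self):
        """The inner solver is pure array arithmetic: it must not import or
        call any ODE integration machinery."""
        import hieropt.inner as inner_mod

        source = open(inner_mod.__file__).read()
        assert "solve_ivp" not in source
        assert "import scipy" not in source and "from scipy" not in source

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        c=st.floats(0.1, 10.0),
        seed=st.integers(0, 10_000),
    )
    def test_equivariance_under_rescaling(self, c, seed):
        """Scaling all y by c scales (s, b, sigma) by c; scaling h by c
        scales s by 1/c (with b = 0)."""
        rng = np.random.default_rng(seed)
        h, y, sigma = random_inner_group(rng, n=8)
        s1, b1 = hp.optimal_scaling_offset(h, y, sigma)
        s2, b2 = hp.optimal_scaling_offset(h, c * y, sigma * c)
        assert s2 == pytest.approx(c * s1, rel=1e-9)
        assert b2 == pytest.approx(c * b1, rel=1e-9, abs=1e-12)
        r1 = y - (s1 * h + b1)
        sig1, _ = hp.optimal_sigma(r1, 1e-14)
        sig2, _ = hp.optimal_sigma(c * y - (s2 * h + b2), 1e-14)
        assert sig2 == pytest.approx(c * sig1, rel=1e-9)
        s3 = hp.optimal_scaling(c * h, y, 0.0, sigma)
        assert s3 == pytest.approx(hp.optimal_scaling(h, y, 0.0, sigma) / c, rel=1e-9)
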