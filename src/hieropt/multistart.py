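"""Multi-start gradient-based optimization in standard and hierarchical mode.

Start points are sampled uniformly within bounds on each coordinate's
declared optimization scale (log10 bounds -> uniform in the exponent) and are
reproducible from ``(global_seed, start_id)``.  The dynamic-parameter part of
a start is identical across modes for the same start id, so paired
standard-vs-hierarchical comparisons share initial conditions; only the
static coordinates (absent from the hierarchical outer problem) differ.

Local optimization runs through adapters over scipy's bounded gradient-based
methods (L-BFGS-B, TNC, trust-constr), each capped at a configurable number
of iterations (default 150).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize as sopt

from .errors import HieroptError
from .objective import Evaluator, ParameterSpace
from .problem import Problem

#: Large finite stand-in for an infinite objective inside local optimizers.
FAILURE_OBJECTIVE = 1e100

DEFAULT_MAX_ITER = 150
DEFAULT_GTOL = 1e-6
DEFAULT_FTOL = 1e-10


@dataclass(frozen=True)
class StartPoint:
    start_id: int
    seed: int
    theta0: tuple[float, ...]  # internal-scale values, dynamic block first


@dataclass
class OptimizerConfig:
    name: str = "lbfgsb"
    max_iter: int = DEFAULT_MAX_ITER
    gtol: float = DEFAULT_GTOL
    ftol: float = DEFAULT_FTOL
    gradient_method: str = "forward"
    # forward-solver tolerances for the objective evaluations of this run
    rtol: float = 1e-8
    atol: float = 1e-12


@dataclass
class StartResult:
    start_id: int
    final_objective: float
    final_x: tuple[float, ...]
    final_parameters: dict
    final_statics: dict
    iterations: int
    n_evaluations: int
    exit_status: str
    objective_trajectory: list[float] = field(default_factory=list)
    gradient_norm_trajectory: list[float] = field(default_factory=list)
    ratio_trajectory: list[float | None] = field(default_factory=list)
    n_failures: int = 0


@dataclass
class MultistartResult:
    mode: str
    optimizer: str
    starts: list[StartResult]
    parameter_names: tuple[str, ...]

    @property
    def final_objectives(self) -> np.ndarray:
        return np.array([s.final_objective for s in self.starts])

    @property
    def sorted_final_objectives(self) -> np.ndarray:
        return np.sort(self.final_objectives)

    @property
    def best(self) -> StartResult:
        return min(self.starts, key=lambda s: s.final_objective)

    @property
    def n_converged(self) -> int:
        return sum(1 for s in self.starts if s.exit_status != "failed")


def sample_startpoints(
    problem: Problem,
    n_starts: int,
    global_seed: int,
    mode: str = "hierarchical",
) -> list[StartPoint]:
    """Uniform start points on the internal (declared) parameter scales.

    Deterministic given ``global_seed``; the dynamic block is drawn from a
    stream keyed only by ``(global_seed, start_id)`` so it coincides across
    modes, while static coordinates come from a separate stream.
    """
    space = ParameterSpace(problem, mode)
    bounds = space.internal_bounds()
    for (lo, hi), e in zip(bounds, space.entries):
        if not (math.isfinite(lo) and math.isfinite(hi)):
            raise HieroptError(
                f"parameter '{e['name']}' has non-finite sampling bounds"
            )
    n_dyn = space.n_dynamic
    starts = []
    for start_id in range(n_starts):
        rng_dyn = np.random.default_rng([global_seed, start_id, 0])
        x = np.empty(space.n)
        for i in range(n_dyn):
            lo, hi = bounds[i]
            x[i] = rng_dyn.uniform(lo, hi)
        if space.n > n_dyn:
            rng_static = np.random.default_rng([global_seed, start_id, 1])
            for i in range(n_dyn, space.n):
                lo, hi = bounds[i]
                x[i] = rng_static.uniform(lo, hi)
        starts.append(StartPoint(start_id=start_id, seed=global_seed, theta0=tuple(x)))
    return starts


_SCIPY_METHODS = {"lbfgsb": "L-BFGS-B", "tnc": "TNC", "trustconstr": "trust-constr"}


def _run_local(evaluator, space, x0, config: OptimizerConfig) -> StartResult:
    trace_start = len(evaluator.trace)
    n_failures = 0

    def fun(x):
        nonlocal n_failures
        value, grad = evaluator.objective_and_gradient(
            x, space, method=config.gradient_method
        )
        if value.failure_flag or grad.failure_flag or not math.isfinite(value.value):
            n_failures += 1
            return FAILURE_OBJECTIVE, np.zeros(space.n)
        return value.value, grad.gradient

    method = _SCIPY_METHODS[config.name]
    if method == "L-BFGS-B":
        options: dict = {"maxiter": config.max_iter, "gtol": config.gtol,
                         "ftol": config.ftol}
    elif method == "TNC":
        # TNC caps function evaluations rather than iterations
        options = {"maxfun": config.max_iter, "gtol": config.gtol,
                   "ftol": config.ftol, "xtol": -1}
    else:  # trust-constr
        options = {"maxiter": config.max_iter, "gtol": config.gtol,
                   "xtol": 1e-12}
    try:
        res = sopt.minimize(
            fun,
            np.asarray(x0, dtype=float),
            jac=True,
            bounds=space.internal_bounds(),
            method=method,
            options=options,
        )
        final_x = np.asarray(res.x, dtype=float)
        final_f = float(res.fun)
        iterations = int(getattr(res, "nit", 0))
        status = "converged" if res.success else f"stopped ({res.message})"
    except Exception as err:  # unrecoverable start; multistart continues
        final_x = np.asarray(x0, dtype=float)
        final_f = math.inf
        iterations = 0
        status = f"failed ({err})"
    if final_f >= FAILURE_OBJECTIVE:
        status = "failed"

    trace = evaluator.trace[trace_start:]
    objective_values = [t["J"] for t in trace if t["J"] is not None]
    # best-so-far trajectory (monotone non-increasing)
    best_so_far = []
    best = math.inf
    for v in objective_values:
        best = min(best, v)
        best_so_far.append(best)
    theta, statics = space.unpack(final_x)
    final_parameters = dict(zip(evaluator.problem.model.parameter_ids, theta))
    if space.mode == "hierarchical" and math.isfinite(final_f):
        value = evaluator.hierarchical_objective(theta, numeric_values=statics)
        if value.inner_solution is not None:
            inner = value.inner_solution
            statics = dict(statics)
            statics.update({("scaling", g): v for g, v in inner.s.items()})
            statics.update({("offset", g): v for g, v in inner.b.items()})
            statics.update({("noise", g): v for g, v in inner.sigma.items()})
    return StartResult(
        start_id=-1,
        final_objective=final_f,
        final_x=tuple(final_x),
        final_parameters=final_parameters,
        final_statics={f"{k}:{g}": v for (k, g), v in statics.items()},
        iterations=iterations,
        n_evaluations=len(trace),
        exit_status=status,
        objective_trajectory=best_so_far,
        gradient_norm_trajectory=[t["grad_norm"] for t in trace],
        ratio_trajectory=[t["ratio"] for t in trace],
        n_failures=n_failures,
    )


def optimize(
    problem: Problem,
    mode: str,
    starts: list[StartPoint],
    optimizer_config: OptimizerConfig | None = None,
    evaluator: Evaluator | None = None,
) -> MultistartResult:
    """Run one local optimization per start point.

    Standard mode optimizes (theta, all non-fixed statics) jointly against
    the explicit objective; hierarchical mode optimizes theta plus
    numeric-mode statics against the reduced objective with analytic inner
    solves at every evaluation.
    """
    config = optimizer_config or OptimizerConfig()
    if config.name not in _SCIPY_METHODS:
        raise HieroptError(
            f"unknown optimizer '{config.name}' (have {sorted(_SCIPY_METHODS)})"
        )
    evaluator = evaluator or Evaluator(problem, rtol=config.rtol, atol=config.atol)
    space = ParameterSpace(problem, mode)
    results = []
    for start in starts:
        x0 = np.asarray(start.theta0, dtype=float)[: space.n]
        if len(x0) != space.n:
            raise HieroptError(
                f"start point dimension {len(start.theta0)} < outer dimension {space.n}"
            )
        result = _run_local(evaluator, space, x0, config)
        result.start_id = start.start_id
        results.append(result)
    if results and all(r.exit_status == "failed" for r in results):
        raise HieroptError(
            f"all {len(results)} starts failed in {mode} mode"
        )
    return MultistartResult(
        mode=mode, optimizer=config.name, starts=results, parameter_names=space.names
    )


@dataclass
class ComparisonReport:
    """Paired standard-vs-hierarchical multistart comparison."""

    n_starts: int
    seed: int
    optimizer: str
    standard_final: list[float]
    hierarchical_final: list[float]
    standard_waterfall: list[float]
    hierarchical_waterfall: list[float]
    median_standard: float
    median_hierarchical: float
    median_gap: float  # median(standard) - median(hierarchical); >= 0 favours hierarchical
    ratio_traces: list[list[float | None]] = field(default_factory=list)
    iteration_matched_gaps: list[float] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ComparisonReport":
        return cls(**json.loads(text))


def compare_modes(
    problem: Problem,
    n_starts: int,
    seed: int,
    optimizer_config: OptimizerConfig | None = None,
    modes: tuple[str, str] = ("standard", "hierarchical"),
) -> tuple[ComparisonReport, MultistartResult, MultistartResult]:
    """Run both modes from paired start points and report final objectives,
    waterfalls, gradient-ratio traces and the per-start iteration-matched
    objective gap."""
    config = optimizer_config or OptimizerConfig()
    mode_a, mode_b = modes
    starts_a = sample_startpoints(problem, n_starts, seed, mode=mode_a)
    starts_b = sample_startpoints(problem, n_starts, seed, mode=mode_b)
    result_a = optimize(problem, mode_a, starts_a, config)
    result_b = optimize(problem, mode_b, starts_b, config)
    finals_a = [s.final_objective for s in result_a.starts]
    finals_b = [s.final_objective for s in result_b.starts]

    def _finite_median(values):
        finite = [v for v in values if math.isfinite(v)]
        return float(np.median(finite)) if finite else math.inf

    median_a = _finite_median(finals_a)
    median_b = _finite_median(finals_b)
    gaps = [
        a - b if math.isfinite(a) and math.isfinite(b) else math.nan
        for a, b in zip(finals_a, finals_b)
    ]
    report = ComparisonReport(
        n_starts=n_starts,
        seed=seed,
        optimizer=config.name,
        standard_final=finals_a,
        hierarchical_final=finals_b,
        standard_waterfall=sorted(finals_a),
        hierarchical_waterfall=sorted(finals_b),
        median_standard=median_a,
        median_hierarchical=median_b,
        median_gap=median_a - median_b,
        ratio_traces=[s.ratio_trajectory for s in result_a.starts],
        iteration_matched_gaps=gaps,
    )
    return report, result_a, result_b
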