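"""Small closed-form-checkable benchmark problems and synthetic relative data.

The registry holds:

- ``exp_decay``            — one-state exponential decay, one analytic
                             scaling group, noise fixed to 1;
- ``conversion_reaction``  — reversible two-state conversion with a known
                             closed-form solution (absolute data, no groups);
- ``cascade3``             — three-state signaling cascade with 8 dynamic
                             parameters, 3 scaling, 2 offset and 2 noise
                             groups, all analytic;
- ``dataset1_like``        — viability-style structure: one scaling per
                             cell-line, a single noise parameter shared by
                             all datapoints (fixed to 1);
- ``dataset2_like``        — proteomics-style structure: log2 observables
                             built as stoichiometric combinations of states,
                             one analytic offset and noise parameter per
                             protein plus one numeric offset per cell-line.

The data generator emulates the simulate-then-add-noise design: measurement
values are ``y_i = s_i h_i(theta_true) + b_i + eps_i`` with i.i.d. Gaussian
``eps_i`` and group-wise true statics, plus an *absolute-data twin* (same
simulations, s=1, b=0) for the information-loss comparison.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import HieroptError
from .objective import Evaluator
from .multistart import (
    MultistartResult,
    OptimizerConfig,
    optimize,
    sample_startpoints,
)
from .problem import (
    Condition,
    Measurement,
    Observable,
    OdeModel,
    Problem,
    StaticParameterSpec,
    build_group_structure,
)


@dataclass
class Benchmark:
    """A problem skeleton plus the ground truth used for data generation."""

    name: str
    problem: Problem  # measurement values are placeholders until generate_data
    theta_true: dict
    statics_true: dict  # {(kind, group_id): value}; noise entries are sigma_true

    @property
    def theta_true_vector(self) -> np.ndarray:
        return np.array(
            [self.theta_true[p] for p in self.problem.model.parameter_ids]
        )


def _problem(model, conditions, measurements, specs, **kw) -> Problem:
    groups = build_group_structure(measurements, specs)
    problem = Problem(
        model=model,
        conditions=tuple(conditions),
        measurements=tuple(measurements),
        groups=groups,
        **kw,
    )
    problem.validate(strict=True)
    return problem


def _exp_decay() -> Benchmark:
    model = OdeModel(
        state_ids=("x",),
        parameter_ids=("k",),
        condition_variable_ids=(),
        rhs_expressions=("-k*x",),
        initial_expressions=("1",),
        observables=(Observable("obs_x", "x"),),
    )
    times = [0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0]
    conditions = [Condition("c0")]
    measurements = [
        Measurement("obs_x", "c0", t, 0.0, scaling_group="s_all", noise_group="sigma_all")
        for t in times
    ]
    specs = [
        StaticParameterSpec("s_all", "scaling", "analytic"),
        StaticParameterSpec("sigma_all", "noise", "fixed", fixed_value=1.0),
    ]
    problem = _problem(
        model, conditions, measurements, specs,
        dynamic_bounds={"k": (1e-2, 1e1)},
    )
    return Benchmark(
        "exp_decay", problem,
        theta_true={"k": 0.8},
        statics_true={("scaling", "s_all"): 2.0, ("noise", "sigma_all"): 0.1},
    )


def _conversion_reaction() -> Benchmark:
    model = OdeModel(
        state_ids=("x1", "x2"),
        parameter_ids=("k1", "k2"),
        condition_variable_ids=(),
        rhs_expressions=("-k1*x1 + k2*x2", "k1*x1 - k2*x2"),
        initial_expressions=("1", "0"),
        observables=(Observable("obs_x2", "x2"),),
    )
    times = [0.2, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 5.0, 7.5, 10.0]
    conditions = [Condition("c0")]
    measurements = [
        Measurement("obs_x2", "c0", t, 0.0, noise_group="sigma_all") for t in times
    ]
    specs = [StaticParameterSpec("sigma_all", "noise", "fixed", fixed_value=0.02)]
    problem = _problem(
        model, conditions, measurements, specs,
        dynamic_bounds={"k1": (1e-2, 1e1), "k2": (1e-2, 1e1)},
    )
    return Benchmark(
        "conversion_reaction", problem,
        theta_true={"k1": 0.8, "k2": 0.6},
        statics_true={("noise", "sigma_all"): 0.02},
    )


def conversion_reaction_closed_form(k1, k2, t):
    """x2(t) for the reversible conversion x1 <-> x2 with x0 = (1, 0)."""
    t = np.asarray(t, dtype=float)
    rate = k1 + k2
    return k1 / rate * (1.0 - np.exp(-rate * t))


def _cascade3() -> Benchmark:
    model = OdeModel(
        state_ids=("x1", "x2", "x3"),
        parameter_ids=("k1", "k2", "k3", "k4", "k5", "k6", "x01", "x02"),
        condition_variable_ids=("u",),
        rhs_expressions=(
            "k1*u - k2*x1",
            "k3*x1 - k4*x2",
            "k5*x2 - k6*x3",
        ),
        initial_expressions=("x01", "x02", "0"),
        observables=(
            Observable("obs1", "x1"),
            Observable("obs2", "x2"),
            # cross-reactive readout: keeps k5 identifiable despite the
            # free scaling on this observable (x3 alone is proportional
            # to k5, which the scaling would absorb exactly)
            Observable("obs3", "x3 + 0.25*x2"),
        ),
    )
    times = [1.0, 2.5, 5.0, 10.0]
    u_levels = {"low": 0.4, "mid": 1.0, "high": 2.5}
    conditions = [Condition(cid, {"u": u}) for cid, u in u_levels.items()]
    scaling = {"obs1": "s_obs1", "obs2": "s_obs2", "obs3": "s_obs3"}
    offset = {"obs2": "b_obs2", "obs3": "b_obs3"}
    noise = {"obs1": "sigma_12", "obs2": "sigma_12", "obs3": "sigma_3"}
    measurements = [
        Measurement(
            obs, cid, t, 0.0,
            scaling_group=scaling[obs],
            offset_groups=(offset[obs],) if obs in offset else (),
            noise_group=noise[obs],
        )
        for cid in u_levels
        for obs in ("obs1", "obs2", "obs3")
        for t in times
    ]
    specs = [
        StaticParameterSpec("s_obs1", "scaling", "analytic"),
        StaticParameterSpec("s_obs2", "scaling", "analytic"),
        StaticParameterSpec("s_obs3", "scaling", "analytic"),
        StaticParameterSpec("b_obs2", "offset", "analytic"),
        StaticParameterSpec("b_obs3", "offset", "analytic"),
        StaticParameterSpec("sigma_12", "noise", "analytic"),
        StaticParameterSpec("sigma_3", "noise", "analytic"),
    ]
    problem = _problem(
        model, conditions, measurements, specs,
        dynamic_bounds={p: (1e-2, 1e2) for p in model.parameter_ids},
    )
    theta_true = {
        "k1": 1.2, "k2": 0.8, "k3": 1.5, "k4": 0.6,
        "k5": 0.9, "k6": 0.4, "x01": 0.5, "x02": 0.3,
    }
    # noise levels ~10% of the rescaled-signal spread
    statics_true = {
        ("scaling", "s_obs1"): 2.0,
        ("scaling", "s_obs2"): 1.5,
        ("scaling", "s_obs3"): 3.0,
        ("offset", "b_obs2"): 0.4,
        ("offset", "b_obs3"): -0.2,
        ("noise", "sigma_12"): 0.08,
        ("noise", "sigma_3"): 0.12,
    }
    return Benchmark("cascade3", problem, theta_true, statics_true)


def _dataset1_like(n_cell_lines: int = 96, n_concentrations: int = 4) -> Benchmark:
    """Viability-style structure: cell-line specific scalings, one global
    noise parameter (fixed to 1 when this dataset stands alone)."""
    model = OdeModel(
        state_ids=("v",),
        parameter_ids=("k_grow", "k_kill"),
        condition_variable_ids=("dose",),
        rhs_expressions=("k_grow*v*(1 - v) - k_kill*dose*v",),
        initial_expressions=("0.1",),
        observables=(Observable("viability", "v"),),
    )
    doses = [0.0, 0.3, 1.0, 3.0][:n_concentrations]
    conditions = []
    measurements = []
    specs = [StaticParameterSpec("sigma_all", "noise", "fixed", fixed_value=1.0)]
    statics_true = {("noise", "sigma_all"): 1.0}
    rng = np.random.default_rng(1234)  # fixed structural seed for true scalings
    for j in range(n_cell_lines):
        gid = f"s_cell_{j}"
        specs.append(StaticParameterSpec(gid, "scaling", "analytic"))
        statics_true[("scaling", gid)] = float(10.0 ** rng.uniform(-0.5, 0.5))
        for d, dose in enumerate(doses):
            cid = f"cell{j}_dose{d}"
            conditions.append(Condition(cid, {"dose": dose}))
            measurements.append(
                Measurement(
                    "viability", cid, 10.0, 0.0,
                    scaling_group=gid, noise_group="sigma_all",
                )
            )
    problem = _problem(
        model, conditions, measurements, specs,
        dynamic_bounds={"k_grow": (1e-2, 1e1), "k_kill": (1e-2, 1e1)},
    )
    return Benchmark(
        "dataset1_like", problem,
        theta_true={"k_grow": 0.5, "k_kill": 0.7},
        statics_true=statics_true,
    )


def _dataset2_like(n_cell_lines: int = 54, n_proteins: int = 48) -> Benchmark:
    """Proteomics-style structure: log2 observables h = sum_l k_l x_l with one
    analytic offset + noise parameter per protein and one numeric offset per
    cell-line (the latter cannot be analytic: its datapoints span all
    per-protein noise parameters)."""
    model = OdeModel(
        state_ids=("x1", "x2"),
        parameter_ids=("k1", "k2", "k3", "k4"),
        condition_variable_ids=("u",),
        rhs_expressions=("k1*u - k2*x1", "k3*x1 - k4*x2"),
        initial_expressions=("0.5", "0.5"),
        observables=tuple(
            Observable(
                f"protein_{i}",
                # stoichiometric multiplicities: small positive integers
                f"{1 + i % 3}*x1 + {1 + (i // 3) % 2}*x2",
                transformation="log2",
            )
            for i in range(n_proteins)
        ),
    )
    conditions = []
    measurements = []
    specs = []
    statics_true = {}
    rng = np.random.default_rng(4321)
    for i in range(n_proteins):
        specs.append(StaticParameterSpec(f"b_prot_{i}", "offset", "analytic"))
        specs.append(StaticParameterSpec(f"sigma_prot_{i}", "noise", "analytic"))
        statics_true[("offset", f"b_prot_{i}")] = float(rng.normal(0.0, 0.5))
        statics_true[("noise", f"sigma_prot_{i}")] = float(rng.uniform(0.1, 0.3))
    for j in range(n_cell_lines):
        specs.append(
            StaticParameterSpec(f"b_cell_{j}", "offset", "numeric", bounds=(-5.0, 5.0))
        )
        statics_true[("offset", f"b_cell_{j}")] = float(rng.normal(0.0, 0.3))
        cid = f"cell{j}"
        conditions.append(Condition(cid, {"u": float(0.5 + j / n_cell_lines)}))
        for i in range(n_proteins):
            measurements.append(
                Measurement(
                    f"protein_{i}", cid, 5.0, 0.0,
                    offset_groups=(f"b_prot_{i}", f"b_cell_{j}"),
                    noise_group=f"sigma_prot_{i}",
                )
            )
    problem = _problem(
        model, conditions, measurements, specs,
        dynamic_bounds={p: (1e-2, 1e1) for p in model.parameter_ids},
    )
    return Benchmark(
        "dataset2_like", problem,
        theta_true={"k1": 1.0, "k2": 0.7, "k3": 0.9, "k4": 0.5},
        statics_true=statics_true,
    )


_REGISTRY = {
    "exp_decay": _exp_decay,
    "conversion_reaction": _conversion_reaction,
    "cascade3": _cascade3,
    "dataset1_like": _dataset1_like,
    "dataset2_like": _dataset2_like,
}


def benchmark_names() -> tuple[str, ...]:
    return tuple(sorted(_REGISTRY))


def make_benchmark(name: str, **kwargs) -> Benchmark:
    """Instantiate a registered benchmark skeleton (measurement values are
    placeholders; see :func:`generate_data`)."""
    try:
        builder = _REGISTRY[name]
    except KeyError:
        raise HieroptError(
            f"unknown benchmark '{name}' (have {', '.join(benchmark_names())})"
        ) from None
    return builder(**kwargs)


@dataclass
class SyntheticTruth:
    """Generated dataset plus everything needed to score recovery."""

    theta_true: dict
    statics_true: dict
    seed: int
    problem: Problem  # relative data
    absolute_problem: Problem  # twin: same simulations, s=1, b=0
    h_true: np.ndarray  # transformed unscaled observables at theta_true
    measurement_table: pd.DataFrame = field(repr=False, default=None)


def generate_data(
    problem: Problem,
    theta_true: dict,
    statics_true: dict,
    seed: int,
    noise_sd: float | None = None,
) -> SyntheticTruth:
    """Simulate at theta_true and add i.i.d. Gaussian noise.

    ``y_i = s_i h_i + b_i + eps_i`` with eps_i ~ N(0, sigma_i^2) where
    sigma_i comes from the datapoint's true noise group (``noise_sd``
    overrides all of them; 0 yields exact data).  The absolute twin uses the
    same h with s=1, b=0 and its own noise draws from the same stream.
    Regeneration with the same seed is bit-exact.
    """
    evaluator = Evaluator(problem)
    theta = np.array([theta_true[p] for p in problem.model.parameter_ids])
    h, _, err = evaluator.observables(theta)
    if err is not None:
        raise HieroptError(f"simulation failed at theta_true: {err}")
    n = len(problem.measurements)
    s_i = np.ones(n)
    b_i = np.zeros(n)
    sigma_i = np.ones(n)
    groups = problem.groups
    for (kind, gid), value in statics_true.items():
        idx = list(groups.groups(kind).get(gid, ()))
        if kind == "scaling":
            s_i[idx] = value
        elif kind == "offset":
            b_i[idx] += value
        else:
            sigma_i[idx] = value
    for gid, idx in groups.groups("noise").items():
        if ("noise", gid) not in statics_true:
            spec = groups.spec(gid)
            if spec.mode == "fixed":
                sigma_i[list(idx)] = spec.fixed_value
    if noise_sd is not None:
        sigma_i[:] = noise_sd

    rng = np.random.default_rng(seed)
    y_rel = s_i * h + b_i + rng.normal(0.0, 1.0, size=n) * sigma_i
    y_abs = h + rng.normal(0.0, 1.0, size=n) * sigma_i

    def with_values(p: Problem, values, strip_statics: bool) -> Problem:
        measurements = []
        for m, v in zip(p.measurements, values):
            if strip_statics:
                measurements.append(
                    replace(m, value=float(v), scaling_group=None, offset_groups=())
                )
            else:
                measurements.append(replace(m, value=float(v)))
        specs = p.groups.specs
        if strip_statics:
            specs = tuple(s for s in specs if s.kind == "noise")
        return Problem(
            model=p.model,
            conditions=p.conditions,
            measurements=tuple(measurements),
            groups=build_group_structure(measurements, list(specs)),
            dynamic_parameter_scale=dict(p.dynamic_parameter_scale),
            dynamic_bounds=dict(p.dynamic_bounds),
            sigma_floor=p.sigma_floor,
            config=dict(p.config),
        )

    rel_problem = with_values(problem, y_rel, strip_statics=False)
    abs_problem = with_values(problem, y_abs, strip_statics=True)
    table = pd.DataFrame(
        {
            "observableId": [m.observable_id for m in problem.measurements],
            "conditionId": [m.condition_id for m in problem.measurements],
            "time": [m.time for m in problem.measurements],
            "measurement": y_rel,
            "absolute_measurement": y_abs,
            "h_true": h,
        }
    )
    return SyntheticTruth(
        theta_true=dict(theta_true),
        statics_true=dict(statics_true),
        seed=seed,
        problem=rel_problem,
        absolute_problem=abs_problem,
        h_true=h,
        measurement_table=table,
    )


def pearson_fit_metric(measurements, rescaled_simulations) -> float:
    """Pearson correlation between data and (rescaled) simulation.

    Raises :class:`HieroptError` when either side has zero variance (the
    correlation is undefined there).
    """
    y = np.asarray(measurements, dtype=float)
    yhat = np.asarray(rescaled_simulations, dtype=float)
    if y.size < 2:
        raise HieroptError("Pearson correlation needs at least 2 datapoints")
    if np.std(y) == 0.0 or np.std(yhat) == 0.0:
        raise HieroptError("Pearson correlation undefined: zero variance")
    return float(stats.pearsonr(y, yhat)[0])


@dataclass
class InformationLossReport:
    """Pearson correlations for absolute predictions after training on
    relative vs absolute data (Fig-2D-style comparison)."""

    benchmark: str
    seed: int
    r_rel_to_abs: float
    r_abs_to_abs: float

    @property
    def information_lost(self) -> bool:
        return self.r_rel_to_abs <= self.r_abs_to_abs

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "InformationLossReport":
        return cls(**json.loads(text))


def _best_fit(problem, n_starts, seed, max_iter) -> tuple[MultistartResult, np.ndarray]:
    starts = sample_startpoints(problem, n_starts, seed, mode="hierarchical")
    result = optimize(
        problem, "hierarchical", starts, OptimizerConfig(max_iter=max_iter)
    )
    best = result.best
    theta = np.array(
        [best.final_parameters[p] for p in problem.model.parameter_ids]
    )
    return result, theta


def information_loss_experiment(
    benchmark: Benchmark | str,
    seed: int,
    n_starts: int = 3,
    max_iter: int = 75,
) -> InformationLossReport:
    """Quantify the information lost by normalization.

    Fits the benchmark on relative data, predicts *absolute* values with the
    fitted dynamic parameters (s=1, b=0) and correlates them with the
    absolute-data twin; compares against a fit on the absolute data itself.
    """
    if isinstance(benchmark, str):
        benchmark = make_benchmark(benchmark)
    truth = generate_data(
        benchmark.problem, benchmark.theta_true, benchmark.statics_true, seed=seed
    )
    y_abs = np.array([m.value for m in truth.absolute_problem.measurements])

    _, theta_rel = _best_fit(truth.problem, n_starts, seed, max_iter)
    h_rel, _, err = Evaluator(truth.problem).observables(theta_rel)
    if err is not None:
        raise HieroptError(f"prediction failed: {err}")
    r_rel_to_abs = pearson_fit_metric(y_abs, h_rel)

    _, theta_abs = _best_fit(truth.absolute_problem, n_starts, seed, max_iter)
    h_abs, _, err = Evaluator(truth.absolute_problem).observables(theta_abs)
    if err is not None:
        raise HieroptError(f"prediction failed: {err}")
    r_abs_to_abs = pearson_fit_metric(y_abs, h_abs)

    return InformationLossReport(
        benchmark=benchmark.name,
        seed=seed,
        r_rel_to_abs=r_rel_to_abs,
        r_abs_to_abs=r_abs_to_abs,
    )
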