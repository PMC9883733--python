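"""Reading and writing problem directories.

A problem lives in five text files:

- ``model.yaml``        — states, parameters, condition_variables, rhs, x0, observables
- ``measurements.tsv``  — observableId, conditionId, time, measurement,
                          scalingGroup, offsetGroup, noiseGroup (empty cell = none;
                          several offset groups are ';'-separated)
- ``static_parameters.tsv`` — groupId, kind, mode, fixedValue, lowerBound, upperBound
- ``conditions.tsv``    — conditionId plus one column per overridden variable
- ``config.yaml``       — optimizer, n_starts, seed, mode, sigma_floor,
                          parameter_scales, parameter_bounds, tolerances

Tables are UTF-8 TSV with a header row and '.' decimal separator.
"""

from __future__ import annotations

import logging
import math
import os
from pathlib import Path

import pandas as pd
import yaml

from .errors import FormatError
from .problem import (
    Condition,
    Measurement,
    Observable,
    OdeModel,
    Problem,
    StaticParameterSpec,
    build_group_structure,
)

logger = logging.getLogger(__name__)

MEASUREMENT_COLUMNS = [
    "observableId",
    "conditionId",
    "time",
    "measurement",
    "scalingGroup",
    "offsetGroup",
    "noiseGroup",
]

FILENAMES = {
    "model": "model.yaml",
    "measurements": "measurements.tsv",
    "static_parameters": "static_parameters.tsv",
    "conditions": "conditions.tsv",
    "config": "config.yaml",
}


def _load_yaml(path):
    try:
        with open(path) as fh:
            return yaml.safe_load(fh)
    except yaml.YAMLError as err:
        raise FormatError(f"{path}: not valid YAML ({err})") from err
    except OSError as err:
        raise FormatError(f"{path}: cannot read ({err})") from err


def load_model(path) -> OdeModel:
    doc = _load_yaml(path)
    if not isinstance(doc, dict):
        raise FormatError(f"{path}: expected a mapping at top level")
    try:
        states = list(doc["states"])
        rhs = doc["rhs"]
        x0 = doc["x0"]
        observables = doc.get("observables", [])
    except KeyError as err:
        raise FormatError(f"{path}: missing required key {err}") from err
    missing = [s for s in states if s not in rhs]
    if missing:
        raise FormatError(f"{path}: states without rhs expression: {missing}")
    missing = [s for s in states if s not in x0]
    if missing:
        raise FormatError(f"{path}: states without x0 expression: {missing}")
    obs = tuple(
        Observable(
            observable_id=o["id"],
            formula=str(o["formula"]),
            transformation=o.get("transformation", "identity"),
        )
        for o in observables
    )
    return OdeModel(
        state_ids=tuple(states),
        parameter_ids=tuple(doc.get("parameters", [])),
        condition_variable_ids=tuple(
            doc.get("condition_variables", doc.get("conditions_variables", []))
        ),
        rhs_expressions=tuple(str(rhs[s]) for s in states),
        initial_expressions=tuple(str(x0[s]) for s in states),
        observables=obs,
    )


def _read_tsv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", dtype=str)
    except (pd.errors.ParserError, OSError, UnicodeDecodeError) as err:
        raise FormatError(f"{path}: cannot parse TSV ({err})") from err


def _cell(row, column):
    value = row.get(column)
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    value = str(value).strip()
    return value or None


def load_measurements(path) -> list[Measurement]:
    df = _read_tsv(path)
    missing = [c for c in MEASUREMENT_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    measurements = []
    n_dropped = 0
    for line, (_, row) in enumerate(df.iterrows(), start=2):
        raw_value = _cell(row, "measurement")
        value = float(raw_value) if raw_value is not None else math.nan
        if not math.isfinite(value):
            n_dropped += 1
            continue
        offset_cell = _cell(row, "offsetGroup")
        offsets = tuple(p for p in offset_cell.split(";") if p) if offset_cell else ()
        try:
            measurements.append(
                Measurement(
                    observable_id=_cell(row, "observableId"),
                    condition_id=_cell(row, "conditionId"),
                    time=float(_cell(row, "time")),
                    value=value,
                    scaling_group=_cell(row, "scalingGroup"),
                    offset_groups=offsets,
                    noise_group=_cell(row, "noiseGroup"),
                )
            )
        except (TypeError, ValueError) as err:
            raise FormatError(f"{path}, line {line}: {err}") from err
    if n_dropped:
        logger.info("%s: dropped %d rows with missing measurement values", path, n_dropped)
    return measurements


def load_static_parameters(path) -> list[StaticParameterSpec]:
    df = _read_tsv(path)
    specs = []
    for line, (_, row) in enumerate(df.iterrows(), start=2):
        try:
            fixed = _cell(row, "fixedValue")
            lo, hi = _cell(row, "lowerBound"), _cell(row, "upperBound")
            specs.append(
                StaticParameterSpec(
                    group_id=_cell(row, "groupId"),
                    kind=_cell(row, "kind"),
                    mode=_cell(row, "mode"),
                    fixed_value=float(fixed) if fixed is not None else None,
                    bounds=(float(lo), float(hi)) if lo is not None else None,
                )
            )
        except (TypeError, ValueError) as err:
            raise FormatError(f"{path}, line {line}: {err}") from err
    return specs


def load_conditions(path) -> list[Condition]:
    df = _read_tsv(path)
    if "conditionId" not in df.columns:
        raise FormatError(f"{path}: missing column 'conditionId'")
    conditions = []
    override_cols = [c for c in df.columns if c != "conditionId"]
    for _, row in df.iterrows():
        overrides = {}
        for col in override_cols:
            value = _cell(row, col)
            if value is not None:
                overrides[col] = float(value)
        conditions.append(Condition(condition_id=_cell(row, "conditionId"), overrides=overrides))
    return conditions


def load_problem(
    model_file,
    measurement_table,
    static_param_table,
    condition_table,
    config=None,
) -> Problem:
    """Load and validate a problem from its five files.

    ``config`` may be a path to a YAML/JSON file or an already-parsed dict.
    """
    model = load_model(model_file)
    measurements = load_measurements(measurement_table)
    specs = load_static_parameters(static_param_table)
    conditions = load_conditions(condition_table)
    if config is None:
        config = {}
    elif not isinstance(config, dict):
        config = _load_yaml(config) or {}
    groups = build_group_structure(measurements, specs)
    problem = Problem(
        model=model,
        conditions=tuple(conditions),
        measurements=tuple(measurements),
        groups=groups,
        dynamic_parameter_scale=config.get("parameter_scales", {}),
        dynamic_bounds={
            k: tuple(v) for k, v in config.get("parameter_bounds", {}).items()
        },
        sigma_floor=float(config.get("sigma_floor", 1e-10)),
        config={
            k: v
            for k, v in config.items()
            if k not in ("parameter_scales", "parameter_bounds", "sigma_floor")
        },
    )
    problem.validate(strict=True)
    return problem


def load_problem_dir(problem_dir) -> Problem:
    """Load a problem from a directory using the canonical file names."""
    d = Path(problem_dir)
    for key, name in FILENAMES.items():
        if key != "config" and not (d / name).exists():
            raise FormatError(f"{d / name}: file not found")
    config = d / FILENAMES["config"]
    return load_problem(
        d / FILENAMES["model"],
        d / FILENAMES["measurements"],
        d / FILENAMES["static_parameters"],
        d / FILENAMES["conditions"],
        config if config.exists() else None,
    )


def write_problem(problem: Problem, out_dir) -> dict[str, Path]:
    """Write a problem to a directory; ``load_problem_dir`` round-trips it."""
    d = Path(out_dir)
    try:
        d.mkdir(parents=True, exist_ok=True)
    except OSError as err:
        raise FormatError(f"{d}: cannot create directory ({err})") from err
    if not os.access(d, os.W_OK):
        raise FormatError(f"{d}: directory not writable")

    model = problem.model
    model_doc = {
        "states": list(model.state_ids),
        "parameters": list(model.parameter_ids),
        "condition_variables": list(model.condition_variable_ids),
        "rhs": dict(zip(model.state_ids, model.rhs_expressions)),
        "x0": dict(zip(model.state_ids, model.initial_expressions)),
        "observables": [
            {
                "id": o.observable_id,
                "formula": o.formula,
                "transformation": o.transformation,
            }
            for o in model.observables
        ],
    }
    paths = {}
    paths["model"] = d / FILENAMES["model"]
    with open(paths["model"], "w") as fh:
        yaml.safe_dump(model_doc, fh, sort_keys=False)

    rows = [
        {
            "observableId": m.observable_id,
            "conditionId": m.condition_id,
            "time": repr(m.time),
            "measurement": repr(m.value),
            "scalingGroup": m.scaling_group or "",
            "offsetGroup": ";".join(m.offset_groups),
            "noiseGroup": m.noise_group or "",
        }
        for m in problem.measurements
    ]
    paths["measurements"] = d / FILENAMES["measurements"]
    pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS).to_csv(
        paths["measurements"], sep="\t", index=False
    )

    spec_rows = [
        {
            "groupId": s.group_id,
            "kind": s.kind,
            "mode": s.mode,
            "fixedValue": repr(s.fixed_value) if s.fixed_value is not None else "",
            "lowerBound": repr(s.bounds[0]) if s.bounds else "",
            "upperBound": repr(s.bounds[1]) if s.bounds else "",
        }
        for s in problem.groups.specs
    ]
    paths["static_parameters"] = d / FILENAMES["static_parameters"]
    pd.DataFrame(
        spec_rows,
        columns=["groupId", "kind", "mode", "fixedValue", "lowerBound", "upperBound"],
    ).to_csv(paths["static_parameters"], sep="\t", index=False)

    override_cols = sorted({k for c in problem.conditions for k in c.override_map})
    cond_rows = [
        {"conditionId": c.condition_id}
        | {k: repr(v) for k, v in c.override_map.items()}
        for c in problem.conditions
    ]
    paths["conditions"] = d / FILENAMES["conditions"]
    pd.DataFrame(cond_rows, columns=["conditionId"] + override_cols).to_csv(
        paths["conditions"], sep="\t", index=False
    )

    config = dict(problem.config_map)
    config["sigma_floor"] = problem.sigma_floor
    config["parameter_scales"] = dict(problem.dynamic_parameter_scale)
    config["parameter_bounds"] = {
        k: list(v) for k, v in problem.dynamic_bounds
    }
    paths["config"] = d / FILENAMES["config"]
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    return paths


# spec naming alias
save_results = write_problem
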