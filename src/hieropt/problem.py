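"""Domain types for hierarchical ODE parameter-estimation problems.

An estimation task couples an ODE model (dynamic parameters ``theta``) to a
table of relative measurements through an observation layer of *static*
parameters: scaling factors ``s``, offsets ``b`` and Gaussian noise standard
deviations ``sigma``.  Each measurement is related to the model output by

    ybar_i = s_i * h_i(theta) + b_i + eps_i,     eps_i ~ N(0, sigma_i^2),

where ``h_i`` is the (possibly log-transformed) unscaled observable.  Static
parameters are shared between datapoints through *groups*; the index sets of
datapoints sharing one static parameter determine whether that parameter can
be optimized analytically in the inner problem (see
:func:`validate_group_structure`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import sympy as sp

from .errors import UnknownIdentifierError, ValidationError

logger = logging.getLogger(__name__)

TRANSFORMATIONS = ("identity", "log2", "log10")
KINDS = ("scaling", "offset", "noise")
MODES = ("analytic", "numeric", "fixed")

#: Effective value used for a datapoint that carries no group of a given kind.
DEFAULT_STATIC_VALUES = {"scaling": 1.0, "offset": 0.0, "noise": 1.0}

#: Sampling/optimization bounds used for statics that enter the outer
#: problem without declared bounds (standard mode over analytic-mode groups).
DEFAULT_STATIC_BOUNDS = {
    "scaling": (1e-3, 1e3),
    "offset": (-10.0, 10.0),
    "noise": (1e-3, 1e2),
}

#: Optimization scale per static kind (common practice: multiplicative
#: parameters on log10, additive ones linear).
STATIC_SCALES = {"scaling": "log10", "offset": "lin", "noise": "log10"}


@dataclass(frozen=True)
class Observable:
    """Unscaled observable: a symbolic formula in states/parameters plus an
    optional log transformation applied before the static parameters."""

    observable_id: str
    formula: str
    transformation: str = "identity"

    def __post_init__(self):
        if self.transformation not in TRANSFORMATIONS:
            raise ValidationError(
                f"observable '{self.observable_id}': unknown transformation "
                f"'{self.transformation}' (expected one of {TRANSFORMATIONS})"
            )


@dataclass(frozen=True)
class OdeModel:
    """ODE model xdot = f(x, theta, u), x(t0) = x0(theta, u) with observables."""

    state_ids: tuple[str, ...]
    parameter_ids: tuple[str, ...]
    condition_variable_ids: tuple[str, ...]
    rhs_expressions: tuple[str, ...]
    initial_expressions: tuple[str, ...]
    observables: tuple[Observable, ...]

    def __post_init__(self):
        object.__setattr__(self, "state_ids", tuple(self.state_ids))
        object.__setattr__(self, "parameter_ids", tuple(self.parameter_ids))
        object.__setattr__(
            self, "condition_variable_ids", tuple(self.condition_variable_ids)
        )
        object.__setattr__(self, "rhs_expressions", tuple(self.rhs_expressions))
        object.__setattr__(self, "initial_expressions", tuple(self.initial_expressions))
        object.__setattr__(self, "observables", tuple(self.observables))
        self._check()

    @property
    def n_states(self):
        return len(self.state_ids)

    @property
    def n_parameters(self):
        return len(self.parameter_ids)

    @property
    def observable_ids(self):
        return tuple(o.observable_id for o in self.observables)

    def _check(self):
        if len(self.rhs_expressions) != len(self.state_ids):
            raise ValidationError("need exactly one rhs expression per state")
        if len(self.initial_expressions) != len(self.state_ids):
            raise ValidationError("need exactly one initial expression per state")
        all_ids = (
            list(self.state_ids)
            + list(self.parameter_ids)
            + list(self.condition_variable_ids)
        )
        if len(set(all_ids)) != len(all_ids):
            raise ValidationError("state/parameter/condition-variable ids not unique")
        obs_ids = [o.observable_id for o in self.observables]
        if len(set(obs_ids)) != len(obs_ids):
            raise ValidationError("observable ids not unique")
        known = set(all_ids) | {"t"}
        for label, exprs in (
            ("rhs", self.rhs_expressions),
            ("x0", self.initial_expressions),
            ("observable", [o.formula for o in self.observables]),
        ):
            for expr in exprs:
                for symbol in sp.sympify(expr).free_symbols:
                    if str(symbol) not in known:
                        raise UnknownIdentifierError(
                            f"unknown symbol '{symbol}' in {label} expression '{expr}'"
                        )


@dataclass(frozen=True)
class Condition:
    """Experimental condition: numeric overrides for condition variables and,
    optionally, model parameters (which are then constants in that condition)."""

    condition_id: str
    overrides: tuple[tuple[str, float], ...] = ()

    def __post_init__(self):
        if isinstance(self.overrides, dict):
            object.__setattr__(
                self, "overrides", tuple(sorted(self.overrides.items()))
            )
        else:
            object.__setattr__(self, "overrides", tuple(self.overrides))

    @property
    def override_map(self) -> dict[str, float]:
        return dict(self.overrides)


@dataclass(frozen=True)
class Measurement:
    """One datapoint: observable, condition, time, value and its group ids.

    ``offset_groups`` is a tuple because normalized data may carry several
    additive offsets (e.g. one per observable plus one per cell-line); the
    effective offset of the datapoint is the sum of its groups' values.
    ``None`` group means the defaults s=1, b=0, sigma=1 apply.
    """

    observable_id: str
    condition_id: str
    time: float
    value: float
    scaling_group: str | None = None
    offset_groups: tuple[str, ...] = ()
    noise_group: str | None = None

    def __post_init__(self):
        if isinstance(self.offset_groups, str):
            object.__setattr__(self, "offset_groups", (self.offset_groups,))
        else:
            object.__setattr__(self, "offset_groups", tuple(self.offset_groups))


@dataclass(frozen=True)
class StaticParameterSpec:
    """Declaration of one static-parameter group: its kind (scaling, offset
    or noise) and how it is estimated (analytic, numeric or fixed)."""

    group_id: str
    kind: str
    mode: str
    fixed_value: float | None = None
    bounds: tuple[float, float] | None = None

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValidationError(f"group '{self.group_id}': unknown kind '{self.kind}'")
        if self.mode not in MODES:
            raise ValidationError(f"group '{self.group_id}': unknown mode '{self.mode}'")
        if self.mode == "fixed":
            if self.fixed_value is None:
                raise ValidationError(
                    f"group '{self.group_id}': mode=fixed requires fixed_value"
                )
            if self.kind == "noise" and self.fixed_value <= 0:
                raise ValidationError(
                    f"group '{self.group_id}': fixed noise value must be > 0"
                )
        if self.mode == "numeric":
            bounds = self.bounds or DEFAULT_STATIC_BOUNDS[self.kind]
            object.__setattr__(self, "bounds", (float(bounds[0]), float(bounds[1])))
            lo, hi = self.bounds
            import math

            if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
                raise ValidationError(
                    f"group '{self.group_id}': numeric bounds must be finite, lower < upper"
                )
        if self.bounds is not None:
            object.__setattr__(self, "bounds", tuple(self.bounds))


@dataclass(frozen=True)
class GroupVerdict:
    """Validator verdict for one group: analytic-eligible or not, and why."""

    group_id: str
    kind: str
    mode: str
    analytic_eligible: bool
    reason: str = ""


@dataclass
class ValidationReport:
    """Per-group eligibility verdicts plus structural errors (A4)."""

    verdicts: list[GroupVerdict] = field(default_factory=list)
    structural_errors: list[str] = field(default_factory=list)

    def verdict(self, group_id: str) -> GroupVerdict:
        for v in self.verdicts:
            if v.group_id == group_id:
                return v
        raise KeyError(group_id)

    def n_eligible(self, kind: str) -> int:
        return sum(1 for v in self.verdicts if v.kind == kind and v.analytic_eligible)

    def n_groups(self, kind: str) -> int:
        return sum(1 for v in self.verdicts if v.kind == kind)

    @property
    def ok(self) -> bool:
        """True iff no structural error and no analytic-mode group is ineligible."""
        if self.structural_errors:
            return False
        return all(
            v.analytic_eligible for v in self.verdicts if v.mode == "analytic"
        )

    def summary(self) -> str:
        lines = []
        for v in self.verdicts:
            status = "analytic-eligible" if v.analytic_eligible else f"ineligible ({v.reason})"
            lines.append(f"{v.kind:8s} {v.group_id:24s} mode={v.mode:8s} {status}")
        lines.extend(f"STRUCTURAL ERROR: {e}" for e in self.structural_errors)
        return "\n".join(lines)


@dataclass(frozen=True)
class GroupStructure:
    """Index sets of datapoints sharing each static parameter.

    ``scaling_groups`` etc. map group id -> sorted tuple of datapoint indices
    into the problem's measurement list.  Built from the measurement table by
    :func:`build_group_structure`.
    """

    scaling_groups: tuple[tuple[str, tuple[int, ...]], ...]
    offset_groups: tuple[tuple[str, tuple[int, ...]], ...]
    noise_groups: tuple[tuple[str, tuple[int, ...]], ...]
    specs: tuple[StaticParameterSpec, ...]

    def __post_init__(self):
        for name in ("scaling_groups", "offset_groups", "noise_groups"):
            value = getattr(self, name)
            if isinstance(value, dict):
                value = tuple(sorted((k, tuple(v)) for k, v in value.items()))
            else:
                value = tuple((k, tuple(v)) for k, v in value)
            object.__setattr__(self, name, value)
        object.__setattr__(self, "specs", tuple(self.specs))

    def groups(self, kind: str) -> dict[str, tuple[int, ...]]:
        return dict(
            {
                "scaling": self.scaling_groups,
                "offset": self.offset_groups,
                "noise": self.noise_groups,
            }[kind]
        )

    def spec(self, group_id: str) -> StaticParameterSpec:
        for s in self.specs:
            if s.group_id == group_id:
                return s
        raise UnknownIdentifierError(f"no static-parameter spec for group '{group_id}'")

    def mode(self, group_id: str) -> str:
        return self.spec(group_id).mode

    def n_analytic(self, kind: str) -> int:
        ids = self.groups(kind)
        return sum(1 for g in ids if self.mode(g) == "analytic")


def build_group_structure(
    measurements: list[Measurement], specs: list[StaticParameterSpec]
) -> GroupStructure:
    """Construct the index sets I^s_alpha, I^b_beta, I^sigma_gamma from the
    measurement table and attach the per-group estimation-mode specs."""
    by_kind: dict[str, dict[str, list[int]]] = {k: {} for k in KINDS}
    for i, m in enumerate(measurements):
        if m.scaling_group is not None:
            by_kind["scaling"].setdefault(m.scaling_group, []).append(i)
        for g in m.offset_groups:
            by_kind["offset"].setdefault(g, []).append(i)
        if m.noise_group is not None:
            by_kind["noise"].setdefault(m.noise_group, []).append(i)

    spec_ids = {s.group_id: s for s in specs}
    for kind in KINDS:
        for gid in by_kind[kind]:
            if gid not in spec_ids:
                raise UnknownIdentifierError(
                    f"measurements reference {kind} group '{gid}' with no spec"
                )
            if spec_ids[gid].kind != kind:
                raise ValidationError(
                    f"group '{gid}' used as {kind} but declared kind={spec_ids[gid].kind}"
                )
    return GroupStructure(
        scaling_groups={g: tuple(ix) for g, ix in by_kind["scaling"].items()},
        offset_groups={g: tuple(ix) for g, ix in by_kind["offset"].items()},
        noise_groups={g: tuple(ix) for g, ix in by_kind["noise"].items()},
        specs=tuple(specs),
    )


def _noise_signature(groups: GroupStructure, measurements, indices) -> tuple[set, bool]:
    """Return (set of noise group ids incl. None placeholders, any_analytic)."""
    noise_ids = set()
    any_analytic = False
    for i in indices:
        g = measurements[i].noise_group
        noise_ids.add(g)
        if g is not None and groups.mode(g) == "analytic":
            any_analytic = True
    return noise_ids, any_analytic


def validate_group_structure(
    groups: GroupStructure,
    measurements: list[Measurement],
    strict: bool = False,
) -> ValidationReport:
    """Check the sharing assumptions that make analytic inner optima valid.

    For each scaling/offset group the validator decides whether it is
    *analytic-eligible*:

    - A1: an analytic scaling group and an analytic offset group that share
      any datapoint must share all of them (identical index sets), otherwise
      the closed-form expressions are interdependent.
    - A2: a group whose datapoints involve an analytically estimated noise
      parameter must lie entirely within that single noise group (so the
      unknown sigma is constant within the group and drops out).
    - A3: when all sigma values in the group are known (fixed/numeric or the
      default 1), the sigma-weighted closed forms apply as-is, so spanning
      several known-noise groups is allowed.
    - A4: index sets within one kind must be disjoint among analytic groups
      (a datapoint with two analytic offsets is unidentifiable) -> structural
      error.

    Noise groups themselves are always analytic-eligible: their closed form
    only needs the residuals, which are known once s and b are resolved.

    Verdicts depend only on the index-set structure, never on measurement
    values.  With ``strict=True`` a :class:`ValidationError` is raised if any
    analytic-mode group is ineligible or a structural error was found (no
    silent demotion).
    """
    report = ValidationReport()

    # A4 among analytic groups, per kind (scaling/noise are single-assignment
    # per datapoint by construction; offsets may stack).
    for kind in ("offset",):
        analytic_cover: dict[int, str] = {}
        for gid, indices in groups.groups(kind).items():
            if groups.mode(gid) != "analytic":
                continue
            for i in indices:
                if i in analytic_cover:
                    report.structural_errors.append(
                        f"A4: datapoint {i} belongs to two analytic {kind} groups "
                        f"('{analytic_cover[i]}' and '{gid}')"
                    )
                else:
                    analytic_cover[i] = gid

    scaling_sets = {g: frozenset(ix) for g, ix in groups.groups("scaling").items()}
    offset_sets = {g: frozenset(ix) for g, ix in groups.groups("offset").items()}

    def eligibility(gid, indices, kind) -> tuple[bool, str]:
        iset = frozenset(indices)
        # A1 against analytic partners of the other kind
        partner_sets = offset_sets if kind == "scaling" else scaling_sets
        partner_kind = "offset" if kind == "scaling" else "scaling"
        for pg, pset in partner_sets.items():
            if groups.mode(pg) != "analytic":
                continue
            if iset & pset and iset != pset:
                return False, (
                    f"A1: overlaps analytic {partner_kind} group '{pg}' "
                    "without identical datapoints"
                )
        # A2/A3 noise nesting
        noise_ids, any_analytic = _noise_signature(groups, measurements, indices)
        if any_analytic and len(noise_ids) > 1:
            return False, (
                "A2: datapoints span more than one noise parameter although "
                "the noise is estimated analytically"
            )
        if kind == "offset":
            # A4': another *analytic* offset group on the same datapoints
            for og, oset in offset_sets.items():
                if og == gid or groups.mode(og) != "analytic":
                    continue
                if iset & oset and iset != oset:
                    return False, (
                        f"A4: overlaps analytic offset group '{og}' without "
                        "identical datapoints"
                    )
        return True, ""

    for kind in ("scaling", "offset"):
        for gid, indices in groups.groups(kind).items():
            ok, reason = eligibility(gid, indices, kind)
            report.verdicts.append(
                GroupVerdict(gid, kind, groups.mode(gid), ok, reason)
            )
    for gid, indices in groups.groups("noise").items():
        if len(indices) == 0:
            report.verdicts.append(
                GroupVerdict(gid, "noise", groups.mode(gid), False, "empty group")
            )
        else:
            report.verdicts.append(GroupVerdict(gid, "noise", groups.mode(gid), True))

    if strict:
        problems = list(report.structural_errors)
        problems += [
            f"group '{v.group_id}' requests mode=analytic but is ineligible: {v.reason}"
            for v in report.verdicts
            if v.mode == "analytic" and not v.analytic_eligible
        ]
        if problems:
            raise ValidationError(
                "group structure invalid:\n" + "\n".join(problems), report=report
            )
    return report


@dataclass(frozen=True)
class Problem:
    """The full estimation task: model, conditions, measurements, group
    structure, parameter scales/bounds and the sigma lower bound."""

    model: OdeModel
    conditions: tuple[Condition, ...]
    measurements: tuple[Measurement, ...]
    groups: GroupStructure
    dynamic_parameter_scale: tuple[tuple[str, str], ...] = ()
    dynamic_bounds: tuple[tuple[str, tuple[float, float]], ...] = ()
    sigma_floor: float = 1e-10
    config: tuple[tuple[str, object], ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "conditions", tuple(self.conditions))
        object.__setattr__(self, "measurements", tuple(self.measurements))
        for name, default in (
            ("dynamic_parameter_scale", "log10"),
            ("dynamic_bounds", (1e-3, 1e3)),
        ):
            value = getattr(self, name)
            if isinstance(value, dict):
                value = tuple(sorted(value.items()))
            mapping = dict(value)
            full = tuple(
                (p, mapping.get(p, default)) for p in self.model.parameter_ids
            )
            object.__setattr__(self, name, full)
        if isinstance(self.config, dict):
            object.__setattr__(self, "config", tuple(sorted(self.config.items())))
        if self.sigma_floor <= 0:
            raise ValidationError("sigma_floor must be positive")
        self._check_references()

    @property
    def scale_map(self) -> dict[str, str]:
        return dict(self.dynamic_parameter_scale)

    @property
    def bounds_map(self) -> dict[str, tuple[float, float]]:
        return dict(self.dynamic_bounds)

    @property
    def config_map(self) -> dict:
        return dict(self.config)

    @property
    def condition_map(self) -> dict[str, Condition]:
        return {c.condition_id: c for c in self.conditions}

    def _check_references(self):
        obs_ids = set(self.model.observable_ids)
        cond_ids = {c.condition_id for c in self.conditions}
        model_ids = set(self.model.parameter_ids) | set(
            self.model.condition_variable_ids
        )
        for c in self.conditions:
            for target in c.override_map:
                if target not in model_ids:
                    raise UnknownIdentifierError(
                        f"condition '{c.condition_id}' overrides unknown id '{target}'"
                    )
        for m in self.measurements:
            if m.observable_id not in obs_ids:
                raise UnknownIdentifierError(
                    f"measurement references unknown observable '{m.observable_id}'"
                )
            if m.condition_id not in cond_ids:
                raise UnknownIdentifierError(
                    f"measurement references unknown condition '{m.condition_id}'"
                )
            if m.time < 0:
                raise ValidationError("measurement time before initial time 0")

    def validate(self, strict: bool = True) -> ValidationReport:
        report = validate_group_structure(
            self.groups, list(self.measurements), strict=strict
        )
        logger.info(
            "problem: %d datapoints, %d conditions; scalings %d (%d analytic), "
            "offsets %d (%d analytic), noise %d (%d analytic)",
            len(self.measurements),
            len(self.conditions),
            report.n_groups("scaling"),
            report.n_eligible("scaling"),
            report.n_groups("offset"),
            report.n_eligible("offset"),
            report.n_groups("noise"),
            report.n_eligible("noise"),
        )
        return report

    # -- per-datapoint resolution -------------------------------------------

    def datapoint_groups(self) -> list[dict]:
        """For each measurement: its scaling/offset/noise group ids."""
        return [
            {
                "scaling": m.scaling_group,
                "offsets": m.offset_groups,
                "noise": m.noise_group,
            }
            for m in self.measurements
        ]
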