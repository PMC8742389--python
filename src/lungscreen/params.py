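"""Cohort parameter sets for the screening model.

Holds the base-case inputs for the four modelled cohorts (Japan/US x
male/female 60-year-old never smokers), loads and validates user-supplied
configurations, and exposes the one-way sensitivity ranges attached to each
scalar input.

All probabilities (including test sensitivities/specificities) are stored on
the [0, 1] scale; costs are 2019-adjusted US dollars; utilities are standard
health-state weights with healthy = 1 and dead = 0.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Any, Iterable, Mapping

import yaml

__all__ = [
    "TestAccuracy",
    "StageDistribution",
    "StageSurvival",
    "CostSet",
    "UtilitySet",
    "ParameterSet",
    "ParamRange",
    "COHORTS",
    "STRATEGIES",
    "STAGES",
    "default_parameters",
    "load_parameters",
    "save_parameters",
    "to_dict",
    "sensitivity_ranges",
    "validate_parameter_set",
    "get_parameter",
    "apply_parameter",
    "parameter_kind",
    "PARAMETER_NAMES",
]

STRATEGIES = ("ldct", "cxr", "no_screening")
STAGES = (1, 2, 3, 4)
COHORTS = (("japan", "male"), ("japan", "female"), ("us", "male"), ("us", "female"))

_SUM_TOL = 1e-9


class ParameterError(ValueError):
    """Raised when a parameter set violates a model invariant."""


@dataclass(frozen=True)
class TestAccuracy:
    """Sensitivity and specificity of a screening test, as probabilities."""

    sensitivity: float
    specificity: float


@dataclass(frozen=True)
class StageDistribution:
    """Distribution of NSCLC stage (I-IV) at diagnosis for one detection route."""

    p_stage1: float
    p_stage2: float
    p_stage3: float
    p_stage4: float

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.p_stage1, self.p_stage2, self.p_stage3, self.p_stage4)


@dataclass(frozen=True)
class StageSurvival:
    """Stage-specific five-year survival proportions."""

    s5_stage1: float
    s5_stage2: float
    s5_stage3: float
    s5_stage4: float

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.s5_stage1, self.s5_stage2, self.s5_stage3, self.s5_stage4)


@dataclass(frozen=True)
class CostSet:
    """Unit costs in US$: screening tests, diagnostic workup, stage treatments.

    ``cost_workup`` is chest CT bronchoscopy with CT-guided lung biopsy, the
    single diagnostic procedure charged after a positive screen.
    """

    cost_screen_cxr: float
    cost_screen_ldct: float
    cost_workup: float
    cost_treat_stage1: float
    cost_treat_stage2: float
    cost_treat_stage3: float
    cost_treat_stage4: float

    def treatment(self, stage: int) -> float:
        return getattr(self, f"cost_treat_stage{stage}")


@dataclass(frozen=True)
class UtilitySet:
    """Health-state utility weights; healthy and dead are anchored at 1 and 0."""

    u_stage1: float
    u_stage2: float
    u_stage3: float
    u_stage4: float
    u_cured: float
    u_healthy: float = 1.0
    u_dead: float = 0.0

    def stage(self, stage: int) -> float:
        return getattr(self, f"u_stage{stage}")


@dataclass(frozen=True)
class ParamRange:
    """One-way sensitivity range for a named scalar parameter."""

    name: str
    low: float
    high: float

    @property
    def width(self) -> float:
        return self.high - self.low


@dataclass(frozen=True)
class ParameterSet:
    """All inputs needed to run the model for one cohort.

    ``incidence`` is the annual probability that a cancer-free never smoker
    develops lung cancer at or after the start age. ``radiogenic_risk_total``
    is the cumulative excess cancer risk from repeated annual LDCT over a
    screening lifetime; the engine spreads it uniformly over the expected
    number of screens.
    """

    country: str
    sex: str
    start_age: int
    incidence: float
    detection_no_screening: StageDistribution
    detection_cxr: StageDistribution
    detection_ldct: StageDistribution
    survival: StageSurvival
    accuracy_cxr: TestAccuracy
    accuracy_ldct: TestAccuracy
    costs: CostSet
    utilities: UtilitySet
    radiogenic_risk_total: float
    discount_rate: float = 0.03
    wtp: float = 100_000.0
    cycle_length: float = 1.0
    max_age: int = 100
    adherence: float = 1.0
    sclc_fraction: float = 0.0

    @property
    def cohort(self) -> str:
        return f"{self.country}_{self.sex}"

    def detection(self, strategy: str) -> StageDistribution:
        if strategy == "ldct":
            return self.detection_ldct
        if strategy == "cxr":
            return self.detection_cxr
        if strategy == "no_screening":
            return self.detection_no_screening
        raise ParameterError(f"unknown strategy {strategy!r}")

    def accuracy(self, strategy: str) -> TestAccuracy:
        if strategy == "ldct":
            return self.accuracy_ldct
        if strategy == "cxr":
            return self.accuracy_cxr
        raise ParameterError(f"no test accuracy for strategy {strategy!r}")


# ---------------------------------------------------------------------------
# validation

def _check_prob(errors: list[str], name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        errors.append(f"{name} = {value} outside [0, 1]")


def validate_parameter_set(ps: ParameterSet, strict: bool = False) -> None:
    """Raise :class:`ParameterError` listing every violated invariant.

    ``strict`` additionally enforces the base-case orderings (stage survival
    non-increasing, stage utilities non-increasing I >= III >= IV) that a
    randomly sampled set is allowed to break.
    """
    errors: list[str] = []
    _check_prob(errors, "incidence", ps.incidence)
    _check_prob(errors, "adherence", ps.adherence)
    _check_prob(errors, "sclc_fraction", ps.sclc_fraction)
    _check_prob(errors, "radiogenic_risk_total", ps.radiogenic_risk_total)
    for label, dist in (
        ("detection_no_screening", ps.detection_no_screening),
        ("detection_cxr", ps.detection_cxr),
        ("detection_ldct", ps.detection_ldct),
    ):
        shares = dist.as_tuple()
        for i, p in enumerate(shares, start=1):
            _check_prob(errors, f"{label}.p_stage{i}", p)
        if abs(sum(shares) - 1.0) > _SUM_TOL:
            errors.append(f"{label} shares sum to {sum(shares)!r}, expected 1")
    for i, s5 in enumerate(ps.survival.as_tuple(), start=1):
        _check_prob(errors, f"survival.s5_stage{i}", s5)
    for label, acc in (("accuracy_cxr", ps.accuracy_cxr), ("accuracy_ldct", ps.accuracy_ldct)):
        _check_prob(errors, f"{label}.sensitivity", acc.sensitivity)
        _check_prob(errors, f"{label}.specificity", acc.specificity)
    for f_ in dataclasses.fields(ps.costs):
        value = getattr(ps.costs, f_.name)
        if value < 0:
            errors.append(f"costs.{f_.name} = {value} is negative")
    for f_ in dataclasses.fields(ps.utilities):
        _check_prob(errors, f"utilities.{f_.name}", getattr(ps.utilities, f_.name))
    if ps.utilities.u_healthy != 1.0:
        errors.append("utilities.u_healthy must be 1")
    if ps.utilities.u_dead != 0.0:
        errors.append("utilities.u_dead must be 0")
    if ps.discount_rate < 0:
        errors.append(f"discount_rate = {ps.discount_rate} is negative")
    if ps.wtp < 0:
        errors.append(f"wtp = {ps.wtp} is negative")
    if ps.cycle_length <= 0:
        errors.append("cycle_length must be positive")
    if not ps.start_age < ps.max_age:
        errors.append(f"start_age {ps.start_age} must be below max_age {ps.max_age}")
    if strict:
        s = ps.survival.as_tuple()
        if not (s[0] >= s[1] >= s[2] >= s[3]):
            errors.append("survival must be non-increasing from stage I to IV")
        u = ps.utilities
        if not (u.u_stage1 >= u.u_stage3 >= u.u_stage4):
            errors.append("utilities must satisfy u_stage1 >= u_stage3 >= u_stage4")
        if ps.adherence != 1.0:
            errors.append("adherence is fixed at 1 in the base model")
        if ps.sclc_fraction != 0.0:
            errors.append("sclc_fraction is fixed at 0 (all cancers NSCLC)")
    if errors:
        raise ParameterError("; ".join(errors))


# ---------------------------------------------------------------------------
# packaged defaults and config I/O

_NESTED_TYPES: dict[str, type] = {
    "detection_no_screening": StageDistribution,
    "detection_cxr": StageDistribution,
    "detection_ldct": StageDistribution,
    "survival": StageSurvival,
    "accuracy_cxr": TestAccuracy,
    "accuracy_ldct": TestAccuracy,
    "costs": CostSet,
    "utilities": UtilitySet,
}


def _cohort_resource(country: str, sex: str) -> dict[str, Any]:
    name = f"{country}_{sex}.yaml"
    ref = resources.files("lungscreen.data") / name
    if not ref.is_file():
        known = ", ".join(f"{c}/{s}" for c, s in COHORTS)
        raise ParameterError(f"unknown cohort {country!r}/{sex!r}; known cohorts: {known}")
    return yaml.safe_load(ref.read_text())


def _from_mapping(data: Mapping[str, Any]) -> ParameterSet:
    kwargs: dict[str, Any] = {}
    for f_ in dataclasses.fields(ParameterSet):
        if f_.name not in data:
            continue
        value = data[f_.name]
        if f_.name in _NESTED_TYPES and isinstance(value, Mapping):
            value = _NESTED_TYPES[f_.name](**value)
        kwargs[f_.name] = value
    missing = {f_.name for f_ in dataclasses.fields(ParameterSet)
               if f_.default is dataclasses.MISSING} - set(kwargs)
    if missing:
        raise ParameterError(f"missing required parameter fields: {sorted(missing)}")
    return ParameterSet(**kwargs)


def default_parameters(country: str, sex: str) -> ParameterSet:
    """Packaged base-case parameter set for one of the four cohorts."""
    data = _cohort_resource(str(country).lower(), str(sex).lower())
    ps = _from_mapping(data)
    validate_parameter_set(ps, strict=True)
    return ps


def load_parameters(source: str | Path | Mapping[str, Any]) -> ParameterSet:
    """Load a parameter set from a YAML/JSON file path or an in-memory mapping.

    A ``base: <country>_<sex>`` key starts from the packaged cohort defaults
    and overrides only the fields present in the config; nested sections
    (``costs``, ``survival``, ...) may be partial in that case.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, Mapping):
            raise ParameterError(f"config {source} did not parse to a mapping")
    else:
        data = dict(source)
    data = dict(data)
    base_name = data.pop("base", None)
    data.pop("sensitivity_ranges", None)
    if base_name is not None:
        country, _, sex = str(base_name).partition("_")
        base = to_dict(default_parameters(country, sex))
        for key, value in data.items():
            if key in _NESTED_TYPES and isinstance(value, Mapping):
                base[key] = {**base[key], **value}
            else:
                base[key] = value
        data = base
    ps = _from_mapping(data)
    validate_parameter_set(ps)
    return ps


def to_dict(ps: ParameterSet) -> dict[str, Any]:
    """Plain-dict form of a parameter set (YAML/JSON serializable)."""
    return dataclasses.asdict(ps)


def save_parameters(ps: ParameterSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(to_dict(ps), fh, sort_keys=False)


def sensitivity_ranges(ps: ParameterSet) -> list[ParamRange]:
    """One-way ranges for every varied scalar of the given cohort.

    Covers incidence, the four stage survivals, the twelve stage shares, the
    seven costs, the four test accuracies and the five stage/cured utilities.
    """
    data = _cohort_resource(ps.country, ps.sex)
    ranges = data.get("sensitivity_ranges", {})
    return [ParamRange(name, float(lo), float(hi)) for name, (lo, hi) in ranges.items()]


# ---------------------------------------------------------------------------
# flat parameter access (used by one-way sensitivity analysis and the PSA)

_SHARE_PREFIXES = {
    "p_noscreen": "detection_no_screening",
    "p_cxr": "detection_cxr",
    "p_ldct": "detection_ldct",
}
_ACCURACY_NAMES = {
    "sens_cxr": ("accuracy_cxr", "sensitivity"),
    "spec_cxr": ("accuracy_cxr", "specificity"),
    "sens_ldct": ("accuracy_ldct", "sensitivity"),
    "spec_ldct": ("accuracy_ldct", "specificity"),
}

PARAMETER_NAMES: tuple[str, ...] = (
    ("incidence",)
    + tuple(f"s5_stage{i}" for i in STAGES)
    + tuple(f"{p}_stage{i}" for p in _SHARE_PREFIXES for i in STAGES)
    + ("cost_screen_cxr", "cost_screen_ldct", "cost_workup")
    + tuple(f"cost_treat_stage{i}" for i in STAGES)
    + tuple(_ACCURACY_NAMES)
    + tuple(f"u_stage{i}" for i in STAGES)
    + ("u_cured",)
)


def parameter_kind(name: str) -> str:
    """Classify a flat parameter name as 'probability', 'share' or 'cost'."""
    if name.startswith("cost_"):
        return "cost"
    for prefix in _SHARE_PREFIXES:
        if name.startswith(prefix):
            return "share"
    if name in _ACCURACY_NAMES or name.startswith(("s5_", "u_")) or name == "incidence":
        return "probability"
    raise ParameterError(f"unknown parameter name {name!r}")


def _split_share(name: str) -> tuple[str, int]:
    prefix, _, stage = name.rpartition("_stage")
    return _SHARE_PREFIXES[prefix], int(stage)


def get_parameter(ps: ParameterSet, name: str) -> float:
    kind = parameter_kind(name)
    if name == "incidence":
        return ps.incidence
    if kind == "cost":
        return getattr(ps.costs, name)
    if kind == "share":
        fieldname, stage = _split_share(name)
        return getattr(getattr(ps, fieldname), f"p_stage{stage}")
    if name in _ACCURACY_NAMES:
        attr, sub = _ACCURACY_NAMES[name]
        return getattr(getattr(ps, attr), sub)
    if name.startswith("s5_"):
        return getattr(ps.survival, name)
    return getattr(ps.utilities, name)


def apply_parameter(ps: ParameterSet, name: str, value: float) -> ParameterSet:
    """Return a copy of ``ps`` with one flat parameter set to ``value``.

    Setting one share of a stage distribution rescales the other three
    proportionally so the distribution still sums to 1 (equal split of the
    remainder if the other shares are all zero).
    """
    kind = parameter_kind(name)
    if name == "incidence":
        return replace(ps, incidence=value)
    if kind == "cost":
        return replace(ps, costs=replace(ps.costs, **{name: value}))
    if kind == "share":
        fieldname, stage = _split_share(name)
        dist: StageDistribution = getattr(ps, fieldname)
        shares = list(dist.as_tuple())
        rest = sum(p for i, p in enumerate(shares, start=1) if i != stage)
        new = [0.0] * 4
        new[stage - 1] = value
        for i, p in enumerate(shares, start=1):
            if i == stage:
                continue
            new[i - 1] = p * (1.0 - value) / rest if rest > 0 else (1.0 - value) / 3.0
        return replace(ps, **{fieldname: StageDistribution(*new)})
    if name in _ACCURACY_NAMES:
        attr, sub = _ACCURACY_NAMES[name]
        return replace(ps, **{attr: replace(getattr(ps, attr), **{sub: value})})
    if name.startswith("s5_"):
        return replace(ps, survival=replace(ps.survival, **{name: value}))
    return replace(ps, utilities=replace(ps.utilities, **{name: value}))
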