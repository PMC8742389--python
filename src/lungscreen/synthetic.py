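"""Synthetic all-cause mortality tables and randomized parameter sets.

National period life tables are not shipped with the package; instead a
Gompertz-Makeham hazard stands in for them.  The annual death probability at
integer age x is

    qx(x) = 1 - exp(-(a + b * exp(c * x)))

with Makeham background ``a``, Gompertz scale ``b`` and aging rate ``c``.
``calibrate_life_table`` tunes ``b`` so the discounted, half-cycle-corrected
life expectancy at the cohort start age matches a target value, which anchors
the synthetic background survival to the discounted life-year scale the
screening model operates on.  Users can substitute a real national table via
the two-column ``age,qx`` CSV interface.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .params import (
    ParameterSet,
    ParamRange,
    StageDistribution,
    apply_parameter,
    parameter_kind,
    validate_parameter_set,
)

__all__ = [
    "MortalityModelSpec",
    "LifeTable",
    "make_life_table",
    "calibrate_life_table",
    "default_life_table",
    "discounted_life_expectancy",
    "expected_screen_count",
    "sample_parameter_set",
    "DEFAULT_MORTALITY_SPEC",
    "LIFE_EXPECTANCY_TARGETS",
]


@dataclass(frozen=True)
class MortalityModelSpec:
    """Gompertz-Makeham hazard parameters for a synthetic life table."""

    makeham_a: float = 5e-4
    gompertz_b: float = 2.5e-5
    gompertz_c: float = 0.098
    max_age: int = 100

    def validate(self) -> None:
        if self.makeham_a < 0:
            raise ValueError(f"makeham_a = {self.makeham_a} must be >= 0")
        if self.gompertz_b < 0:
            raise ValueError(f"gompertz_b = {self.gompertz_b} must be >= 0")
        if self.gompertz_c <= 0:
            raise ValueError(f"gompertz_c = {self.gompertz_c} must be > 0")


DEFAULT_MORTALITY_SPEC = MortalityModelSpec()

# Discounted (3%/yr) life-expectancy anchors at age 60 for each cohort's
# background mortality, chosen as the strategy least distorted by lung-cancer
# deaths in each country (near-background survival scale).
LIFE_EXPECTANCY_TARGETS: dict[tuple[str, str], float] = {
    ("japan", "male"): 18.0655,
    ("japan", "female"): 17.9603,
    ("us", "male"): 15.2639,
    ("us", "female"): 16.9346,
}


@dataclass(frozen=True)
class LifeTable:
    """Age-indexed annual all-cause death probabilities.

    Ages are contiguous integers; the last age is absorbing (qx = 1) so every
    cohort trace closes by the table horizon.
    """

    ages: np.ndarray
    qx: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        qx = np.asarray(self.qx, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "qx", qx)
        if ages.ndim != 1 or ages.shape != qx.shape or ages.size == 0:
            raise ValueError("ages and qx must be matching non-empty 1-d arrays")
        if not np.all(np.diff(ages) == 1):
            raise ValueError("ages must be contiguous and increasing")
        if np.any((qx < 0) | (qx > 1)):
            raise ValueError("qx values must lie in [0, 1]")
        if qx[-1] != 1.0:
            raise ValueError("qx at the final age must be 1 (absorbing horizon)")

    @property
    def min_age(self) -> int:
        return int(self.ages[0])

    @property
    def max_age(self) -> int:
        return int(self.ages[-1])

    def qx_at(self, age: int) -> float:
        if age < self.min_age or age > self.max_age:
            raise ValueError(f"age {age} outside life table [{self.min_age}, {self.max_age}]")
        return float(self.qx[age - self.min_age])

    def survival_from(self, start_age: int) -> np.ndarray:
        """S(t): probability of being alive t whole years after ``start_age``."""
        q = self.qx[start_age - self.min_age:]
        return np.concatenate([[1.0], np.cumprod(1.0 - q)])

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("age,qx\n")
            for age, q in zip(self.ages, self.qx):
                fh.write(f"{int(age)},{float(q)!r}\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        rows = Path(path).read_text().strip().splitlines()
        header = [h.strip().lower() for h in rows[0].split(",")]
        if header[:2] != ["age", "qx"]:
            raise ValueError(f"life table CSV {path} must have header 'age,qx'")
        ages, qx = [], []
        for line in rows[1:]:
            a, q = line.split(",")[:2]
            ages.append(int(a))
            qx.append(float(q))
        return cls(np.array(ages), np.array(qx))


def make_life_table(spec: MortalityModelSpec, min_age: int = 0) -> LifeTable:
    """Evaluate the Gompertz-Makeham annual death probabilities on an age grid."""
    spec.validate()
    ages = np.arange(min_age, spec.max_age + 1)
    with np.errstate(over="raise"):
        try:
            hazard = spec.makeham_a + spec.gompertz_b * np.exp(spec.gompertz_c * ages)
        except FloatingPointError:
            bad = spec.max_age
            raise OverflowError(f"mortality hazard overflows at age {bad}") from None
    if not np.all(np.isfinite(hazard)):
        bad = int(ages[~np.isfinite(hazard)][0])
        raise OverflowError(f"mortality hazard overflows at age {bad}")
    qx = 1.0 - np.exp(-hazard)
    qx = np.clip(qx, 0.0, 1.0)
    qx[-1] = 1.0
    return LifeTable(ages, qx)


def discounted_life_expectancy(
    life_table: LifeTable, start_age: int, discount_rate: float
) -> float:
    """Discounted life expectancy at ``start_age`` with half-cycle correction.

    Trapezoidal accrual over the cancer-free survival curve: half weight on
    the first and last points of the trace, full weight in between.
    """
    surv = life_table.survival_from(start_age)
    t = np.arange(surv.size)
    disc = (1.0 + discount_rate) ** (-t)
    w = np.ones_like(surv)
    w[0] = w[-1] = 0.5
    return float(np.sum(w * disc * surv))


def expected_screen_count(life_table: LifeTable, start_age: int) -> int:
    """Expected number of annual screens attended over a cancer-free lifetime.

    One screen per cycle while alive at the cycle start, so the expectation is
    the sum of the survival curve, rounded to whole screens (at least 1).
    """
    surv = life_table.survival_from(start_age)
    return max(1, round(float(surv[:-1].sum())))


def calibrate_life_table(
    target_discounted_le: float,
    start_age: int = 60,
    discount_rate: float = 0.03,
    spec_template: MortalityModelSpec = DEFAULT_MORTALITY_SPEC,
    tol: float = 1e-4,
) -> LifeTable:
    """Bisect the Gompertz scale ``b`` to hit a discounted life expectancy.

    Deterministic; raises with the achievable bracket when the target cannot
    be reached by varying ``b`` alone.
    """
    log_b_lo, log_b_hi = -9.0, -1.0

    def le_at(log_b: float) -> float:
        table = make_life_table(replace(spec_template, gompertz_b=10.0 ** log_b))
        return discounted_life_expectancy(table, start_age, discount_rate)

    le_max, le_min = le_at(log_b_lo), le_at(log_b_hi)
    if not (le_min <= target_discounted_le <= le_max):
        raise ValueError(
            f"target {target_discounted_le} outside achievable bracket "
            f"[{le_min:.4f}, {le_max:.4f}] discounted years"
        )
    log_b = brentq(
        lambda x: le_at(x) - target_discounted_le, log_b_lo, log_b_hi, xtol=1e-12
    )
    table = make_life_table(replace(spec_template, gompertz_b=10.0 ** log_b))
    achieved = discounted_life_expectancy(table, start_age, discount_rate)
    if abs(achieved - target_discounted_le) > tol:
        raise RuntimeError(
            f"calibration stalled: achieved {achieved}, target {target_discounted_le}"
        )
    return table


@lru_cache(maxsize=None)
def _default_life_table_cached(country: str, sex: str, start_age: int, rate: float) -> LifeTable:
    target = LIFE_EXPECTANCY_TARGETS[(country, sex)]
    return calibrate_life_table(target, start_age=start_age, discount_rate=rate)


def default_life_table(ps_or_country: ParameterSet | str, sex: str | None = None) -> LifeTable:
    """Synthetic life table calibrated for one of the four packaged cohorts."""
    if isinstance(ps_or_country, ParameterSet):
        ps = ps_or_country
        return _default_life_table_cached(ps.country, ps.sex, ps.start_age, ps.discount_rate)
    return _default_life_table_cached(str(ps_or_country), str(sex), 60, 0.03)


# ---------------------------------------------------------------------------
# randomized parameter sets (test fixtures, property suites)

def sample_parameter_set(
    base: ParameterSet, ranges: list[ParamRange], seed: int
) -> ParameterSet:
    """Draw each ranged scalar uniformly; renormalize stage distributions.

    Deterministic for a fixed seed; the result always passes (non-strict)
    validation.
    """
    rng = np.random.default_rng(seed)
    ps = base
    shares: dict[str, dict[int, float]] = {}
    for pr in sorted(ranges, key=lambda r: r.name):
        value = float(rng.uniform(pr.low, pr.high)) if pr.width > 0 else pr.low
        if parameter_kind(pr.name) == "share":
            prefix, _, stage = pr.name.rpartition("_stage")
            shares.setdefault(prefix, {})[int(stage)] = value
        else:
            ps = apply_parameter(ps, pr.name, value)
    prefix_to_field = {
        "p_noscreen": "detection_no_screening",
        "p_cxr": "detection_cxr",
        "p_ldct": "detection_ldct",
    }
    for prefix, drawn in shares.items():
        fieldname = prefix_to_field[prefix]
        current = getattr(ps, fieldname).as_tuple()
        raw = [drawn.get(i, current[i - 1]) for i in (1, 2, 3, 4)]
        total = sum(raw)
        if total <= 0:
            raise ValueError(f"sampled {fieldname} shares sum to {total}")
        ps = dataclass_replace_distribution(ps, fieldname, [p / total for p in raw])
    validate_parameter_set(ps)
    return ps


def dataclass_replace_distribution(
    ps: ParameterSet, fieldname: str, shares: list[float]
) -> ParameterSet:
    return replace(ps, **{fieldname: StageDistribution(*shares)})
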