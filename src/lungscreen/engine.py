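"""Yearly-cycle Markov cohort engine for one screening strategy.

The cohort starts cancer-free at the start age and is propagated one yearly
cycle at a time through the health states: no lung cancer, undiagnosed
cancer (screen false negatives awaiting re-screen), NSCLC stage I-IV (with a
five-year cure clock), cured, and death split into lung-cancer and
other-cause substates.

Within each cycle events occur in a fixed order: screening (test costs for
everyone screened, workup for positives, stage assignment and treatment cost
for true positives), cancer incidence (symptomatic diagnosis in the same
cycle under no screening), mortality (background qx plus the additive
stage-specific cancer death probability during the five post-diagnosis
cycles), and finally the cure-clock advance.  State-membership payoffs are
accrued on the cycle-boundary trace with a half-cycle (trapezoidal)
correction; one-time event costs are discounted at the cycle they occur.

A false-positive screen sends the individual to diagnostic workup.  The
default policy (``fp_workup="baseline"``) treats false-positive findings as
prevalent benign disease worked up once at the first (prevalence) screen;
``"first"`` charges one workup at each individual's first false-positive
result whenever it occurs, and ``"every"`` re-biopsies on every
false-positive cycle.  The cumulative radiogenic risk of annual LDCT is
spread over the scheduled screening course (one screen per cycle to the
model horizon), so individuals who die early accrue proportionally less
excess risk.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .natural_history import (
    annual_cancer_mortality,
    radiogenic_incidence_increment,
    screen_outcome_probs,
    stage_at_detection,
)
from .params import ParameterSet, STRATEGIES
from .synthetic import LifeTable

__all__ = [
    "STATE_NAMES",
    "CohortTrace",
    "StrategyResult",
    "run_cohort",
    "accrue_outcomes",
    "run_strategy_set",
]

# Aggregate trace states, in column order.
STATE_NAMES = (
    "no_lung_cancer",
    "undiagnosed_cancer",
    "stage1",
    "stage2",
    "stage3",
    "stage4",
    "cured",
    "dead_lung_cancer",
    "dead_other_cause",
)
_ALIVE = slice(0, 7)
_CURE_YEARS = 5


@dataclass(frozen=True)
class CohortTrace:
    """Cycle-boundary occupancy and per-cycle event costs for one strategy.

    ``occupancy[t]`` is the state distribution at the start of cycle ``t``
    (cycle 0 = all in no-lung-cancer at the start age); ``cycle_cost[t]`` is
    the undiscounted event cost incurred during cycle ``t``.
    """

    strategy: str
    start_age: int
    occupancy: np.ndarray  # (n_cycles + 1, 9)
    cycle_cost: np.ndarray  # (n_cycles,)

    @property
    def n_cycles(self) -> int:
        return self.cycle_cost.shape[0]

    def alive(self) -> np.ndarray:
        return self.occupancy[:, _ALIVE].sum(axis=1)

    def to_frame(self):
        import pandas as pd

        frame = pd.DataFrame(self.occupancy, columns=list(STATE_NAMES))
        frame.insert(0, "age", self.start_age + np.arange(self.occupancy.shape[0]))
        frame["cycle_cost"] = np.append(self.cycle_cost, np.nan)
        return frame


@dataclass(frozen=True)
class StrategyResult:
    """Discounted lifetime outcomes of one strategy for one cohort."""

    strategy: str
    discounted_cost: float
    discounted_qalys: float
    discounted_lys: float
    lung_cancer_death_fraction: float
    country: str | None = None
    sex: str | None = None


class ProbabilityOverflowError(ValueError):
    """Combined per-cycle exit probability exceeded 1 in some state."""


def run_cohort(
    parameter_set: ParameterSet,
    strategy: str,
    life_table: LifeTable,
    fp_workup: str = "baseline",
    treatment_cost: str = "annual",
    min_alive: float = 1e-9,
) -> CohortTrace:
    """Propagate the cohort under one strategy until extinction or the horizon."""
    ps = parameter_set
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    if fp_workup not in ("baseline", "first", "every"):
        raise ValueError(f"fp_workup must be 'baseline', 'first' or 'every', got {fp_workup!r}")
    if treatment_cost not in ("annual", "once"):
        raise ValueError(f"treatment_cost must be 'annual' or 'once', got {treatment_cost!r}")
    annual_treat = treatment_cost == "annual"
    if life_table.min_age > ps.start_age or life_table.max_age < ps.max_age:
        raise ValueError(
            f"life table [{life_table.min_age}, {life_table.max_age}] does not cover "
            f"ages {ps.start_age}..{ps.max_age}"
        )
    screening = strategy in ("ldct", "cxr")
    det = stage_at_detection(strategy, ps).as_tuple()
    hazards = annual_cancer_mortality(ps.survival).as_tuple()
    treat = tuple(ps.costs.treatment(i) for i in (1, 2, 3, 4))
    cost_workup = ps.costs.cost_workup
    if screening:
        outcome = screen_outcome_probs(ps.accuracy(strategy))
        cost_test = ps.costs.cost_screen_ldct if strategy == "ldct" else ps.costs.cost_screen_cxr
        p_fp, p_tp = outcome.p_false_positive, outcome.p_true_positive
    inc_extra = 0.0
    if strategy == "ldct":
        # cumulative full-course risk spread over the scheduled annual screens
        inc_extra = radiogenic_incidence_increment(
            ps, ps.max_age - ps.start_age, strategy
        )
    mean_treat_det = sum(d * c for d, c in zip(det, treat))

    n_cycles_max = ps.max_age - ps.start_age + 1
    occ = np.zeros((n_cycles_max + 1, len(STATE_NAMES)))
    costs = np.zeros(n_cycles_max)

    h0 = 1.0  # cancer-free, no prior false-positive workup
    h1 = 0.0  # cancer-free, prior false-positive workup
    undiag = 0.0
    stage = [[0.0] * _CURE_YEARS for _ in range(4)]
    cured = 0.0
    dead_lc = 0.0
    dead_oc = 0.0

    def record(row: int) -> None:
        occ[row, 0] = h0 + h1
        occ[row, 1] = undiag
        for j in range(4):
            occ[row, 2 + j] = sum(stage[j])
        occ[row, 6] = cured
        occ[row, 7] = dead_lc
        occ[row, 8] = dead_oc

    record(0)
    n_cycles = n_cycles_max
    for t in range(n_cycles_max):
        age = ps.start_age + t
        qx = life_table.qx_at(age)
        cycle_cost = 0.0

        if screening:
            cycle_cost += (h0 + h1 + undiag) * cost_test
            fp0 = h0 * p_fp
            if fp_workup == "every":
                cycle_cost += (fp0 + h1 * p_fp) * cost_workup
            elif fp_workup == "first" or t == 0:
                cycle_cost += fp0 * cost_workup
            h0 -= fp0
            h1 += fp0
            tp = undiag * p_tp
            cycle_cost += tp * (cost_workup if annual_treat else cost_workup + mean_treat_det)
            undiag -= tp
            for j in range(4):
                stage[j][0] += tp * det[j]

        # incidence; symptomatic same-cycle diagnosis when not screening
        if screening:
            p_inc = ps.incidence + inc_extra
            new = (h0 + h1) * p_inc
            h0 *= 1.0 - p_inc
            h1 *= 1.0 - p_inc
            undiag += new
        else:
            new = (h0 + h1) * ps.incidence
            h0 *= 1.0 - ps.incidence
            h1 *= 1.0 - ps.incidence
            for j in range(4):
                stage[j][0] += new * det[j]
            if not annual_treat:
                cycle_cost += new * mean_treat_det

        if annual_treat:
            for j in range(4):
                cycle_cost += sum(stage[j]) * treat[j]

        # mortality: background qx everywhere, additive cancer hazard in stage
        # states; at the absorbing final age (qx = 1) the cancer hazard takes
        # its share and the remainder dies of other causes
        dead_oc += (h0 + h1 + undiag + cured) * qx
        h0 *= 1.0 - qx
        h1 *= 1.0 - qx
        undiag *= 1.0 - qx
        cured *= 1.0 - qx
        for j in range(4):
            d = hazards[j]
            if qx >= 1.0 - 1e-12:
                p_lc, p_oc = d, 1.0 - d
            else:
                if qx + d > 1.0:
                    raise ProbabilityOverflowError(
                        f"combined exit probability {qx + d:.4f} > 1 in state "
                        f"stage{j + 1} at cycle {t} (age {age})"
                    )
                p_lc, p_oc = d, qx
            keep = 1.0 - p_lc - p_oc
            row = stage[j]
            for dur in range(_CURE_YEARS):
                m = row[dur]
                if m > 0.0:
                    dead_lc += m * p_lc
                    dead_oc += m * p_oc
                    row[dur] = m * keep

        # cure clock: five completed post-diagnosis years -> cured
        for j in range(4):
            row = stage[j]
            cured += row[_CURE_YEARS - 1]
            for dur in range(_CURE_YEARS - 1, 0, -1):
                row[dur] = row[dur - 1]
            row[0] = 0.0

        costs[t] = cycle_cost
        record(t + 1)
        if 1.0 - dead_lc - dead_oc < min_alive:
            n_cycles = t + 1
            break

    return CohortTrace(
        strategy=strategy,
        start_age=ps.start_age,
        occupancy=occ[: n_cycles + 1].copy(),
        cycle_cost=costs[:n_cycles].copy(),
    )


def accrue_outcomes(trace: CohortTrace, parameter_set: ParameterSet) -> StrategyResult:
    """Discounted lifetime cost, QALYs and LYs from a cohort trace.

    State-membership payoffs use the trapezoidal half-cycle correction (half
    weight on the first and last trace rows); event costs are discounted at
    the cycle they occur.
    """
    ps = parameter_set
    u = ps.utilities
    util_vec = np.array(
        [u.u_healthy, u.u_healthy, u.u_stage1, u.u_stage2, u.u_stage3, u.u_stage4,
         u.u_cured, u.u_dead, u.u_dead]
    )
    n_rows = trace.occupancy.shape[0]
    t = np.arange(n_rows)
    disc = (1.0 + ps.discount_rate) ** (-t)
    weights = np.ones(n_rows)
    if n_rows > 1:
        weights[0] = weights[-1] = 0.5
    alive = trace.alive()
    qalys = float(np.sum(weights * disc * (trace.occupancy @ util_vec)))
    lys = float(np.sum(weights * disc * alive))
    cost = float(np.sum(disc[: trace.n_cycles] * trace.cycle_cost))
    return StrategyResult(
        strategy=trace.strategy,
        discounted_cost=cost,
        discounted_qalys=qalys,
        discounted_lys=lys,
        lung_cancer_death_fraction=float(trace.occupancy[-1, 7]),
        country=ps.country,
        sex=ps.sex,
    )


def run_strategy_set(
    parameter_set: ParameterSet,
    life_table: LifeTable,
    strategies: tuple[str, ...] = STRATEGIES,
    fp_workup: str = "baseline",
    treatment_cost: str = "annual",
) -> list[StrategyResult]:
    """Run every strategy on the same parameters and life table."""
    return [
        accrue_outcomes(
            run_cohort(
                parameter_set, s, life_table,
                fp_workup=fp_workup, treatment_cost=treatment_cost,
            ),
            parameter_set,
        )
        for s in strategies
    ]
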