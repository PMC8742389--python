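"""Independent individual-level microsimulation oracle.

Simulates each cohort member's trajectory with explicit random draws, using
the same event ordering and accrual conventions as the cohort engine but
none of its code: screening, incidence, additive mortality, the five-year
cure clock, trapezoidal half-cycle accrual of utilities, and event costs
discounted at the cycle they occur.  Used to cross-check the deterministic
cohort trace against Monte-Carlo estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from lungscreen.params import ParameterSet
from lungscreen.synthetic import LifeTable

# state codes
H0, H1, UNDIAG, S1, S2, S3, S4, CURED, DEAD_LC, DEAD_OC = range(10)
_STAGE_STATES = (S1, S2, S3, S4)


@dataclass
class MicrosimResult:
    cost_mean: float
    cost_se: float
    qaly_mean: float
    qaly_se: float
    ly_mean: float
    ly_se: float
    lc_death_fraction: float
    n: int


def simulate(
    ps: ParameterSet,
    strategy: str,
    life_table: LifeTable,
    n: int = 100_000,
    seed: int = 0,
    fp_workup: str = "baseline",
    treatment_cost: str = "annual",
) -> MicrosimResult:
    rng = np.random.default_rng(seed)
    screening = strategy in ("ldct", "cxr")
    det = np.cumsum(ps.detection(strategy).as_tuple())
    hazards = np.array([1.0 - s5 ** 0.2 if s5 > 0 else 1.0
                        for s5 in ps.survival.as_tuple()])
    treat = np.array([ps.costs.treatment(i) for i in (1, 2, 3, 4)])
    mean_treat = float(np.sum(np.diff(np.concatenate([[0.0], det])) * treat))
    annual_treat = treatment_cost == "annual"
    if screening:
        acc = ps.accuracy(strategy)
        p_tp, p_fp = acc.sensitivity, 1.0 - acc.specificity
        cost_test = (ps.costs.cost_screen_ldct if strategy == "ldct"
                     else ps.costs.cost_screen_cxr)
    inc_extra = (ps.radiogenic_risk_total / (ps.max_age - ps.start_age)
                 if strategy == "ldct" else 0.0)
    cost_workup = ps.costs.cost_workup

    state = np.full(n, H0, dtype=np.int8)
    dur = np.zeros(n, dtype=np.int8)
    cost = np.zeros(n)
    qaly = np.zeros(n)
    ly = np.zeros(n)
    util = np.array([1.0, 1.0, 1.0, ps.utilities.u_stage1, ps.utilities.u_stage2,
                     ps.utilities.u_stage3, ps.utilities.u_stage4,
                     ps.utilities.u_cured, 0.0, 0.0])
    alive_vec = np.array([1.0] * 8 + [0.0, 0.0])

    n_cycles = ps.max_age - ps.start_age + 1
    for t in range(n_cycles + 1):
        disc = (1.0 + ps.discount_rate) ** (-t)
        w = 0.5 if t in (0, n_cycles) else 1.0
        qaly += w * disc * util[state]
        ly += w * disc * alive_vec[state]
        if t == n_cycles:
            break
        qx = life_table.qx_at(ps.start_age + t)

        if screening:
            screened = (state == H0) | (state == H1) | (state == UNDIAG)
            cost[screened] += disc * cost_test
            u = rng.random(n)
            fp = (state == H0) & (u < p_fp)
            if fp_workup == "every":
                fp_pay = ((state == H0) | (state == H1)) & (u < p_fp)
            elif fp_workup == "first":
                fp_pay = fp
            else:  # baseline screen only
                fp_pay = fp if t == 0 else np.zeros(n, dtype=bool)
            cost[fp_pay] += disc * cost_workup
            state[fp] = H1
            tp = (state == UNDIAG) & (u < p_tp)
            cost[tp] += disc * (cost_workup if annual_treat
                                else cost_workup + mean_treat)
            stage_draw = np.searchsorted(det, rng.random(n))
            state[tp] = S1 + np.minimum(stage_draw[tp], 3)
            dur[tp] = 0

        u = rng.random(n)
        healthy = (state == H0) | (state == H1)
        if screening:
            incident = healthy & (u < ps.incidence + inc_extra)
            state[incident] = UNDIAG
        else:
            incident = healthy & (u < ps.incidence)
            stage_draw = np.searchsorted(det, rng.random(n))
            state[incident] = S1 + np.minimum(stage_draw[incident], 3)
            dur[incident] = 0
            if not annual_treat:
                cost[incident] += disc * mean_treat

        in_stage = (state >= S1) & (state <= S4)
        if annual_treat:
            cost[in_stage] += disc * treat[state[in_stage] - S1]

        u = rng.random(n)
        alive_nonstage = (state <= UNDIAG) | (state == CURED)
        state[alive_nonstage & (u < qx)] = DEAD_OC
        d = np.zeros(n)
        d[in_stage] = hazards[state[in_stage] - S1]
        if qx >= 1.0 - 1e-12:
            die_lc = in_stage & (u < d)
            die_oc = in_stage & ~die_lc
        else:
            die_lc = in_stage & (u < d)
            die_oc = in_stage & ~die_lc & (u < d + qx)
        state[die_lc] = DEAD_LC
        state[die_oc] = DEAD_OC

        in_stage = (state >= S1) & (state <= S4)
        dur[in_stage] += 1
        done = in_stage & (dur >= 5)
        state[done] = CURED

    return MicrosimResult(
        cost_mean=float(cost.mean()),
        cost_se=float(cost.std(ddof=1) / np.sqrt(n)),
        qaly_mean=float(qaly.mean()),
        qaly_se=float(qaly.std(ddof=1) / np.sqrt(n)),
        ly_mean=float(ly.mean()),
        ly_se=float(ly.std(ddof=1) / np.sqrt(n)),
        lc_death_fraction=float((state == DEAD_LC).mean()),
        n=n,
    )
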