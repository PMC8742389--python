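"""Cohort engine: conservation, limiting identities, accrual conventions,
monotonicity, and the overflow guard."""

import dataclasses

import numpy as np
import pytest

from lungscreen.engine import (
    CohortTrace,
    ProbabilityOverflowError,
    STATE_NAMES,
    accrue_outcomes,
    run_cohort,
    run_strategy_set,
)
from lungscreen.params import (
    apply_parameter,
    default_parameters,
    sensitivity_ranges,
)
from lungscreen.synthetic import LifeTable, default_life_table, sample_parameter_set

STRATEGIES = ("ldct", "cxr", "no_screening")


def _zero_disease(ps):
    return dataclasses.replace(ps, incidence=0.0, radiogenic_risk_total=0.0)


def test_trace_shape_and_conservation(params_jm, table_jm):
    for strategy in STRATEGIES:
        trace = run_cohort(params_jm, strategy, table_jm)
        assert trace.occupancy.shape[1] == len(STATE_NAMES)
        sums = trace.occupancy.sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)
        assert np.all(trace.occupancy >= -1e-15)
        dead = trace.occupancy[:, 7] + trace.occupancy[:, 8]
        assert np.all(np.diff(dead) >= -1e-12)


def test_conservation_on_sampled_parameter_sets(params_jm, table_jm):
    ranges = sensitivity_ranges(params_jm)
    for seed in range(100):
        ps = sample_parameter_set(params_jm, ranges, seed)
        for strategy in STRATEGIES:
            trace = run_cohort(ps, strategy, table_jm)
            assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)


def test_zero_incidence_confines_states(params_jm, table_jm):
    ps = _zero_disease(params_jm)
    for strategy in STRATEGIES:
        trace = run_cohort(ps, strategy, table_jm)
        occupied = trace.occupancy.max(axis=0) > 0
        names = {STATE_NAMES[i] for i in np.flatnonzero(occupied)}
        assert names == {"no_lung_cancer", "dead_other_cause"}


def test_zero_incidence_screening_traces_differ_only_in_cost(params_jm, table_jm):
    ps = _zero_disease(params_jm)
    ldct = run_cohort(ps, "ldct", table_jm)
    cxr = run_cohort(ps, "cxr", table_jm)
    assert np.allclose(ldct.occupancy, cxr.occupancy, atol=1e-12)
    assert ldct.cycle_cost[0] > cxr.cycle_cost[0]


def test_disease_free_strategies_equivalent_in_health(params_jm, table_jm):
    ps = _zero_disease(params_jm)
    results = run_strategy_set(ps, table_jm)
    qalys = {r.discounted_qalys for r in results}
    lys = {r.discounted_lys for r in results}
    assert max(qalys) - min(qalys) < 1e-9
    assert max(lys) - min(lys) < 1e-9
    assert all(r.lung_cancer_death_fraction == 0 for r in results)


def test_immediate_death_gives_half_cycle_lys(params_jm):
    qx = np.ones(41)
    table = LifeTable(np.arange(60, 101), qx)
    trace = run_cohort(params_jm, "no_screening", table)
    result = accrue_outcomes(trace, dataclasses.replace(params_jm, discount_rate=0.0))
    assert result.discounted_lys == pytest.approx(0.5, abs=1e-6)


def test_hand_computed_three_row_trace(params_jm):
    # occupancies 1, 0.5, 0 alive at utility 1, discounted at 3%:
    # LY = 0.5*1 + 0.5/1.03 + 0.5*0/1.03^2
    occ = np.zeros((3, len(STATE_NAMES)))
    occ[0, 0] = 1.0
    occ[1, 0] = 0.5
    occ[1, 8] = 0.5
    occ[2, 8] = 1.0
    trace = CohortTrace("no_screening", 60, occ, np.zeros(2))
    result = accrue_outcomes(trace, params_jm)
    assert result.discounted_lys == pytest.approx(0.9854368932038835, rel=1e-12)
    assert result.discounted_qalys == pytest.approx(result.discounted_lys)


def test_zero_discount_equals_undiscounted_sum(params_jm, table_jm):
    ps = dataclasses.replace(params_jm, discount_rate=0.0)
    trace = run_cohort(ps, "cxr", table_jm)
    result = accrue_outcomes(trace, ps)
    alive = trace.alive()
    w = np.ones(alive.size)
    w[0] = w[-1] = 0.5
    assert result.discounted_lys == pytest.approx(float((w * alive).sum()))
    assert result.discounted_cost == pytest.approx(float(trace.cycle_cost.sum()))


def test_unit_utilities_make_qalys_equal_lys(params_jm, table_jm):
    utilities = dataclasses.replace(
        params_jm.utilities, u_stage1=1.0, u_stage2=1.0, u_stage3=1.0,
        u_stage4=1.0, u_cured=1.0,
    )
    ps = dataclasses.replace(params_jm, utilities=utilities)
    for strategy in STRATEGIES:
        r = accrue_outcomes(run_cohort(ps, strategy, table_jm), ps)
        assert r.discounted_qalys == pytest.approx(r.discounted_lys, rel=1e-12)


def test_qalys_bounded_by_lys_and_horizon(cohort, all_cohorts):
    ps, table, _ = all_cohorts[f"{cohort[0]}_{cohort[1]}"]
    for r in run_strategy_set(ps, table):
        assert r.discounted_qalys <= r.discounted_lys + 1e-12
        assert r.discounted_lys <= ps.max_age - ps.start_age
        assert 0.0 <= r.lung_cancer_death_fraction <= 1.0
        assert r.discounted_cost >= 0.0


def test_qalys_monotone_in_incidence(params_jm, table_jm):
    qalys, deaths = [], []
    for inc in (0.0, 0.002, 0.009, 0.02):
        ps = apply_parameter(params_jm, "incidence", inc)
        r = accrue_outcomes(run_cohort(ps, "cxr", table_jm), ps)
        qalys.append(r.discounted_qalys)
        deaths.append(r.lung_cancer_death_fraction)
    assert all(a >= b for a, b in zip(qalys, qalys[1:]))
    assert all(a <= b for a, b in zip(deaths, deaths[1:]))


def test_ldct_sensitivity_effect_is_detection_timing_only(params_jm, table_jm):
    # without stage progression the stage mix at diagnosis does not depend on
    # when a cancer is found, so higher sensitivity only starts the morbidity
    # clock earlier: QALYs decrease very slightly and costs rise slightly.
    # The effect is bounded by the discounting of a one-to-two-cycle delay.
    qalys, costs = [], []
    for sens in (0.80, 0.906, 0.963, 1.0):
        ps = apply_parameter(params_jm, "sens_ldct", sens)
        r = accrue_outcomes(run_cohort(ps, "ldct", table_jm), ps)
        qalys.append(r.discounted_qalys)
        costs.append(r.discounted_cost)
    assert all(b <= a for a, b in zip(qalys, qalys[1:]))
    assert all(b >= a for a, b in zip(costs, costs[1:]))
    assert qalys[0] - qalys[-1] < 0.02


def test_detected_stage_mix_matches_detection_distribution(params_jm, table_jm):
    # with a perfect test, no cancer deaths (s5 = 1) and the five-year cure
    # clock, cumulative stage person-years are proportional to the detection
    # distribution
    ps = apply_parameter(params_jm, "sens_ldct", 1.0)
    survival = dataclasses.replace(
        ps.survival, s5_stage1=1.0, s5_stage2=1.0, s5_stage3=1.0, s5_stage4=1.0
    )
    ps = dataclasses.replace(ps, survival=survival, radiogenic_risk_total=0.0)
    trace = run_cohort(ps, "ldct", table_jm)
    stage_years = trace.occupancy[:, 2:6].sum(axis=0)
    shares = stage_years / stage_years.sum()
    assert shares == pytest.approx(np.array(ps.detection_ldct.as_tuple()), rel=1e-6)


def test_probability_overflow_identifies_cycle_and_state(params_jm):
    qx = np.full(41, 0.9)
    qx[-1] = 1.0
    table = LifeTable(np.arange(60, 101), qx)
    with pytest.raises(ProbabilityOverflowError, match=r"stage\d at cycle 0 \(age 60\)"):
        run_cohort(params_jm, "no_screening", table)


def test_treatment_cost_conventions_differ_only_in_cost(params_jm, table_jm):
    annual = accrue_outcomes(
        run_cohort(params_jm, "cxr", table_jm, treatment_cost="annual"), params_jm
    )
    once = accrue_outcomes(
        run_cohort(params_jm, "cxr", table_jm, treatment_cost="once"), params_jm
    )
    assert annual.discounted_qalys == pytest.approx(once.discounted_qalys, rel=1e-12)
    assert annual.discounted_cost != once.discounted_cost


def test_trace_export_frame(params_jm, table_jm):
    frame = run_cohort(params_jm, "ldct", table_jm).to_frame()
    assert list(frame.columns[1:-1]) == list(STATE_NAMES)
    assert frame["age"].iloc[0] == 60


def test_unknown_strategy_and_bad_fp_policy(params_jm, table_jm):
    with pytest.raises(ValueError, match="strategy"):
        run_cohort(params_jm, "mri", table_jm)
    with pytest.raises(ValueError, match="fp_workup"):
        run_cohort(params_jm, "ldct", table_jm, fp_workup="never")
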