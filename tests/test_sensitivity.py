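"""One-way/tornado analysis and the probabilistic sensitivity analysis."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lungscreen.params import ParamRange, get_parameter
from lungscreen.sensitivity import (
    CEACCurve,
    PSAResult,
    build_distributions,
    ceac,
    one_way,
    run_psa,
    tornado,
)


def test_zero_width_range_has_no_threshold(params_jm, table_jm):
    base = get_parameter(params_jm, "incidence")
    entry = one_way(params_jm, ParamRange("incidence", base, base), table_jm)
    assert entry.nmb_at_low == entry.nmb_at_high
    assert entry.optimal_at_low == entry.optimal_at_high
    assert entry.threshold is None


def test_unknown_parameter_rejected(params_jm, table_jm):
    with pytest.raises(Exception, match="unknown parameter"):
        one_way(params_jm, ParamRange("bogus", 0.0, 1.0), table_jm)


def test_incidence_threshold_below_japan_range(params_jm, table_jm):
    # extend the bracket below the published range: LDCT loses to CXR at
    # very low incidence and the crossing is located deterministically
    entry = one_way(params_jm, ParamRange("incidence", 0.0002, 0.03), table_jm)
    assert entry.optimal_at_low == "cxr"
    assert entry.optimal_at_high == "ldct"
    assert 0.0004 < entry.threshold < 0.0012


def test_threshold_invariant_to_bracket_widening(params_um, table_um):
    narrow = one_way(params_um, ParamRange("incidence", 0.00009, 0.000215), table_um)
    wide = one_way(params_um, ParamRange("incidence", 0.00005, 0.0004), table_um)
    assert narrow.threshold is not None
    assert wide.threshold == pytest.approx(narrow.threshold, rel=1e-3)


def test_tornado_sorting_and_duplicates(params_um, table_um):
    ranges = [
        ParamRange("incidence", 0.00009, 0.000215),
        ParamRange("cost_screen_ldct", 127.3, 509.2),
        ParamRange("cost_screen_ldct", 127.3, 509.2),
    ]
    entries = tornado(params_um, ranges, table_um)
    assert len(entries) == 3
    spans = [e.span for e in entries]
    assert spans == sorted(spans, reverse=True)
    dupes = [e for e in entries if e.parameter == "cost_screen_ldct"]
    assert dupes[0] == dupes[1]


def test_tornado_requires_ranges(params_jm, table_jm):
    with pytest.raises(ValueError):
        tornado(params_jm, [], table_jm)


def test_tornado_single_range(params_jm, table_jm):
    entries = tornado(params_jm, [ParamRange("u_cured", 0.7, 0.9)], table_jm)
    assert len(entries) == 1


# -- PSA ---------------------------------------------------------------------

def test_distribution_families(params_jm):
    from lungscreen.params import sensitivity_ranges

    spec = build_distributions(params_jm, sensitivity_ranges(params_jm))
    assert spec["incidence"][0] == "beta"
    assert spec["u_stage4"][0] == "beta"
    assert spec["cost_workup"][0] == "lognormal"
    # log-normal median equals the base value
    assert np.exp(spec["cost_workup"][1]) == pytest.approx(906.2)
    # beta mean equals the base value
    family, a, b = spec["incidence"]
    assert a / (a + b) == pytest.approx(0.009)


def test_degenerate_psa_returns_base(params_jm, table_jm):
    from lungscreen.engine import run_strategy_set
    from lungscreen.params import PARAMETER_NAMES

    ranges = [
        ParamRange(n, get_parameter(params_jm, n), get_parameter(params_jm, n))
        for n in PARAMETER_NAMES
    ]
    psa = run_psa(params_jm, ranges, table_jm, n_draws=1, seed=1)
    base = run_strategy_set(params_jm, table_jm)
    for j, r in enumerate(base):
        assert psa.costs[0, j] == pytest.approx(r.discounted_cost, rel=1e-9)
        assert psa.qalys[0, j] == pytest.approx(r.discounted_qalys, rel=1e-9)


def test_psa_bitwise_reproducible(params_um, table_um):
    from lungscreen.params import sensitivity_ranges

    ranges = sensitivity_ranges(params_um)
    a = run_psa(params_um, ranges, table_um, n_draws=50, seed=99)
    b = run_psa(params_um, ranges, table_um, n_draws=50, seed=99)
    assert np.array_equal(a.costs, b.costs)
    assert np.array_equal(a.qalys, b.qalys)
    c = run_psa(params_um, ranges, table_um, n_draws=50, seed=100)
    assert not np.array_equal(a.costs, c.costs)


def test_beta_draw_means_converge_to_base(params_jm):
    # sample means of beta-drawn parameters match the base values within
    # 3 standard errors at 10,000 draws
    from lungscreen.params import sensitivity_ranges

    spec = build_distributions(params_jm, sensitivity_ranges(params_jm))
    rng = np.random.default_rng(2)
    n = 10_000
    for name, (family, a, b) in spec.items():
        if family != "beta":
            continue
        draws = rng.beta(a, b, size=n)
        mean = a / (a + b)
        sd = np.sqrt(a * b / ((a + b) ** 2 * (a + b + 1)))
        assert abs(draws.mean() - mean) < 3 * sd / np.sqrt(n), name


def test_infeasible_beta_names_parameter(params_jm):
    with pytest.raises(ValueError, match="u_cured"):
        build_distributions(params_jm, [ParamRange("u_cured", 0.0, 3.5)])


def test_ceac_single_draw_is_indicator():
    psa = PSAResult(
        ("a", "b"), np.array([[10.0, 20.0]]), np.array([[1.0, 1.1]]), 0, {}
    )
    curve = ceac(psa, [0.0, 1_000.0])
    assert curve.prob_cost_effective[0].tolist() == [1.0, 0.0]  # cheapest at wtp 0
    assert curve.prob_cost_effective[1].tolist() == [0.0, 1.0]


def test_ceac_ties_split_equally():
    psa = PSAResult(
        ("a", "b"), np.array([[10.0, 10.0]]), np.array([[1.0, 1.0]]), 0, {}
    )
    curve = ceac(psa, [50_000.0])
    assert curve.prob_cost_effective[0].tolist() == [0.5, 0.5]


@settings(max_examples=100, deadline=None)
@given(
    costs=st.lists(
        st.lists(st.floats(0, 1e5), min_size=3, max_size=3), min_size=1, max_size=20
    ),
    qalys=st.lists(
        st.lists(st.floats(0, 30), min_size=3, max_size=3), min_size=1, max_size=20
    ),
    wtps=st.lists(st.floats(0, 3e5), min_size=1, max_size=5),
)
def test_ceac_rows_sum_to_one(costs, qalys, wtps):
    n = min(len(costs), len(qalys))
    psa = PSAResult(
        ("x", "y", "z"), np.array(costs[:n]), np.array(qalys[:n]), 0, {}
    )
    curve = ceac(psa, wtps)
    assert np.allclose(curve.prob_cost_effective.sum(axis=1), 1.0, atol=1e-12)
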