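"""One-way (tornado) and probabilistic sensitivity analysis.

One-way analysis re-evaluates the model at the endpoints of a parameter's
range with everything else held at base, records the optimal-strategy net
monetary benefit at both ends, and bisects for the threshold value where the
optimal strategy switches.

The PSA draws second-order parameter uncertainty: bounded quantities
(probabilities, accuracies, utilities, stage shares) from beta distributions
with mean equal to the base value and standard deviation (high - low)/3.92,
reading each one-way range as an approximate 95% central interval; costs
from log-normal distributions with median equal to the base value and
sigma = (ln high - ln low)/3.92.  Stage distributions are renormalized per
draw.  All strategies are evaluated on the same draw (common random
parameters), so incremental quantities propagate correlation correctly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .cea import optimal_strategy
from .engine import StrategyResult, run_strategy_set
from .params import (
    ParameterSet,
    ParamRange,
    StageDistribution,
    apply_parameter,
    get_parameter,
    parameter_kind,
)
from .synthetic import LifeTable

__all__ = [
    "TornadoEntry",
    "PSAResult",
    "CEACCurve",
    "one_way",
    "tornado",
    "run_psa",
    "ceac",
    "DEFAULT_PSA_SEED",
]

DEFAULT_PSA_SEED = 20220108


@dataclass(frozen=True)
class TornadoEntry:
    """One-way sensitivity result for a single parameter."""

    parameter: str
    low: float
    high: float
    nmb_at_low: float
    nmb_at_high: float
    optimal_at_low: str
    optimal_at_high: str
    threshold: float | None

    @property
    def span(self) -> float:
        return abs(self.nmb_at_high - self.nmb_at_low)


@dataclass(frozen=True)
class PSAResult:
    """Per-draw strategy outcomes from the second-order Monte Carlo."""

    strategies: tuple[str, ...]
    costs: np.ndarray  # (n_draws, n_strategies)
    qalys: np.ndarray  # (n_draws, n_strategies)
    seed: int
    distribution_spec: dict[str, tuple[str, float, float]]

    @property
    def n_draws(self) -> int:
        return self.costs.shape[0]


@dataclass(frozen=True)
class CEACCurve:
    """Probability each strategy is cost-effective across a WTP grid."""

    wtp_grid: np.ndarray
    strategies: tuple[str, ...]
    prob_cost_effective: np.ndarray  # (n_wtp, n_strategies)


def _evaluate(ps: ParameterSet, life_table: LifeTable, wtp: float):
    results = run_strategy_set(ps, life_table)
    best = optimal_strategy(results, wtp)
    nmb = max(wtp * r.discounted_qalys - r.discounted_cost for r in results)
    return best, nmb


def one_way(
    parameter_set: ParameterSet,
    param_range: ParamRange,
    life_table: LifeTable,
    wtp: float | None = None,
    rel_tol: float = 1e-6,
) -> TornadoEntry:
    """Evaluate the model at a range's endpoints and bisect for a threshold.

    The threshold is the parameter value at which the NMB-optimal strategy
    switches between the endpoint optima; bisection runs to ``rel_tol`` of
    the range width and is fully deterministic.
    """
    wtp = parameter_set.wtp if wtp is None else wtp
    get_parameter(parameter_set, param_range.name)  # raises on unknown name
    lo_ps = apply_parameter(parameter_set, param_range.name, param_range.low)
    hi_ps = apply_parameter(parameter_set, param_range.name, param_range.high)
    opt_lo, nmb_lo = _evaluate(lo_ps, life_table, wtp)
    opt_hi, nmb_hi = _evaluate(hi_ps, life_table, wtp)

    threshold = None
    if opt_lo != opt_hi and param_range.width > 0:
        a, b = param_range.low, param_range.high
        xtol = rel_tol * param_range.width
        while b - a > xtol:
            mid = 0.5 * (a + b)
            opt_mid, _ = _evaluate(
                apply_parameter(parameter_set, param_range.name, mid), life_table, wtp
            )
            if opt_mid == opt_lo:
                a = mid
            else:
                b = mid
        threshold = 0.5 * (a + b)

    return TornadoEntry(
        parameter=param_range.name,
        low=param_range.low,
        high=param_range.high,
        nmb_at_low=nmb_lo,
        nmb_at_high=nmb_hi,
        optimal_at_low=opt_lo,
        optimal_at_high=opt_hi,
        threshold=threshold,
    )


def tornado(
    parameter_set: ParameterSet,
    ranges: list[ParamRange],
    life_table: LifeTable,
    wtp: float | None = None,
) -> list[TornadoEntry]:
    """One-way analysis for every range, sorted by descending NMB span."""
    if not ranges:
        raise ValueError("tornado needs at least one parameter range")
    entries = [one_way(parameter_set, pr, life_table, wtp=wtp) for pr in ranges]
    return sorted(entries, key=lambda e: -e.span)


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis

def _beta_params(mean: float, sd: float, name: str) -> tuple[float, float]:
    if not (0.0 < mean < 1.0):
        raise ValueError(f"cannot fit beta for {name!r}: mean {mean} outside (0, 1)")
    var = sd * sd
    cap = mean * (1.0 - mean)
    if var >= cap:
        raise ValueError(f"cannot fit beta for {name!r}: variance {var} >= {cap}")
    nu = cap / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def build_distributions(
    base: ParameterSet, ranges: list[ParamRange]
) -> dict[str, tuple[str, float, float]]:
    """Per-parameter sampling family and hyperparameters for the PSA."""
    spec: dict[str, tuple[str, float, float]] = {}
    for pr in sorted(ranges, key=lambda r: r.name):
        value = get_parameter(base, pr.name)
        if pr.width == 0:
            spec[pr.name] = ("fixed", value, 0.0)
        elif parameter_kind(pr.name) == "cost":
            if value <= 0 or pr.low <= 0:
                raise ValueError(f"cannot fit log-normal for {pr.name!r}")
            sigma = (math.log(pr.high) - math.log(pr.low)) / 3.92
            spec[pr.name] = ("lognormal", math.log(value), sigma)
        else:
            sd = pr.width / 3.92
            alpha, beta = _beta_params(value, sd, pr.name)
            spec[pr.name] = ("beta", alpha, beta)
    return spec


def _draw_parameter_sets(
    base: ParameterSet,
    spec: dict[str, tuple[str, float, float]],
    n_draws: int,
    rng: np.random.Generator,
) -> list[ParameterSet]:
    draws: dict[str, np.ndarray] = {}
    for name in sorted(spec):
        family, a, b = spec[name]
        if family == "fixed":
            draws[name] = np.full(n_draws, a)
        elif family == "beta":
            draws[name] = rng.beta(a, b, size=n_draws)
        else:
            draws[name] = np.exp(rng.normal(a, b, size=n_draws))

    share_fields = {
        "p_noscreen": "detection_no_screening",
        "p_cxr": "detection_cxr",
        "p_ldct": "detection_ldct",
    }
    out = []
    for k in range(n_draws):
        ps = base
        for name in sorted(spec):
            if parameter_kind(name) == "share":
                continue
            ps = apply_parameter(ps, name, float(draws[name][k]))
        for prefix, fieldname in share_fields.items():
            current = getattr(ps, fieldname).as_tuple()
            raw = [
                float(draws[f"{prefix}_stage{i}"][k])
                if f"{prefix}_stage{i}" in draws
                else current[i - 1]
                for i in (1, 2, 3, 4)
            ]
            total = sum(raw)
            ps = replace(ps, **{fieldname: StageDistribution(*(p / total for p in raw))})
        out.append(ps)
    return out


def run_psa(
    parameter_set: ParameterSet,
    ranges: list[ParamRange],
    life_table: LifeTable,
    n_draws: int = 10_000,
    seed: int = DEFAULT_PSA_SEED,
) -> PSAResult:
    """Second-order Monte Carlo over the parameter distributions.

    Every draw passes parameter validation, and all strategies are run on the
    same drawn parameter set and life table.  Reproducible bit-for-bit for a
    fixed seed.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    spec = build_distributions(parameter_set, ranges)
    rng = np.random.default_rng(seed)
    strategies = ("ldct", "cxr", "no_screening")
    costs = np.empty((n_draws, len(strategies)))
    qalys = np.empty((n_draws, len(strategies)))
    for k, ps in enumerate(_draw_parameter_sets(parameter_set, spec, n_draws, rng)):
        for j, r in enumerate(run_strategy_set(ps, life_table, strategies=strategies)):
            costs[k, j] = r.discounted_cost
            qalys[k, j] = r.discounted_qalys
    return PSAResult(strategies, costs, qalys, seed, spec)


def ceac(psa: PSAResult, wtp_grid) -> CEACCurve:
    """Cost-effectiveness acceptability curves over a WTP grid.

    For each WTP, the fraction of draws in which each strategy attains the
    maximum NMB; exact ties split their draw equally, so the probabilities
    sum to 1 at every WTP.
    """
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    if psa.n_draws == 0:
        raise ValueError("PSA result has no draws")
    probs = np.empty((wtp_grid.size, len(psa.strategies)))
    for i, wtp in enumerate(wtp_grid):
        nmb = wtp * psa.qalys - psa.costs
        best = nmb.max(axis=1, keepdims=True)
        winners = nmb == best
        weights = winners / winners.sum(axis=1, keepdims=True)
        probs[i] = weights.mean(axis=0)
    return CEACCurve(wtp_grid, psa.strategies, probs)
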