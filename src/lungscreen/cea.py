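"""Incremental cost-effectiveness analysis: dominance frontier, ICERs, NMB.

Strategies are ordered by ascending cost.  A strategy is strictly dominated
if some alternative is at least as cheap and at least as effective (one
strictly); extended dominance removes frontier members whose ICER exceeds
the next ICER along the frontier, leaving strictly increasing ICERs.
Dominated strategies remain in the table, reported against the cheapest
frontier strategy, which mirrors the usual league-table presentation.
"""

from __future__ import annotations

from dataclasses import dataclass

from .engine import StrategyResult

__all__ = [
    "CEARow",
    "NMBResult",
    "incremental_analysis",
    "net_monetary_benefit",
    "optimal_strategy",
]

_EFFECTS = {"qaly": "discounted_qalys", "ly": "discounted_lys"}


@dataclass(frozen=True)
class CEARow:
    """One strategy's line in the incremental cost-effectiveness table."""

    strategy: str
    cost: float
    qalys: float
    lys: float
    status: str  # 'frontier', 'dominated', 'extended_dominated'
    comparator: str | None = None
    incr_cost: float | None = None
    incr_qalys: float | None = None
    incr_lys: float | None = None
    icer_qaly: float | None = None
    icer_ly: float | None = None


@dataclass(frozen=True)
class NMBResult:
    """Net monetary benefit of one strategy at a given willingness to pay."""

    strategy: str
    nmb: float


def _strictly_dominated(row: StrategyResult, others: list[StrategyResult], eff: str) -> bool:
    c, e = row.discounted_cost, getattr(row, eff)
    for other in others:
        if other is row:
            continue
        oc, oe = other.discounted_cost, getattr(other, eff)
        if oc <= c and oe >= e and (oc < c or oe > e):
            return True
    return False


def incremental_analysis(
    results: list[StrategyResult], effect: str = "qaly"
) -> list[CEARow]:
    """Build the incremental CEA table for two or more strategies.

    ICERs are computed between adjacent frontier strategies at full internal
    precision; exact cost-and-effect ties are both kept on the frontier with
    the ICER between them left undefined.
    """
    if effect not in _EFFECTS:
        raise ValueError(f"effect must be one of {sorted(_EFFECTS)}, got {effect!r}")
    if len(results) < 2:
        raise ValueError("incremental analysis needs at least two strategies")
    eff = _EFFECTS[effect]
    ordered = sorted(results, key=lambda r: (r.discounted_cost, getattr(r, eff), r.strategy))

    status = {
        r.strategy: ("dominated" if _strictly_dominated(r, ordered, eff) else "frontier")
        for r in ordered
    }
    # extended dominance: prune frontier members until ICERs strictly increase
    frontier = [r for r in ordered if status[r.strategy] == "frontier"]
    changed = True
    while changed and len(frontier) > 2:
        changed = False
        for i in range(1, len(frontier) - 1):
            lo, mid, hi = frontier[i - 1], frontier[i], frontier[i + 1]
            de_lo = getattr(mid, eff) - getattr(lo, eff)
            de_hi = getattr(hi, eff) - getattr(mid, eff)
            if de_lo <= 0 or de_hi <= 0:
                continue
            icer_lo = (mid.discounted_cost - lo.discounted_cost) / de_lo
            icer_hi = (hi.discounted_cost - mid.discounted_cost) / de_hi
            if icer_lo >= icer_hi:
                status[mid.strategy] = "extended_dominated"
                frontier.pop(i)
                changed = True
                break

    anchor = frontier[0]
    rows: list[CEARow] = []
    for r in ordered:
        st = status[r.strategy]
        if r is anchor:
            rows.append(
                CEARow(r.strategy, r.discounted_cost, r.discounted_qalys,
                       r.discounted_lys, st)
            )
            continue
        comparator = frontier[frontier.index(r) - 1] if st == "frontier" else anchor
        d_cost = r.discounted_cost - comparator.discounted_cost
        d_q = r.discounted_qalys - comparator.discounted_qalys
        d_l = r.discounted_lys - comparator.discounted_lys
        d_eff = d_q if effect == "qaly" else d_l
        icer_q = icer_l = None
        if st == "frontier" and d_eff > 0:
            icer_q = d_cost / d_q if d_q > 0 else None
            icer_l = d_cost / d_l if d_l > 0 else None
        rows.append(
            CEARow(r.strategy, r.discounted_cost, r.discounted_qalys, r.discounted_lys,
                   st, comparator.strategy, d_cost, d_q, d_l, icer_q, icer_l)
        )
    return rows


def net_monetary_benefit(results: list[StrategyResult], wtp: float) -> list[NMBResult]:
    """NMB = wtp * QALYs - cost for each strategy; the argmax is optimal."""
    if wtp < 0:
        raise ValueError(f"willingness to pay must be >= 0, got {wtp}")
    return [
        NMBResult(r.strategy, wtp * r.discounted_qalys - r.discounted_cost)
        for r in results
    ]


def optimal_strategy(results: list[StrategyResult], wtp: float) -> str:
    """Strategy with the highest NMB (stable tie-break on strategy name)."""
    nmb = net_monetary_benefit(results, wtp)
    best = max(nmb, key=lambda n: (n.nmb, n.strategy))
    return best.strategy
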