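"""Population-level lifetime impact and report rendering.

Scales per-person incremental outcomes to national cohorts of 60-year-old
never smokers, verifies the cohort-scaling arithmetic against published
reference values, and writes the tabular report files (CEA table, cohort
impact, tornado, CEAC, PSA draws).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
import yaml

from .cea import CEARow, incremental_analysis
from .engine import StrategyResult
from .sensitivity import CEACCurve, PSAResult, TornadoEntry

__all__ = [
    "Increment",
    "CohortImpact",
    "COHORT_SIZES",
    "per_person_increment",
    "scale_to_cohort",
    "verify_cohort_scaling",
    "render_reports",
    "round_half_away",
]

# National counts of 60-year-old never smokers used for lifetime scaling.
COHORT_SIZES: dict[str, int] = {
    "japan_male": 5_463_770,
    "japan_female": 7_588_028,
    "us_male": 14_904_704,
    "us_female": 16_977_059,
}


class Increment(NamedTuple):
    """Per-person incremental outcomes of strategy a over strategy b."""

    cost: float
    qalys: float
    lys: float
    death_fraction: float


@dataclass(frozen=True)
class CohortImpact:
    """Cumulative lifetime impact of a strategy over a comparator."""

    country: str
    sex: str
    comparator: str
    n_individuals: int
    cost_saving: float  # positive = money saved vs comparator
    qalys_gain: int
    lys_gain: int
    deaths_averted_fraction: float
    deaths_averted_n: int


def round_half_away(x: float) -> int:
    """Round to nearest integer, ties away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def per_person_increment(a: StrategyResult, b: StrategyResult) -> Increment:
    """Componentwise a - b at full internal precision; cohorts must match."""
    if (a.country, a.sex) != (b.country, b.sex) and None not in (
        a.country, b.country, a.sex, b.sex
    ):
        raise ValueError(
            f"mismatched cohorts: {a.country}/{a.sex} vs {b.country}/{b.sex}"
        )
    return Increment(
        cost=a.discounted_cost - b.discounted_cost,
        qalys=a.discounted_qalys - b.discounted_qalys,
        lys=a.discounted_lys - b.discounted_lys,
        death_fraction=a.lung_cancer_death_fraction - b.lung_cancer_death_fraction,
    )


def scale_to_cohort(
    increment: Increment,
    n_individuals: int,
    country: str = "",
    sex: str = "",
    comparator: str = "",
) -> CohortImpact:
    """Multiply per-person increments by cohort size.

    Person-valued and person-year-valued outputs are rounded to the nearest
    integer (half away from zero); money is kept at full precision with
    positive values denoting savings of the strategy over its comparator.
    """
    if n_individuals < 0:
        raise ValueError("n_individuals must be >= 0")
    return CohortImpact(
        country=country,
        sex=sex,
        comparator=comparator,
        n_individuals=n_individuals,
        cost_saving=-increment.cost * n_individuals,
        qalys_gain=round_half_away(increment.qalys * n_individuals),
        lys_gain=round_half_away(increment.lys * n_individuals),
        deaths_averted_fraction=-increment.death_fraction,
        deaths_averted_n=round_half_away(-increment.death_fraction * n_individuals),
    )


def _reference_outcomes() -> dict:
    ref = resources.files("lungscreen.data") / "reference_cohort_outcomes.yaml"
    return yaml.safe_load(ref.read_text())


def verify_cohort_scaling() -> pd.DataFrame:
    """Recompute the published cohort QALY/LY gains from per-person values.

    For each cohort, scales the reference per-person LDCT-vs-CXR increments
    by the national cohort size and compares round(n * delta) with the
    published cumulative gain.  Returns one row per cell with a match flag.
    """
    ref = _reference_outcomes()
    rows = []
    for cohort, vals in ref["cohorts"].items():
        n = int(vals["n_individuals"])
        for metric, delta_key, expected_key in (
            ("qalys_gain", "dqaly_vs_cxr", "expected_qalys_gain"),
            ("lys_gain", "dly_vs_cxr", "expected_lys_gain"),
        ):
            computed = round_half_away(float(vals[delta_key]) * n)
            expected = int(vals[expected_key])
            rows.append(
                {
                    "cohort": cohort,
                    "metric": metric,
                    "n_individuals": n,
                    "per_person_delta": float(vals[delta_key]),
                    "computed": computed,
                    "expected": expected,
                    "match": computed == expected,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# report rendering

def _cea_frame(rows: list[CEARow]) -> pd.DataFrame:
    out = []
    for r in rows:
        out.append(
            {
                "strategy": r.strategy,
                "cost_usd": round(r.cost),
                "qalys": round(r.qalys, 4),
                "lys": round(r.lys, 4),
                "status": r.status,
                "comparator": r.comparator or "",
                "incr_cost_usd": "" if r.incr_cost is None else round(r.incr_cost),
                "incr_qalys": "" if r.incr_qalys is None else round(r.incr_qalys, 4),
                "incr_lys": "" if r.incr_lys is None else round(r.incr_lys, 4),
                "icer_per_qaly": "" if r.icer_qaly is None else round(r.icer_qaly),
                "icer_per_ly": "" if r.icer_ly is None else round(r.icer_ly),
            }
        )
    return pd.DataFrame(out)


def render_reports(
    out_dir: str | Path,
    cohort: str,
    results: list[StrategyResult],
    impacts: list[CohortImpact] | None = None,
    tornado_entries: list[TornadoEntry] | None = None,
    ceac_curve: CEACCurve | None = None,
    psa: PSAResult | None = None,
    metadata: dict | None = None,
) -> list[Path]:
    """Write the report files for one cohort; returns the paths written.

    Deterministic for identical inputs: rerunning with the same seed and
    configuration produces byte-identical files.
    """
    if not results:
        raise ValueError("no strategy results to report")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, frame: pd.DataFrame) -> None:
        path = out_dir / name
        frame.to_csv(path, index=False)
        written.append(path)

    emit(f"{cohort}_cea_table.csv", _cea_frame(incremental_analysis(results)))

    base_frame = pd.DataFrame(
        [
            {
                "strategy": r.strategy,
                "cost_usd": round(r.discounted_cost, 2),
                "qalys": round(r.discounted_qalys, 4),
                "lys": round(r.discounted_lys, 4),
                "lung_cancer_death_pct": round(100 * r.lung_cancer_death_fraction, 1),
            }
            for r in results
        ]
    )
    emit(f"{cohort}_basecase.csv", base_frame)

    if impacts:
        emit(
            f"{cohort}_cohort_impact.csv",
            pd.DataFrame(
                [
                    {
                        "comparator": im.comparator,
                        "n_individuals": im.n_individuals,
                        "cost_saving_usd": round(im.cost_saving),
                        "qalys_gain": im.qalys_gain,
                        "lys_gain": im.lys_gain,
                        "deaths_averted_pct": round(100 * im.deaths_averted_fraction, 2),
                        "deaths_averted_n": im.deaths_averted_n,
                    }
                    for im in impacts
                ]
            ),
        )
    if tornado_entries:
        emit(
            f"{cohort}_tornado.csv",
            pd.DataFrame(
                [
                    {
                        "parameter": e.parameter,
                        "low": e.low,
                        "high": e.high,
                        "nmb_at_low_usd": round(e.nmb_at_low),
                        "nmb_at_high_usd": round(e.nmb_at_high),
                        "optimal_at_low": e.optimal_at_low,
                        "optimal_at_high": e.optimal_at_high,
                        "threshold": "" if e.threshold is None else e.threshold,
                        "nmb_span_usd": round(e.span),
                    }
                    for e in tornado_entries
                ]
            ),
        )
    if ceac_curve is not None:
        rows = []
        for i, wtp in enumerate(ceac_curve.wtp_grid):
            for j, s in enumerate(ceac_curve.strategies):
                rows.append(
                    {
                        "wtp_per_qaly": float(wtp),
                        "strategy": s,
                        "prob_cost_effective_pct": round(
                            100 * ceac_curve.prob_cost_effective[i, j], 1
                        ),
                    }
                )
        emit(f"{cohort}_ceac.csv", pd.DataFrame(rows))
    if psa is not None:
        n = psa.n_draws
        frame = pd.DataFrame(
            {
                "draw": np.repeat(np.arange(n), len(psa.strategies)),
                "strategy": list(psa.strategies) * n,
                "cost_usd": psa.costs.reshape(-1),
                "qalys": psa.qalys.reshape(-1),
            }
        )
        emit(f"{cohort}_psa_draws.csv", frame)

    meta = dict(metadata or {})
    meta.setdefault("cohort", cohort)
    if psa is not None:
        meta.setdefault("psa_seed", psa.seed)
        meta.setdefault("psa_draws", psa.n_draws)
    meta["config_hash"] = hashlib.sha256(
        json.dumps(meta, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    meta_path = out_dir / f"{cohort}_run_metadata.json"
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True, default=str) + "\n")
    written.append(meta_path)
    return written
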