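"""Clinical pathway primitives: test outcomes, stage at detection, hazards.

Converts the screening test accuracies into per-cycle outcome probabilities,
the stage-specific five-year survival proportions into annual cancer death
probabilities (constant-hazard annualization, exactly invertible), and the
cumulative radiogenic risk of repeated LDCT into a per-screen incidence
increment.
"""

from __future__ import annotations

from dataclasses import dataclass

from .params import ParameterSet, StageDistribution, StageSurvival, TestAccuracy

__all__ = [
    "ScreenCycleOutcome",
    "StageHazards",
    "screen_outcome_probs",
    "annual_cancer_mortality",
    "stage_at_detection",
    "radiogenic_incidence_increment",
]


@dataclass(frozen=True)
class ScreenCycleOutcome:
    """Per-cycle test outcome probabilities conditioned on cancer status."""

    p_true_positive: float
    p_false_negative: float
    p_false_positive: float
    p_true_negative: float


@dataclass(frozen=True)
class StageHazards:
    """Annual probability of dying of lung cancer, by stage at diagnosis.

    Applied (on top of background mortality) for the first five cycles after
    diagnosis; survivors of that window move to the cured state.
    """

    stage1: float
    stage2: float
    stage3: float
    stage4: float

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.stage1, self.stage2, self.stage3, self.stage4)


def screen_outcome_probs(accuracy: TestAccuracy) -> ScreenCycleOutcome:
    return ScreenCycleOutcome(
        p_true_positive=accuracy.sensitivity,
        p_false_negative=1.0 - accuracy.sensitivity,
        p_false_positive=1.0 - accuracy.specificity,
        p_true_negative=accuracy.specificity,
    )


def annual_cancer_mortality(survival: StageSurvival) -> StageHazards:
    """Annual cancer death probability d with (1 - d)^5 = five-year survival."""
    return StageHazards(*(1.0 - s5 ** 0.2 if s5 > 0 else 1.0 for s5 in survival.as_tuple()))


def stage_at_detection(strategy: str, parameter_set: ParameterSet) -> StageDistribution:
    """Stage distribution of diagnosed cancers for a detection route.

    The LDCT and CXR distributions are shared across countries (equal reader
    capability assumed); the symptomatic/no-screening distribution is
    country-specific.
    """
    return parameter_set.detection(strategy)


def radiogenic_incidence_increment(
    parameter_set: ParameterSet, expected_screens: int, strategy: str = "ldct"
) -> float:
    """Per-cycle lung-cancer incidence increment from LDCT radiation exposure.

    The cumulative excess risk is spread uniformly over the expected number of
    screens in a cancer-free lifetime; only the LDCT strategy irradiates.
    """
    if strategy != "ldct":
        return 0.0
    if expected_screens < 1:
        raise ValueError(f"expected_screens must be >= 1, got {expected_screens}")
    return parameter_set.radiogenic_risk_total / expected_screens
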