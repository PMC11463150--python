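"""Anthropometric indices, WHO weight-status classes and instrument scoring.

Covers body-mass index, waist-to-height ratio and the WHO adult weight
classes, plus scoring for three eating-behavior instruments:

* TFEQ-R18 (Three-Factor Eating Questionnaire, 18 items on a 1-4 Likert
  scale) with cognitive-restraint (CR), uncontrolled-eating (UE) and
  emotional-eating (EE) subscales, each scored as the mean item response;
* RVFQ (Food Reinforcement Value Questionnaire): 12 choices between a
  snack (press requirement escalating 20, 40, ..., 240) and a
  constant-cost fruit/vegetable alternative, summarised as the percent of
  snack choices and the breakpoint (highest press schedule accepted);
* YFAS (Yale Food Addiction Scale, first version) operating on seven
  pre-dichotomized symptom indicators plus a clinical-distress indicator;
  a food-addiction diagnosis requires both a symptom threshold (default 3)
  and distress.

No missing-item imputation is performed anywhere: incomplete instrument
responses are an error.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Sequence

__all__ = [
    "Sex",
    "WeightStatus",
    "AnthropometricRecord",
    "TFEQ_SUBSCALES",
    "RVFQ_N_ITEMS",
    "RVFQ_PRESS_STEP",
    "bmi",
    "waist_height_ratio",
    "classify_weight_status",
    "is_underweight",
    "score_tfeq",
    "score_rvfq",
    "score_yfas",
]


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"


class WeightStatus(str, enum.Enum):
    UNDERWEIGHT = "underweight"
    NORMAL = "normal"
    OVERWEIGHT = "overweight"
    OBESE = "obese"


@dataclass(frozen=True)
class AnthropometricRecord:
    weight: float        # kg
    height: float        # m
    waist: float         # cm
    body_fat: float      # percent
    age: float           # years
    sex: Sex

    def __post_init__(self) -> None:
        if self.weight <= 0 or self.height <= 0 or self.waist <= 0:
            raise ValueError("weight, height and waist must be positive")
        if not 0 <= self.body_fat <= 100:
            raise ValueError("body fat percentage outside [0, 100]")


def bmi(weight_kg: float, height_m: float) -> float:
    """Body-mass index, kg/m^2."""
    if height_m <= 0:
        raise ValueError("height must be positive")
    return weight_kg / height_m**2


def waist_height_ratio(waist_cm: float, height_m: float) -> float:
    """Waist circumference over height, both taken in centimetres."""
    if height_m <= 0:
        raise ValueError("height must be positive")
    return waist_cm / (height_m * 100.0)


def is_underweight(bmi_value: float) -> bool:
    return 0 < bmi_value < 18.5


def classify_weight_status(
    bmi_value: float, separate_underweight: bool = False
) -> WeightStatus:
    """WHO adult weight class from BMI.

    Half-open intervals: NORMAL below 25.0, OVERWEIGHT in [25.0, 30.0),
    OBESE at or above 30.0.  BMI below 18.5 is pooled with NORMAL unless
    ``separate_underweight`` is set (the underweight flag is still
    available through :func:`is_underweight`).
    """
    if bmi_value <= 0:
        raise ValueError("BMI must be positive")
    if bmi_value < 18.5 and separate_underweight:
        return WeightStatus.UNDERWEIGHT
    if bmi_value < 25.0:
        return WeightStatus.NORMAL
    if bmi_value < 30.0:
        return WeightStatus.OVERWEIGHT
    return WeightStatus.OBESE


#: TFEQ-R18 item -> subscale assignment (1-based item numbers)
TFEQ_SUBSCALES: dict[str, tuple[int, ...]] = {
    "cr": (2, 11, 12, 15, 16, 18),
    "ue": (1, 4, 5, 7, 8, 9, 13, 14, 17),
    "ee": (3, 6, 10),
}


def score_tfeq(
    responses: Sequence[float],
    subscales: Mapping[str, Sequence[int]] | None = None,
) -> dict[str, float]:
    """Mean-item subscale scores from the 18 TFEQ responses.

    ``responses`` is the full ordered item vector (item 1 first); each
    response must lie on the 1-4 scale.  A custom item->subscale map may
    be supplied; items must partition 1..len(responses).
    """
    if subscales is None:
        subscales = TFEQ_SUBSCALES
    n_items = len(responses)
    claimed = sorted(i for items in subscales.values() for i in items)
    if claimed != list(range(1, n_items + 1)):
        raise ValueError("subscale map must assign every item to exactly one subscale")
    for i, r in enumerate(responses, start=1):
        if r is None or not 1 <= r <= 4:
            raise ValueError(f"TFEQ item {i} response {r!r} outside the 1-4 scale")
    return {
        name: sum(responses[i - 1] for i in items) / len(items)
        for name, items in subscales.items()
    }


RVFQ_N_ITEMS = 12
RVFQ_PRESS_STEP = 20


def score_rvfq(snack_choices: Sequence[bool]) -> tuple[float, int]:
    """Percent snack choices and breakpoint from the 12 RVFQ items.

    ``snack_choices[k-1]`` is True when the snack was chosen at item *k*
    (press requirement 20*k; the fruit/vegetable alternative stays at 20).
    Returns ``(percent, breakpoint_presses)``; the breakpoint is 0 when
    the snack is never chosen.
    """
    if len(snack_choices) != RVFQ_N_ITEMS:
        raise ValueError(f"expected {RVFQ_N_ITEMS} choices, got {len(snack_choices)}")
    chosen = [bool(c) for c in snack_choices]
    percent = 100.0 * sum(chosen) / RVFQ_N_ITEMS
    breakpoint = 0
    for item, c in enumerate(chosen, start=1):
        if c:
            breakpoint = RVFQ_PRESS_STEP * item
    return percent, breakpoint


YFAS_N_SYMPTOMS = 7


def score_yfas(
    symptoms: Sequence[bool],
    clinical_distress: bool,
    diagnosis_min_symptoms: int = 3,
) -> tuple[int, bool]:
    """Symptom count and food-addiction diagnosis from YFAS indicators.

    The diagnosis requires at least ``diagnosis_min_symptoms`` of the
    seven dependence-style symptoms *and* clinically significant
    distress/impairment; symptom count alone never diagnoses.
    """
    if len(symptoms) != YFAS_N_SYMPTOMS:
        raise ValueError(f"expected {YFAS_N_SYMPTOMS} symptom indicators, got {len(symptoms)}")
    if any(s is None for s in symptoms) or clinical_distress is None:
        raise ValueError("missing YFAS indicator")
    count = sum(bool(s) for s in symptoms)
    diagnosis = count >= diagnosis_min_symptoms and bool(clinical_distress)
    return count, diagnosis
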