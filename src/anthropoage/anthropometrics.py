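"""Anthropometric quantities, benchmark body-shape indices, functional scores,
and cohort eligibility filtering.

BMI and waist-to-height ratio (WHtR) are the two measurements feeding the
biological-age models.  The Body Roundness Index (BRI), Weight-Adjusted Waist
Index (WWI) and A Body Shape Index (ABSI) are published body-shape indices
used as benchmark mortality predictors:

* BRI  (Thomas et al., Obesity 2013):
  ``364.2 - 365.5 * sqrt(1 - ((WC/(2*pi))**2 / (0.5*H)**2))`` with waist
  circumference WC and height H in metres.
* WWI  (Park et al., Sci Rep 2018): ``WC_cm / sqrt(weight_kg)``.
* ABSI (Krakauer & Krakauer, PLoS ONE 2012):
  ``WC_m / (BMI**(2/3) * H_m**(1/2))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AnthroMeasures",
    "FunctionalScores",
    "compute_bmi_whtr",
    "body_roundness_index",
    "weight_adjusted_waist_index",
    "a_body_shape_index",
    "score_functionality",
    "apply_eligibility",
    "ELIGIBILITY_BOUNDS",
]

# Plausibility ranges of the development cohort; rows outside them are
# excluded so the fitted models are never extrapolated.  All bounds inclusive.
ELIGIBILITY_BOUNDS = {
    "age": (50.0, 94.0),
    "height_cm": (125.0, 200.0),
    "weight_kg": (30.0, 150.0),
    "waist_cm": (50.0, 160.0),
    "bmi": (10.0, 60.0),
}


@dataclass(frozen=True)
class AnthroMeasures:
    """Height/weight/waist with the two derived quantities."""

    height_cm: float
    weight_kg: float
    waist_cm: float
    bmi: float
    whtr: float


@dataclass(frozen=True)
class FunctionalScores:
    """Deficit counts and self-rated-health / comorbidity summaries.

    ``adl`` counts difficulties among 5 activities of daily living,
    ``iadl`` among 4 instrumental activities; ``multimorbidity`` means two
    or more self-reported chronic conditions.
    """

    adl: int
    iadl: int
    poor_srh: bool
    comorbidity_count: int
    multimorbidity: bool


def _check_positive_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value) or value <= 0:
        raise ValueError(f"{name} must be positive and finite, got {value!r}")
    return value


def compute_bmi_whtr(height_cm: float, weight_kg: float, waist_cm: float) -> AnthroMeasures:
    """BMI (kg/m^2) and waist-to-height ratio from measured anthropometry.

    Raises ``ValueError`` naming the offending field for non-positive or
    non-finite inputs, and for values outside broad plausibility limits
    (e.g. height passed in metres instead of centimetres).
    """
    height_cm = _check_positive_finite("height_cm", height_cm)
    weight_kg = _check_positive_finite("weight_kg", weight_kg)
    waist_cm = _check_positive_finite("waist_cm", waist_cm)
    if not (50.0 <= height_cm <= 272.0):
        raise ValueError(
            f"height_cm={height_cm} outside plausible range 50-272 cm; "
            "check the unit (centimetres expected)"
        )
    bmi = weight_kg / (height_cm / 100.0) ** 2
    whtr = waist_cm / height_cm
    return AnthroMeasures(height_cm, weight_kg, waist_cm, bmi, whtr)


def body_roundness_index(waist_cm: float, height_cm: float) -> float:
    """Body Roundness Index from waist circumference and height (cm)."""
    waist_cm = _check_positive_finite("waist_cm", waist_cm)
    height_cm = _check_positive_finite("height_cm", height_cm)
    wc_m = waist_cm / 100.0
    h_m = height_cm / 100.0
    arg = 1.0 - (wc_m / (2.0 * math.pi)) ** 2 / (0.5 * h_m) ** 2
    if arg < 0:
        raise ValueError(
            "BRI undefined: waist/(2*pi) exceeds height/2 "
            f"(waist_cm={waist_cm}, height_cm={height_cm})"
        )
    return 364.2 - 365.5 * math.sqrt(arg)


def weight_adjusted_waist_index(waist_cm: float, weight_kg: float) -> float:
    """Weight-Adjusted Waist Index: waist (cm) / sqrt(weight (kg))."""
    waist_cm = _check_positive_finite("waist_cm", waist_cm)
    weight_kg = _check_positive_finite("weight_kg", weight_kg)
    return waist_cm / math.sqrt(weight_kg)


def a_body_shape_index(waist_cm: float, bmi: float, height_cm: float) -> float:
    """A Body Shape Index: WC_m / (BMI^(2/3) * H_m^(1/2))."""
    waist_cm = _check_positive_finite("waist_cm", waist_cm)
    bmi = _check_positive_finite("bmi", bmi)
    height_cm = _check_positive_finite("height_cm", height_cm)
    return (waist_cm / 100.0) / (bmi ** (2.0 / 3.0) * (height_cm / 100.0) ** 0.5)


def score_functionality(
    adl_items,
    iadl_items,
    srh_level: int,
    diagnoses,
    poor_srh_cut: str = "poor",
) -> FunctionalScores:
    """Deficit counts from item-level reports.

    Parameters
    ----------
    adl_items, iadl_items
        Exactly 5 and 4 booleans; True = any difficulty with the activity.
    srh_level
        Self-rated health, 1 (excellent) .. 5 (poor).
    diagnoses
        7 booleans for the self-reported chronic conditions (hypertension,
        diabetes, myocardial infarction, stroke, cancer, chronic lung
        disease, arthritis).
    poor_srh_cut
        "poor" flags level 5 only (default); "fair_or_poor" flags 4-5.
    """
    adl_items = list(adl_items)
    iadl_items = list(iadl_items)
    diagnoses = list(diagnoses)
    if len(adl_items) != 5:
        raise ValueError(f"adl_items must have exactly 5 entries, got {len(adl_items)}")
    if len(iadl_items) != 4:
        raise ValueError(f"iadl_items must have exactly 4 entries, got {len(iadl_items)}")
    if len(diagnoses) != 7:
        raise ValueError(f"diagnoses must have exactly 7 entries, got {len(diagnoses)}")
    srh_level = int(srh_level)
    if srh_level not in (1, 2, 3, 4, 5):
        raise ValueError(f"srh_level must be in 1..5, got {srh_level}")
    if poor_srh_cut not in ("poor", "fair_or_poor"):
        raise ValueError(f"unknown poor_srh_cut {poor_srh_cut!r}")
    n_comorb = sum(bool(d) for d in diagnoses)
    threshold = 5 if poor_srh_cut == "poor" else 4
    return FunctionalScores(
        adl=sum(bool(a) for a in adl_items),
        iadl=sum(bool(a) for a in iadl_items),
        poor_srh=srh_level >= threshold,
        comorbidity_count=n_comorb,
        multimorbidity=n_comorb >= 2,
    )


#: columns apply_eligibility requires in the panel
_REQUIRED_COLS = ("age", "height_cm", "weight_kg", "waist_cm", "time_years", "event")

def apply_eligibility(panel: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a panel into eligible rows and excluded rows with reason codes.

    A row is kept when age is within 50-94 years, height/weight/waist/BMI
    are within the plausibility bounds (all inclusive), and mortality
    follow-up and anthropometry are non-missing.  The excluded frame
    carries a ``drop_reason`` column with the first violated rule; the two
    frames partition the input.
    """
    missing = [c for c in _REQUIRED_COLS if c not in panel.columns]
    if missing:
        raise KeyError(f"panel is missing required column(s): {', '.join(missing)}")

    df = panel.copy()
    bmi = df["weight_kg"] / (df["height_cm"] / 100.0) ** 2

    def in_range(series, key):
        lo, hi = ELIGIBILITY_BOUNDS[key]
        return series.notna() & (series >= lo) & (series <= hi)

    reason = pd.Series(pd.NA, index=df.index, dtype="object")

    checks = [
        ("mortality_missing", df["time_years"].isna() | df["event"].isna()),
        (
            "anthro_missing",
            df["height_cm"].isna() | df["weight_kg"].isna() | df["waist_cm"].isna(),
        ),
        ("age_range", ~in_range(df["age"], "age")),
        ("height_range", ~in_range(df["height_cm"], "height_cm")),
        ("weight_range", ~in_range(df["weight_kg"], "weight_kg")),
        ("waist_range", ~in_range(df["waist_cm"], "waist_cm")),
        ("bmi_range", ~(bmi.notna() & bmi.between(*ELIGIBILITY_BOUNDS["bmi"]))),
    ]
    for code, violated in checks:
        hit = violated & reason.isna()
        reason[hit] = code

    kept = df[reason.isna()].copy()
    dropped = df[reason.notna()].copy()
    dropped["drop_reason"] = reason[reason.notna()]
    return kept, dropped
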