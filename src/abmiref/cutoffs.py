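"""Percentile cutoffs anchored at adult index values.

A cutoff is built by fixing an adult index value (17, 25 and 30 kg/m^p for
underweight, overweight and obesity) at an anchor age near the end of
growth, converting it to the standard-normal quantile z* it occupies there,
and tracing that same quantile across all ages.  Anchors follow the ends of
growth: 17, 18, 19 and 20 years for girls and 18, 19 and 20 years for boys
(girls stabilize stature and body mass earlier).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .lms import CentileCurve, centile_curve, z_score
from .reference import GrowthReference, lms_at

__all__ = [
    "CutoffSet",
    "ANCHOR_VALUES",
    "ANCHOR_AGES_MONTHS",
    "derive_cutoff",
    "derive_standard_cutoffs",
    "cutoffs_to_frame",
]

#: adult index values anchoring each nutritional-status label (kg/m^p)
ANCHOR_VALUES = {"underweight": 17.0, "overweight": 25.0, "obesity": 30.0}

#: anchor ages in months per sex (17 y only for girls)
ANCHOR_AGES_MONTHS = {"M": (216, 228, 240), "F": (204, 216, 228, 240)}

_LABEL_BY_VALUE = {v: k for k, v in ANCHOR_VALUES.items()}


@dataclass(frozen=True)
class CutoffSet:
    """One anchored cutoff: the quantile z*, its percentile, and the full curve."""

    label: str
    sex: str
    anchor_age_months: float
    anchor_value: float
    z_star: float
    percentile: float
    curve: CentileCurve


def derive_cutoff(
    ref: GrowthReference,
    sex: str,
    anchor_age_months: float,
    value: float,
    ages=None,
    label: str | None = None,
) -> CutoffSet:
    """Anchor ``value`` at ``anchor_age_months`` and trace its centile.

    z* = z_score(value, LMS(anchor age)); the returned curve evaluates that
    quantile over ``ages`` (default: the reference's 6-month grid) and
    passes through the anchor value at the anchor age by construction.
    """
    pt = lms_at(ref, sex, anchor_age_months)
    z_star = z_score(value, pt)
    if ages is None:
        ages = ref.ages(sex)
    curve = centile_curve(ref, sex, z_star, ages)
    if label is None:
        label = _LABEL_BY_VALUE.get(value, f"value_{value:g}")
    return CutoffSet(
        label=label,
        sex=sex,
        anchor_age_months=float(anchor_age_months),
        anchor_value=float(value),
        z_star=float(z_star),
        percentile=float(100.0 * norm.cdf(z_star)),
        curve=curve,
    )


def derive_standard_cutoffs(ref: GrowthReference) -> list[CutoffSet]:
    """All anchored cutoffs: {17, 25, 30} at each sex's anchor ages (21 sets)."""
    lo_m, hi_m = ref.domain("M")
    lo_f, hi_f = ref.domain("F")
    if hi_m < 240 or hi_f < 240 or lo_m > 204 or lo_f > 204:
        raise ValueError(
            "reference must cover 204-240 months to anchor adult cutoffs"
        )
    out = []
    for sex, anchor_ages in ANCHOR_AGES_MONTHS.items():
        for age in anchor_ages:
            for label, value in ANCHOR_VALUES.items():
                out.append(derive_cutoff(ref, sex, age, value, label=label))
    return out


def cutoffs_to_frame(cutoffs: list[CutoffSet]) -> pd.DataFrame:
    """Long-format table: one row per (cutoff set, age)."""
    rows = []
    for c in cutoffs:
        for a, v in zip(c.curve.ages, c.curve.values):
            rows.append(
                {
                    "sex": c.sex,
                    "label": c.label,
                    "anchor_age_months": c.anchor_age_months,
                    "anchor_value": c.anchor_value,
                    "z_star": c.z_star,
                    "percentile": c.percentile,
                    "age_months": a,
                    "curve_value": v,
                }
            )
    return pd.DataFrame(rows)
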