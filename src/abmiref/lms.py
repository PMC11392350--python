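"""Cole's LMS transformation: z-scores, inverse values, centile curves,
and comparison of growth references.

For a positive index value y at an age with parameters (L, M, S),

    z = ((y/M)**L - 1) / (L*S)      if L != 0
    z = ln(y/M) / S                 if L == 0,

with the L = 0 branch the analytic limit of the first.  The inverse maps a
standard-normal quantile back to the measurement scale,
y = M*(1 + L*S*z)**(1/L) (or M*exp(S*z)), and is exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .allometry import DomainError, compute_abmi, compute_bmi
from .reference import (
    AgeOutOfRangeError,
    ExponentSchedule,
    GrowthReference,
    LMSPoint,
    ReferenceValidationError,
    exponent_at,
    lms_at,
)

__all__ = [
    "CentileCurve",
    "z_score",
    "inverse_z",
    "centile_curve",
    "z_for_dataset",
    "compare_references",
]

_L_EPS = 1e-12  # |L| below this uses the log (L = 0) branch


@dataclass(frozen=True)
class CentileCurve:
    """Age trajectory of one standard-normal quantile of a reference."""

    reference: str
    sex: str
    z_level: float
    ages: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.ages) <= 0):
            raise ReferenceValidationError("centile curve ages must increase")
        if np.any(self.values <= 0):
            raise ReferenceValidationError("centile curve values must be positive")


def z_score(y: float, pt: LMSPoint) -> float:
    """LMS z-score of value ``y`` against one age's (L, M, S)."""
    if y <= 0:
        raise DomainError(f"index value must be positive, got {y}")
    if abs(pt.L) < _L_EPS:
        return float(np.log(y / pt.M) / pt.S)
    return float(((y / pt.M) ** pt.L - 1.0) / (pt.L * pt.S))


def inverse_z(z: float, pt: LMSPoint) -> float:
    """Measurement value at standard-normal quantile ``z``; exact inverse of
    :func:`z_score`."""
    if abs(pt.L) < _L_EPS:
        return float(pt.M * np.exp(pt.S * z))
    arg = 1.0 + pt.L * pt.S * z
    if arg <= 0:
        raise DomainError(
            f"z={z} outside the distribution's support at age {pt.age_months} "
            f"(1 + L*S*z = {arg:.4g} <= 0)"
        )
    return float(pt.M * arg ** (1.0 / pt.L))


def centile_curve(
    ref: GrowthReference, sex: str, z_level: float, ages
) -> CentileCurve:
    """Evaluate the centile at ``z_level`` over an age grid."""
    ages = np.asarray(ages, dtype=float)
    vals = np.empty_like(ages)
    for i, a in enumerate(ages):
        try:
            vals[i] = inverse_z(z_level, lms_at(ref, sex, a))
        except DomainError as e:
            raise DomainError(f"age {a} months: {e}") from None
    return CentileCurve(
        reference=ref.name, sex=sex, z_level=float(z_level), ages=ages, values=vals
    )


def _index_for_row(row, ref: GrowthReference, schedule: ExponentSchedule | None):
    h_m = row.height_cm / 100.0
    if ref.index_kind == "bmi":
        return compute_bmi(row.weight_kg, h_m)
    p = exponent_at(schedule, row.sex, row.age_months)
    return compute_abmi(row.weight_kg, h_m, p)


def z_for_dataset(
    records: pd.DataFrame,
    ref: GrowthReference,
    schedule: ExponentSchedule | None = None,
) -> pd.DataFrame:
    """Score every record against a reference.

    Returns the input frame with columns ``index_value``, ``z``,
    ``percentile`` and ``flag`` appended.  Records outside the reference's
    age domain are flagged ``out_of_domain`` (value/z set to NaN), never
    silently dropped.  An ABMI reference needs an exponent schedule, taken
    from the reference itself when not passed explicitly.
    """
    if ref.index_kind == "abmi":
        schedule = schedule or ref.exponents
        if schedule is None:
            raise ReferenceValidationError(
                "scoring against an abmi reference requires an exponent schedule"
            )
    out = records.copy()
    idx_vals = np.full(len(out), np.nan)
    zs = np.full(len(out), np.nan)
    flags = np.full(len(out), "ok", dtype=object)
    for i, row in enumerate(out.itertuples()):
        if not all(
            np.isfinite(v) for v in (row.weight_kg, row.height_cm, row.age_months)
        ):
            flags[i] = "missing"
            continue
        try:
            y = _index_for_row(row, ref, schedule)
            zs[i] = z_score(y, lms_at(ref, row.sex, row.age_months))
            idx_vals[i] = y
        except AgeOutOfRangeError:
            flags[i] = "out_of_domain"
    out["index_value"] = idx_vals
    out["z"] = zs
    out["percentile"] = 100.0 * norm.cdf(zs)
    out["flag"] = flags
    return out


def compare_references(
    refs: list[GrowthReference],
    base: GrowthReference,
    records: pd.DataFrame | None = None,
    schedules: dict | None = None,
    age_step: float = 6.0,
    age_bin_months: float = 12.0,
) -> pd.DataFrame:
    """Compare M/S/L curves (and optionally per-record z-scores) against a base.

    Curve comparison: every reference is evaluated on the 6-month grid of
    the overlapping age span; per age the table carries each reference's M,
    S, L and its difference from the base.  Record comparison (optional):
    each record is scored under each reference and under the base, and the
    per-record z difference is summarized by the median within age bins
    (column ``z_diff_median``).

    ``schedules`` may map reference name -> ExponentSchedule for ABMI
    references that do not carry one.
    """
    schedules = schedules or {}
    all_refs = [base] + [r for r in refs if r is not base]
    lo = max(r.domain(sex)[0] for r in all_refs for sex in ("M", "F"))
    hi = min(r.domain(sex)[1] for r in all_refs for sex in ("M", "F"))
    if lo > hi:
        raise ReferenceValidationError(
            f"references share no common age span (overlap [{lo}, {hi}])"
        )
    grid = np.arange(lo, hi + 0.5 * age_step, age_step)

    z_medians = {}
    if records is not None:
        base_sched = schedules.get(base.name, base.exponents)
        zb = z_for_dataset(records, base, base_sched)
        bins = (np.floor(zb["age_months"] / age_bin_months) * age_bin_months).astype(
            float
        )
        for r in all_refs:
            zr = z_for_dataset(records, r, schedules.get(r.name, r.exponents))
            diff = zr["z"] - zb["z"]
            ok = (zr["flag"] == "ok") & (zb["flag"] == "ok")
            grp = pd.Series(diff[ok]).groupby(bins[ok]).median()
            z_medians[r.name] = grp

    rows = []
    for sex in ("M", "F"):
        base_pts = {a: lms_at(base, sex, a) for a in grid}
        for r in all_refs:
            for a in grid:
                pt = lms_at(r, sex, a)
                bp = base_pts[a]
                row = {
                    "reference": r.name,
                    "sex": sex,
                    "age_months": a,
                    "M": pt.M,
                    "S": pt.S,
                    "L": pt.L,
                    "M_diff": pt.M - bp.M,
                    "S_diff": pt.S - bp.S,
                    "L_diff": pt.L - bp.L,
                }
                if r.name in z_medians:
                    b = np.floor(a / age_bin_months) * age_bin_months
                    row["z_diff_median"] = z_medians[r.name].get(b, np.nan)
                rows.append(row)
    return pd.DataFrame(rows)
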