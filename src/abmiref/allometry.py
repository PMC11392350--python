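"""Body-mass indices with allometric height exponents, and exponent estimation.

BMI divides body mass (kg) by squared height (m); the allometric index
(ABMI) generalizes the exponent to an age- and sex-specific power p chosen
so the index is uncorrelated with height during growth (Benn index).  The
exponent for one age/sex stratum is the slope of an ordinary least-squares
fit of log(weight) on log(height); per-age slopes are then smoothed over age
with a cubic regression spline before being tabulated on a 6-month grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.interpolate import BSpline

from .reference import ExponentSchedule, exponent_at

__all__ = [
    "AnthroRecord",
    "AllometricFit",
    "DomainError",
    "SingularFitError",
    "compute_bmi",
    "compute_abmi",
    "abmi_for_record",
    "records_to_frame",
    "frame_to_records",
    "estimate_exponent",
    "smooth_exponents",
]

ETHNICITIES = (
    "White",
    "Black",
    "AsianIndian",
    "NativePeruvian",
    "EastSoutheastAsian",
)

#: columns of the anthropometry CSV dialect
RECORD_COLUMNS = [
    "subject_id",
    "survey",
    "sweep",
    "sex",
    "age_months",
    "weight_kg",
    "height_cm",
    "ethnicity",
]


class DomainError(ValueError):
    """Non-positive or otherwise out-of-domain numeric input."""


class SingularFitError(ValueError):
    """Degenerate design in the allometric regression (no height variance)."""


@dataclass(frozen=True)
class AnthroRecord:
    """One measurement occasion of one subject."""

    subject_id: str
    survey: str
    sweep: int
    sex: str
    age_months: float
    weight_kg: float
    height_cm: float
    ethnicity: str

    def __post_init__(self) -> None:
        if not (1 < self.weight_kg < 300):
            raise DomainError(f"weight {self.weight_kg} kg outside (1, 300)")
        if not (40 < self.height_cm < 230):
            raise DomainError(f"height {self.height_cm} cm outside (40, 230)")
        if not np.isfinite(self.age_months):
            raise DomainError("age must be finite")


@dataclass(frozen=True)
class AllometricFit:
    """Log-log regression of weight on height for one age-sex stratum."""

    alpha: float
    beta: float
    n: int
    residual_sd: float


def compute_bmi(weight_kg: float, height_m: float) -> float:
    """Body mass index weight / height**2 (kg/m^2)."""
    return compute_abmi(weight_kg, height_m, 2.0)


def compute_abmi(weight_kg, height_m, p):
    """Allometric body mass index weight / height**p (kg/m^p).

    Accepts scalars or arrays; equals :func:`compute_bmi` when p = 2.
    """
    w = np.asarray(weight_kg, dtype=float)
    h = np.asarray(height_m, dtype=float)
    if np.any(w <= 0) or np.any(h <= 0):
        raise DomainError("weight and height must be positive")
    out = w / h ** np.asarray(p, dtype=float)
    return float(out) if out.ndim == 0 else out


def abmi_for_record(rec: AnthroRecord, schedule: ExponentSchedule) -> float:
    """ABMI of one record using the schedule's exponent for its sex and age."""
    p = exponent_at(schedule, rec.sex, rec.age_months)
    return compute_abmi(rec.weight_kg, rec.height_cm / 100.0, p)


def records_to_frame(records) -> pd.DataFrame:
    """List of :class:`AnthroRecord` -> DataFrame in the anthropometry dialect."""
    return pd.DataFrame([vars(r) for r in records], columns=RECORD_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[AnthroRecord]:
    return [
        AnthroRecord(
            subject_id=str(r.subject_id),
            survey=str(r.survey),
            sweep=int(r.sweep),
            sex=str(r.sex),
            age_months=float(r.age_months),
            weight_kg=float(r.weight_kg),
            height_cm=float(r.height_cm),
            ethnicity=str(r.ethnicity),
        )
        for r in df.itertuples()
    ]


def estimate_exponent(records) -> AllometricFit:
    """Allometric exponent for one age-sex stratum via log-log OLS.

    Weights and heights beyond +/-2 SD of the stratum's own mean are trimmed
    first (one pass); the slope of log(weight) on log(height) is the
    exponent.  Requires >= 3 records and non-degenerate heights after the
    trim.
    """
    if len(records) < 3:
        raise DomainError(f"need >= 3 records, got {len(records)}")
    w = np.asarray([r.weight_kg for r in records], dtype=float)
    h = np.asarray([r.height_cm for r in records], dtype=float)

    def _trim(x: np.ndarray) -> np.ndarray:
        sd = x.std(ddof=1)
        if sd == 0:
            return np.ones_like(x, dtype=bool)
        z = (x - x.mean()) / sd
        return np.abs(z) <= 2

    keep = _trim(w) & _trim(h)
    w, h = w[keep], h[keep]
    if len(w) < 3 or np.ptp(h) == 0:
        raise SingularFitError(
            "degenerate design: all heights equal (or too few records) after trim"
        )
    lw, lh = np.log(w), np.log(h / 100.0)
    X = sm.add_constant(lh)
    res = sm.OLS(lw, X).fit()
    resid_sd = float(np.sqrt(res.ssr / max(res.df_resid, 1)))
    return AllometricFit(
        alpha=float(res.params[0]),
        beta=float(res.params[1]),
        n=int(len(w)),
        residual_sd=resid_sd,
    )


def smooth_exponents(
    per_age_fits,
    n_knots: int = 5,
    grid_step: float = 6.0,
) -> ExponentSchedule:
    """Smooth per-age exponent estimates into a 6-month tabulated schedule.

    ``per_age_fits`` maps sex -> list of (age_months, beta).  A cubic
    regression spline with ``n_knots`` interior knots at age quantiles is
    least-squares fitted to the betas and evaluated on a regular
    ``grid_step`` grid spanning the input ages.  Beyond each sex's
    isometric age the exponent is clamped to 2 (growth has stabilized).
    """
    from .reference import ISOMETRIC_AGE

    by_sex = {}
    for sex, fits in per_age_fits.items():
        fits = sorted(fits)
        ages = np.asarray([a for a, _ in fits], dtype=float)
        betas = np.asarray([b for _, b in fits], dtype=float)
        if len(ages) < n_knots + 2:
            raise DomainError(
                f"need >= {n_knots + 2} age points for {n_knots} knots, got {len(ages)}"
            )
        interior = np.quantile(ages, np.linspace(0, 1, n_knots + 2)[1:-1])
        k = 3
        t = np.concatenate(
            [np.repeat(ages[0], k + 1), interior, np.repeat(ages[-1], k + 1)]
        )
        design = BSpline.design_matrix(ages, t, k).toarray()
        coef, *_ = np.linalg.lstsq(design, betas, rcond=None)
        spl = BSpline(t, coef, k)

        grid = np.arange(ages[0], ages[-1] + 0.5 * grid_step, grid_step)
        vals = spl(grid)
        iso = ISOMETRIC_AGE.get(sex)
        if iso is not None:
            vals = np.where(grid >= iso, 2.0, vals)
        by_sex[sex] = tuple((float(a), float(v)) for a, v in zip(grid, vals))
    return ExponentSchedule(by_sex=by_sex)
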