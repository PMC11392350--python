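"""Synthetic longitudinal multiethnic anthropometry with labelled contamination.

The generator emulates the structure the cleaning and fitting stages
assume: several surveys with fixed sweep schedules (ages jittered a few
months), five ethnic groups, subject-correlated index z-scores whose
marginals follow the reference's BCCG distribution, a plausible height
model, and optional injected errors (height decreases, implausible values,
missing fields, weight outliers) with per-record truth labels.

Latent z structure per subject: z_t = u + e_t with u ~ N(0, tau^2) a
subject level and e_t an AR(1) across sweeps with marginal SD sigma_e;
tau^2 + sigma_e^2 = 1 so the marginal z is standard normal and the
reference's S is the sole dispersion source.  The index value at each
occasion is the reference's inverse LMS transform of z; weight is
index * height_m**p with the schedule's exponent.

Clean heights are made non-decreasing within subject (running maximum after
occasion noise), so the height-decrease screen has a zero false-positive
rate on uncontaminated subjects by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cleaning import ScreeningReference
from .lms import inverse_z
from .reference import (
    ExponentSchedule,
    GrowthReference,
    LMSPoint,
    exponent_at,
    lms_at,
)

__all__ = [
    "SurveyPlan",
    "HeightModel",
    "CohortConfig",
    "generate_cohort",
    "inject_errors",
    "make_screening_reference",
    "DEFAULT_SURVEYS",
]

CATEGORIES = ("none", "height_decrease", "implausible", "missing", "weight_outlier")


@dataclass(frozen=True)
class SurveyPlan:
    """One survey: fixed sweep ages (months) with uniform integer jitter."""

    name: str
    sweep_ages: tuple
    jitter_months: int = 3


#: sweep schedules within the 60-240 month reference span, shaped after the
#: longitudinal surveys behind the packaged reference (follow-ups falling
#: outside the span are shifted or omitted)
DEFAULT_SURVEYS = (
    SurveyPlan("YL", (60, 96, 144, 180, 228)),
    SurveyPlan("MCS", (60, 84, 132, 168, 204)),
    SurveyPlan("ELANA_MS", (132, 144, 156, 168)),
    SurveyPlan("ELANA_HS", (180, 192, 204)),
    SurveyPlan("EPITeen", (156, 180, 204, 236)),
)


@dataclass(frozen=True)
class HeightModel:
    """Median height curve per sex plus between-subject variation.

    The median is a saturating-ramp curve
    ``h(a) = h_inf - rate * s * log(1 + exp((t1 - a)/s))``: linear growth of
    ``rate`` cm/month well before ``t1``, levelling to the adult height
    ``h_inf`` over a window of width ``s`` months.  Subjects carry a
    multiplicative offset with SD ``subject_sd``; occasions a small additive
    noise (heights are then made non-decreasing within subject).
    """

    params: dict = field(
        default_factory=lambda: {
            "M": {"h_inf": 177.0, "rate": 0.48, "t1": 200.0, "s": 12.0},
            "F": {"h_inf": 163.0, "rate": 0.48, "t1": 176.0, "s": 12.0},
        }
    )
    subject_sd: float = 0.04
    occasion_sd_cm: float = 0.1

    def median(self, sex: str, ages) -> np.ndarray:
        p = self.params[sex]
        a = np.asarray(ages, dtype=float)
        return p["h_inf"] - p["rate"] * p["s"] * np.log1p(
            np.exp((p["t1"] - a) / p["s"])
        )


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition settings of the generator."""

    surveys: tuple = DEFAULT_SURVEYS
    n_per_cell: int = 20  # subjects per (survey, sex, ethnicity)
    ethnicities: tuple = (
        "White", "Black", "AsianIndian", "NativePeruvian", "EastSoutheastAsian"
    )
    tau: float = np.sqrt(0.6)  # between-subject SD on the z scale
    rho: float = 0.3  # AR(1) correlation of occasion noise across sweeps
    sigma_e: float = np.sqrt(0.4)  # occasion-level z noise SD
    frac_height_decrease: float = 0.0  # fraction of subjects
    frac_implausible: float = 0.0  # fraction of records
    frac_missing: float = 0.0  # fraction of records
    frac_weight_outlier: float = 0.0  # fraction of records
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau < 0 or self.sigma_e < 0 or not (0 <= self.rho < 1):
            raise ValueError("need tau, sigma_e >= 0 and 0 <= rho < 1")
        if abs(self.tau**2 + self.sigma_e**2 - 1.0) > 1e-6:
            raise ValueError("tau^2 + sigma_e^2 must equal 1 (unit marginal z)")
        for f in (
            self.frac_height_decrease, self.frac_implausible,
            self.frac_missing, self.frac_weight_outlier,
        ):
            if not (0 <= f <= 0.2):
                raise ValueError("contamination fractions must lie in [0, 0.2]")


def make_screening_reference(
    ref: GrowthReference,
    height_model: HeightModel | None = None,
    step: float = 6.0,
) -> ScreeningReference:
    """Screening references consistent with the generator's data model.

    Height-for-age: normal (L=1) around the height model's median with CV
    equal to the subject SD.  BMI-for-age: the index reference mapped to
    the BMI scale (median index * median height^(p-2)) keeping the index's
    skewness, with the height contribution folded into S.
    """
    height_model = height_model or HeightModel()
    points_h, points_b = {}, {}
    for sex in ("M", "F"):
        lo, hi = ref.domain(sex)
        ages = np.arange(lo, hi + 0.5 * step, step)
        hmed = height_model.median(sex, ages)
        pts_h, pts_b = [], []
        for a, h in zip(ages, hmed):
            pt = lms_at(ref, sex, a)
            p = (
                exponent_at(ref.exponents, sex, a)
                if ref.index_kind == "abmi"
                else 2.0
            )
            s_b = float(np.hypot(pt.S, (p - 2.0) * height_model.subject_sd))
            pts_h.append(
                LMSPoint(age_months=float(a), L=1.0, M=float(h),
                         S=height_model.subject_sd)
            )
            pts_b.append(
                LMSPoint(age_months=float(a), L=pt.L,
                         M=float(pt.M * (h / 100.0) ** (p - 2.0)), S=s_b)
            )
        points_h[sex] = tuple(pts_h)
        points_b[sex] = tuple(pts_b)
    return ScreeningReference(
        height_ref=GrowthReference("screen_height", "bmi", points_h),
        bmi_ref=GrowthReference("screen_bmi", "bmi", points_b),
    )


def _clean_cohort(config, ref, schedule, height_model, rng):
    rows = []
    for survey in config.surveys:
        k = len(survey.sweep_ages)
        for sex in ("M", "F"):
            for eth in config.ethnicities:
                for i in range(config.n_per_cell):
                    sid = f"{survey.name}-{sex}-{eth}-{i:04d}"
                    u = rng.normal(0.0, config.tau)
                    e = np.empty(k)
                    e[0] = rng.normal(0.0, config.sigma_e)
                    for t in range(1, k):
                        e[t] = config.rho * e[t - 1] + rng.normal(
                            0.0, config.sigma_e * np.sqrt(1 - config.rho**2)
                        )
                    z = np.clip(u + e, -5.0, 5.0)
                    jit = rng.integers(
                        -survey.jitter_months, survey.jitter_months + 1, size=k
                    )
                    lo, hi = ref.domain(sex)
                    ages = np.clip(np.asarray(survey.sweep_ages) + jit, lo, hi)
                    ages = np.maximum.accumulate(ages)  # keep within-subject order
                    u_h = rng.normal(0.0, 1.0)
                    h = height_model.median(sex, ages) * (
                        1.0 + height_model.subject_sd * u_h
                    )
                    h = h + rng.normal(0.0, height_model.occasion_sd_cm, size=k)
                    h = np.maximum.accumulate(h)  # stature does not shrink
                    for t in range(k):
                        a = float(ages[t])
                        pt = lms_at(ref, sex, a)
                        idx = inverse_z(float(z[t]), pt)
                        p = (
                            exponent_at(schedule, sex, a)
                            if schedule is not None
                            else 2.0
                        )
                        w = idx * (h[t] / 100.0) ** p
                        rows.append(
                            (sid, survey.name, t + 1, sex, a, w, float(h[t]),
                             eth, float(z[t]))
                        )
    df = pd.DataFrame(
        rows,
        columns=[
            "subject_id", "survey", "sweep", "sex", "age_months",
            "weight_kg", "height_cm", "ethnicity", "latent_z",
        ],
    )
    latent = df.pop("latent_z")
    labels = pd.DataFrame(
        {"category": np.repeat("none", len(df)), "latent_z": latent},
        index=df.index,
    )
    return df, labels


def inject_errors(
    df: pd.DataFrame,
    labels: pd.DataFrame,
    config: CohortConfig,
    screening: ScreeningReference,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Inject labelled contamination; categories are mutually exclusive.

    height_decrease (per subject): one non-first sweep's height set 0.5-3 cm
    below the previous sweep's.  implausible (per record): weight reset so
    BMI sits at z = -8 of the screening BMI reference (the BCCG upper tail
    has no z = +8 support at the reference's skewness).  missing: one core
    field blanked.  weight_outlier: weight moved to its stratum's mean
    +/- 3 internal SD.
    """
    df = df.copy()
    labels = labels.copy()
    n = len(df)
    subjects = df["subject_id"].unique()
    total_frac = (
        config.frac_implausible + config.frac_missing + config.frac_weight_outlier
    )
    if total_frac + config.frac_height_decrease > 0.5:
        raise ValueError("contamination fractions too high to stay exclusive")

    # subject-level: height decreases
    n_hd = int(round(config.frac_height_decrease * len(subjects)))
    hd_subjects = rng.choice(subjects, size=n_hd, replace=False) if n_hd else []
    for sid in hd_subjects:
        idx = df.index[df["subject_id"] == sid]
        if len(idx) < 2:
            continue
        pos = rng.integers(1, len(idx))
        prev_h = df.loc[idx[pos - 1], "height_cm"]
        df.loc[idx[pos], "height_cm"] = prev_h - rng.uniform(0.5, 3.0)
        labels.loc[idx, "category"] = "height_decrease"

    # record-level categories on untouched records
    free = labels.index[labels["category"] == "none"].to_numpy()
    rng.shuffle(free)
    n_imp = int(round(config.frac_implausible * n))
    n_miss = int(round(config.frac_missing * n))
    n_wout = int(round(config.frac_weight_outlier * n))
    imp_idx = free[:n_imp]
    miss_idx = free[n_imp : n_imp + n_miss]
    wout_idx = free[n_imp + n_miss : n_imp + n_miss + n_wout]

    for i in imp_idx:
        row = df.loc[i]
        pt = lms_at(screening.bmi_ref, row["sex"], row["age_months"])
        bmi = inverse_z(-8.0, pt)
        df.loc[i, "weight_kg"] = bmi * (row["height_cm"] / 100.0) ** 2
        labels.loc[i, "category"] = "implausible"

    miss_fields = rng.choice(
        ["weight_kg", "height_cm", "ethnicity"], size=len(miss_idx)
    )
    for i, f in zip(miss_idx, miss_fields):
        df.loc[i, f] = np.nan
        labels.loc[i, "category"] = "missing"

    if len(wout_idx):
        bins = np.floor(df["age_months"] / 6.0) * 6.0
        strata = df.groupby([df["sex"], bins])["weight_kg"]
        mean = strata.transform("mean")
        sd = strata.transform("std")
        signs = rng.choice([-1.0, 1.0], size=len(wout_idx))
        for i, s in zip(wout_idx, signs):
            if not np.isfinite(sd.loc[i]) or sd.loc[i] == 0:
                continue
            df.loc[i, "weight_kg"] = mean.loc[i] + s * 3.0 * sd.loc[i]
            labels.loc[i, "category"] = "weight_outlier"

    return df, labels


def generate_cohort(
    config: CohortConfig | None = None,
    ref: GrowthReference | None = None,
    schedule: ExponentSchedule | None = None,
    height_model: HeightModel | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, ScreeningReference]:
    """Generate a cohort; returns (records, truth labels, screening reference).

    Fully reproducible from ``config.seed``.  ``ref`` defaults to the
    packaged ABMI reference (whose exponent schedule is used unless one is
    passed).  Sweep ages outside the reference domain are clipped into it.
    """
    from .reference import load_packaged_reference

    config = config or CohortConfig()
    ref = ref or load_packaged_reference()
    if schedule is None:
        schedule = ref.exponents if ref.index_kind == "abmi" else None
    height_model = height_model or HeightModel()
    rng = np.random.default_rng(config.seed)
    df, labels = _clean_cohort(config, ref, schedule, height_model, rng)
    screening = make_screening_reference(ref, height_model)
    if (
        config.frac_height_decrease or config.frac_implausible
        or config.frac_missing or config.frac_weight_outlier
    ):
        df, labels = inject_errors(df, labels, config, screening, rng)
    return df, labels, screening
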