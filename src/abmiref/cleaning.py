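"""Ordered exclusion cascade for longitudinal anthropometry.

Stages, applied in order, each producing an accounting entry:

1. eligibility — subjects must belong to one of the five ethnic categories
   and have been assessed in at least their survey's minimum number of
   sweeps (3 for the ELANA high-school cohort, 4 elsewhere);
2. missing — records lacking weight, height, age, sex or ethnicity are
   dropped, then subjects falling below their sweep minimum;
3. measurement errors — subjects whose height decreases by >= 0.5 cm
   between any two occasions are removed entirely;
4. implausible values — subjects with any height-for-age z beyond +/-6 or
   BMI-for-age z beyond +/-5 under a screening reference are removed;
5. sparse ages — all records at (sex-pooled) age-months with fewer than 10
   observations are dropped;
6. population-level weight outliers — records beyond +/-2 internal SD of
   weight within (sex, 6-month age bin) strata;
7. individual-level BMI outliers — records whose BMI deviates more than 2
   residual SDs from the subject-specific prediction of a linear
   mixed-effects growth model.

Boundary semantics follow the rules' wording: "below -X or above +X" is
strictly beyond, the 0.5 cm height decrease is inclusive.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .allometry import ETHNICITIES
from .lms import z_score
from .reference import AgeOutOfRangeError, GrowthReference, lms_at

__all__ = [
    "CleaningConfig",
    "CleaningReport",
    "StageEntry",
    "ScreeningReference",
    "PipelineError",
    "filter_eligibility",
    "filter_missing",
    "flag_height_decrease",
    "flag_implausible",
    "filter_sparse_ages",
    "flag_population_weight_outliers",
    "flag_individual_bmi_outliers",
    "run_pipeline",
]

log = logging.getLogger("abmiref.cleaning")

_CORE_FIELDS = ["weight_kg", "height_cm", "age_months", "sex", "ethnicity"]


class PipelineError(RuntimeError):
    """A cleaning stage failed."""


@dataclass(frozen=True)
class CleaningConfig:
    """Thresholds of the exclusion cascade (defaults are the published rules)."""

    min_sweeps_default: int = 4
    min_sweeps_by_survey: dict = field(default_factory=lambda: {"ELANA_HS": 3})
    height_decrease_cm: float = 0.5
    haz_limits: float = 6.0
    bmiz_limits: float = 5.0
    min_obs_per_age_month: int = 10
    weight_z_limits: float = 2.0
    individual_bmi_sd_limits: float = 2.0

    def __post_init__(self) -> None:
        for name in (
            "height_decrease_cm", "haz_limits", "bmiz_limits",
            "weight_z_limits", "individual_bmi_sd_limits",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def min_sweeps(self, survey: str) -> int:
        return self.min_sweeps_by_survey.get(survey, self.min_sweeps_default)


@dataclass(frozen=True)
class ScreeningReference:
    """References used only to screen implausible values (not for scoring)."""

    height_ref: GrowthReference
    bmi_ref: GrowthReference


@dataclass
class StageEntry:
    stage: str
    subjects_removed: int
    observations_removed: int
    subjects_remaining: int
    observations_remaining: int


@dataclass
class CleaningReport:
    """Ordered per-stage accounting; counts are conserved across stages."""

    input_subjects: int
    input_observations: int
    stages: list = field(default_factory=list)

    def add(self, stage: str, before: pd.DataFrame, after: pd.DataFrame) -> None:
        e = StageEntry(
            stage=stage,
            subjects_removed=before["subject_id"].nunique()
            - after["subject_id"].nunique(),
            observations_removed=len(before) - len(after),
            subjects_remaining=after["subject_id"].nunique(),
            observations_remaining=len(after),
        )
        log.info(
            "stage %-22s removed %6d obs / %5d subjects (remaining: %6d obs, %5d subjects)",
            e.stage, e.observations_removed, e.subjects_removed,
            e.observations_remaining, e.subjects_remaining,
        )
        self.stages.append(e)

    def to_dict(self) -> dict:
        return {
            "input_subjects": self.input_subjects,
            "input_observations": self.input_observations,
            "stages": [asdict(s) for s in self.stages],
        }


def _drop_short_subjects(df: pd.DataFrame, config: CleaningConfig) -> pd.DataFrame:
    counts = df.groupby(["subject_id", "survey"])["sweep"].nunique().reset_index()
    counts["min_req"] = counts["survey"].map(config.min_sweeps)
    ok = counts.loc[counts["sweep"] >= counts["min_req"], "subject_id"]
    return df[df["subject_id"].isin(set(ok))]


def filter_eligibility(df: pd.DataFrame, config: CleaningConfig) -> pd.DataFrame:
    """Keep subjects in the five ethnic categories with enough assessed sweeps."""
    if df.empty:
        return df
    # a recorded ethnicity outside the five categories is ineligible; a
    # missing one is handled by the missing-data stage
    eth_ok = df.groupby("subject_id")["ethnicity"].agg(
        lambda s: s.dropna().isin(ETHNICITIES).all()
    )
    df = df[df["subject_id"].map(eth_ok)]
    return _drop_short_subjects(df, config)


def filter_missing(df: pd.DataFrame, config: CleaningConfig) -> pd.DataFrame:
    """Drop records with missing anthropometry/demographics, then subjects
    falling below their sweep minimum."""
    if df.empty:
        return df
    complete = df.dropna(subset=_CORE_FIELDS)
    return _drop_short_subjects(complete, config)


def flag_height_decrease(
    df: pd.DataFrame, threshold_cm: float = 0.5
) -> set[str]:
    """Subjects whose height drops by >= threshold between any two occasions.

    Any later measurement lower than any earlier one by at least the
    threshold flags the subject (inclusive boundary).  Duplicate ages
    within a subject are a validation error.
    """
    dup = df.duplicated(subset=["subject_id", "age_months"], keep=False)
    if dup.any():
        offenders = (
            df.loc[dup, ["subject_id", "age_months"]]
            .drop_duplicates()
            .to_records(index=False)
            .tolist()
        )
        raise PipelineError(f"duplicate ages within subject: {offenders[:10]}")
    flagged = set()
    for sid, grp in df.sort_values("age_months").groupby("subject_id"):
        h = grp["height_cm"].to_numpy(dtype=float)
        running_max = np.maximum.accumulate(h)
        if np.any(running_max[:-1] - h[1:] >= threshold_cm - 1e-12):
            flagged.add(sid)
    return flagged


def flag_implausible(
    df: pd.DataFrame, screening: ScreeningReference,
    haz_limits: float = 6.0, bmiz_limits: float = 5.0,
) -> set[str]:
    """Subjects with height-for-age z strictly beyond +/-haz_limits or
    BMI-for-age z strictly beyond +/-bmiz_limits under the screening
    reference.  Ages not covered by the screening reference are an error."""
    flagged = set()
    for row in df.itertuples():
        try:
            haz = z_score(
                row.height_cm,
                lms_at(screening.height_ref, row.sex, row.age_months),
            )
            bmi = row.weight_kg / (row.height_cm / 100.0) ** 2
            bmiz = z_score(
                bmi, lms_at(screening.bmi_ref, row.sex, row.age_months)
            )
        except AgeOutOfRangeError as e:
            raise PipelineError(
                f"screening reference does not cover record age: {e}"
            ) from None
        if abs(haz) > haz_limits or abs(bmiz) > bmiz_limits:
            flagged.add(row.subject_id)
    return flagged


def filter_sparse_ages(df: pd.DataFrame, min_obs: int = 10) -> pd.DataFrame:
    """Drop all records at (sex-pooled) integer age-months with < min_obs
    observations."""
    if df.empty:
        return df
    month = np.floor(df["age_months"].to_numpy(dtype=float)).astype(int)
    counts = pd.Series(month).value_counts()
    keep_months = set(counts[counts >= min_obs].index)
    return df[pd.Series(month, index=df.index).isin(keep_months)]


def flag_population_weight_outliers(
    df: pd.DataFrame, z_limits: float = 2.0, bin_months: float = 6.0
) -> pd.Index:
    """Record index of weights strictly beyond +/-z_limits internal SD within
    (sex, 6-month age bin) strata.  Degenerate strata are skipped with a
    warning."""
    flagged = []
    bins = np.floor(df["age_months"] / bin_months) * bin_months
    for (sex, b), grp in df.groupby([df["sex"], bins]):
        w = grp["weight_kg"].to_numpy(dtype=float)
        if len(w) < 2 or w.std(ddof=1) == 0:
            warnings.warn(
                f"weight stratum (sex={sex}, bin={b}) degenerate; skipped"
            )
            continue
        z = (w - w.mean()) / w.std(ddof=1)
        flagged.extend(grp.index[np.abs(z) > z_limits])
    return pd.Index(flagged)


def flag_individual_bmi_outliers(
    df: pd.DataFrame, sd_limits: float = 2.0
) -> pd.Index:
    """Record index of BMI values deviating > sd_limits residual SDs from the
    subject-specific prediction of a linear mixed-effects growth model.

    Fixed effects: sex-specific cubic polynomial in age; random effects:
    per-subject intercept and slope in age.  Subjects with a single
    observation are scored against the population-level prediction.
    """
    d = df.copy()
    d["bmi"] = d["weight_kg"] / (d["height_cm"] / 100.0) ** 2
    if np.ptp(d["bmi"].to_numpy()) == 0:
        warnings.warn("all BMI values identical; zero residual SD, nothing flagged")
        return pd.Index([])
    d["a"] = (d["age_months"] - d["age_months"].mean()) / 60.0
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(
                "bmi ~ C(sex) * (a + I(a**2) + I(a**3))",
                data=d,
                groups=d["subject_id"],
                re_formula="~a",
            )
            res = model.fit(method="lbfgs", maxiter=200)
    except Exception as e:  # noqa: BLE001 - surfaced with diagnostics
        raise PipelineError(f"mixed-effects BMI model failed: {e}") from e
    if not np.all(np.isfinite(res.params)):
        raise PipelineError(
            f"mixed-effects BMI model did not converge: params={res.params.to_dict()}"
        )
    fixed = res.predict(d)
    re = res.random_effects
    n_per_subject = d.groupby("subject_id")["bmi"].transform("size")
    subj_adj = np.zeros(len(d))
    for i, (sid, a) in enumerate(zip(d["subject_id"], d["a"])):
        eff = re.get(sid)
        if eff is not None:
            subj_adj[i] = eff.iloc[0] + eff.iloc[1] * a
    pred = fixed.to_numpy() + np.where(n_per_subject.to_numpy() > 1, subj_adj, 0.0)
    resid = d["bmi"].to_numpy() - pred
    # scale by the SD of the deviations themselves (not the model's sigma:
    # BLUP predictions shrink residuals, so sigma would under-flag)
    sd = float(np.std(resid, ddof=1))
    if sd == 0:
        warnings.warn("zero residual SD in mixed model; nothing flagged")
        return pd.Index([])
    return d.index[np.abs(resid) > sd_limits * sd]


def run_pipeline(
    df: pd.DataFrame,
    config: CleaningConfig | None = None,
    screening: ScreeningReference | None = None,
) -> tuple[pd.DataFrame, CleaningReport]:
    """Apply all stages in order; returns (cleaned records, report).

    ``screening`` may be None only when the implausibility stage has no
    work to do (empty input); otherwise it is required.
    """
    config = config or CleaningConfig()
    report = CleaningReport(
        input_subjects=df["subject_id"].nunique(), input_observations=len(df)
    )
    cur = df

    nxt = filter_eligibility(cur, config)
    report.add("eligibility", cur, nxt)
    cur = nxt

    nxt = filter_missing(cur, config)
    report.add("missing", cur, nxt)
    cur = nxt

    flagged = flag_height_decrease(cur, config.height_decrease_cm)
    nxt = cur[~cur["subject_id"].isin(flagged)]
    report.add("height_decrease", cur, nxt)
    cur = nxt

    if screening is None and not cur.empty:
        raise PipelineError("a screening reference is required for the "
                            "implausible-values stage")
    if screening is not None and not cur.empty:
        flagged = flag_implausible(
            cur, screening, config.haz_limits, config.bmiz_limits
        )
        nxt = cur[~cur["subject_id"].isin(flagged)]
    else:
        nxt = cur
    report.add("implausible", cur, nxt)
    cur = nxt

    nxt = filter_sparse_ages(cur, config.min_obs_per_age_month)
    report.add("sparse_ages", cur, nxt)
    cur = nxt

    if not cur.empty:
        idx = flag_population_weight_outliers(cur, config.weight_z_limits)
        nxt = cur.drop(index=idx)
    else:
        nxt = cur
    report.add("population_weight_outliers", cur, nxt)
    cur = nxt

    if not cur.empty:
        idx = flag_individual_bmi_outliers(cur, config.individual_bmi_sd_limits)
        nxt = cur.drop(index=idx)
    else:
        nxt = cur
    report.add("individual_bmi_outliers", cur, nxt)
    cur = nxt

    return cur.copy(), report
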