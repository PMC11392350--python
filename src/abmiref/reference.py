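"""Growth-reference tables: LMS grids, allometric exponent schedules, I/O.

A growth reference is a per-sex table of L (Box-Cox skewness power), M
(median) and S (coefficient of variation) over age in months.  The packaged
multiethnic ABMI reference spans 60-240 months in 6-month steps and carries
an additional column ``p`` with the age/sex-specific allometric exponent
used to form the index weight / height**p.

Between printed rows each of L, M and S is interpolated independently with a
shape-preserving piecewise-cubic (monotone Hermite / PCHIP) interpolant, so
interpolated values never overshoot the bracketing printed values.  The
exponent schedule is *not* interpolated: exponents are discrete per-age
values and are looked up piecewise-constantly (right-continuous), with the
isometric exponent 2 beyond the last printed age.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from typing import IO, Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

__all__ = [
    "LMSPoint",
    "GrowthReference",
    "ExponentSchedule",
    "ObservationCountTable",
    "ReferenceError",
    "ReferenceParseError",
    "ReferenceValidationError",
    "AgeOutOfRangeError",
    "load_reference",
    "write_reference",
    "load_packaged_reference",
    "load_packaged_counts",
    "lms_at",
    "exponent_at",
]

SEXES = ("M", "F")

#: age (months) at and beyond which the isometric exponent 2 applies
ISOMETRIC_AGE = {"M": 216, "F": 192}


class ReferenceError(ValueError):
    """Base class for reference-table errors."""


class ReferenceParseError(ReferenceError):
    """A row of a reference CSV could not be parsed."""


class ReferenceValidationError(ReferenceError):
    """A parsed table violates a structural invariant."""


class AgeOutOfRangeError(ReferenceError):
    """Query age outside the reference's printed age span (no extrapolation)."""


@dataclass(frozen=True)
class LMSPoint:
    """One age's LMS triple: skewness power L, median M, coefficient of variation S."""

    age_months: float
    L: float
    M: float
    S: float

    def __post_init__(self) -> None:
        if not (self.M > 0 and self.S > 0):
            raise ReferenceValidationError(
                f"LMS point at age {self.age_months}: M and S must be positive "
                f"(got M={self.M}, S={self.S})"
            )


@dataclass(frozen=True)
class ExponentSchedule:
    """Per-sex discrete schedule of allometric exponents p over age in months.

    Lookup is piecewise constant and right-continuous: a query age maps to
    the entry at the greatest tabulated age <= the query; ages beyond the
    last tabulated row return the isometric exponent 2 exactly.
    """

    by_sex: Mapping[str, tuple[tuple[float, float], ...]]

    def __post_init__(self) -> None:
        if not self.by_sex:
            raise ReferenceValidationError("exponent schedule is empty")
        for sex, rows in self.by_sex.items():
            if not rows:
                raise ReferenceValidationError(f"exponent schedule empty for {sex!r}")
            ages = np.asarray([a for a, _ in rows], dtype=float)
            ps = np.asarray([p for _, p in rows], dtype=float)
            if not np.all(np.diff(ages) > 0):
                raise ReferenceValidationError(
                    f"exponent schedule ages must be strictly increasing for sex {sex!r}"
                )
            if not np.all((ps > 1.5) & (ps < 3.5)):
                raise ReferenceValidationError(
                    f"exponents must lie in (1.5, 3.5); offending sex {sex!r}"
                )
            iso = ISOMETRIC_AGE.get(sex)
            if iso is not None and np.any((ages >= iso) & (ps != 2.0)):
                raise ReferenceValidationError(
                    f"exponent must be 2 for sex {sex!r} at ages >= {iso} months"
                )

    def domain(self, sex: str) -> tuple[float, float]:
        ages = [a for a, _ in self.by_sex[sex]]
        return ages[0], float("inf")


@dataclass
class GrowthReference:
    """Named per-sex LMS grid with optional exponent schedule.

    ``index_kind`` is ``"bmi"`` (fixed exponent 2) or ``"abmi"`` (age/sex
    exponents from ``exponents``).
    """

    name: str
    index_kind: str
    points: Mapping[str, tuple[LMSPoint, ...]]
    exponents: ExponentSchedule | None = None
    _interp: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.index_kind not in ("bmi", "abmi"):
            raise ReferenceValidationError(
                f"index_kind must be 'bmi' or 'abmi', got {self.index_kind!r}"
            )
        for sex in SEXES:
            if sex not in self.points or not self.points[sex]:
                raise ReferenceValidationError(
                    f"reference {self.name!r} must contain both sexes; missing {sex!r}"
                )
        for sex, pts in self.points.items():
            ages = np.asarray([p.age_months for p in pts])
            if not np.all(np.diff(ages) > 0):
                raise ReferenceValidationError(
                    f"ages must be strictly increasing within sex {sex!r}"
                )
        if self.index_kind == "abmi":
            if self.exponents is None:
                raise ReferenceValidationError(
                    "an abmi reference requires an exponent schedule"
                )
            for sex in SEXES:
                if sex not in self.exponents.by_sex:
                    raise ReferenceValidationError(
                        f"exponent schedule of an abmi reference missing sex {sex!r}"
                    )

    def domain(self, sex: str) -> tuple[float, float]:
        pts = self.points[sex]
        return pts[0].age_months, pts[-1].age_months

    def ages(self, sex: str) -> np.ndarray:
        return np.asarray([p.age_months for p in self.points[sex]], dtype=float)

    def _interpolators(self, sex: str):
        if sex not in self._interp:
            pts = self.points[sex]
            ages = np.asarray([p.age_months for p in pts], dtype=float)
            self._interp[sex] = {
                c: PchipInterpolator(ages, np.asarray([getattr(p, c) for p in pts]))
                for c in ("L", "M", "S")
            }
        return self._interp[sex]


def _require_sex(obj_sexes: Iterable[str], sex: str) -> None:
    if sex not in obj_sexes:
        raise ReferenceValidationError(f"unknown sex {sex!r}; expected one of {SEXES}")


def lms_at(ref: GrowthReference, sex: str, age_months: float) -> LMSPoint:
    """LMS triple at an age, PCHIP-interpolated between printed rows.

    Exact grid ages return the stored point bit-for-bit; ages outside the
    printed span raise :class:`AgeOutOfRangeError` (the reference is never
    extrapolated).
    """
    _require_sex(ref.points.keys(), sex)
    lo, hi = ref.domain(sex)
    if not (lo <= age_months <= hi):
        raise AgeOutOfRangeError(
            f"age {age_months} months outside reference {ref.name!r} domain "
            f"[{lo}, {hi}] for sex {sex!r}"
        )
    for p in ref.points[sex]:
        if p.age_months == age_months:
            return p
    itp = ref._interpolators(sex)
    return LMSPoint(
        age_months=float(age_months),
        L=float(itp["L"](age_months)),
        M=float(itp["M"](age_months)),
        S=float(itp["S"](age_months)),
    )


def exponent_at(schedule: ExponentSchedule, sex: str, age_months: float) -> float:
    """Allometric exponent for (sex, age): piecewise-constant lookup.

    Returns the entry at the greatest tabulated age <= the query age; ages
    beyond the last tabulated row return 2.0 exactly.  Ages below the first
    tabulated age raise :class:`AgeOutOfRangeError`.
    """
    _require_sex(schedule.by_sex.keys(), sex)
    rows = schedule.by_sex[sex]
    ages = np.asarray([a for a, _ in rows], dtype=float)
    if age_months < ages[0]:
        raise AgeOutOfRangeError(
            f"age {age_months} months below exponent schedule start {ages[0]}"
        )
    if age_months > ages[-1]:
        return 2.0
    idx = int(np.searchsorted(ages, age_months, side="right")) - 1
    return float(rows[idx][1])


# ---------------------------------------------------------------------------
# I/O — reference CSV dialect: UTF-8, comma-separated, '.' decimal,
# header `sex,age_months,L,M,S[,p]`, one row per (sex, age).
# ---------------------------------------------------------------------------

_REQUIRED_COLS = ["sex", "age_months", "L", "M", "S"]


def load_reference(
    source: str | IO[str],
    name: str = "reference",
    index_kind: str | None = None,
) -> GrowthReference:
    """Read a growth reference from a CSV path or text stream.

    The index kind defaults to ``"abmi"`` when a ``p`` column is present and
    ``"bmi"`` otherwise.  Duplicate (sex, age) rows, missing sexes and
    non-monotone ages are rejected.
    """
    try:
        df = pd.read_csv(source, dtype=str, skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise ReferenceValidationError("empty reference stream") from None
    missing = [c for c in _REQUIRED_COLS if c not in df.columns]
    if missing:
        raise ReferenceParseError(f"reference CSV missing columns {missing}")
    if df.empty:
        raise ReferenceValidationError("reference CSV contains no rows")
    has_p = "p" in df.columns

    num_cols = ["age_months", "L", "M", "S"] + (["p"] if has_p else [])
    parsed = {}
    for col in num_cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ReferenceParseError(
                f"malformed value in column {col!r} at data row {row + 1}"
            )
        parsed[col] = vals.to_numpy(dtype=float)
    sex_col = df["sex"].astype(str).str.strip()
    bad_sex = ~sex_col.isin(SEXES)
    if bad_sex.any():
        row = int(np.flatnonzero(bad_sex.to_numpy())[0])
        raise ReferenceParseError(
            f"unknown sex {sex_col.iloc[row]!r} at data row {row + 1}"
        )

    dup = df.assign(sex=sex_col, age=parsed["age_months"]).duplicated(["sex", "age"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise ReferenceValidationError(f"duplicate (sex, age) at data row {row + 1}")

    points: dict[str, tuple[LMSPoint, ...]] = {}
    sched: dict[str, tuple[tuple[float, float], ...]] = {}
    for sex in SEXES:
        mask = (sex_col == sex).to_numpy()
        if not mask.any():
            raise ReferenceValidationError(f"reference has no rows for sex {sex!r}")
        order = np.argsort(parsed["age_months"][mask], kind="stable")
        idx = np.flatnonzero(mask)[order]
        if not np.array_equal(idx, np.flatnonzero(mask)):
            raise ReferenceValidationError(
                f"ages not increasing for sex {sex!r} (rows must be sorted by age)"
            )
        points[sex] = tuple(
            LMSPoint(
                age_months=parsed["age_months"][i],
                L=parsed["L"][i],
                M=parsed["M"][i],
                S=parsed["S"][i],
            )
            for i in idx
        )
        if has_p:
            sched[sex] = tuple(
                (parsed["age_months"][i], parsed["p"][i]) for i in idx
            )

    exponents = ExponentSchedule(by_sex=sched) if has_p else None
    if index_kind is None:
        index_kind = "abmi" if has_p else "bmi"
    return GrowthReference(
        name=name, index_kind=index_kind, points=points, exponents=exponents
    )


def write_reference(ref: GrowthReference, dest: str | IO[str]) -> None:
    """Write a reference in the CSV dialect, numbers formatted to 4 decimals.

    ``write_reference(load_reference(f))`` reproduces every numeric cell of a
    4-decimal source file bit-exactly.
    """
    has_p = ref.exponents is not None
    lines = ["sex,age_months,L,M,S" + (",p" if has_p else "")]
    for sex in SEXES:
        sched = dict(ref.exponents.by_sex[sex]) if has_p else {}
        for p in ref.points[sex]:
            row = (
                f"{sex},{p.age_months:g},{p.L:.4f},{p.M:.4f},{p.S:.4f}"
            )
            if has_p:
                row += f",{sched[p.age_months]:.1f}"
            lines.append(row)
    text = "\n".join(lines) + "\n"
    if isinstance(dest, (str, bytes)):
        with open(dest, "w", encoding="utf-8") as fh:
            fh.write(text)
    else:
        dest.write(text)


def load_packaged_reference() -> GrowthReference:
    """The packaged multiethnic ABMI reference (60-240 months, both sexes)."""
    text = resources.files("abmiref.data").joinpath("mult_abmi.csv").read_text()
    return load_reference(io.StringIO(text), name="MULT_ABMI", index_kind="abmi")


@dataclass(frozen=True)
class ObservationCountTable:
    """Per-sex, per-age-group observation counts behind the packaged reference."""

    table: pd.DataFrame  # columns: age_lo_months, age_hi_months, boys_obs, girls_obs

    def __post_init__(self) -> None:
        t = self.table
        if (t[["boys_obs", "girls_obs"]] < 0).any().any():
            raise ReferenceValidationError("observation counts must be >= 0")

    @property
    def totals(self) -> dict[str, int]:
        return {
            "M": int(self.table["boys_obs"].sum()),
            "F": int(self.table["girls_obs"].sum()),
        }


def load_packaged_counts() -> ObservationCountTable:
    text = resources.files("abmiref.data").joinpath("table1_counts.csv").read_text()
    return ObservationCountTable(table=pd.read_csv(io.StringIO(text)))
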