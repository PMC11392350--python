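"""Residual diagnostics for fitted references: worm plots and per-ethnicity
median panels.

A worm plot (van Buuren & Fredriks) splits z-scores into equal-count age
bins and, per bin, plots the deviation of empirical z order statistics from
their standard-normal expectations against the theoretical quantiles.  A
cubic fitted to the deviations summarizes misfit: b0 location, b1 scale,
b2 skewness, b3 kurtosis.  Coefficients beyond the conventional thresholds
(|b0| > 0.10, |b1| > 0.10, |b2| > 0.05, |b3| > 0.03) flag the bin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .lms import z_for_dataset
from .reference import ExponentSchedule, GrowthReference, lms_at

__all__ = ["WormPanel", "worm_plot", "worm_table", "ethnicity_fit"]

#: van Buuren & Fredriks misfit thresholds for (b0, b1, b2, b3)
WORM_THRESHOLDS = (0.10, 0.10, 0.05, 0.03)


@dataclass(frozen=True)
class WormPanel:
    """Detrended QQ summary of one age bin."""

    age_lo: float
    age_hi: float
    n: int
    coef: tuple[float, float, float, float]  # b0..b3
    flags: tuple[bool, bool, bool, bool]

    @property
    def flagged(self) -> bool:
        return any(self.flags)


def worm_plot(z, ages, n_bins: int = 16, min_bin: int = 50) -> list[WormPanel]:
    """Worm-plot panels over equal-count age bins.

    Per bin, sorted z-scores are compared with normal order-statistic
    expectations at Blom plotting positions; a cubic in the theoretical
    quantile is least-squares fitted to (empirical - theoretical).
    Invariant to the ordering of the input records.
    """
    z = np.asarray(z, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if z.shape != ages.shape:
        raise ValueError("z and ages must have equal length")
    if len(z) < n_bins * min_bin:
        raise ValueError(
            f"{len(z)} observations cannot fill {n_bins} bins of >= {min_bin}; "
            f"use fewer bins"
        )
    order = np.argsort(ages, kind="stable")
    panels = []
    for chunk in np.array_split(order, n_bins):
        n = len(chunk)
        if n < min_bin:
            raise ValueError(f"a bin has {n} < {min_bin} observations; use fewer bins")
        zb = np.sort(z[chunk])
        theo = norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))
        dev = zb - theo
        coef = np.polynomial.polynomial.polyfit(theo, dev, 3)
        flags = tuple(bool(abs(c) > t) for c, t in zip(coef, WORM_THRESHOLDS))
        panels.append(
            WormPanel(
                age_lo=float(ages[chunk].min()),
                age_hi=float(ages[chunk].max()),
                n=n,
                coef=tuple(float(c) for c in coef),
                flags=flags,
            )
        )
    return panels


def worm_table(panels: list[WormPanel]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "age_lo": [p.age_lo for p in panels],
            "age_hi": [p.age_hi for p in panels],
            "n": [p.n for p in panels],
            "b0": [p.coef[0] for p in panels],
            "b1": [p.coef[1] for p in panels],
            "b2": [p.coef[2] for p in panels],
            "b3": [p.coef[3] for p in panels],
            "flagged": [p.flagged for p in panels],
        }
    )


def ethnicity_fit(
    records: pd.DataFrame,
    ref: GrowthReference,
    schedule: ExponentSchedule | None = None,
    age_bin_months: float = 6.0,
) -> pd.DataFrame:
    """Median index per (sex, ethnicity, age bin) with the reference M overlaid.

    A well-fitting reference has group medians tracking the M curve; a
    systematically offset group signals ethnicity-specific misfit.  Empty
    groups are omitted with a warning.
    """
    scored = z_for_dataset(records, ref, schedule)
    ok = scored[scored["flag"] == "ok"].copy()
    dropped = scored["flag"].ne("ok").sum()
    if dropped:
        warnings.warn(f"{dropped} out-of-domain records omitted from ethnicity panels")
    ok["age_bin"] = np.floor(ok["age_months"] / age_bin_months) * age_bin_months
    rows = []
    for (sex, eth, b), grp in ok.groupby(["sex", "ethnicity", "age_bin"]):
        mid = b + age_bin_months / 2.0
        lo, hi = ref.domain(sex)
        m_ref = lms_at(ref, sex, min(max(mid, lo), hi)).M
        rows.append(
            {
                "sex": sex,
                "ethnicity": eth,
                "age_bin_months": b,
                "n": len(grp),
                "median_index": float(grp["index_value"].median()),
                "reference_M": m_ref,
            }
        )
    return pd.DataFrame(rows)
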