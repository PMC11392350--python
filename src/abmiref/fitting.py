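"""Penalized-spline LMS (BCCG) fitting with cyclic backfitting and BIC
degrees-of-freedom selection.

The age-conditional distribution of a positive index y is modelled as
Box-Cox Cole-Green: the Box-Cox transform of y/mu(age) with power nu(age)
is (truncated) standard normal after scaling by sigma(age).  The three
parameter curves correspond to the LMS method's L (nu), M (mu) and S
(sigma).  Each curve is a cubic P-spline in age (second-order difference
penalty); fitting cyclically applies penalized weighted least squares to
one parameter's coefficients at a time, holding the others fixed, with the
working response and weights of a Fisher-scoring step (the
Rigby-Stasinopoulos algorithm).  Each curve's smoothing penalty is tuned so
its realized effective df hits a requested target; candidate df triples are
compared by BIC = -2*loglik + ln(n)*(total effective df).

Links: identity for mu and nu, log for sigma (the usual BCCG convention;
invalid candidate states from the identity links are rejected by
step-halving).

df convention: a target df counts flexibility beyond a baseline — beyond
constant+linear for M and S (df=0 means a straight line in age) and beyond
constant for L (df=0 means a constant skewness, df=1 a linear one).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import norm

from .reference import (
    ExponentSchedule,
    GrowthReference,
    LMSPoint,
    SEXES,
)

__all__ = [
    "PSplineSpec",
    "FitConfig",
    "FittedLMS",
    "FitError",
    "DegenerateDataError",
    "bccg_logpdf",
    "bccg_loglik",
    "fit_lms",
    "select_df",
    "export_reference",
]

_NU_EPS = 1e-5  # |nu| below this uses series expansions around nu = 0


class FitError(RuntimeError):
    """Fitting failed (non-convergence or unusable data)."""


class DegenerateDataError(FitError):
    """Response has no usable variation."""


@dataclass(frozen=True)
class PSplineSpec:
    """P-spline settings for one parameter curve."""

    df: float
    n_interior_knots: int = 20
    degree: int = 3
    penalty_order: int = 2

    def __post_init__(self) -> None:
        if self.df < 0:
            raise ValueError("df must be >= 0")
        if self.n_interior_knots + self.degree + 1 < self.degree + 2:
            raise ValueError("basis too small")


@dataclass(frozen=True)
class FitConfig:
    """Fitting controls: df grids, convergence tolerance, iteration caps."""

    df_grid_L: tuple = (0, 1)
    df_grid_M: tuple = (0, 1, 2, 3, 4)
    df_grid_S: tuple = (0, 1, 2, 3)
    tol: float = 1e-4
    max_iter: int = 200
    edf_tol: float = 0.05

    def __post_init__(self) -> None:
        if not (self.df_grid_L and self.df_grid_M and self.df_grid_S):
            raise ValueError("df grids must be non-empty")
        if self.tol <= 0:
            raise ValueError("tolerance must be positive")


# ---------------------------------------------------------------------------
# BCCG density
# ---------------------------------------------------------------------------

def _bccg_z(y, mu, sigma, nu):
    """Box-Cox z-transform, continuous through nu = 0."""
    l = np.log(y / mu)
    small = np.abs(nu) < _NU_EPS
    nu_safe = np.where(small, 1.0, nu)
    z_big = (np.exp(nu * l) - 1.0) / (nu_safe * sigma)
    z_small = (l / sigma) * (1.0 + nu * l / 2.0 + nu**2 * l**2 / 6.0)
    return np.where(small, z_small, z_big)


def bccg_logpdf(y, mu, sigma, nu):
    """Per-observation BCCG log-density (vectorized).

    log f = (nu-1) ln y - nu ln mu - ln sigma - z^2/2 - ln sqrt(2 pi)
            - ln Phi(1/(sigma |nu|)),
    the last term normalizing the truncation that keeps y positive.
    """
    y, mu, sigma, nu = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (y, mu, sigma, nu))
    )
    if np.any(y <= 0) or np.any(mu <= 0) or np.any(sigma <= 0):
        raise ValueError("y, mu and sigma must all be positive")
    z = _bccg_z(y, mu, sigma, nu)
    trunc = norm.logcdf(1.0 / (sigma * np.maximum(np.abs(nu), _NU_EPS)))
    return (
        (nu - 1.0) * np.log(y)
        - nu * np.log(mu)
        - np.log(sigma)
        - 0.5 * z**2
        - 0.5 * np.log(2.0 * np.pi)
        - trunc
    )


def bccg_loglik(y, mu, sigma, nu) -> float:
    """Total BCCG log-likelihood over a sample."""
    return float(np.sum(bccg_logpdf(y, mu, sigma, nu)))


# ---------------------------------------------------------------------------
# P-spline machinery
# ---------------------------------------------------------------------------

def _make_basis(ages: np.ndarray, spec: PSplineSpec):
    lo, hi = float(ages.min()), float(ages.max())
    k = spec.degree
    interior = np.linspace(lo, hi, spec.n_interior_knots + 2)[1:-1]
    t = np.concatenate([np.repeat(lo, k + 1), interior, np.repeat(hi, k + 1)])
    B = BSpline.design_matrix(ages, t, k, extrapolate=True).toarray()
    nb = B.shape[1]
    D = np.diff(np.eye(nb), n=spec.penalty_order, axis=0)
    P = D.T @ D
    return t, B, P


def _edf(BtWB: np.ndarray, P: np.ndarray, lam: float) -> float:
    c = cho_factor(BtWB + lam * P + 1e-10 * np.eye(len(P)))
    return float(np.trace(cho_solve(c, BtWB)))


def _solve_pwls(BtWB, BtWu, P, lam):
    c = cho_factor(BtWB + lam * P + 1e-10 * np.eye(len(P)))
    return cho_solve(c, BtWu)


def _lambda_for_edf(BtWB, P, target: float, tol: float) -> float:
    """Bisection on log-lambda so trace edf matches the target.

    Exponents are relative to the scale ratio tr(BtWB)/tr(P), which keeps
    the search numerically sane across sample sizes and weight scales.
    Callers guarantee target > penalty null-space dimension (2).
    """
    scale = np.trace(BtWB) / max(np.trace(P), 1e-12)
    lo, hi = -10.0, 10.0
    if _edf(BtWB, P, scale * 10.0**hi) > target:
        return scale * 10.0**hi
    if _edf(BtWB, P, scale * 10.0**lo) < target:
        return scale * 10.0**lo
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        e = _edf(BtWB, P, scale * 10.0**mid)
        if abs(e - target) < tol * 0.5:
            return scale * 10.0**mid
        if e > target:
            lo = mid
        else:
            hi = mid
    return scale * 10.0 ** (0.5 * (lo + hi))


# ---------------------------------------------------------------------------
# Score and weight functions (per linear predictor)
# ---------------------------------------------------------------------------

def _score_mu(y, mu, sigma, nu):
    """d loglik / d mu (identity link) and its expected information."""
    z = _bccg_z(y, mu, sigma, nu)
    u = z / (mu * sigma) + (nu / mu) * (z**2 - 1.0)
    w = (1.0 + 2.0 * sigma**2 * nu**2) / (mu**2 * sigma**2)
    return u, w


def _score_sigma(y, mu, sigma, nu):
    """d loglik / d eta_sigma (log link); expected information = 2."""
    z = _bccg_z(y, mu, sigma, nu)
    u = z**2 - 1.0
    w = np.full_like(z, 2.0)
    return u, w


def _score_nu(y, mu, sigma, nu):
    """d loglik / d nu (identity link); expected information ~ 7 sigma^2/4."""
    l = np.log(y / mu)
    z = _bccg_z(y, mu, sigma, nu)
    small = np.abs(nu) < _NU_EPS
    nu_safe = np.where(small, 1.0, nu)
    dzdnu_big = (np.exp(nu * l) * l) / (nu_safe * sigma) - z / nu_safe
    dzdnu_small = (l / sigma) * (l / 2.0 + nu * l**2 / 3.0)
    dzdnu = np.where(small, dzdnu_small, dzdnu_big)
    u = l - z * dzdnu
    w = 7.0 * sigma**2 / 4.0
    return u, np.broadcast_to(w, z.shape).copy()


_SCORES = {"mu": _score_mu, "sigma": _score_sigma, "nu": _score_nu}
_LINKS = {"mu": "identity", "sigma": "log", "nu": "identity"}


@dataclass
class _Curve:
    """State of one parameter curve during fitting.

    kind 'const'/'linear': exact unpenalized polynomial baselines (edf 1/2);
    kind 'spline': P-spline whose penalty is tuned to the edf target.
    """

    name: str
    spec: PSplineSpec
    target_edf: float
    kind: str  # 'const' | 'linear' | 'spline'
    B: np.ndarray  # design on the data ages
    coef: np.ndarray
    knots: np.ndarray | None = None
    P: np.ndarray | None = None
    age_mid: float = 0.0
    age_scale: float = 1.0
    lam: float = 0.0
    edf: float = 1.0

    @property
    def penalized(self) -> bool:
        return self.kind == "spline"

    def eta(self) -> np.ndarray:
        return self.B @ self.coef

    def value(self) -> np.ndarray:
        eta = self.eta()
        return np.exp(eta) if _LINKS[self.name] == "log" else eta

    def design_at(self, ages: np.ndarray) -> np.ndarray:
        if self.kind == "const":
            return np.ones((len(ages), 1))
        if self.kind == "linear":
            return np.column_stack(
                [np.ones(len(ages)), (ages - self.age_mid) / self.age_scale]
            )
        return BSpline.design_matrix(
            ages, self.knots, self.spec.degree, extrapolate=True
        ).toarray()

    def eval_at(self, ages: np.ndarray) -> np.ndarray:
        eta = self.design_at(np.asarray(ages, dtype=float)) @ self.coef
        return np.exp(eta) if _LINKS[self.name] == "log" else eta


@dataclass
class FittedLMS:
    """One sex's fitted BCCG parameter curves and fit summaries."""

    sex: str | None
    age_lo: float
    age_hi: float
    curves: dict
    edf: dict
    loglik: float
    bic: float
    converged: bool
    n: int
    df_request: tuple
    deviance_trace: list = field(default_factory=list)

    def predict(self, ages) -> dict[str, np.ndarray]:
        """Evaluate the fitted L/M/S at ages (within the fitted span)."""
        ages = np.asarray(ages, dtype=float)
        if np.any(ages < self.age_lo) or np.any(ages > self.age_hi):
            raise ValueError(
                f"ages outside fitted span [{self.age_lo}, {self.age_hi}]"
            )
        return {
            "M": self.curves["mu"].eval_at(ages),
            "S": self.curves["sigma"].eval_at(ages),
            "L": self.curves["nu"].eval_at(ages),
        }


def _initial_curves(ages, y, specs, targets, n) -> dict[str, _Curve]:
    """Robust deterministic start: binned running median / MAD, nu = 0."""
    order = np.argsort(ages, kind="stable")
    nbins = min(20, max(4, n // 25))
    med_age, med_y, mad_log = [], [], []
    for chunk in np.array_split(order, nbins):
        med_age.append(np.median(ages[chunk]))
        m = np.median(y[chunk])
        med_y.append(m)
        mad_log.append(np.median(np.abs(np.log(y[chunk]) - np.log(m))))
    med_age, med_y = np.asarray(med_age), np.asarray(med_y)
    sigma0 = max(float(np.median(mad_log)) * 1.4826, 1e-3)

    curves = {}
    mid = float(ages.mean())
    scale = max(float(np.ptp(ages)) / 2.0, 1.0)
    for name, tgt in targets.items():
        spec = specs[name]
        if name == "mu":
            target_eta = np.interp(ages, med_age, med_y)
        elif name == "sigma":
            target_eta = np.full(n, np.log(sigma0))
        else:
            target_eta = np.zeros(n)
        if tgt <= 1.0 + 1e-9:
            c = _Curve(name, spec, tgt, "const", np.ones((n, 1)),
                       np.array([float(np.mean(target_eta))]))
            c.edf = 1.0
        elif tgt <= 2.0 + 1e-9:
            B = np.column_stack([np.ones(n), (ages - mid) / scale])
            coef = np.linalg.lstsq(B, target_eta, rcond=None)[0]
            c = _Curve(name, spec, tgt, "linear", B, coef,
                       age_mid=mid, age_scale=scale)
            c.edf = 2.0
        else:
            knots, B, P = _make_basis(ages, spec)
            coef = np.linalg.lstsq(
                B.T @ B + 1e-6 * np.eye(B.shape[1]), B.T @ target_eta, rcond=None
            )[0]
            c = _Curve(name, spec, tgt, "spline", B, coef, knots=knots, P=P)
        curves[name] = c
    return curves


def _penalized_deviance(y, curves) -> float:
    mu = curves["mu"].value()
    sigma = curves["sigma"].value()
    nu = curves["nu"].value()
    if np.any(mu <= 0) or np.any(sigma <= 0) or not (
        np.all(np.isfinite(mu)) and np.all(np.isfinite(sigma))
        and np.all(np.isfinite(nu))
    ):
        return np.inf  # invalid candidate state; step-halving backs off
    dev = -2.0 * bccg_loglik(y, mu, sigma, nu)
    pen = 0.0
    for c in curves.values():
        if c.penalized:
            pen += c.lam * float(c.coef @ c.P @ c.coef)
    return dev + pen


def fit_lms(
    ages,
    y,
    specs: dict[str, PSplineSpec] | tuple = (1, 4, 3),
    config: FitConfig | None = None,
    sex: str | None = None,
) -> FittedLMS:
    """Fit BCCG parameter curves to (age, y) by cyclic penalized scoring.

    ``specs`` is either a (df_L, df_M, df_S) triple or a mapping
    {'nu'/'mu'/'sigma': PSplineSpec}.  Requires n >= 50 observations
    spanning >= 12 months of age, all y > 0.

    Raises :class:`FitError` (with the deviance trace attached) on
    non-convergence and :class:`DegenerateDataError` for constant y.
    """
    config = config or FitConfig()
    ages = np.asarray(ages, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(ages) != len(y):
        raise ValueError("ages and y must have equal length")
    n = len(y)
    if n < 50:
        raise FitError(f"need >= 50 observations, got {n}")
    if np.ptp(ages) < 12:
        raise FitError("ages must span at least 12 months")
    if np.any(y <= 0):
        raise ValueError("index values must be positive")
    if np.ptp(y) == 0:
        raise DegenerateDataError("all index values are equal")

    if not isinstance(specs, dict):
        df_l, df_m, df_s = specs
        specs = {
            "nu": PSplineSpec(df=df_l),
            "mu": PSplineSpec(df=df_m),
            "sigma": PSplineSpec(df=df_s),
        }
    df_request = (specs["nu"].df, specs["mu"].df, specs["sigma"].df)
    # total trace-edf targets: baseline linear (2) for mu/sigma, constant (1) for nu
    targets = {
        "mu": specs["mu"].df + 2.0,
        "sigma": specs["sigma"].df + 2.0,
        "nu": specs["nu"].df + 1.0,
    }
    curves = _initial_curves(ages, y, specs, targets, n)

    warmup = 3  # cycles during which smoothing penalties are re-tuned
    trace: list[float] = []
    converged = False
    pen_dev = _penalized_deviance(y, curves)
    for it in range(config.max_iter):
        for name in ("mu", "sigma", "nu"):
            c = curves[name]
            mu = curves["mu"].value()
            sigma = curves["sigma"].value()
            nu = curves["nu"].value()
            u, w = _SCORES[name](y, mu, sigma, nu)
            w = np.clip(w, 1e-8, 1e8)
            eta = c.eta()
            work = eta + u / w
            BtWB = (c.B * w[:, None]).T @ c.B
            BtWu = c.B.T @ (w * work)
            if c.penalized:
                if it < warmup:
                    c.lam = _lambda_for_edf(BtWB, c.P, c.target_edf, config.edf_tol)
                new = _solve_pwls(BtWB, BtWu, c.P, c.lam)
                c.edf = _edf(BtWB, c.P, c.lam)
            else:
                new = np.linalg.solve(
                    BtWB + 1e-10 * np.eye(BtWB.shape[0]), BtWu
                )
                c.edf = float(BtWB.shape[0])
            # step-halving: never let a parameter update increase the
            # penalized deviance.  The baseline is re-evaluated because a
            # warmup cycle may just have re-tuned this curve's penalty;
            # once the penalties are frozen the outer trace is monotone.
            old = c.coef
            base = _penalized_deviance(y, curves)
            pen_dev = base
            step = 1.0
            for _ in range(12):
                c.coef = old + step * (new - old)
                cand = _penalized_deviance(y, curves)
                if np.isfinite(cand) and cand <= base + 1e-10:
                    pen_dev = cand
                    break
                step *= 0.5
            else:
                c.coef = old
        if it >= warmup:
            trace.append(pen_dev)
            if len(trace) >= 2 and abs(trace[-2] - trace[-1]) < config.tol:
                converged = True
                break

    mu = curves["mu"].value()
    sigma = curves["sigma"].value()
    nu = curves["nu"].value()
    loglik = bccg_loglik(y, mu, sigma, nu)
    edf = {name: c.edf for name, c in curves.items()}
    total_edf = sum(edf.values())
    bic = -2.0 * loglik + np.log(n) * total_edf
    if not converged:
        err = FitError(
            f"no convergence in {config.max_iter} cycles "
            f"(last deviance change {abs(trace[-2] - trace[-1]) if len(trace) > 1 else np.nan:.3g})"
        )
        err.deviance_trace = trace
        raise err
    return FittedLMS(
        sex=sex,
        age_lo=float(ages.min()),
        age_hi=float(ages.max()),
        curves=curves,
        edf=edf,
        loglik=float(loglik),
        bic=float(bic),
        converged=converged,
        n=n,
        df_request=df_request,
        deviance_trace=trace,
    )


def select_df(ages, y, config: FitConfig | None = None, sex: str | None = None):
    """Fit every df triple in the config's grids; return (best fit, grid table).

    The default grids (L 0-1, M 0-4, S 0-3) give 40 combinations.  The
    lowest BIC wins; ties within 1e-9 go to the smaller total df.
    """
    config = config or FitConfig()
    rows = []
    fits = {}
    failures = []
    for df_l, df_m, df_s in product(
        config.df_grid_L, config.df_grid_M, config.df_grid_S
    ):
        key = (df_l, df_m, df_s)
        try:
            fit = fit_lms(ages, y, key, config=config, sex=sex)
        except FitError as e:
            failures.append((key, str(e)))
            rows.append(
                {"df_L": df_l, "df_M": df_m, "df_S": df_s,
                 "bic": np.nan, "loglik": np.nan, "total_edf": np.nan,
                 "converged": False}
            )
            continue
        fits[key] = fit
        rows.append(
            {"df_L": df_l, "df_M": df_m, "df_S": df_s,
             "bic": fit.bic, "loglik": fit.loglik,
             "total_edf": sum(fit.edf.values()), "converged": True}
        )
    if not fits:
        raise FitError(f"all {len(failures)} grid fits failed; first: {failures[0]}")
    bic_min = min(f.bic for f in fits.values())
    tied = [k for k, f in fits.items() if f.bic <= bic_min + 1e-9]
    best_key = min(tied, key=lambda k: (sum(k), k))
    return fits[best_key], pd.DataFrame(rows)


def export_reference(
    fits: dict[str, FittedLMS],
    ages,
    name: str = "fitted",
    index_kind: str = "bmi",
    schedule: ExponentSchedule | None = None,
) -> GrowthReference:
    """Tabulate fitted curves on an age grid as a GrowthReference.

    ``fits`` maps sex ('M'/'F') to a converged fit; the output round-trips
    through the reference CSV dialect.  Unconverged fits are refused, as
    are grid ages outside a fit's span.
    """
    ages = np.asarray(ages, dtype=float)
    points = {}
    for sex in SEXES:
        if sex not in fits:
            raise ValueError(f"export requires a fit for sex {sex!r}")
        fit = fits[sex]
        if not fit.converged:
            raise FitError(f"refusing to export unconverged fit for sex {sex!r}")
        pred = fit.predict(ages)  # raises on out-of-span ages
        points[sex] = tuple(
            LMSPoint(age_months=float(a), L=float(l), M=float(m), S=float(s))
            for a, l, m, s in zip(ages, pred["L"], pred["M"], pred["S"])
        )
    return GrowthReference(
        name=name, index_kind=index_kind, points=points, exponents=schedule
    )
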