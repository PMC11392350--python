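"""BCCG density and penalized-spline LMS fitting."""

import numpy as np
import pytest
from scipy.integrate import quad

from abmiref.fitting import (
    DegenerateDataError,
    FitConfig,
    FitError,
    bccg_logpdf,
    bccg_loglik,
    export_reference,
    fit_lms,
    select_df,
)
from abmiref.lms import inverse_z
from abmiref.reference import LMSPoint, lms_at, load_reference, write_reference


class TestBCCGDensity:
    @pytest.mark.parametrize(
        "mu,sigma,nu",
        [(12.0, 0.13, -1.0), (20.0, 0.05, 0.0), (15.0, 0.2, 1.5), (8.0, 0.1, -2.0)],
    )
    def test_density_integrates_to_one(self, mu, sigma, nu):
        f = lambda y: np.exp(bccg_logpdf(y, mu, sigma, nu))  # noqa: E731
        body, _ = quad(f, 1e-9, mu * 12, limit=300)
        tail, _ = quad(f, mu * 12, np.inf, limit=200)
        assert body + tail == pytest.approx(1.0, abs=1e-6)

    def test_continuity_through_nu_zero(self):
        rng = np.random.default_rng(0)
        y = rng.uniform(8, 20, 50)
        a = bccg_loglik(y, 12.0, 0.13, 1e-8)
        b = bccg_loglik(y, 12.0, 0.13, 0.0)
        assert abs(a - b) < 1e-6

    def test_closed_form_at_y_equal_mu(self):
        mu, sigma, nu = 12.0, 0.13, -1.0
        from scipy.stats import norm

        got = float(bccg_logpdf(mu, mu, sigma, nu))
        expect = (
            (nu - 1) * np.log(mu) - nu * np.log(mu) - np.log(sigma)
            - 0.5 * np.log(2 * np.pi)
            - norm.logcdf(1 / (sigma * abs(nu)))
        )
        assert got == pytest.approx(expect, abs=1e-12)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            bccg_logpdf(-1.0, 12.0, 0.13, -1.0)
        with pytest.raises(ValueError):
            bccg_logpdf(10.0, 12.0, 0.0, -1.0)


def _simulate_constant(n, seed, mu=12.0, sigma=0.13, nu=-1.0):
    rng = np.random.default_rng(seed)
    pt = LMSPoint(0.0, nu, mu, sigma)
    ages = rng.uniform(60, 240, n)
    z = np.clip(rng.normal(size=n), -5, 5)
    y = np.array([inverse_z(zz, pt) for zz in z])
    return ages, y


class TestFitLMS:
    def test_constant_parameter_recovery(self):
        ages, y = _simulate_constant(5000, seed=10)
        fit = fit_lms(ages, y, (0, 0, 0))
        pred = fit.predict([150.0])
        assert pred["M"][0] == pytest.approx(12.0, rel=0.02)
        assert pred["S"][0] == pytest.approx(0.13, rel=0.02)
        assert pred["L"][0] == pytest.approx(-1.0, abs=0.3)

    def test_median_mu_error_under_one_percent_over_seeds(self):
        errs = []
        for seed in range(10):
            ages, y = _simulate_constant(2000, seed=seed)
            fit = fit_lms(ages, y, (0, 0, 0))
            errs.append(abs(fit.predict([150.0])["M"][0] / 12.0 - 1))
        assert np.median(errs) < 0.01

    def test_curve_recovery_from_packaged_boys(self, boys_month_sim):
        ages, y, pts = boys_month_sim
        fit = fit_lms(ages, y, (1, 4, 3))
        ev = np.arange(72, 229, 6, dtype=float)
        pred = fit.predict(ev)
        true_m = np.array([pts[int(a)].M for a in ev])
        assert np.max(np.abs(pred["M"] / true_m - 1)) < 0.025

    def test_deviance_trace_monotone(self, boys_month_sim):
        ages, y, _ = boys_month_sim
        fit = fit_lms(ages, y, (1, 4, 3))
        trace = np.asarray(fit.deviance_trace)
        assert np.all(np.diff(trace) <= 1e-6)

    def test_edf_matches_requested_targets(self, boys_month_sim):
        ages, y, _ = boys_month_sim
        fit = fit_lms(ages, y, (1, 4, 3))
        assert fit.edf["nu"] == pytest.approx(2.0, abs=0.06)
        assert fit.edf["mu"] == pytest.approx(6.0, abs=0.06)
        assert fit.edf["sigma"] == pytest.approx(5.0, abs=0.06)

    def test_bic_formula_invariant(self, boys_month_sim):
        ages, y, _ = boys_month_sim
        fit = fit_lms(ages, y, (1, 4, 3))
        expect = -2 * fit.loglik + np.log(fit.n) * sum(fit.edf.values())
        assert fit.bic == pytest.approx(expect, abs=1e-9)

    def test_normal_limit_agrees_with_linear_regression(self):
        # small dispersion, near-normal data around a linear trend: the
        # fitted M curve should match ordinary least squares
        rng = np.random.default_rng(4)
        n = 4000
        ages = rng.uniform(60, 240, n)
        mean = 10.0 + 0.02 * ages
        y = mean * np.exp(rng.normal(0, 0.02, n))
        fit = fit_lms(ages, y, (0, 0, 0))
        coef = np.polyfit(ages, y, 1)
        ev = np.array([80.0, 150.0, 220.0])
        np.testing.assert_allclose(
            fit.predict(ev)["M"], np.polyval(coef, ev), rtol=0.005
        )

    def test_constant_y_degenerate(self):
        ages = np.linspace(60, 240, 100)
        with pytest.raises(DegenerateDataError):
            fit_lms(ages, np.full(100, 12.0), (0, 0, 0))

    def test_too_few_or_too_narrow(self):
        ages, y = _simulate_constant(40, seed=1)
        with pytest.raises(FitError):
            fit_lms(ages, y, (0, 0, 0))
        ages2, y2 = _simulate_constant(100, seed=1)
        with pytest.raises(FitError):
            fit_lms(np.full(100, 100.0) + np.linspace(0, 5, 100), y2, (0, 0, 0))


@pytest.fixture(scope="module")
def small_sim(ref):
    rng = np.random.default_rng(21)
    months = np.arange(60, 241, 6)
    pts = {m: lms_at(ref, "M", float(m)) for m in months}
    ages = np.repeat(months, 40).astype(float)
    z = np.clip(rng.normal(size=len(ages)), -5, 5)
    y = np.array([inverse_z(zz, pts[m]) for zz, m in zip(z, ages.astype(int))])
    return ages, y


class TestSelectDF:
    def test_grid_table_has_every_combination(self, small_sim):
        ages, y = small_sim
        cfg = FitConfig(df_grid_L=(0, 1), df_grid_M=(2, 4), df_grid_S=(1, 3))
        best, table = select_df(ages, y, cfg)
        assert len(table) == 8
        assert best.bic == table["bic"].min()

    def test_matches_exhaustive_refit_argmin(self, small_sim):
        ages, y = small_sim
        cfg = FitConfig(df_grid_L=(0, 1), df_grid_M=(2, 4), df_grid_S=(1, 3))
        best, _ = select_df(ages, y, cfg)
        # independent exhaustive search over the same grid
        candidates = {}
        for dl in cfg.df_grid_L:
            for dm in cfg.df_grid_M:
                for ds in cfg.df_grid_S:
                    try:
                        candidates[(dl, dm, ds)] = fit_lms(
                            ages, y, (dl, dm, ds), cfg
                        ).bic
                    except FitError:
                        pass
        oracle = min(candidates, key=lambda k: (candidates[k], sum(k), k))
        assert best.df_request == oracle

    def test_tie_breaks_to_smaller_total_df(self, monkeypatch):
        import abmiref.fitting as F

        class Fake:
            def __init__(self, df):
                self.df_request = df
                self.bic = 100.0 + 5e-10 * sum(df)  # ties within 1e-9
                self.edf = {"mu": 2, "sigma": 2, "nu": 1}
                self.loglik = -50.0

        monkeypatch.setattr(
            F, "fit_lms", lambda ages, y, key, config=None, sex=None: Fake(key)
        )
        cfg = FitConfig(df_grid_L=(0, 1), df_grid_M=(0,), df_grid_S=(0,))
        best, table = F.select_df(np.arange(100.0), np.ones(100), cfg)
        assert best.df_request == (0, 0, 0)


class TestExportReference:
    def test_round_trips_through_reference_io(self, boys_month_sim, tmp_path):
        ages, y, _ = boys_month_sim
        fit = fit_lms(ages, y, (1, 4, 3))
        grid = np.arange(60, 241, 6, dtype=float)
        ref_out = export_reference({"M": fit, "F": fit}, grid, name="fitted")
        path = tmp_path / "fitted.csv"
        write_reference(ref_out, str(path))
        back = load_reference(str(path), name="fitted")
        for sex in ("M", "F"):
            for p_orig, p_back in zip(ref_out.points[sex], back.points[sex]):
                assert p_back.M == pytest.approx(p_orig.M, abs=1e-4)
                assert p_back.S == pytest.approx(p_orig.S, abs=1e-4)

    def test_exported_M_close_to_printed_table(self, boys_month_sim, ref):
        ages, y, _ = boys_month_sim
        fit = fit_lms(ages, y, (1, 4, 3))
        grid = np.arange(72, 229, 6, dtype=float)
        out = export_reference({"M": fit, "F": fit}, grid)
        printed = np.array([lms_at(ref, "M", a).M for a in grid])
        got = np.array([p.M for p in out.points["M"]])
        assert np.max(np.abs(got / printed - 1)) < 0.025

    def test_unconverged_fit_refused(self, boys_month_sim):
        ages, y, _ = boys_month_sim
        fit = fit_lms(ages, y, (1, 4, 3))
        fit.converged = False
        with pytest.raises(FitError):
            export_reference({"M": fit, "F": fit}, np.array([100.0]))

    def test_grid_outside_span_rejected(self, boys_month_sim):
        ages, y, _ = boys_month_sim
        fit = fit_lms(ages, y, (1, 4, 3))
        with pytest.raises(ValueError):
            export_reference({"M": fit, "F": fit}, np.array([250.0]))
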