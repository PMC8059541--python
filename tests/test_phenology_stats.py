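"""Seasonal curve fitting, shallowing extraction, regressions, dAIC."""

import numpy as np
import pandas as pd
import pytest

from icepulse import phenology_stats as ps
from icepulse.synthetic import (SeasonScenario, generate_mass_gain,
                                generate_multiyear_sealdays, generate_sealdays)


def sealday_frame(days, depth_fn, n_seals=3, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_seals):
        for d in days:
            rows.append({"seal_id": f"s{s}", "day": float(d),
                         "mean_max_depth": depth_fn(d) + rng.normal(0, noise)})
    return pd.DataFrame(rows)


class TestSeasonalCurve:
    def test_constant_input_flat_curve(self):
        df = sealday_frame(range(40), lambda d: 150.0)
        curve = ps.fit_seasonal_curve(df)
        assert np.allclose(curve.fit, 150.0, atol=0.5)
        assert np.all(curve.hi - curve.lo < 5.0)

    def test_recovers_planted_minimum(self):
        scn = SeasonScenario(seed=31)
        sd, truth = generate_sealdays(scn)
        curve = ps.fit_seasonal_curve(sd)
        sp = ps.extract_shallow_period(curve)
        assert sp is not None
        assert abs(sp.shallowest_depth - truth["shallowest_depth"]) < 10.0
        assert abs(sp.shallowest_day - truth["shallowest_day"]) < 5.0

    def test_identical_covariates_identical_aic(self):
        scn = SeasonScenario(n_seals=4, days=60, seed=32)
        sd, _ = generate_sealdays(scn)
        a = ps.fit_seasonal_curve(sd, covariate="calendar_day")
        sd2 = sd.copy()
        sd2["arrival_day"] = 0.0
        b = ps.fit_seasonal_curve(sd2, covariate="days_since_arrival")
        assert a.aic == pytest.approx(b.aic, abs=1e-6)

    def test_depth_shift_shifts_fit(self):
        scn = SeasonScenario(n_seals=3, days=50, seed=33)
        sd, _ = generate_sealdays(scn)
        a = ps.fit_seasonal_curve(sd)
        sd2 = sd.copy()
        sd2["mean_max_depth"] += 77.0
        b = ps.fit_seasonal_curve(sd2)
        assert np.allclose(b.fit, a.fit + 77.0, atol=1e-6)

    def test_seal_relabel_invariance(self):
        scn = SeasonScenario(n_seals=3, days=50, seed=34)
        sd, _ = generate_sealdays(scn)
        a = ps.fit_seasonal_curve(sd)
        sd2 = sd.copy()
        sd2["seal_id"] = sd2["seal_id"].map(
            {"seal00": "zz", "seal01": "aa", "seal02": "mm"})
        b = ps.fit_seasonal_curve(sd2)
        assert np.allclose(a.fit, b.fit, atol=1e-8)

    def test_single_date_raises(self):
        df = sealday_frame([5], lambda d: 100.0)
        with pytest.raises(ValueError):
            ps.fit_seasonal_curve(df)

    def test_ci_brackets_fit(self):
        scn = SeasonScenario(n_seals=3, days=50, seed=35)
        sd, _ = generate_sealdays(scn)
        c = ps.fit_seasonal_curve(sd)
        assert np.all(c.lo <= c.fit) and np.all(c.fit <= c.hi)


class TestShallowPeriod:
    def test_always_deep_returns_none(self):
        df = sealday_frame(range(40), lambda d: 200.0)
        curve = ps.fit_seasonal_curve(df)
        assert ps.extract_shallow_period(curve) is None

    def test_parabola_closed_form(self):
        """Vertex (20, 100), crossing 140 m at days 10 and 30."""
        df = sealday_frame(range(41), lambda d: 100.0 + 0.4 * (d - 20.0) ** 2)
        curve = ps.fit_seasonal_curve(df, basis_dim=12)
        sp = ps.extract_shallow_period(curve, threshold_m=140.0, plateau_tol_m=0.5)
        assert sp.start_day == pytest.approx(10.0, abs=1.0)
        assert sp.end_day == pytest.approx(30.0, abs=1.0)
        assert sp.duration == pytest.approx(20.0, abs=2.0)
        assert sp.shallowest_day == pytest.approx(20.0, abs=1.0)
        assert sp.shallowest_depth == pytest.approx(100.0, abs=2.0)

    def test_matches_brute_force_scan(self):
        scn = SeasonScenario(seed=36)
        sd, _ = generate_sealdays(scn)
        curve = ps.fit_seasonal_curve(sd)
        sp = ps.extract_shallow_period(curve)
        # brute force: longest run of grid days with fit <= 140
        best, cur, runs = None, [], []
        for d, f in zip(curve.days, curve.fit):
            if f <= 140.0:
                cur.append(d)
            else:
                if cur:
                    runs.append(cur)
                cur = []
        if cur:
            runs.append(cur)
        best = max(runs, key=len)
        assert sp.start_day == best[0] and sp.end_day == best[-1]
        inside = (curve.days >= sp.start_day) & (curve.days <= sp.end_day)
        assert sp.shallowest_depth == curve.fit[inside].min()


class TestRegressions:
    def test_exact_line(self):
        x = np.array([1.0, 2, 3, 4])
        r = ps.cross_year_regression(x, 2 * x + 1)
        assert r.slope == pytest.approx(2.0)
        assert r.intercept == pytest.approx(1.0)
        assert r.r2 == pytest.approx(1.0)

    def test_matches_normal_equations(self):
        """Four points, closed-form OLS computed by hand."""
        x = np.array([10.0, 14.0, 21.0, 30.0])
        y = np.array([120.0, 131.0, 150.0, 160.0])
        n = len(x)
        sxx = (x ** 2).sum() - x.sum() ** 2 / n
        sxy = (x * y).sum() - x.sum() * y.sum() / n
        slope = sxy / sxx
        intercept = y.mean() - slope * x.mean()
        r = ps.cross_year_regression(x, y)
        assert r.slope == pytest.approx(slope)
        assert r.intercept == pytest.approx(intercept)

    def test_one_tailed_p_uniform_under_null(self):
        """Null slope at n=4: one-tailed p should look uniform."""
        rng = np.random.default_rng(8)
        ps_ = [ps.cross_year_regression(np.arange(4.0),
                                        rng.normal(0, 1, 4)).p
               for _ in range(400)]
        ps_ = np.sort(ps_)
        grid = (np.arange(400) + 0.5) / 400
        assert np.max(np.abs(ps_ - grid)) < 0.1   # KS-style bound

    def test_too_few_years_raises(self):
        with pytest.raises(ValueError):
            ps.cross_year_regression(np.array([1.0, 2.0]), np.array([1.0, 2.0]))

    def test_wiggle_depth_slope_recovery(self):
        scn = SeasonScenario(seed=37)
        sd, truth = generate_sealdays(scn)
        daily = sd.groupby("day")[["mean_max_depth", "wiggle_rate"]].mean().reset_index()
        r = ps.wiggle_depth_regression(daily)
        assert abs(r.slope - truth["wiggle_slope"]) < 2 * r.slope_se
        assert r.r2 > 0.5

    def test_shuffled_pairing_kills_slope(self):
        scn = SeasonScenario(seed=38)
        sd, _ = generate_sealdays(scn)
        daily = sd.groupby("day")[["mean_max_depth", "wiggle_rate"]].mean().reset_index()
        rng = np.random.default_rng(0)
        daily["wiggle_rate"] = rng.permutation(daily["wiggle_rate"].to_numpy())
        r = ps.wiggle_depth_regression(daily)
        lo, hi = r.slope_ci
        assert lo <= 0 <= hi

    def test_zero_variance_depth_raises(self):
        daily = pd.DataFrame({"mean_max_depth": [100.0] * 12,
                              "wiggle_rate": np.arange(12.0)})
        with pytest.raises(ValueError):
            ps.wiggle_depth_regression(daily)

    def test_ancillary_mass_gain_recovery(self):
        rng = np.random.default_rng(2)
        rates = pd.Series(rng.uniform(1.0, 3.0, 12),
                          index=[f"s{i}" for i in range(12)])
        mg = generate_mass_gain(rates, slope=0.5, intercept=0.2, sd=0.05, seed=3)
        r = ps.ancillary_regression(mg["wiggle_rate"], mg["mass_gain_kg_per_h"])
        assert abs(r.slope - 0.5) < 2 * r.slope_se
        assert r.r2 > 0.5
        # zero-slope truth covers zero
        mg0 = generate_mass_gain(rates, slope=0.0, intercept=1.0, sd=0.1, seed=4)
        r0 = ps.ancillary_regression(mg0["wiggle_rate"], mg0["mass_gain_kg_per_h"])
        lo, hi = r0.slope_ci
        assert lo <= 0 <= hi


class TestPeriodContrasts:
    @staticmethod
    def _daily(early, mid, late):
        rows = []
        for d in range(30):
            if d < 10:
                f, e = early
            elif d < 20:
                f, e = mid
            else:
                f, e = late
            rows.append({"day": float(d), "wiggle_rate": f, "efficiency": e})
        return pd.DataFrame(rows)

    @staticmethod
    def _shallow():
        return ps.ShallowPeriod(start_day=10.0, end_day=19.0, duration=9.0,
                                shallowest_day=15.0, shallowest_depth=110.0)

    def test_worked_percentages(self):
        """2.0 -> 2.32 wiggles/min is a 16 % rise."""
        out = ps.period_contrasts(self._daily((2.0, 0.30), (2.32, 0.50),
                                              (2.0, 0.40)), self._shallow())
        assert out["feeding"]["rise_pct"] == pytest.approx(16.0)
        assert out["efficiency"]["rise_pct"] == pytest.approx(66.667, abs=0.01)
        assert out["efficiency"]["fall_pct"] == pytest.approx(-20.0)

    def test_identical_periods_zero_change(self):
        out = ps.period_contrasts(self._daily((2.0, 0.4), (2.0, 0.4), (2.0, 0.4)),
                                  self._shallow())
        assert out["feeding"]["rise_pct"] == 0.0
        assert out["efficiency"]["rise_pct"] == 0.0
        assert out["compound_rise_pct"] == 0.0

    def test_planted_contrast_recovered(self):
        """Generator trajectory implies its own contrast; pipeline recovers it."""
        scn = SeasonScenario(seed=39)
        sd, truth = generate_sealdays(scn)
        daily = sd.groupby("day")[["mean_max_depth", "wiggle_rate",
                                   "efficiency"]].mean().reset_index()
        sp = ps.ShallowPeriod(start_day=truth["shallow_start_day"],
                              end_day=truth["shallow_end_day"],
                              duration=truth["shallow_duration"],
                              shallowest_day=truth["shallowest_day"],
                              shallowest_depth=truth["shallowest_depth"])
        out = ps.period_contrasts(daily, sp)
        # planted expectation from the trajectory and the wiggle regression
        mu_early = scn.trajectory(np.arange(scn.start_day, scn.start_day + 10.0))
        inside = np.arange(np.ceil(sp.start_day), sp.end_day + 1)
        mu_mid = scn.trajectory(inside)
        rate = lambda d: scn.wiggle_intercept + scn.wiggle_slope * d
        expected = 100 * (rate(mu_mid).mean() / rate(mu_early).mean() - 1)
        assert out["feeding"]["rise_pct"] == pytest.approx(expected, abs=3.0)

    def test_missing_flank_warns_partial(self):
        daily = self._daily((2.0, 0.4), (2.3, 0.5), (2.0, 0.4)).iloc[5:]
        out = ps.period_contrasts(daily, self._shallow())
        assert out["warnings"]


class TestCompareCovariates:
    arrivals = [340.0, 355.0, 345.0, 360.0]

    def test_arrival_driven_prefers_arrival(self):
        scn = SeasonScenario(n_seals=6, days=80, seed=41)
        sd, _ = generate_multiyear_sealdays(scn, self.arrivals, lag_days=5.0)
        delta = ps.compare_covariates(
            sd, {scn.year + k: a for k, a in enumerate(self.arrivals)})
        assert delta["delta_aic"].iloc[0] > 0

    def test_identical_arrivals_indifferent(self):
        scn = SeasonScenario(n_seals=4, days=60, seed=42)
        sd, _ = generate_multiyear_sealdays(scn, [350.0, 350.0], lag_days=0.0)
        delta = ps.compare_covariates(sd, {scn.year: 350.0, scn.year + 1: 350.0})
        assert abs(delta["delta_aic"].iloc[0]) < 2.0

    def test_calendar_driven_prefers_calendar(self):
        """Depth locked to the calendar while candidate arrivals vary."""
        scn = SeasonScenario(n_seals=6, days=80, seed=43)
        sd, _ = generate_multiyear_sealdays(scn, [350.0] * 4, lag_days=0.0)
        fake = {scn.year + k: a for k, a in enumerate(self.arrivals)}
        delta = ps.compare_covariates(sd, fake)
        assert delta["delta_aic"].iloc[0] < 0

    def test_single_year_raises(self):
        scn = SeasonScenario(n_seals=3, days=40, seed=44)
        sd, _ = generate_multiyear_sealdays(scn, [350.0])
        with pytest.raises(ValueError):
            ps.compare_covariates(sd, {scn.year: 350.0})
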