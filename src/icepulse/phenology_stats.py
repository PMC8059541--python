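"""Seasonal depth phenology: smooth curve fits, the shallowing period,
period contrasts and covariate (calendar vs advection-arrival) comparison.

The seasonal curve is a generalized additive mixed model: a penalized cubic
spline of seal-day mean maximum dive depth on a time covariate with a
Gaussian random intercept per seal (see :mod:`icepulse._pspline`).  The
shallowing period is the longest contiguous span of the fitted curve at or
below 140 m.  Model comparison refits the same smooth with time measured as
calendar day versus days since phytoplankton-advection arrival and reports
dAIC = AIC(calendar) - AIC(arrival); positive values favour arrival
alignment.  AICs come from the marginal ML likelihood — ML, not REML, is the
default precisely because REML likelihoods are not comparable across
fixed-effect parameterizations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._pspline import PSplineFit, fit_pspline_mixed


@dataclass
class SeasonCurve:
    days: np.ndarray          # evaluation grid (covariate units)
    fit: np.ndarray           # fitted mean depth, m
    lo: np.ndarray            # pointwise 95 % CI
    hi: np.ndarray
    seal_effects: dict        # per-seal random intercepts, m
    aic: float
    covariate: str
    model: PSplineFit


@dataclass
class ShallowPeriod:
    start_day: float
    end_day: float
    duration: float
    shallowest_day: float
    shallowest_depth: float


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    slope_se: float
    r2: float
    p: float
    n: int
    tail: str = "two"

    @property
    def slope_ci(self) -> tuple[float, float]:
        return (self.slope - 1.96 * self.slope_se, self.slope + 1.96 * self.slope_se)


def fit_seasonal_curve(
    sealdays: pd.DataFrame,
    basis_dim: int = 20,
    covariate: str = "calendar_day",
    likelihood: str = "ml",
    response: str = "mean_max_depth",
) -> SeasonCurve:
    """Penalized-spline + random-intercept fit of seal-day depth on time.

    ``covariate`` is ``calendar_day`` (the ``day`` column, day-of-year) or
    ``days_since_arrival`` (``day`` minus the per-row ``arrival_day``).  The
    fitted curve, its pointwise 95 % CI and the fit's AIC are returned; the
    curve is evaluated on integer steps over the observed covariate range
    only.
    """
    df = sealdays
    if covariate == "calendar_day":
        x = df["day"].to_numpy(float)
    elif covariate == "days_since_arrival":
        if "arrival_day" not in df.columns:
            raise ValueError("days_since_arrival needs an 'arrival_day' column")
        x = (df["day"] - df["arrival_day"]).to_numpy(float)
    else:
        raise ValueError(f"unknown covariate {covariate!r}")
    y = df[response].to_numpy(float)
    g = df["seal_id"].to_numpy()
    if np.ptp(x) == 0:
        raise ValueError("rank-deficient design: covariate has a single value")
    if df["seal_id"].nunique() < 2 or len(df) < 20 or np.ptp(x) < 30:
        warnings.warn("thin design: want >= 2 seals, >= 20 seal-days over >= 30 days")
    fit = fit_pspline_mixed(x, y, g, n_basis=basis_dim, order=4, method=likelihood)
    grid = np.arange(np.floor(x.min()), np.ceil(x.max()) + 1.0)
    f, se = fit.predict(grid, se=True)
    return SeasonCurve(days=grid, fit=f, lo=f - 1.96 * se, hi=f + 1.96 * se,
                       seal_effects=fit.group_effects, aic=fit.aic,
                       covariate=covariate, model=fit)


def extract_shallow_period(curve: SeasonCurve, threshold_m: float = 140.0,
                           plateau_tol_m: float = 5.0) -> Optional[ShallowPeriod]:
    """Longest contiguous run of the fitted curve at or below the threshold.

    Returns None if the curve never reaches the threshold.  The shallowest
    depth is the minimum of the fitted curve within the run; because a
    seasonal curve can be flat near its minimum (where an argmin is
    ill-conditioned), the shallowest date is the midpoint of the contiguous
    span within ``plateau_tol_m`` of that minimum — for a curve with a sharp
    vertex this collapses to the argmin itself.
    """
    below = curve.fit <= threshold_m
    if not below.any():
        return None
    d = np.diff(below.astype(int))
    starts = list(np.nonzero(d == 1)[0] + 1)
    ends = list(np.nonzero(d == -1)[0])
    if below[0]:
        starts.insert(0, 0)
    if below[-1]:
        ends.append(len(below) - 1)
    runs = list(zip(starts, ends))
    i0, i1 = max(runs, key=lambda r: r[1] - r[0])
    seg = slice(i0, i1 + 1)
    k = i0 + int(np.argmin(curve.fit[seg]))
    zmin = float(curve.fit[k])
    # contiguous near-minimum span around the argmin
    j0 = k
    while j0 > i0 and curve.fit[j0 - 1] <= zmin + plateau_tol_m:
        j0 -= 1
    j1 = k
    while j1 < i1 and curve.fit[j1 + 1] <= zmin + plateau_tol_m:
        j1 += 1
    return ShallowPeriod(
        start_day=float(curve.days[i0]), end_day=float(curve.days[i1]),
        duration=float(curve.days[i1] - curve.days[i0]),
        shallowest_day=float((curve.days[j0] + curve.days[j1]) / 2),
        shallowest_depth=zmin,
    )


def _ols(x: np.ndarray, y: np.ndarray, tail: str = "two") -> RegressionResult:
    X = sm.add_constant(np.asarray(x, float))
    fit = sm.OLS(np.asarray(y, float), X).fit()
    slope, se = float(fit.params[1]), float(fit.bse[1])
    if tail == "greater":
        p = float(stats.t.sf(slope / se, fit.df_resid))
    elif tail == "less":
        p = float(stats.t.cdf(slope / se, fit.df_resid))
    else:
        p = float(fit.pvalues[1])
    return RegressionResult(slope=slope, intercept=float(fit.params[0]),
                            slope_se=se, r2=float(fit.rsquared), p=p,
                            n=int(fit.nobs), tail=tail)


def cross_year_regression(dates: np.ndarray, depths: np.ndarray) -> RegressionResult:
    """OLS of per-year shallowest depth on its date (one-tailed, slope > 0).

    The one-tailed test asks whether later shallowing comes with deeper
    shallowest diving (depth measured positive downward).
    """
    if len(dates) < 3:
        raise ValueError("need at least 3 years")
    return _ols(dates, depths, tail="greater")


def wiggle_depth_regression(daily: pd.DataFrame) -> RegressionResult:
    """OLS of across-seal daily wiggle rate on daily mean maximum depth."""
    if len(daily) < 10:
        raise ValueError("need at least 10 days")
    x = daily["mean_max_depth"].to_numpy(float)
    if np.ptp(x) == 0:
        raise ValueError("zero-variance depth")
    return _ols(x, daily["wiggle_rate"].to_numpy(float))


def ancillary_regression(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    """Generic OLS utility (e.g. per-seal mass gain per hour on wiggle rate)."""
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    return _ols(x, y)


def period_contrasts(daily: pd.DataFrame, shallow: ShallowPeriod,
                     flank_days: int = 10, day_col: str = "day") -> dict:
    """Percent changes of feeding rate and efficiency across the season.

    Early-deep is the first ``flank_days`` days of the pre-shallowing data,
    late-deep the last ``flank_days`` days after it.  For each of feeding
    (wiggle) rate and diving efficiency the table reports the percent change
    early-deep -> shallow and shallow -> late-deep, plus the compound change:
    the early-deep -> shallow change of the product rate x efficiency
    (feeding per minute of total dive time), which accumulates both effects.
    """
    d = daily[day_col].to_numpy(float)
    pre = daily[d < shallow.start_day]
    mid = daily[(d >= shallow.start_day) & (d <= shallow.end_day)]
    post = daily[d > shallow.end_day]
    if mid.empty:
        raise ValueError("no data inside the shallow period")
    out: dict = {"warnings": []}
    if len(pre) < flank_days:
        out["warnings"].append("pre-period shorter than flank_days")
    if len(post) < flank_days:
        out["warnings"].append("post-period shorter than flank_days")
    early = pre.nsmallest(flank_days, day_col) if not pre.empty else pre
    late = post.nlargest(flank_days, day_col) if not post.empty else post

    def pct(a: float, b: float) -> float:
        return 100.0 * (b - a) / a

    for var, key in (("wiggle_rate", "feeding"), ("efficiency", "efficiency")):
        e = early[var].mean() if not early.empty else np.nan
        m = mid[var].mean()
        l = late[var].mean() if not late.empty else np.nan
        out[key] = {"early_deep": float(e), "shallow": float(m), "late_deep": float(l),
                    "rise_pct": pct(e, m) if np.isfinite(e) else np.nan,
                    "fall_pct": pct(m, l) if np.isfinite(l) else np.nan}
    f = out["feeding"]["rise_pct"]
    g = out["efficiency"]["rise_pct"]
    out["compound_rise_pct"] = (100.0 * ((1 + f / 100) * (1 + g / 100) - 1)
                                if np.isfinite(f) and np.isfinite(g) else np.nan)
    return out


def compare_covariates(
    sealdays: pd.DataFrame,
    arrivals: Mapping[int, float] | pd.DataFrame,
    basis_dim: int = 20,
    likelihood: str = "ml",
) -> pd.DataFrame:
    """dAIC between calendar-day and days-since-arrival depth models.

    ``arrivals`` is either a mapping year -> arrival day-of-year, or an
    advection frame with (source, velocity_km_day, year, arrival_date)
    giving one comparison per source x velocity.  dAIC > 0 means the
    arrival-aligned model explains foraging depth better than the calendar.
    """
    if sealdays["year"].nunique() < 2:
        raise ValueError("need >= 2 years: with one year the covariates are collinear")
    base = fit_seasonal_curve(sealdays, basis_dim, "calendar_day", likelihood)

    def one(arrival_by_year: Mapping[int, float]) -> float:
        df = sealdays.copy()
        df["arrival_day"] = df["year"].map(arrival_by_year)
        if df["arrival_day"].isna().any():
            raise ValueError("missing arrival day for some year")
        alt = fit_seasonal_curve(df, basis_dim, "days_since_arrival", likelihood)
        return base.aic - alt.aic

    if isinstance(arrivals, pd.DataFrame):
        rows = []
        for (src, vel), grp in arrivals.groupby(["source", "velocity_km_day"]):
            by_year = {}
            for _, r in grp.iterrows():
                if pd.isna(r["arrival_date"]):
                    continue
                ts = pd.Timestamp(r["arrival_date"])
                season_year = int(r["year"])
                doy = (ts - pd.Timestamp(season_year, 1, 1)).days + 1
                by_year[season_year] = float(doy)
            if set(by_year) < set(sealdays["year"].unique()):
                rows.append({"source": src, "velocity_km_day": vel, "delta_aic": np.nan})
                continue
            rows.append({"source": src, "velocity_km_day": vel,
                         "delta_aic": one(by_year)})
        return pd.DataFrame(rows)
    return pd.DataFrame([{"source": "given", "velocity_km_day": np.nan,
                          "delta_aic": one(dict(arrivals))}])
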