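"""Sea-ice break-out detection and phytoplankton advection timing.

Break-out at a grid cell is the first date whose trailing 7-day running mean
ice concentration drops below 50 % cover.  Phytoplankton advection travel
times from five source areas around Ross Island to the Erebus Bay study site
are path distance / current velocity, rounded to whole days, for three
published current velocities (6.5, 10.3 and 12 km/day); the resource pulse is
the 35-day bloom window that opens on the arrival date.

Path distances are great-circle (haversine).  ``mode="coastal"`` measures the
cumulative distance along the ordered chain of source areas
Northeast -> North -> Northwest -> West -> Southwest -> Erebus Bay, which is
how the break-out (and the advected bloom) actually progresses around the
island; ``mode="direct"`` is the straight great-circle line.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from datetime import date, timedelta
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0

# Source areas, in the order ice break-out progresses (anticlockwise around
# Ross Island), plus the study site.  Latitudes are degrees South (stored as
# negative), longitudes degrees East.
SOURCE_CHAIN = ("Northeast", "North", "Northwest", "West", "Southwest")

SOURCE_COORDS: dict[str, tuple[float, float]] = {
    "Northeast": (-77.24, 169.10),
    "North": (-77.20, 168.09),
    "Northwest": (-77.10, 166.09),
    "West": (-77.32, 165.84),
    "Southwest": (-77.54, 165.58),
}

STUDY_SITE = (-77.6, 167.0)  # Erebus Bay


@dataclass(frozen=True)
class SourceLocation:
    name: str
    lat: float
    lon: float


def default_sources() -> list[SourceLocation]:
    return [SourceLocation(n, *SOURCE_COORDS[n]) for n in SOURCE_CHAIN]


@dataclass
class AdvectionEstimate:
    source: str
    velocity_km_day: float
    path_km: float
    duration_days: int
    breakout_date: Optional[date]
    arrival_date: Optional[date]
    bloom_window: Optional[tuple[date, date]]
    year: Optional[int] = None


def haversine_km(a: tuple[float, float], b: tuple[float, float],
                 radius_km: float = EARTH_RADIUS_KM) -> float:
    """Great-circle distance between two (lat, lon) points in decimal degrees."""
    lat1, lon1, lat2, lon2 = map(math.radians, (*a, *b))
    dlat, dlon = lat2 - lat1, lon2 - lon1
    h = math.sin(dlat / 2) ** 2 + math.cos(lat1) * math.cos(lat2) * math.sin(dlon / 2) ** 2
    return 2 * radius_km * math.asin(min(1.0, math.sqrt(h)))


def path_km(source: str | SourceLocation, mode: str = "coastal",
            site: tuple[float, float] = STUDY_SITE) -> float:
    """Distance from a source area to the study site.

    ``coastal`` follows the break-out chain from the source through the
    remaining downstream areas and then to the site; ``direct`` is the
    straight great-circle distance.  For the last chain member (Southwest)
    the two modes coincide.
    """
    name = source.name if isinstance(source, SourceLocation) else source
    if name not in SOURCE_COORDS:
        raise KeyError(f"unknown source {name!r}; expected one of {SOURCE_CHAIN}")
    if mode == "direct":
        return haversine_km(SOURCE_COORDS[name], site)
    if mode != "coastal":
        raise ValueError("mode must be 'direct' or 'coastal'")
    idx = SOURCE_CHAIN.index(name)
    waypoints = [SOURCE_COORDS[n] for n in SOURCE_CHAIN[idx:]] + [site]
    return sum(haversine_km(a, b) for a, b in zip(waypoints[:-1], waypoints[1:]))


def advection_duration(path_km_: float, velocity_km_day: float) -> int:
    """Whole-day travel time: path / velocity, rounded to nearest, ties half up."""
    if velocity_km_day <= 0:
        raise ValueError("velocity must be positive")
    return int(math.floor(path_km_ / velocity_km_day + 0.5))


def breakout_date(series: pd.Series, window_days: int = 7,
                  threshold_pct: float = 50.0) -> Optional[pd.Timestamp]:
    """First date whose trailing ``window_days`` running mean is < threshold.

    ``series`` is daily % concentration indexed by date.  The window is
    trailing and inclusive of the reported date, so the break-out is causal:
    it could be declared in real time on the day it happens.  Windows that
    contain missing days (calendar gaps or NaN) are skipped with a warning.
    Returns None if the running mean never drops below the threshold.
    """
    if len(series) < window_days:
        raise ValueError(f"need at least {window_days} observations")
    s = series.sort_index()
    idx = pd.DatetimeIndex(s.index)
    full = pd.date_range(idx[0], idx[-1], freq="D")
    s = s.reindex(full)
    if s.isna().any():
        warnings.warn("gaps in ice series: windows containing missing days skipped")
    means = s.rolling(window_days, min_periods=window_days).mean()
    hit = means < threshold_pct
    if not hit.any():
        return None
    return pd.Timestamp(hit.idxmax())


def refreeze_dates(series: pd.Series, window_days: int = 7,
                   threshold_pct: float = 50.0) -> list[pd.Timestamp]:
    """Dates after break-out where the running mean recrosses the threshold upward.

    Diagnostic only: a transient refreeze never resets the break-out date.
    """
    b = breakout_date(series, window_days, threshold_pct)
    if b is None:
        return []
    s = series.sort_index()
    s = s.reindex(pd.date_range(s.index[0], s.index[-1], freq="D"))
    means = s.rolling(window_days, min_periods=window_days).mean()
    after = means.loc[means.index > b]
    above = after >= threshold_pct
    starts = above & ~above.shift(1, fill_value=False)
    return [pd.Timestamp(t) for t in after.index[starts]]


def advection_table(
    ice: pd.DataFrame,
    sources: Sequence[str | SourceLocation] | None = None,
    velocities: Iterable[float] = (6.5, 10.3, 12.0),
    mode: str = "coastal",
    window_days: int = 7,
    threshold_pct: float = 50.0,
    bloom_days: int = 35,
) -> list[AdvectionEstimate]:
    """Break-out, travel time, arrival and bloom window per source x velocity x year.

    ``ice`` is long format with columns (date, cell_id, concentration); cell_id
    must name the source areas.  Years are taken from the break-out year of
    each cell's series split at 1 July (austral summer spans new year).
    """
    if sources is None:
        sources = list(SOURCE_CHAIN)
    names = [s.name if isinstance(s, SourceLocation) else s for s in sources]
    ice = ice.copy()
    ice["date"] = pd.to_datetime(ice["date"])
    # austral season label: Jul-Jun, labelled by the July year
    season = ice["date"].dt.year.where(ice["date"].dt.month >= 7,
                                       ice["date"].dt.year - 1)
    ice["season"] = season
    out: list[AdvectionEstimate] = []
    for name in names:
        cell = ice[ice["cell_id"] == name]
        if cell.empty:
            raise KeyError(f"no ice data for cell {name!r}")
        dist = path_km(name, mode=mode)
        for yr, grp in cell.groupby("season"):
            series = grp.set_index("date")["concentration"]
            b = breakout_date(series, window_days, threshold_pct)
            for v in velocities:
                dur = advection_duration(dist, v)
                if b is None:
                    out.append(AdvectionEstimate(name, v, dist, dur, None, None,
                                                 None, year=int(yr)))
                else:
                    arrival = (b + timedelta(days=dur)).date()
                    bloom = (arrival, arrival + timedelta(days=bloom_days))
                    out.append(AdvectionEstimate(name, v, dist, dur, b.date(),
                                                 arrival, bloom, year=int(yr)))
    return out


def advection_frame(estimates: Sequence[AdvectionEstimate]) -> pd.DataFrame:
    rows = []
    for e in estimates:
        rows.append({
            "source": e.source, "year": e.year, "velocity_km_day": e.velocity_km_day,
            "path_km": e.path_km, "duration_days": e.duration_days,
            "breakout_date": e.breakout_date, "arrival_date": e.arrival_date,
            "bloom_start": e.bloom_window[0] if e.bloom_window else None,
            "bloom_end": e.bloom_window[1] if e.bloom_window else None,
        })
    return pd.DataFrame(rows)


def min_travel_days(velocity_km_day: float, mode: str = "coastal") -> int:
    """Minimum whole-day travel time across the five source areas."""
    return min(advection_duration(path_km(n, mode=mode), velocity_km_day)
               for n in SOURCE_CHAIN)
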