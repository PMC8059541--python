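"""Dive segmentation and per-dive metrics from 6-s depth records.

A depth record is a two-column frame (timestamp, depth_m) per seal.  The
stages are the classical TDR chain: zero-offset correction, dive detection,
bottom-phase extraction (depth >= 80 % of the dive's maximum), wiggle
counting inside the bottom phase, a benthic/pelagic classification, and
aggregation to per-seal-day summaries with benthic dives excluded.

A "wiggle" is a vertical direction reversal toward the surface — a local
minimum of depth within the bottom phase — whose ascending and subsequent
descending limbs each span at least ``min_excursion`` metres (default 1 m,
twice the sensor resolution, which suppresses quantization chatter).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .params import Params


@dataclass
class Dive:
    seal_id: str
    start_time: pd.Timestamp
    end_time: pd.Timestamp
    max_depth: float
    duration: float
    bottom_start: pd.Timestamp
    bottom_end: pd.Timestamp
    bottom_duration: float
    n_wiggles: int
    dive_class: Optional[str] = None


def zero_offset_correct(record: pd.DataFrame, window: str = "2h",
                        shallow_m: float = 10.0) -> pd.DataFrame:
    """Remove pressure-sensor surface drift.

    The offset is the rolling 10th percentile (time-based window, default
    2 h) of readings shallower than ``shallow_m``, interpolated over the
    whole record, subtracted, with negatives clamped to zero.  A record with
    no shallow readings is returned unchanged with a warning.
    """
    if record.empty:
        raise ValueError("empty depth record")
    out = record.copy()
    depth = out["depth_m"].to_numpy(float)
    t = pd.DatetimeIndex(out["timestamp"])
    shallow = pd.Series(np.where(depth < shallow_m, depth, np.nan), index=t)
    if shallow.notna().sum() == 0:
        warnings.warn("no near-surface samples: zero-offset correction skipped")
        return out
    offset = shallow.rolling(window, min_periods=1).quantile(0.10)
    offset = offset.interpolate(method="time").bfill().ffill()
    out["depth_m"] = np.maximum(depth - offset.to_numpy(), 0.0)
    return out


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [i0, i1] index runs where mask is True (inclusive ends)."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(int))
    starts = list(np.nonzero(d == 1)[0] + 1)
    ends = list(np.nonzero(d == -1)[0])
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask) - 1)
    return list(zip(starts, ends))


def detect_dives(record: pd.DataFrame, min_depth: float = 10.0,
                 min_duration: float = 30.0, surface_threshold: float = 2.0,
                 gap_factor: float = 2.0) -> list[tuple[int, int]]:
    """Index intervals (inclusive) of dives in a corrected record.

    A dive is a maximal run of samples deeper than ``surface_threshold``
    reaching at least ``min_depth`` and lasting at least ``min_duration``
    seconds, extended to the adjacent surface samples when present.  Time
    gaps larger than ``gap_factor`` times the nominal step split a run
    (instrument dropouts are never interpolated across).
    """
    depth = record["depth_m"].to_numpy(float)
    t = pd.DatetimeIndex(record["timestamp"]).asi8 / 1e9
    if len(depth) < 2:
        return []
    step = float(np.median(np.diff(t)))
    out = []
    for i0, i1 in _runs(depth > surface_threshold):
        # split at gaps
        cuts = [i0]
        gaps = np.nonzero(np.diff(t[i0:i1 + 1]) > gap_factor * step)[0]
        for g in gaps:
            cuts.extend([i0 + g, i0 + g + 1])
        cuts.append(i1)
        for a, b in zip(cuts[::2], cuts[1::2]):
            # extend to bounding surface samples
            a_ext = a - 1 if a > 0 and depth[a - 1] <= surface_threshold \
                and t[a] - t[a - 1] <= gap_factor * step else a
            b_ext = b + 1 if b < len(depth) - 1 and depth[b + 1] <= surface_threshold \
                and t[b + 1] - t[b] <= gap_factor * step else b
            if depth[a:b + 1].max() >= min_depth and t[b_ext] - t[a_ext] >= min_duration:
                out.append((a_ext, b_ext))
    return out


def compute_bottom_phase(times: np.ndarray, depths: np.ndarray,
                         bottom_fraction: float = 0.8) -> tuple[int, int, float]:
    """Bottom interval: first to last sample at >= fraction * max depth.

    Returns (index_start, index_end, duration_seconds); a single qualifying
    sample yields a zero-length interval.
    """
    if len(depths) < 3:
        raise ValueError("dive needs at least 3 samples")
    depths = np.asarray(depths, float)
    thresh = bottom_fraction * depths.max()
    qual = np.nonzero(depths >= thresh)[0]
    i0, i1 = int(qual[0]), int(qual[-1])
    return i0, i1, float(times[i1] - times[i0])


def count_wiggles(depths: np.ndarray, min_excursion: float = 1.0) -> int:
    """Wiggles in a bottom-phase depth profile.

    Counts local minima of depth (reversals toward the surface) whose
    preceding ascent and following descent both span >= ``min_excursion``.
    A monotone traverse counts zero.
    """
    d = np.asarray(depths, float)
    if len(d) < 3:
        return 0
    # compress plateaus so turning points are well defined
    keep = np.concatenate([[True], np.diff(d) != 0])
    d = d[keep]
    if len(d) < 3:
        return 0
    sign = np.sign(np.diff(d))
    turns = np.nonzero(sign[1:] != sign[:-1])[0] + 1   # indices of local extrema
    extremes = np.concatenate([[0], turns, [len(d) - 1]])
    count = 0
    for k in range(1, len(extremes) - 1):
        i = extremes[k]
        prev_i, next_i = extremes[k - 1], extremes[k + 1]
        if d[i] < d[prev_i] and d[i] < d[next_i]:       # local depth minimum
            if d[prev_i] - d[i] >= min_excursion and d[next_i] - d[i] >= min_excursion:
                count += 1
    return count


def process_record(record: pd.DataFrame, seal_id: str,
                   params: Params | None = None) -> pd.DataFrame:
    """Full per-record chain: detect dives and fill every per-dive metric."""
    p = params or Params()
    idx = detect_dives(record, p.min_dive_depth_m, p.min_dive_duration_s,
                       p.surface_threshold_m, p.gap_factor)
    t = pd.DatetimeIndex(record["timestamp"])
    tsec = t.asi8 / 1e9
    depth = record["depth_m"].to_numpy(float)
    rows = []
    for a, b in idx:
        seg_t, seg_d = tsec[a:b + 1], depth[a:b + 1]
        i0, i1, bdur = compute_bottom_phase(seg_t, seg_d, p.bottom_fraction)
        wig = count_wiggles(seg_d[i0:i1 + 1], p.wiggle_min_excursion_m)
        # flatness for the benthic rule is judged on the bottom core (>= 95 %
        # of max depth) so descent/ascent shoulder samples inside the 80 %
        # zone do not swamp the signal
        core = seg_d[seg_d >= 0.95 * seg_d.max()]
        cv = float(np.std(core) / np.mean(core)) if core.mean() > 0 else np.nan
        rows.append({
            "seal_id": seal_id,
            "start_time": t[a], "end_time": t[b],
            "max_depth": float(seg_d.max()),
            "duration": float(seg_t[-1] - seg_t[0]),
            "bottom_start": t[a + i0], "bottom_end": t[a + i1],
            "bottom_duration": bdur,
            "n_wiggles": wig,
            "bottom_cv": cv,
        })
    return pd.DataFrame(rows)


def classify_dives(dives: pd.DataFrame, params: Params | None = None) -> pd.DataFrame:
    """Benthic/pelagic classification against the seal's rolling depth ceiling.

    A dive is benthic iff its maximum depth reaches ``benthic_depth_ratio``
    of the seal's trailing 7-day maximum depth AND its bottom-phase depth
    coefficient of variation is at most ``benthic_cv_max`` (a flat bottom).
    Dives with under one day of history are pelagic with ``history_ok=False``.
    """
    p = params or Params()
    out = dives.copy().sort_values(["seal_id", "start_time"]).reset_index(drop=True)
    out["dive_class"] = "pelagic"
    out["history_ok"] = True
    for seal, grp in out.groupby("seal_id"):
        ts = pd.DatetimeIndex(grp["start_time"])
        md = grp["max_depth"].to_numpy()
        roll = pd.Series(md, index=ts).rolling(f"{p.benthic_window_days}D").max()
        history = (ts - ts[0]) >= pd.Timedelta(days=1)
        benthic = (md >= p.benthic_depth_ratio * roll.to_numpy()) \
            & (grp["bottom_cv"].to_numpy() <= p.benthic_cv_max) & history
        out.loc[grp.index[benthic], "dive_class"] = "benthic"
        out.loc[grp.index[~history], "history_ok"] = False
    return out


def benthic_depth_trend(benthic_dives: pd.DataFrame) -> dict:
    """Random-intercept linear trend of benthic maximum depth on date.

    Returns slope (m/day), its SE, 95 % CI and whether the CI covers zero —
    the check that benthic (seabed) depths are stable across the season,
    i.e. that the seals kept foraging over the same ground.
    """
    df = benthic_dives.copy()
    if df["seal_id"].nunique() < 2 or len(df) < 10:
        raise ValueError("need >= 2 seals and >= 10 benthic dives")
    t0 = pd.Timestamp(df["start_time"].min())
    df["day"] = (pd.to_datetime(df["start_time"]) - t0).dt.total_seconds() / 86400.0
    if df["day"].nunique() < 2:
        raise ValueError("degenerate design: all dives on one date")
    model = smf.mixedlm("max_depth ~ day", df, groups=df["seal_id"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=True)
    slope = float(fit.params["day"])
    se = float(fit.bse["day"])
    lo, hi = slope - 1.96 * se, slope + 1.96 * se
    return {"slope": slope, "se": se, "ci": (lo, hi), "covers_zero": lo <= 0 <= hi,
            "n_dives": len(df), "n_seals": int(df["seal_id"].nunique())}


def daily_summaries(dives: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seal-day summaries (pelagic dives only) and the across-seal daily mean.

    Wiggle rate is total wiggles over total bottom minutes for the seal-day;
    efficiency is the dive-averaged bottom_duration / duration.  The
    across-seal table averages seal-day values per calendar (UTC) day, so
    each seal contributes one point per day regardless of dive count.
    """
    if "dive_class" not in dives.columns:
        raise ValueError("dives must be classified first")
    pel = dives[dives["dive_class"] == "pelagic"].copy()
    pel["date"] = pd.to_datetime(pel["start_time"]).dt.date
    pel["eff"] = pel["bottom_duration"] / pel["duration"]

    def agg(grp: pd.DataFrame) -> pd.Series:
        bottom_min = grp["bottom_duration"].sum() / 60.0
        return pd.Series({
            "mean_max_depth": grp["max_depth"].mean(),
            "n_dives": len(grp),
            "wiggle_rate": grp["n_wiggles"].sum() / bottom_min if bottom_min > 0 else 0.0,
            "efficiency": grp["eff"].mean(),
        })

    sealdays = (pel.groupby(["seal_id", "date"]).apply(agg, include_groups=False)
                .reset_index())
    daily = (sealdays.groupby("date")[["mean_max_depth", "wiggle_rate", "efficiency"]]
             .mean().reset_index()
             .merge(sealdays.groupby("date")["n_dives"].sum().rename("n_dives"),
                    on="date"))
    return sealdays, daily
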