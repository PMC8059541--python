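"""Dive segmentation and metrics against independent brute-force oracles."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from icepulse import dive_processing as dp
from icepulse.synthetic import SAMPLE_S


def make_record(depths, step_s=SAMPLE_S, start="2016-11-01"):
    t = pd.date_range(start, periods=len(depths), freq=f"{int(step_s)}s")
    return pd.DataFrame({"timestamp": t, "depth_m": np.asarray(depths, float)})


def triangle_dive(depth, rate=1.0, step_s=SAMPLE_S):
    """V-shaped dive profile at constant vertical rate, no flat bottom."""
    down = np.arange(step_s * rate, depth, step_s * rate)
    return np.concatenate([[0.0], down, [depth], down[::-1], [0.0]])


# --- independent oracles -----------------------------------------------------

def wiggle_oracle(depths, exc=1.0):
    """Count local depth minima with both limbs >= exc (plain loop)."""
    xs = [depths[0]]
    for v in depths[1:]:
        if v != xs[-1]:
            xs.append(v)
    n = 0
    for i in range(1, len(xs) - 1):
        if xs[i] < xs[i - 1] and xs[i] < xs[i + 1]:
            j = i
            while j > 0 and xs[j - 1] > xs[j]:
                j -= 1
            k = i
            while k < len(xs) - 1 and xs[k + 1] > xs[k]:
                k += 1
            if xs[j] - xs[i] >= exc and xs[k] - xs[i] >= exc:
                n += 1
    return n


def dive_oracle(depths, step_s=SAMPLE_S, min_depth=10.0, min_dur=30.0, surf=2.0):
    """Single-pass scan for dive intervals (inclusive indices)."""
    out, i, n = [], 0, len(depths)
    while i < n:
        if depths[i] > surf:
            j = i
            while j + 1 < n and depths[j + 1] > surf:
                j += 1
            a = i - 1 if i > 0 and depths[i - 1] <= surf else i
            b = j + 1 if j + 1 < n and depths[j + 1] <= surf else j
            if max(depths[i:j + 1]) >= min_depth and (b - a) * step_s >= min_dur:
                out.append((a, b))
            i = j + 1
        else:
            i += 1
    return out


def bottom_oracle(depths, frac=0.8):
    dmax = max(depths)
    qual = [i for i, d in enumerate(depths) if d >= frac * dmax]
    return qual[0], qual[-1]


# --- zero-offset correction --------------------------------------------------

class TestZeroOffset:
    def test_constant_offset_removed(self):
        prof = np.concatenate([np.full(200, 2.0), triangle_dive(100) + 2.0,
                               np.full(200, 2.0)])
        rec = make_record(prof)
        out = dp.zero_offset_correct(rec)
        surface = out["depth_m"].to_numpy()[:200]
        assert np.abs(surface).max() <= 0.5
        assert out["depth_m"].max() == pytest.approx(100.0, abs=0.5)

    def test_linear_drift_removed(self):
        """0 -> 3 m drift over 24 h leaves surface bias under 0.5 m."""
        n = int(24 * 3600 / SAMPLE_S)
        rng = np.random.default_rng(0)
        depth = np.zeros(n)
        # a dive every hour
        for h in range(0, 24):
            prof = triangle_dive(80)
            k = int(h * 3600 / SAMPLE_S)
            depth[k:k + len(prof)] = prof[:max(0, min(len(prof), n - k))]
        drift = np.linspace(0, 3, n)
        rec = make_record(np.round((depth + drift) * 2) / 2)
        out = dp.zero_offset_correct(rec)
        surface = out["depth_m"].to_numpy()[depth == 0]
        assert np.abs(np.mean(surface)) < 0.5

    def test_clean_series_unchanged(self):
        prof = np.concatenate([np.zeros(100), triangle_dive(60), np.zeros(100)])
        rec = make_record(prof)
        out = dp.zero_offset_correct(rec)
        assert np.abs(out["depth_m"] - rec["depth_m"]).max() <= 0.5

    def test_all_deep_record_warns_and_skips(self):
        rec = make_record(np.full(300, 150.0))
        with pytest.warns(UserWarning):
            out = dp.zero_offset_correct(rec)
        assert (out["depth_m"] == 150.0).all()


# --- dive detection ----------------------------------------------------------

class TestDetectDives:
    def test_single_trapezoid(self):
        prof = np.concatenate([np.zeros(10), triangle_dive(120), np.zeros(10)])
        rec = make_record(prof)
        dives = dp.detect_dives(rec)
        assert len(dives) == 1
        a, b = dives[0]
        assert prof[a:b + 1].max() == 120.0

    def test_two_dives_split_by_surface(self):
        surf = np.zeros(10)
        prof = np.concatenate([surf, triangle_dive(50), surf, triangle_dive(70), surf])
        rec = make_record(prof)
        assert len(dp.detect_dives(rec)) == 2

    def test_all_shallow_gives_empty(self):
        rec = make_record(np.full(100, 5.0))
        assert dp.detect_dives(rec) == []

    def test_gap_splits_dive(self):
        prof = triangle_dive(100)
        t = pd.date_range("2016-11-01", periods=len(prof), freq="6s")
        t = t.to_numpy()
        t[len(prof) // 2:] += np.timedelta64(120, "s")  # dropout mid-dive
        rec = pd.DataFrame({"timestamp": t, "depth_m": prof})
        assert len(dp.detect_dives(rec)) == 2

    def test_matches_oracle_on_random_series(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            segs = []
            for _ in range(rng.integers(1, 6)):
                segs.append(np.zeros(rng.integers(1, 15)))
                segs.append(triangle_dive(float(rng.uniform(3, 150))))
            prof = np.round(np.concatenate(segs) * 2) / 2
            rec = make_record(prof)
            assert dp.detect_dives(rec) == dive_oracle(prof)


# --- bottom phase ------------------------------------------------------------

class TestBottomPhase:
    def test_triangular_closed_form(self):
        """V-dive to 120 m at 1 m/s: samples >= 96 m span ~48 s."""
        prof = triangle_dive(120)
        t = np.arange(len(prof)) * SAMPLE_S
        i0, i1, dur = dp.compute_bottom_phase(t, prof)
        assert prof[i0 - 1] < 96.0 <= prof[i0]
        assert abs(dur - 48.0) <= SAMPLE_S

    def test_flat_bottom_duration(self):
        prof = np.concatenate([triangle_dive(100)[:18], np.full(10, 100.0),
                               triangle_dive(100)[18:]])
        t = np.arange(len(prof)) * SAMPLE_S
        _, _, dur = dp.compute_bottom_phase(t, prof)
        assert dur >= 60.0

    def test_single_apex_zero_length(self):
        prof = np.array([0.0, 50.0, 100.0, 50.0, 0.0])
        t = np.arange(5) * SAMPLE_S
        i0, i1, dur = dp.compute_bottom_phase(t, prof)
        assert i0 == i1 == 2 and dur == 0.0

    def test_matches_oracle_on_random_profiles(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            prof = np.round(rng.uniform(10, 200, rng.integers(3, 60)) * 2) / 2
            t = np.arange(len(prof)) * SAMPLE_S
            i0, i1, _ = dp.compute_bottom_phase(t, prof)
            assert (i0, i1) == bottom_oracle(prof)


# --- wiggles -----------------------------------------------------------------

class TestWiggles:
    def test_v_dive_has_none(self):
        assert dp.count_wiggles(triangle_dive(120)) == 0

    def test_worked_sequence(self):
        assert dp.count_wiggles(np.array([100, 98, 100, 97, 100.0])) == 2

    def test_quantization_jitter_suppressed(self):
        d = np.array([100, 99.5, 100, 99.5, 100, 99.5, 100.0])
        assert dp.count_wiggles(d) == 0

    def test_offset_invariance(self):
        d = np.array([100, 98, 100, 97, 100.0])
        assert dp.count_wiggles(d) == dp.count_wiggles(d + 57.0)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.lists(st.integers(min_value=0, max_value=12), min_size=3, max_size=40))
    def test_matches_oracle(self, halves):
        depths = 100.0 + np.array(halves) * 0.5
        assert dp.count_wiggles(depths) == wiggle_oracle(depths)


# --- classification ----------------------------------------------------------

class TestClassification:
    def test_planted_benthic_fraction_recovered(self, processed_dives):
        dives, truth = processed_dives
        frac = (dives["dive_class"] == "benthic").mean()
        assert 0.002 <= frac <= 0.03  # ~1 % planted
        ok = dives["history_ok"].to_numpy()
        agree = (dives.loc[ok, "dive_class"].to_numpy()
                 == truth.loc[ok, "dive_class"].to_numpy())
        assert agree.mean() > 0.97

    def test_rule_flat_deep_is_benthic_midwater_is_pelagic(self):
        rows = []
        t0 = pd.Timestamp("2016-11-01")
        for d in range(9):
            for k in range(3):
                rows.append({"seal_id": "s", "start_time": t0 + pd.Timedelta(days=d, hours=k),
                             "max_depth": 200.0, "bottom_cv": 0.05})
        rows.append({"seal_id": "s", "start_time": t0 + pd.Timedelta(days=8, hours=5),
                     "max_depth": 400.0, "bottom_cv": 0.0})   # flat, at ceiling
        rows.append({"seal_id": "s", "start_time": t0 + pd.Timedelta(days=8, hours=6),
                     "max_depth": 240.0, "bottom_cv": 0.0})   # 60 % of ceiling
        out = dp.classify_dives(pd.DataFrame(rows))
        out = out.sort_values("start_time").reset_index(drop=True)
        assert out.loc[len(out) - 2, "dive_class"] == "benthic"
        assert out.loc[len(out) - 1, "dive_class"] == "pelagic"

    def test_insufficient_history_flagged_pelagic(self):
        t0 = pd.Timestamp("2016-11-01")
        df = pd.DataFrame([{"seal_id": "s", "start_time": t0,
                            "max_depth": 300.0, "bottom_cv": 0.0}])
        out = dp.classify_dives(df)
        assert out.loc[0, "dive_class"] == "pelagic"
        assert not out.loc[0, "history_ok"]


# --- benthic trend -----------------------------------------------------------

class TestBenthicTrend:
    @staticmethod
    def _benthic_frame(slope, n_seals=4, days=30, seed=0):
        rng = np.random.default_rng(seed)
        t0 = pd.Timestamp("2016-11-01")
        rows = []
        for s in range(n_seals):
            b0 = 380 + rng.normal(0, 10)
            for d in range(days):
                rows.append({"seal_id": f"s{s}",
                             "start_time": t0 + pd.Timedelta(days=d),
                             "max_depth": b0 + slope * d + rng.normal(0, 4)})
        return pd.DataFrame(rows)

    def test_flat_depths_cover_zero(self):
        res = dp.benthic_depth_trend(self._benthic_frame(0.0, seed=1))
        assert res["covers_zero"]

    def test_injected_trend_recovered(self):
        res = dp.benthic_depth_trend(self._benthic_frame(0.5, seed=2))
        assert abs(res["slope"] - 0.5) < 2 * res["se"]
        assert not res["covers_zero"]

    def test_degenerate_design_raises(self):
        df = self._benthic_frame(0.0, days=1)
        with pytest.raises(ValueError):
            dp.benthic_depth_trend(df)


# --- daily summaries ---------------------------------------------------------

class TestDailySummaries:
    def test_arithmetic(self):
        t0 = pd.Timestamp("2016-11-01 03:00")
        dives = pd.DataFrame([
            {"seal_id": "s", "start_time": t0, "max_depth": 100.0,
             "duration": 600.0, "bottom_duration": 60.0, "n_wiggles": 3,
             "dive_class": "pelagic"},
            {"seal_id": "s", "start_time": t0 + pd.Timedelta(hours=1),
             "max_depth": 200.0, "duration": 600.0, "bottom_duration": 60.0,
             "n_wiggles": 0, "dive_class": "pelagic"},
        ])
        sealdays, daily = dp.daily_summaries(dives)
        assert sealdays.loc[0, "mean_max_depth"] == 150.0
        assert sealdays.loc[0, "wiggle_rate"] == pytest.approx(3 / 2.0)  # 3 per 2 min
        assert sealdays.loc[0, "efficiency"] == pytest.approx(0.1)
        assert daily.loc[0, "mean_max_depth"] == 150.0

    def test_benthic_excluded(self):
        t0 = pd.Timestamp("2016-11-01")
        dives = pd.DataFrame([
            {"seal_id": "s", "start_time": t0, "max_depth": 100.0,
             "duration": 600.0, "bottom_duration": 60.0, "n_wiggles": 1,
             "dive_class": "pelagic"},
            {"seal_id": "s", "start_time": t0, "max_depth": 400.0,
             "duration": 600.0, "bottom_duration": 300.0, "n_wiggles": 0,
             "dive_class": "benthic"},
        ])
        sealdays, _ = dp.daily_summaries(dives)
        assert sealdays.loc[0, "mean_max_depth"] == 100.0
        assert sealdays.loc[0, "n_dives"] == 1

    def test_pipeline_matches_generator_truth(self, processed_dives):
        """Summaries built from detected dives equal those from planted truth."""
        dives, truth = processed_dives
        ok = dives["history_ok"].to_numpy()
        det = dives.loc[ok]
        sd_det, _ = dp.daily_summaries(det)
        tr = truth.loc[ok].copy()
        tr["duration"] = (pd.to_datetime(tr["end_time"])
                          - pd.to_datetime(tr["start_time"])).dt.total_seconds()
        tr["bottom_duration"] = (pd.to_datetime(tr["bottom_end"])
                                 - pd.to_datetime(tr["bottom_start"])).dt.total_seconds()
        sd_tr, _ = dp.daily_summaries(tr)
        merged = sd_det.merge(sd_tr, on=["seal_id", "date"], suffixes=("_d", "_t"))
        assert np.allclose(merged["mean_max_depth_d"], merged["mean_max_depth_t"],
                           atol=1.0)
        assert np.allclose(merged["wiggle_rate_d"], merged["wiggle_rate_t"], atol=0.05)

    def test_efficiency_bounded(self, processed_dives):
        dives, _ = processed_dives
        eff = dives["bottom_duration"] / dives["duration"]
        assert ((eff >= 0) & (eff <= 1)).all()


class TestInvariances:
    def test_concatenation_invariance(self):
        """Processing two halves split at a surface gap equals whole-record."""
        surf = np.zeros(20)
        prof = np.concatenate([surf, triangle_dive(80), surf,
                               triangle_dive(120), surf])
        rec = make_record(prof)
        whole = dp.process_record(rec, "s")
        cut = 20 + len(triangle_dive(80)) + 10   # inside the middle surface gap
        h1 = dp.process_record(rec.iloc[:cut].reset_index(drop=True), "s")
        h2 = dp.process_record(rec.iloc[cut:].reset_index(drop=True), "s")
        both = pd.concat([h1, h2], ignore_index=True)
        assert len(both) == len(whole)
        assert np.allclose(both["max_depth"], whole["max_depth"])
        assert (both["n_wiggles"] == whole["n_wiggles"]).all()

    def test_time_shift_invariance(self):
        prof = np.concatenate([np.zeros(5), triangle_dive(90), np.zeros(5)])
        a = dp.process_record(make_record(prof, start="2016-11-01"), "s")
        b = dp.process_record(make_record(prof, start="2017-01-15"), "s")
        assert np.allclose(a["max_depth"], b["max_depth"])
        assert np.allclose(a["bottom_duration"], b["bottom_duration"])
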