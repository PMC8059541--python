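"""End-to-end orchestration: simulate -> dives -> captures -> ice -> phenology -> isotopes.

A run is described by one YAML config (flat, one section per stage) plus a
seed; all randomness flows from that seed.  Each stage reads the standard
files the previous stages wrote, so stages can also be run independently on
real data dropped into the same layout.  Any stage failure raises
:class:`StageError` naming the stage, and partial outputs are moved to a
``quarantine/`` directory.  A manifest records parameters, seed, software
version, per-stage row counts and a content hash of every output file.
"""

from __future__ import annotations

import dataclasses
import logging
import shutil
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import dive_processing as dp
from . import ice_phenology as ice
from . import io as iio
from . import isotope_mixing as im
from . import phenology_stats as ps
from . import prey_capture as pc
from . import synthetic as syn
from .params import Params

log = logging.getLogger("icepulse")

STAGES = ("simulate", "dives", "captures", "ice", "phenology", "isotopes")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _doy(dates: pd.Series) -> pd.Series:
    """Continuous day-of-year anchored at 1 Jan of the earliest year."""
    d = pd.to_datetime(dates)
    anchor = pd.Timestamp(int(d.dt.year.min()), 1, 1)
    return (d - anchor).dt.total_seconds() / 86400.0 + 1.0


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> dict:
    """Execute the configured stages; returns the manifest dictionary."""
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text()) or {}
    out = Path(out_dir or config.get("out", "icepulse_run"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    params = Params.from_dict(config.get("params", {}))
    stages = config.get("stages", list(STAGES))
    manifest: dict = {"version": __version__, "seed": seed,
                      "params": params.to_dict(), "stages": {}, "files": {}}
    try:
        for stage in stages:
            if stage not in STAGES:
                raise StageError(stage, ValueError("unknown stage"))
            log.info("stage %s", stage)
            try:
                counts = _STAGE_FUNCS[stage](config.get(stage, {}) or {},
                                             out, seed, params)
            except StageError:
                raise
            except Exception as e:  # noqa: BLE001 - re-raised labelled
                raise StageError(stage, e) from e
            manifest["stages"][stage] = counts
    except StageError:
        q = out / "quarantine"
        q.mkdir(exist_ok=True)
        for f in out.iterdir():
            if f.is_file():
                shutil.move(str(f), q / f.name)
        raise
    for f in sorted(out.rglob("*")):
        if f.is_file() and f.name != "manifest.json":
            manifest["files"][str(f.relative_to(out))] = iio.sha256(f)
    iio.write_json(manifest, out / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# stages

def _stage_simulate(cfg: dict, out: Path, seed: int, params: Params) -> dict:
    scn = syn.SeasonScenario(**{**{"seed": seed}, **cfg.get("scenario", {})})
    records, dive_truth = syn.generate_tdr(scn)
    iio.write_tdr(records, out)
    dive_truth.to_csv(out / "truth_dives.csv", index=False)

    accel_cfg = cfg.get("accel", {})
    seal0 = sorted(records)[0]
    sub = dive_truth[dive_truth["seal_id"] == seal0]
    n_dives = int(accel_cfg.get("n_dives", 20))
    accel, ev_truth = syn.generate_accel(sub.head(n_dives),
                                         capture_rate=accel_cfg.get("capture_rate"),
                                         seed=seed + 1)
    iio.write_accel(accel, out / f"accel_{seal0}.csv")
    ev_truth.to_csv(out / "truth_captures.csv", index=False)

    ice_cfg = cfg.get("ice", {})
    breakouts = ice_cfg.get("breakout_days") or syn.default_ice_scenario(
        year=scn.year, first_day=float(ice_cfg.get("first_day", 330.0)))
    ice_df, ice_truth = syn.generate_ice(breakouts, year=scn.year,
                                         refreeze=ice_cfg.get("refreeze"))
    iio.write_ice_csv(ice_df, out / "ice.csv")

    iso_cfg = cfg.get("isotopes", {})
    whiskers, consumers, iso_truth = syn.generate_isotopes(
        n_seals=int(iso_cfg.get("n_seals", 9)),
        n_segments=int(iso_cfg.get("n_segments", 5)),
        trend_per_day=tuple(iso_cfg.get("trend_per_day", (0.0, 0.0))),
        seed=seed + 2, year=scn.year)
    whiskers.to_csv(out / "whiskers.csv", index=False)
    consumers.to_csv(out / "consumers.csv", index=False)
    syn.DEFAULT_SOURCES.to_csv(out / "sources.csv", index=False)

    iio.write_json({"scenario": dataclasses.asdict(scn), "ice": ice_truth,
                    "isotopes": iso_truth, "season": scn.truth()},
                   out / "truth.json")
    return {"seals": len(records), "dives": len(dive_truth),
            "capture_events": len(ev_truth), "ice_rows": len(ice_df),
            "whisker_segments": len(whiskers)}


def _stage_dives(cfg: dict, out: Path, seed: int, params: Params) -> dict:
    records = iio.read_tdr(Path(cfg.get("in", out)))
    frames = []
    for seal, rec in sorted(records.items()):
        rec = dp.zero_offset_correct(rec)
        frames.append(dp.process_record(rec, seal, params))
    dives = pd.concat(frames, ignore_index=True)
    dives = dp.classify_dives(dives, params)
    dives.to_csv(out / "dives.csv", index=False,
                 date_format="%Y-%m-%dT%H:%M:%SZ")
    sealdays, daily = dp.daily_summaries(dives)
    sealdays.to_csv(out / "sealdays.csv", index=False)
    daily.to_csv(out / "daily.csv", index=False)
    return {"dives": len(dives),
            "benthic": int((dives["dive_class"] == "benthic").sum()),
            "sealdays": len(sealdays), "days": len(daily)}


def _stage_captures(cfg: dict, out: Path, seed: int, params: Params) -> dict:
    accel_files = sorted(Path(cfg.get("in", out)).glob("accel_*.csv"))
    if not accel_files:
        raise FileNotFoundError("no accel_*.csv found")
    dives = pd.read_csv(out / "dives.csv",
                        parse_dates=["start_time", "end_time",
                                     "bottom_start", "bottom_end"])
    all_events = []
    for f in accel_files:
        seal = f.stem.removeprefix("accel_")
        rec = iio.read_accel(f)
        filt = pc.highpass_surge(rec, params.highpass_cutoff_hz)
        ev = pc.detect_prey_captures(filt, params.capture_threshold_g,
                                     params.capture_refractory_s)
        ev["seal_id"] = seal
        ev = pc.assign_events_to_dives(ev, dives[dives["seal_id"] == seal])
        all_events.append(ev)
    events = pd.concat(all_events, ignore_index=True)
    events.to_csv(out / "events.csv", index=False,
                  date_format="%Y-%m-%dT%H:%M:%S.%fZ")
    return {"events": len(events)}


def _stage_ice(cfg: dict, out: Path, seed: int, params: Params) -> dict:
    path = Path(cfg.get("in", out / "ice.csv"))
    if path.is_dir():
        path = path / "ice.csv"
    if not path.exists():
        raise FileNotFoundError(f"ice input {path} not found")
    ice_df = iio.read_ice(path)
    est = ice.advection_table(ice_df, velocities=params.velocities_km_day,
                              mode=cfg.get("mode", "coastal"),
                              window_days=params.ice_window_days,
                              threshold_pct=params.ice_threshold_pct,
                              bloom_days=params.bloom_days)
    adv = ice.advection_frame(est)
    adv.to_csv(out / "advection.csv", index=False)
    return {"estimates": len(adv),
            "breakouts": int(adv["breakout_date"].notna().sum())}


def _stage_phenology(cfg: dict, out: Path, seed: int, params: Params) -> dict:
    sealdays = pd.read_csv(out / "sealdays.csv")
    sealdays["day"] = _doy(sealdays["date"])
    curve = ps.fit_seasonal_curve(sealdays, params.basis_dim, "calendar_day",
                                  params.likelihood)
    pd.DataFrame({"day": curve.days, "fit": curve.fit,
                  "lo": curve.lo, "hi": curve.hi}).to_csv(
        out / "curve.csv", index=False)
    shallow = ps.extract_shallow_period(curve, params.shallow_threshold_m,
                                        params.plateau_tol_m)
    iio.write_json(dataclasses.asdict(shallow) if shallow else None,
                   out / "shallow_period.json")

    daily = pd.read_csv(out / "daily.csv")
    daily["day"] = _doy(daily["date"])
    reg = {}
    if len(daily) >= 10 and daily["mean_max_depth"].nunique() > 1:
        r = ps.wiggle_depth_regression(daily)
        reg["wiggle_depth"] = dataclasses.asdict(r)
    if shallow is not None:
        try:
            reg["period_contrasts"] = ps.period_contrasts(daily, shallow,
                                                          params.flank_days)
        except ValueError as e:
            reg["period_contrasts"] = {"error": str(e)}
    iio.write_json(reg, out / "regressions.json")

    counts = {"curve_points": len(curve.days),
              "shallow_duration": shallow.duration if shallow else None}
    adv_path = out / "advection.csv"
    if adv_path.exists() and "year" in sealdays.columns \
            and sealdays["year"].nunique() > 1:
        adv = pd.read_csv(adv_path, parse_dates=["arrival_date"])
        delta = ps.compare_covariates(sealdays, adv, params.basis_dim,
                                      params.likelihood)
        delta.to_csv(out / "delta_aic.csv", index=False)
        counts["delta_aic_rows"] = len(delta)
    return counts


def _stage_isotopes(cfg: dict, out: Path, seed: int, params: Params) -> dict:
    whiskers = pd.read_csv(out / "whiskers.csv", parse_dates=["date"])
    sources = pd.read_csv(out / "sources.csv")
    consumers_path = out / "consumers.csv"
    if consumers_path.exists():
        consumers = pd.read_csv(consumers_path)
    else:
        consumers = whiskers.groupby("seal_id")[["d13C", "d15N"]].mean().reset_index()
    trend = im.isotope_trend(whiskers)
    result = im.fit_mixing_model(consumers, sources,
                                 alpha=params.dirichlet_alpha,
                                 walkers=params.mcmc_walkers,
                                 steps=params.mcmc_steps,
                                 burn=params.mcmc_burn, seed=seed + 3,
                                 rhat_max=params.rhat_max)
    result.summary.to_csv(out / "mixing_summary.csv", index=False)
    pd.DataFrame(result.p_draws, columns=result.source_names).to_csv(
        out / "mixing_posterior.csv", index=False)
    iio.write_json({"trend": trend, "rhat": result.rhat,
                    "converged": result.converged,
                    "summary": result.summary.to_dict("records")},
                   out / "isotopes.json")
    return {"consumers": len(consumers), "draws": int(result.p_draws.shape[0]),
            "converged": result.converged}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "dives": _stage_dives,
    "captures": _stage_captures,
    "ice": _stage_ice,
    "phenology": _stage_phenology,
    "isotopes": _stage_isotopes,
}


# ---------------------------------------------------------------------------
# validation

def validate_inputs(paths: dict[str, str | Path]) -> dict:
    """Schema / unit / monotonicity checks; report-only (never raises).

    ``paths`` maps kind ('tdr', 'accel', 'ice', 'whiskers') to a file or
    directory.  Fatal issues make the data unusable; warnings flag
    tolerable deviations (e.g. sampling interval within 20 % of nominal).
    """
    fatal: list[str] = []
    warn: list[str] = []

    def check_tdr(path):
        for seal, df in iio.read_tdr(Path(path)).items():
            if not {"timestamp", "depth_m"} <= set(df.columns):
                fatal.append(f"tdr {seal}: missing columns")
                continue
            t = pd.DatetimeIndex(df["timestamp"])
            if not t.is_monotonic_increasing:
                fatal.append(f"tdr {seal}: timestamps not increasing")
            neg = np.nonzero(df["depth_m"].to_numpy() < 0)[0]
            if len(neg):
                fatal.append(f"tdr {seal}: negative depth at row {int(neg[0])}")
            step = np.median(np.diff(t.asi8 / 1e9)) if len(t) > 1 else np.nan
            if np.isfinite(step) and abs(step - syn.SAMPLE_S) > 0.2 * syn.SAMPLE_S:
                warn.append(f"tdr {seal}: sampling interval {step:.1f}s "
                            f"deviates >20% from {syn.SAMPLE_S:.0f}s")
            q = df["depth_m"].to_numpy() / syn.DEPTH_RES_M
            if not np.allclose(q, np.round(q), atol=1e-6):
                warn.append(f"tdr {seal}: depths not multiples of {syn.DEPTH_RES_M} m")

    def check_accel(path):
        files = sorted(Path(path).glob("accel_*.csv")) if Path(path).is_dir() \
            else [Path(path)]
        for f in files:
            df = iio.read_accel(f)
            if not {"timestamp", "surge_g", "heave_g"} <= set(df.columns):
                fatal.append(f"accel {f.name}: missing columns")
                continue
            if not np.isfinite(df[["surge_g", "heave_g"]].to_numpy()).all():
                fatal.append(f"accel {f.name}: non-finite values")
            t = pd.DatetimeIndex(df["timestamp"]).asi8 / 1e9
            if len(t) > 1:
                step = np.median(np.diff(t))
                if abs(step - 1 / syn.ACCEL_HZ) > 0.2 / syn.ACCEL_HZ:
                    warn.append(f"accel {f.name}: not a 20 Hz grid")

    def check_ice(path):
        df = iio.read_ice(Path(path))
        c = df["concentration"].to_numpy(float)
        bad = np.nonzero((c < 0) | (c > 100))[0]
        if len(bad):
            fatal.append(f"ice: concentration outside [0,100] at row {int(bad[0])}")
        dup = df.duplicated(["date", "cell_id"]).sum()
        if dup:
            fatal.append(f"ice: {dup} duplicate cell-day rows")

    checks = {"tdr": check_tdr, "accel": check_accel, "ice": check_ice}
    for kind, path in paths.items():
        fn = checks.get(kind)
        if fn is None:
            warn.append(f"no validator for kind {kind!r}")
            continue
        try:
            fn(path)
        except Exception as e:  # noqa: BLE001
            fatal.append(f"{kind}: unreadable ({e})")
    return {"fatal": fatal, "warnings": warn, "ok": not fatal}
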