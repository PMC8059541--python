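"""CSV / NetCDF / JSON readers and writers for every pipeline interchange.

CSV dialect is UTF-8, comma, one header row, ISO-8601 timestamps.  Gridded
ice can also round-trip through NetCDF (classic format via the scipy
backend); the long-format CSV is the canonical text interchange.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd


def write_tdr(records: dict[str, pd.DataFrame], out_dir: Path) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for seal, df in sorted(records.items()):
        p = out_dir / f"tdr_{seal}.csv"
        df.to_csv(p, index=False, date_format="%Y-%m-%dT%H:%M:%SZ")
        paths.append(p)
    return paths


def read_tdr(path: Path) -> dict[str, pd.DataFrame]:
    """Read one tdr_<seal>.csv or every one in a directory."""
    path = Path(path)
    files = sorted(path.glob("tdr_*.csv")) if path.is_dir() else [path]
    if not files:
        raise FileNotFoundError(f"no tdr_*.csv under {path}")
    out = {}
    for f in files:
        df = pd.read_csv(f, parse_dates=["timestamp"])
        seal = f.stem.removeprefix("tdr_")
        out[seal] = df
    return out


def write_accel(record: pd.DataFrame, path: Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    record.to_csv(path, index=False, date_format="%Y-%m-%dT%H:%M:%S.%fZ")
    return path


def read_accel(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, parse_dates=["timestamp"])


def write_ice_csv(ice: pd.DataFrame, path: Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ice.to_csv(path, index=False)
    return path


def read_ice(path: Path) -> pd.DataFrame:
    """Long-format ice table from CSV or NetCDF (dims time x cell)."""
    path = Path(path)
    if path.suffix in (".nc", ".cdf", ".netcdf"):
        import xarray as xr
        ds = xr.open_dataset(path, engine="scipy")
        df = ds.to_dataframe().reset_index()
        df = df.rename(columns={"time": "date", "cell": "cell_id"})
        return df[["date", "cell_id", "lat", "lon", "concentration"]]
    df = pd.read_csv(path)
    df["date"] = pd.to_datetime(df["date"])
    return df


def write_ice_netcdf(ice: pd.DataFrame, path: Path) -> Path:
    import xarray as xr
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    wide = ice.pivot(index="date", columns="cell_id", values="concentration")
    coords = ice.groupby("cell_id")[["lat", "lon"]].first().loc[wide.columns]
    ds = xr.Dataset(
        {"concentration": (("time", "cell"), wide.to_numpy())},
        coords={"time": pd.DatetimeIndex(wide.index).rename(None),
                "cell": wide.columns.tolist(),
                "lat": ("cell", coords["lat"].to_numpy()),
                "lon": ("cell", coords["lon"].to_numpy())},
    )
    ds["concentration"].attrs["units"] = "% cover"
    ds.to_netcdf(path, engine="scipy")
    return path


def write_json(obj, path: Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (pd.Timestamp,)):
            return o.isoformat()
        if hasattr(o, "isoformat"):
            return o.isoformat()
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, default=default, sort_keys=True))
    return path


def sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
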