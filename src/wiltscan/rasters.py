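"""Raster and tabular I/O helpers.

All rasters share one grid convention: row-major arrays, origin at the
top-left corner, 0-based indices, square pixels of ``pixel_size`` metres
(area ``pixel_size**2``).  Scene coordinates put pixel (row, col) center at
``x = (col + 0.5) * pixel_size``, ``y = (row + 0.5) * pixel_size`` with y
increasing downwards.

Float rasters are written as single- or multi-band float32 TIFF with
nodata −9999 (NaN in memory); label/class rasters as uint8.
"""

from __future__ import annotations

import csv
import datetime as _dt
from pathlib import Path

import numpy as np
import tifffile

NODATA = -9999.0


def write_raster(path: str | Path, arr: np.ndarray) -> None:
    """Write a float raster (2-D, or 3-D band-first) with NaN → nodata."""
    data = np.asarray(arr, dtype=np.float32).copy()
    data[~np.isfinite(data)] = NODATA
    tifffile.imwrite(str(path), data)


def read_raster(path: str | Path) -> np.ndarray:
    """Read a float raster; nodata → NaN."""
    data = tifffile.imread(str(path)).astype(np.float32)
    data[data == NODATA] = np.nan
    return data


def write_byte_raster(path: str | Path, arr: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(arr, dtype=np.uint8))


def read_byte_raster(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(np.uint8)


def write_dates_csv(path: str | Path, serial_days: np.ndarray, year_origin: int = 2018) -> None:
    """Write observation dates as ISO dates (serial day 1 = Jan 1 of origin year)."""
    base = _dt.date(year_origin, 1, 1)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["serial_day", "date"])
        for d in np.asarray(serial_days, dtype=int):
            w.writerow([int(d), (base + _dt.timedelta(days=int(d) - 1)).isoformat()])


def read_dates_csv(path: str | Path) -> np.ndarray:
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    return np.array([int(r["serial_day"]) for r in rows], dtype=int)


def write_series_csv(path: str | Path, dates, values, valid) -> None:
    """Long-format per-pixel series: (pixel_id, date, ndvi, valid)."""
    import pandas as pd

    n_pix, n_t = values.shape
    pd.DataFrame(
        {
            "pixel_id": np.repeat(np.arange(n_pix), n_t),
            "date": np.tile(np.asarray(dates, int), n_pix),
            "ndvi": np.asarray(values, np.float32).ravel(),
            "valid": np.asarray(valid, bool).ravel().astype(int),
        }
    ).to_csv(path, index=False)


def read_series_csv(path: str | Path):
    """Read long-format series back into (dates, values, valid) arrays."""
    import pandas as pd

    df = pd.read_csv(path)
    dates = np.sort(df["date"].unique())
    n_pix = df["pixel_id"].nunique()
    df = df.sort_values(["pixel_id", "date"])
    values = df["ndvi"].to_numpy(np.float32).reshape(n_pix, dates.size)
    valid = df["valid"].to_numpy(bool).reshape(n_pix, dates.size)
    return dates, values, valid
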