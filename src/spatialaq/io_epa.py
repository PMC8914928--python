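"""Reader for the US-EPA daily pollution table (28-field layout).

The daily table carries, per row, one site-day with four pollutant blocks
(NO2, O3, SO2, CO), each holding units, mean concentration, 1st max value,
1st max hour and AQI.  Sites are identified by (State Code, County Code,
Site Num); the table stores street addresses, not coordinates, so a
companion site-location CSV (site key -> lon, lat; sourced from the EPA
monitor listing) supplies the geography.  Sites without a mapping are
dropped and reported, never guessed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyDataError, SchemaError
from .grid import PointDataset

log = logging.getLogger("spatialaq")

POLLUTANTS = ("NO2", "O3", "SO2", "CO")

#: canonical 28-field layout; header matching is case/space-insensitive
EPA_FIELDS = [
    "Index", "State Code", "County Code", "Site Num", "Address", "State",
    "County", "City", "Date Local",
    "NO2 Units", "NO2 Mean", "NO2 1st Max Value", "NO2 1st Max Hour", "NO2 AQI",
    "O3 Units", "O3 Mean", "O3 1st Max Value", "O3 1st Max Hour", "O3 AQI",
    "SO2 Units", "SO2 Mean", "SO2 1st Max Value", "SO2 1st Max Hour", "SO2 AQI",
    "CO Units", "CO Mean", "CO 1st Max Value", "CO 1st Max Hour", "CO AQI",
]


def _canon(name: str) -> str:
    return "".join(name.lower().split())


@dataclass
class ReadReport:
    rows_in: int
    rows_used: int
    rows_dropped_missing_value: int
    rows_dropped_no_site_coords: int
    duplicate_site_days_merged: int

    def check_conservation(self) -> None:
        assert (
            self.rows_in
            == self.rows_used
            + self.rows_dropped_missing_value
            + self.rows_dropped_no_site_coords
            + self.duplicate_site_days_merged
        ), "row accounting does not balance"


def read_site_coords(path: str) -> pd.DataFrame:
    """Sidecar CSV: site_key, lon, lat (site_key = state|county|site)."""
    df = pd.read_csv(path, dtype={"site_key": str})
    missing = {"site_key", "lon", "lat"} - set(df.columns)
    if missing:
        raise SchemaError(f"site-coordinates file lacks columns: {sorted(missing)}")
    return df.set_index("site_key")[["lon", "lat"]]


def _site_key(df: pd.DataFrame) -> pd.Series:
    return (
        df["State Code"].astype(int).astype(str)
        + "|" + df["County Code"].astype(int).astype(str)
        + "|" + df["Site Num"].astype(int).astype(str)
    )


def read_epa_daily(
    path: str,
    pollutant: str,
    site_coords: str | pd.DataFrame,
    date_range: tuple[str, str] | None = None,
    value: str = "aqi",
) -> tuple[PointDataset, ReadReport]:
    """Load one pollutant's daily series as a geographic PointDataset.

    ``value`` selects the observation column: ``"aqi"`` (default, the
    pollutant's reported AQI) or ``"mean"`` (the mean concentration, e.g.
    to recompute AQI through the aqi module).  Duplicate site-day rows are
    averaged with a warning.  Returns the dataset plus a row-accounting
    report (rows_in == rows_used + dropped, asserted).
    """
    if pollutant not in POLLUTANTS:
        raise ValueError(f"pollutant must be one of {POLLUTANTS}")
    if value not in ("aqi", "mean"):
        raise ValueError("value must be 'aqi' or 'mean'")

    df = pd.read_csv(path)
    colmap = {_canon(c): c for c in df.columns}
    needed = ["State Code", "County Code", "Site Num", "Date Local",
              f"{pollutant} AQI" if value == "aqi" else f"{pollutant} Mean"]
    missing = [c for c in needed if _canon(c) not in colmap]
    if missing:
        raise SchemaError(f"input lacks expected columns: {missing}")
    df = df.rename(columns={colmap[_canon(c)]: c for c in needed})
    vcol = needed[-1]

    rows_in = len(df)
    df["Date Local"] = pd.to_datetime(df["Date Local"])
    if date_range is not None:
        lo, hi = pd.to_datetime(date_range[0]), pd.to_datetime(date_range[1])
        sel = (df["Date Local"] >= lo) & (df["Date Local"] <= hi)
        df = df[sel]
        rows_in = len(df)

    df = df.assign(site_key=_site_key(df))
    numeric = pd.to_numeric(df[vcol], errors="coerce")
    ok = numeric.notna() & np.isfinite(numeric.fillna(np.inf))
    dropped_missing = int((~ok).sum())
    df = df[ok].assign(**{vcol: numeric[ok]})

    dup = df.duplicated(subset=["site_key", "Date Local"]).sum()
    if dup:
        warnings.warn(
            f"{dup} duplicate site-day rows averaged", stacklevel=2
        )
        df = (
            df.groupby(["site_key", "Date Local"], as_index=False)
            .agg({vcol: "mean"})
        )
    if isinstance(site_coords, str):
        site_coords = read_site_coords(site_coords)
    merged = df.merge(site_coords, left_on="site_key", right_index=True,
                      how="left")
    no_coords = int(merged["lon"].isna().sum())
    if no_coords:
        log.warning("%d rows dropped: site has no coordinate mapping",
                    no_coords)
    merged = merged.dropna(subset=["lon", "lat"])
    if len(merged) == 0:
        raise EmptyDataError("zero usable rows after filtering")

    report = ReadReport(
        rows_in=rows_in,
        rows_used=len(merged),
        rows_dropped_missing_value=dropped_missing,
        rows_dropped_no_site_coords=no_coords,
        duplicate_site_days_merged=int(dup),
    )
    report.check_conservation()
    log.info(
        "read %d rows: used %d, missing-value %d, unmapped-site %d, "
        "duplicates merged %d",
        rows_in, report.rows_used, dropped_missing, no_coords, int(dup),
    )
    ds = PointDataset(
        x=merged["lon"].to_numpy(float),
        y=merged["lat"].to_numpy(float),
        values=merged[vcol].to_numpy(float),
        crs_tag="geographic-lonlat",
        site=merged["site_key"].to_numpy(object),
        date=merged["Date Local"].dt.strftime("%Y-%m-%d").to_numpy(object),
    )
    return ds, report


def temporal_reduce(
    records: PointDataset,
    period: str = "year",
    statistic: str = "mean",
) -> PointDataset:
    """Reduce multi-day records to one value per site per period.

    ``period`` in {"year", "month", "day"}; ``statistic`` in
    {"mean", "median", "max"}.  When every input falls in one period the
    output has exactly one point per site.
    """
    if records.site is None or records.date is None:
        raise ValueError("temporal_reduce needs site and date metadata")
    if period not in ("year", "month", "day"):
        raise ValueError("period must be year, month or day")
    if statistic not in ("mean", "median", "max"):
        raise ValueError("statistic must be mean, median or max")
    df = pd.DataFrame(
        {
            "site": records.site,
            "date": pd.to_datetime(records.date),
            "x": records.x,
            "y": records.y,
            "value": records.values,
        }
    )
    fmt = {"year": "%Y", "month": "%Y-%m", "day": "%Y-%m-%d"}[period]
    df["period"] = df["date"].dt.strftime(fmt)
    out = (
        df.groupby(["site", "period"], as_index=False)
        .agg(x=("x", "first"), y=("y", "first"), value=("value", statistic),
             date=("period", "first"))
    )
    return PointDataset(
        x=out["x"].to_numpy(float),
        y=out["y"].to_numpy(float),
        values=out["value"].to_numpy(float),
        crs_tag=records.crs_tag,
        proj_origin=records.proj_origin,
        site=out["site"].to_numpy(object),
        date=out["date"].to_numpy(object),
    )
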