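"""Domain types, CSV readers/writers and hourly-to-daily aggregation.

The analysis unit downstream is one site-year of daily mean pollutant
concentrations. Monitoring networks deliver hourly averages; a daily mean is
only trustworthy when enough of the day was actually measured, so aggregation
applies a completeness rule: the daily mean is computed only when at least a
given fraction (default 80%) of the day's expected hourly values are present.
Days failing the rule are dropped, never imputed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd


class SeriesValidationError(ValueError):
    """Raised when a series violates a structural invariant."""


class InfeasibleModelError(ValueError):
    """Raised when a model cannot be fitted to a series (e.g. too few points)."""


@dataclass
class HourlySeries:
    """A univariate hourly concentration series from one monitoring site.

    Missing hours are represented as NaN values; timestamps must be strictly
    increasing, present values finite and non-negative (concentrations in
    ug/m3).
    """

    timestamps: pd.DatetimeIndex
    values: np.ndarray
    site: str = ""
    pollutant: str = ""

    def __post_init__(self) -> None:
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.timestamps) != len(self.values):
            raise SeriesValidationError("timestamps and values differ in length")
        if len(self.timestamps) == 0:
            raise SeriesValidationError("empty hourly series")
        if not self.timestamps.is_monotonic_increasing or self.timestamps.has_duplicates:
            raise SeriesValidationError("timestamps must be strictly increasing")
        present = self.values[~np.isnan(self.values)]
        if not np.all(np.isfinite(present)):
            raise SeriesValidationError("non-finite concentration values")
        if np.any(present < 0):
            bad = np.flatnonzero(np.nan_to_num(self.values, nan=0.0) < 0)
            raise SeriesValidationError(
                f"negative concentrations at rows {bad.tolist()[:10]}"
            )

    def __len__(self) -> int:
        return len(self.values)

    @property
    def n_present(self) -> int:
        return int(np.sum(~np.isnan(self.values)))


@dataclass
class DailySeries:
    """One site-year of daily mean concentrations (the clustering input).

    ``annual_mean`` is the arithmetic mean M of the valid daily values and
    ``n_days`` their count; both are derived, not stored.
    """

    dates: pd.DatetimeIndex
    values: np.ndarray
    site: str = ""
    pollutant: str = ""
    year: int | None = None

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates).normalize()
        self.values = np.asarray(self.values, dtype=float)
        if len(self.dates) != len(self.values):
            raise SeriesValidationError("dates and values differ in length")
        if len(self.dates) == 0:
            raise SeriesValidationError("empty daily series")
        if not self.dates.is_monotonic_increasing or self.dates.has_duplicates:
            raise SeriesValidationError("dates must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise SeriesValidationError("daily values must be finite")
        if np.any(self.values < 0):
            raise SeriesValidationError("negative daily concentrations")
        if self.year is None:
            self.year = int(self.dates[0].year)
        elif self.year not in set(self.dates.year):
            raise SeriesValidationError(
                f"declared year {self.year} does not match the dates"
            )

    def __len__(self) -> int:
        return len(self.values)

    @property
    def n_days(self) -> int:
        return len(self.values)

    @property
    def annual_mean(self) -> float:
        return float(np.mean(self.values))


@dataclass
class FitConfig:
    """Shared fitting configuration for all four clustering techniques.

    tol is the relative log-likelihood convergence threshold of the EM /
    Baum-Welch iterations; k_range the candidate cluster counts swept for
    model selection; variance_floor the minimum component variance expressed
    as a fraction of the total data variance (guards against likelihood
    singularities); n_starts the number of seeded k-means restarts and
    hmm_starts the number of perturbed Baum-Welch restarts on top of the
    deterministic initialization.
    """

    tol: float = 1e-5
    max_iter: int = 100_000
    k_range: tuple[int, ...] = tuple(range(1, 10))
    variance_floor: float = 1e-6
    n_starts: int = 10
    hmm_starts: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        self.k_range = tuple(int(k) for k in self.k_range)
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if not self.k_range or any(k < 1 for k in self.k_range):
            raise ValueError("k_range must be non-empty with all k >= 1")
        if self.variance_floor <= 0:
            raise ValueError("variance_floor must be > 0")


# ---------------------------------------------------------------------------
# CSV IO


DEFAULT_SCHEMA: Mapping[str, str] = {
    "timestamp": "timestamp",
    "value": "value",
    "site": "site",
    "pollutant": "pollutant",
}


def _series_metadata(df: pd.DataFrame, schema: Mapping[str, str]) -> dict[str, str]:
    meta = {}
    for key in ("site", "pollutant"):
        col = schema.get(key)
        if col and col in df.columns:
            vals = df[col].dropna().unique()
            if len(vals) > 1:
                raise SeriesValidationError(f"multiple {key} values in one file: {vals}")
            if len(vals) == 1:
                meta[key] = str(vals[0])
    return meta


def read_series(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    kind: str = "auto",
    na_values: Iterable[str] = (),
) -> HourlySeries | DailySeries:
    """Read an hourly or daily univariate series from CSV.

    ``schema`` maps the logical columns (timestamp, value, site, pollutant)
    to the file's column names; ``kind`` is "hourly", "daily" or "auto"
    (inferred from timestamp spacing: any sub-daily spacing means hourly).
    Missing values may be empty cells or any of ``na_values``.
    """
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, na_values=list(na_values), keep_default_na=True)
    ts_col = schema["timestamp"]
    if ts_col not in df.columns and "date" in df.columns:
        ts_col = "date"
    if ts_col not in df.columns or schema["value"] not in df.columns:
        raise SeriesValidationError(
            f"cannot resolve columns {ts_col!r}/{schema['value']!r} in {path.name}"
        )
    try:
        ts = pd.DatetimeIndex(pd.to_datetime(df[ts_col], format="ISO8601"))
    except (ValueError, TypeError) as exc:
        raise SeriesValidationError(f"unparseable timestamps in {path.name}: {exc}") from None
    values = pd.to_numeric(df[schema["value"]], errors="coerce").to_numpy(float)
    bad = ~np.isnan(values) & (values < 0)
    if bad.any():
        raise SeriesValidationError(
            f"negative concentrations in {path.name} at rows {np.flatnonzero(bad).tolist()[:10]}"
        )
    meta = _series_metadata(df, schema)
    if kind == "auto":
        if len(ts) >= 2 and ts.to_series().diff().dropna().min() < pd.Timedelta("1D"):
            kind = "hourly"
        else:
            kind = "daily"
    if kind == "hourly":
        return HourlySeries(ts, values, **meta)
    keep = ~np.isnan(values)
    return DailySeries(ts[keep], values[keep], **meta)


def write_daily(ds: DailySeries, path: str | Path, sidecar: bool = True) -> Path:
    """Write a daily series as CSV (date,value) plus a JSON metadata sidecar."""
    path = Path(path)
    pd.DataFrame(
        {"date": ds.dates.strftime("%Y-%m-%d"), "value": ds.values}
    ).to_csv(path, index=False)
    if sidecar:
        meta = {
            "site": ds.site,
            "pollutant": ds.pollutant,
            "year": ds.year,
            "n_days": ds.n_days,
            "annual_mean": ds.annual_mean,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    return path


def write_hourly(hs: HourlySeries, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame({"timestamp": hs.timestamps.strftime("%Y-%m-%dT%H:%M:%S"),
                       "value": hs.values})
    if hs.site:
        df["site"] = hs.site
    if hs.pollutant:
        df["pollutant"] = hs.pollutant
    df.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# Aggregation


def _expected_hours(day: pd.Timestamp, tz) -> int:
    if tz is None:
        return 24
    naive = day.tz_localize(None) if day.tz is not None else day
    start = naive.tz_localize(tz)
    end = (naive + pd.Timedelta(days=1)).tz_localize(tz)
    # clock length of the local day: 23/25 on DST transitions
    return int(round((end - start) / pd.Timedelta(hours=1)))


def aggregate_daily(hs: HourlySeries, completeness: float = 0.8) -> DailySeries:
    """Aggregate hourly values to daily means under a completeness rule.

    A day is retained iff (present hours / expected hours) >= completeness;
    for a normal 24-hour day the default 0.8 requires at least 20 present
    hours. Expected hours follow the day's clock length when timestamps are
    zone-aware (23/25 on DST transition days). Dropped days are omitted,
    not imputed.
    """
    if not 0 < completeness <= 1:
        raise ValueError("completeness must lie in (0, 1]")
    tz = hs.timestamps.tz
    days = hs.timestamps.normalize()
    frame = pd.DataFrame({"day": days, "value": hs.values})
    out_dates, out_values = [], []
    for day, grp in frame.groupby("day", sort=True):
        present = grp["value"].notna().sum()
        expected = _expected_hours(day, tz)
        if present / expected >= completeness:
            out_dates.append(day.tz_localize(None) if tz is not None else day)
            out_values.append(grp["value"].mean())
    if not out_dates:
        raise SeriesValidationError("no day satisfies the completeness rule")
    index = pd.DatetimeIndex(out_dates)
    if len(set(index.year)) > 1:
        raise SeriesValidationError(
            "hourly input spans several calendar years; split it first "
            "(see split_hourly_by_year)"
        )
    return DailySeries(index, np.asarray(out_values),
                       site=hs.site, pollutant=hs.pollutant)


def split_hourly_by_year(hs: HourlySeries) -> list[HourlySeries]:
    """Split a multi-year hourly series into per-calendar-year series."""
    out = []
    for year in sorted(set(hs.timestamps.year)):
        mask = hs.timestamps.year == year
        out.append(HourlySeries(hs.timestamps[mask], hs.values[mask],
                                site=hs.site, pollutant=hs.pollutant))
    return out
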