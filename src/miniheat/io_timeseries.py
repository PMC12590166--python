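"""Reading, validation, resampling and alignment of sensor time series.

Indoor traces come from room-level environmental sensors logging air
temperature (°C) and relative humidity (%) nominally once per minute;
outdoor traces come from a local weather station logging every five
minutes.  Timestamps are naive local clock time and are taken as-is —
handling DST transitions is the caller's responsibility.

Conventions fixed here and relied on everywhere downstream:

* resampling bins are left-closed, right-open, labelled by the left edge;
* duplicate timestamps keep the first record seen and drop the rest;
* no imputation anywhere — empty bins are emitted as missing values and
  downstream stages treat gaps explicitly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default plausibility window for air temperature validation (°C).
DEFAULT_TEMP_RANGE = (-10.0, 60.0)


@dataclass(frozen=True)
class ColumnSchema:
    """Maps the package's canonical field names onto CSV column headers."""

    timestamp: str = "timestamp"
    temperature: str = "temperature"
    relative_humidity: str = "relative_humidity"
    wind_speed: str | None = None

    def required(self) -> list[str]:
        return [self.timestamp, self.temperature, self.relative_humidity]


@dataclass
class ReadReport:
    """Row-level accounting for one CSV read."""

    n_rows: int = 0
    n_valid: int = 0
    n_dropped: int = 0
    drop_reasons: dict = field(default_factory=dict)
    n_duplicates: int = 0
    was_sorted: bool = True


@dataclass
class IndoorSeries:
    """Minute-resolution indoor trace for one sensor.

    ``data`` is indexed by a strictly increasing DatetimeIndex and holds
    ``temperature`` (°C) and ``relative_humidity`` (%).  Gaps are allowed;
    values may be NaN only in resampled (aggregated) series.
    """

    sensor_id: str
    data: pd.DataFrame

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return self.data.index

    @property
    def temperature(self) -> pd.Series:
        return self.data["temperature"]

    @property
    def relative_humidity(self) -> pd.Series:
        return self.data["relative_humidity"]

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class OutdoorSeries:
    """Weather-station trace: temperature (°C), RH (%), optional wind (m/s)."""

    data: pd.DataFrame

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return self.data.index

    @property
    def temperature(self) -> pd.Series:
        return self.data["temperature"]

    @property
    def relative_humidity(self) -> pd.Series:
        return self.data["relative_humidity"]

    def __len__(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class AnalysisWindow:
    """Half-open analysis interval [start, end)."""

    start: pd.Timestamp
    end: pd.Timestamp

    def __post_init__(self):
        object.__setattr__(self, "start", pd.Timestamp(self.start))
        object.__setattr__(self, "end", pd.Timestamp(self.end))
        if not self.start < self.end:
            raise ValueError("AnalysisWindow requires start < end")


def _validate_frame(
    df: pd.DataFrame,
    schema: ColumnSchema,
    temp_range: tuple[float, float],
) -> tuple[pd.DataFrame, ReadReport]:
    report = ReadReport(n_rows=len(df))

    for col in schema.required():
        if col not in df.columns:
            raise ValueError(f"mapped column {col!r} not found in CSV")

    out = pd.DataFrame(
        {
            "timestamp": pd.to_datetime(df[schema.timestamp], errors="coerce"),
            "temperature": pd.to_numeric(df[schema.temperature], errors="coerce"),
            "relative_humidity": pd.to_numeric(
                df[schema.relative_humidity], errors="coerce"
            ),
        }
    )
    if schema.wind_speed is not None and schema.wind_speed in df.columns:
        out["wind_speed"] = pd.to_numeric(df[schema.wind_speed], errors="coerce")

    lo, hi = temp_range
    bad_ts = out["timestamp"].isna()
    bad_temp = ~out["temperature"].between(lo, hi) | ~np.isfinite(
        out["temperature"].to_numpy(dtype=float)
    )
    bad_rh = ~out["relative_humidity"].between(0.0, 100.0)
    for reason, mask in (
        ("unparseable_timestamp", bad_ts),
        ("temperature_out_of_range", bad_temp & ~bad_ts),
        ("rh_out_of_range", bad_rh & ~bad_ts & ~bad_temp),
    ):
        n = int(mask.sum())
        if n:
            report.drop_reasons[reason] = n
    keep = ~(bad_ts | bad_temp | bad_rh)
    out = out.loc[keep]

    if not out["timestamp"].is_monotonic_increasing:
        report.was_sorted = False
        logger.warning("timestamps out of order; sorting (stable)")
        out = out.sort_values("timestamp", kind="stable")

    dup = out["timestamp"].duplicated(keep="first")
    report.n_duplicates = int(dup.sum())
    if report.n_duplicates:
        logger.warning(
            "%d duplicate timestamps; keeping first occurrence", report.n_duplicates
        )
        report.drop_reasons["duplicate_timestamp"] = report.n_duplicates
    out = out.loc[~dup].set_index("timestamp")

    report.n_valid = len(out)
    report.n_dropped = report.n_rows - report.n_valid
    if report.n_valid == 0:
        raise ValueError("zero valid rows after validation")
    return out, report


def read_sensor_csv(
    path: str | Path,
    schema: ColumnSchema | Mapping[str, str] | None = None,
    *,
    sensor_id: str | None = None,
    temp_range: tuple[float, float] = DEFAULT_TEMP_RANGE,
) -> tuple[IndoorSeries, ReadReport]:
    """Read and validate one indoor sensor CSV.

    Rows failing validation (unparseable timestamp, temperature outside
    ``temp_range``, RH outside [0, 100]) are dropped and counted in the
    returned :class:`ReadReport`.  Raises ``FileNotFoundError`` for a
    missing file and ``ValueError`` for a missing mapped column or if no
    valid rows remain.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if schema is None:
        schema = ColumnSchema()
    elif isinstance(schema, Mapping):
        schema = ColumnSchema(**schema)
    df = pd.read_csv(path)
    data, report = _validate_frame(df, schema, temp_range)
    data = data[["temperature", "relative_humidity"]]
    return IndoorSeries(sensor_id=sensor_id or path.stem, data=data), report


def read_weather_csv(
    path: str | Path,
    schema: ColumnSchema | Mapping[str, str] | None = None,
    *,
    temp_range: tuple[float, float] = DEFAULT_TEMP_RANGE,
) -> tuple[OutdoorSeries, ReadReport]:
    """Read and validate the outdoor weather-station CSV (5-min nominal)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if schema is None:
        schema = ColumnSchema(wind_speed="wind_speed")
    elif isinstance(schema, Mapping):
        schema = ColumnSchema(**schema)
    df = pd.read_csv(path)
    data, report = _validate_frame(df, schema, temp_range)
    return OutdoorSeries(data=data), report


def resample_mean(series, interval_minutes: int):
    """Average a series onto a regular grid of ``interval_minutes`` bins.

    Bins are left-closed right-open and labelled by their left edge; bins
    containing no samples are emitted as missing (NaN) rows.  Applying the
    same interval twice is idempotent.
    """
    if interval_minutes <= 0 or int(interval_minutes) != interval_minutes:
        raise ValueError("interval must be a positive whole number of minutes")
    rule = f"{int(interval_minutes)}min"
    resampled = series.data.resample(rule, closed="left", label="left").mean()
    if isinstance(series, IndoorSeries):
        return IndoorSeries(sensor_id=series.sensor_id, data=resampled)
    return OutdoorSeries(data=resampled)


def align(
    indoor: IndoorSeries,
    outdoor: OutdoorSeries,
    window: AnalysisWindow,
) -> pd.DataFrame:
    """Inner-join indoor and outdoor series on timestamp within a window.

    Both inputs should already sit on the same resampling grid.  Returns a
    frame indexed by timestamp with columns ``T_in, RH_in, T_out, RH_out``;
    rows where either temperature is missing are dropped.  Raises
    ``ValueError`` if the intersection is empty.
    """
    lhs = indoor.data.loc[
        (indoor.timestamps >= window.start) & (indoor.timestamps < window.end)
    ].rename(columns={"temperature": "T_in", "relative_humidity": "RH_in"})
    rhs = outdoor.data.loc[
        (outdoor.timestamps >= window.start) & (outdoor.timestamps < window.end)
    ].rename(columns={"temperature": "T_out", "relative_humidity": "RH_out"})
    joined = lhs.join(rhs[["T_out", "RH_out"]], how="inner")
    joined = joined.dropna(subset=["T_in", "T_out"])
    if joined.empty:
        raise ValueError("empty timestamp intersection between indoor and outdoor")
    return joined


def hourly_io_difference(
    indoor: IndoorSeries,
    outdoor: OutdoorSeries,
    window: AnalysisWindow,
) -> tuple[pd.Series, dict]:
    """Hourly indoor-minus-outdoor temperature differences for one sensor.

    Each series is averaged per calendar hour within the window; the
    difference of hourly means is returned together with summary statistics
    (mean, median, min, max) over hours.  Antisymmetric under swapping the
    two inputs.  Raises ``ValueError`` when no hour has both series present.
    """
    t_in = (
        indoor.temperature.loc[
            (indoor.timestamps >= window.start) & (indoor.timestamps < window.end)
        ]
        .resample("1h", closed="left", label="left")
        .mean()
    )
    t_out = (
        outdoor.temperature.loc[
            (outdoor.timestamps >= window.start) & (outdoor.timestamps < window.end)
        ]
        .resample("1h", closed="left", label="left")
        .mean()
    )
    diff = (t_in - t_out).dropna()
    if diff.empty:
        raise ValueError("no overlapping hours between indoor and outdoor series")
    diff.name = "io_difference"
    summary = {
        "mean": float(diff.mean()),
        "median": float(diff.median()),
        "min": float(diff.min()),
        "max": float(diff.max()),
        "n_hours": int(len(diff)),
    }
    return diff, summary
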