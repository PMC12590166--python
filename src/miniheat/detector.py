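"""Indoor mini-heatwave detection and outdoor heatwave rules.

A *mini-heatwave* is a continuous period during which indoor temperature
meets or exceeds a threshold (26 °C by default, the English Heatwave Plan
upper limit for safe indoor conditions) for at least a minimum duration.
Detection combines simple thresholding with slope logic so that the onset
of rapid heating is captured and post-peak cooling does not inflate
events.

Given validated samples (t_i, T_i), sorted, NaNs removed, the detector
applies exactly these steps:

1. flag candidates where ``T_i >= temp_threshold``;
2. additionally include points whose forward-difference slope
   ``(T_{i+1}-T_i)/(t_{i+1}-t_i)`` exceeds ``slope_in`` (°C/min), even if
   still below the threshold (onset capture);
3. exclude points with slope ``<= slope_out``, and below-threshold points
   lying in a sustained-cooling run — a maximal monotone non-increasing
   stretch lasting at least ``cooling_run`` minutes;
4. group the surviving candidate timestamps into events, starting a new
   event whenever consecutive candidates are more than ``min_gap``
   minutes apart (this both merges short gaps and splits events across
   long data gaps — events are never extrapolated over missing data);
5. discard events shorter than ``min_duration`` minutes.

Events use a right-open interval convention: ``end`` is the last included
sample plus one nominal sample step, so a 15-sample plateau at 1-min
resolution has duration 15 min.

The outdoor rule is the UK Met Office definition: at least ``min_days``
(3) consecutive calendar days whose daily maximum temperature reaches or
exceeds the regional threshold (28 °C for London).  Day boundaries are
local midnight.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from datetime import date
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_timeseries import IndoorSeries, OutdoorSeries


@dataclass(frozen=True)
class DetectorConfig:
    """User-defined detection parameters.

    temp_threshold : °C, candidate flagging level (default 26).
    min_duration   : minutes, shortest event retained (default 10).
    slope_in       : °C/min, inclusion rate for rapid heating (default 2).
    slope_out      : °C/min, exclusion rate for steep cooling (default −2).
    min_gap        : minutes; candidate runs separated by gaps longer than
                     this start a new event (default 30).
    cooling_run    : minutes, minimum length of a monotone non-increasing
                     stretch counted as sustained cooling (default 10).
    """

    temp_threshold: float = 26.0
    min_duration: float = 10.0
    slope_in: float = 2.0
    slope_out: float = -2.0
    min_gap: float = 30.0
    cooling_run: float = 10.0

    def __post_init__(self):
        if self.min_duration <= 0:
            raise ValueError("min_duration must be positive")
        if self.min_gap < 0:
            raise ValueError("min_gap must be non-negative")
        if self.slope_in <= 0:
            raise ValueError("slope_in must be positive")
        if self.slope_out >= 0:
            raise ValueError("slope_out must be negative")
        if self.cooling_run <= 0:
            raise ValueError("cooling_run must be positive")


@dataclass(frozen=True)
class HeatEvent:
    """One detected indoor mini-heatwave (right-open [start, end))."""

    sensor_id: str
    start: pd.Timestamp
    end: pd.Timestamp
    duration_min: float
    peak_temp: float
    mean_temp: float


@dataclass(frozen=True)
class OutdoorHeatwave:
    """One outdoor heatwave: consecutive hot calendar days, inclusive range."""

    start_date: date
    end_date: date
    n_days: int
    max_temp: float


def candidate_mask(
    t_minutes: np.ndarray, temp: np.ndarray, config: DetectorConfig
) -> np.ndarray:
    """Steps 1–3 of the detector: per-sample candidate flags."""
    n = len(temp)
    cand = temp >= config.temp_threshold

    if n >= 2:
        dt = np.diff(t_minutes)
        dT = np.diff(temp)
        slope = dT / dt
        # step 2: onset capture by rapid heating
        cand[:-1] |= slope > config.slope_in
        # step 3a: steep negative slopes
        cand[:-1] &= ~(slope <= config.slope_out)
        # step 3b: sustained cooling runs (monotone non-increasing stretches
        # lasting >= cooling_run minutes); only below-threshold points removed
        noninc = dT <= 0.0
        i = 0
        while i < n - 1:
            if noninc[i]:
                j = i
                while j < n - 1 and noninc[j]:
                    j += 1
                # run spans indices i..j, elapsed t[j]-t[i]
                if t_minutes[j] - t_minutes[i] >= config.cooling_run:
                    seg = slice(i, j + 1)
                    cand[seg] &= ~(temp[seg] < config.temp_threshold)
                i = j
            else:
                i += 1
    return cand


def _nominal_step(t_minutes: np.ndarray) -> float:
    if len(t_minutes) < 2:
        return 1.0
    return float(np.median(np.diff(t_minutes)))


def detect_mini_heatwaves(
    series: IndoorSeries, config: DetectorConfig | None = None
) -> list[HeatEvent]:
    """Run the full five-step detector on one indoor series.

    Returns time-ordered, disjoint events each lasting at least
    ``config.min_duration`` minutes.  Raises ``ValueError`` on an empty
    series.  Irregular spacing is tolerated: slopes use actual elapsed
    time and gaps longer than ``min_gap`` split events.
    """
    config = config or DetectorConfig()
    temp = series.temperature.dropna()
    if temp.empty:
        raise ValueError("empty series")
    ts = temp.index
    t0 = ts[0]
    t_min = (ts - t0).total_seconds().to_numpy() / 60.0
    values = temp.to_numpy(dtype=float)

    cand = candidate_mask(t_min, values, config)
    step = _nominal_step(t_min)

    idx = np.flatnonzero(cand)
    events: list[HeatEvent] = []
    if idx.size == 0:
        return events

    # step 4: split where consecutive candidates are > min_gap minutes apart
    breaks = np.flatnonzero(np.diff(t_min[idx]) > config.min_gap)
    groups = np.split(idx, breaks + 1)

    for grp in groups:
        start_t = t_min[grp[0]]
        end_t = t_min[grp[-1]] + step
        duration = end_t - start_t
        if duration < config.min_duration:  # step 5
            continue
        in_event = (t_min >= start_t) & (t_min < end_t)
        seg = values[in_event]
        events.append(
            HeatEvent(
                sensor_id=series.sensor_id,
                start=t0 + pd.Timedelta(minutes=start_t),
                end=t0 + pd.Timedelta(minutes=end_t),
                duration_min=float(duration),
                peak_temp=float(seg.max()),
                mean_temp=float(seg.mean()),
            )
        )
    return events


def detect_outdoor_heatwaves(
    outdoor: OutdoorSeries, threshold: float = 28.0, min_days: int = 3
) -> list[OutdoorHeatwave]:
    """Met Office rule: runs of >= min_days consecutive days with daily
    maximum temperature >= threshold.  Days with no data break runs."""
    temp = outdoor.temperature.dropna()
    if temp.empty:
        raise ValueError("empty series")
    daily_max = temp.resample("1D").max().dropna()
    days = daily_max.index.normalize()
    hot = daily_max.to_numpy(dtype=float) >= threshold

    events: list[OutdoorHeatwave] = []
    run: list[tuple[pd.Timestamp, float]] = []

    def flush():
        if len(run) >= min_days:
            events.append(
                OutdoorHeatwave(
                    start_date=run[0][0].date(),
                    end_date=run[-1][0].date(),
                    n_days=len(run),
                    max_temp=float(max(v for _, v in run)),
                )
            )
        run.clear()

    for day, is_hot, tmax in zip(days, hot, daily_max.to_numpy(dtype=float)):
        if is_hot:
            if run and (day - run[-1][0]) != pd.Timedelta(days=1):
                flush()  # a missing day breaks consecutiveness
            run.append((day, tmax))
        else:
            flush()
    flush()
    return events


def heatwave_mask(
    events: Sequence[OutdoorHeatwave], timestamps: pd.DatetimeIndex
) -> np.ndarray:
    """True where a timestamp's calendar date falls inside any event.

    Midnight belongs to the date it starts.
    """
    dates = pd.DatetimeIndex(timestamps).normalize()
    mask = np.zeros(len(dates), dtype=bool)
    for ev in events:
        mask |= (dates >= pd.Timestamp(ev.start_date)) & (
            dates <= pd.Timestamp(ev.end_date)
        )
    return mask


@dataclass
class EventSummary:
    """Cohort-level event statistics (Fig-6-style hour histograms included)."""

    counts_per_household: dict
    n_affected: int
    mean_count: float | None
    median_count: float | None
    mean_duration: float | None
    median_duration: float | None
    start_hour_hist: np.ndarray
    stop_hour_hist: np.ndarray


def event_summaries(events: Sequence[HeatEvent]) -> EventSummary:
    """Summarize detected events across households.

    Count statistics are over affected households (those with >= 1 event);
    hour histograms bin event start/end by local clock hour 0–23.
    """
    start_hist = np.zeros(24, dtype=int)
    stop_hist = np.zeros(24, dtype=int)
    counts: dict[str, int] = {}
    durations = []
    for ev in events:
        counts[ev.sensor_id] = counts.get(ev.sensor_id, 0) + 1
        durations.append(ev.duration_min)
        start_hist[ev.start.hour] += 1
        stop_hist[ev.end.hour] += 1
    if counts:
        cvals = np.array(list(counts.values()), dtype=float)
        dvals = np.array(durations, dtype=float)
        return EventSummary(
            counts_per_household=counts,
            n_affected=len(counts),
            mean_count=float(cvals.mean()),
            median_count=float(np.median(cvals)),
            mean_duration=float(dvals.mean()),
            median_duration=float(np.median(dvals)),
            start_hour_hist=start_hist,
            stop_hour_hist=stop_hist,
        )
    return EventSummary(
        counts_per_household={},
        n_affected=0,
        mean_count=None,
        median_count=None,
        mean_duration=None,
        median_duration=None,
        start_hour_hist=start_hist,
        stop_hour_hist=stop_hist,
    )


def sensitivity_analysis(
    all_series: Mapping[str, IndoorSeries] | Iterable[IndoorSeries],
    base_config: DetectorConfig,
    duration_thresholds: Sequence[float] = (10, 30, 60, 120),
) -> pd.DataFrame:
    """Re-run detection at each duration threshold, all else fixed.

    Returns one row per threshold with the number of affected households,
    median and mean event count per affected household, and the median
    event duration in minutes.
    """
    if isinstance(all_series, Mapping):
        series_list = list(all_series.values())
    else:
        series_list = list(all_series)
    if not series_list:
        raise ValueError("no input series")
    thresholds = list(duration_thresholds)
    if any(t <= 0 for t in thresholds) or sorted(thresholds) != thresholds:
        raise ValueError("duration thresholds must be positive and sorted")

    rows = []
    for th in thresholds:
        cfg = replace(base_config, min_duration=float(th))
        events: list[HeatEvent] = []
        for s in series_list:
            events.extend(detect_mini_heatwaves(s, cfg))
        summ = event_summaries(events)
        rows.append(
            {
                "duration_threshold_min": th,
                "households_affected": summ.n_affected,
                "median_count_per_household": summ.median_count,
                "mean_count_per_household": summ.mean_count,
                "median_event_duration_min": summ.median_duration,
            }
        )
    return pd.DataFrame(rows)


def stratified_event_counts(
    events: Sequence[HeatEvent],
    households: pd.DataFrame,
    strata: str,
    *,
    affected_only: bool = True,
) -> pd.Series:
    """Mean event count per household, grouped by a household attribute.

    ``households`` must be indexed by sensor_id and contain the column
    named by ``strata`` (e.g. ``epc``, ``imd``, ``condition``).  By default
    the mean is over affected households only (households with zero events
    do not enter); set ``affected_only=False`` to average over all
    households in each stratum.  Strata with no contributing households
    are omitted.  Raises ``KeyError`` for an event whose sensor_id is not
    in the table.
    """
    if strata not in households.columns:
        raise KeyError(f"unknown stratification column {strata!r}")
    counts: dict[str, int] = {}
    for ev in events:
        if ev.sensor_id not in households.index:
            raise KeyError(f"sensor_id {ev.sensor_id!r} not in household table")
        counts[ev.sensor_id] = counts.get(ev.sensor_id, 0) + 1
    if affected_only:
        frame = pd.DataFrame(
            {
                "count": pd.Series(counts, dtype=float),
                strata: households.loc[list(counts)][strata]
                if counts
                else pd.Series(dtype=object),
            }
        )
    else:
        frame = pd.DataFrame(
            {
                "count": pd.Series(counts, dtype=float).reindex(
                    households.index, fill_value=0.0
                ),
                strata: households[strata],
            }
        )
    if frame.empty:
        return pd.Series(dtype=float, name="mean_events")
    out = frame.groupby(strata, observed=True)["count"].mean()
    out.name = "mean_events"
    return out


def events_to_frame(events: Sequence[HeatEvent]) -> pd.DataFrame:
    """Tidy export of detected events."""
    return pd.DataFrame(
        [
            {
                "sensor_id": ev.sensor_id,
                "start": ev.start,
                "end": ev.end,
                "duration_min": ev.duration_min,
                "peak_temp": ev.peak_temp,
                "mean_temp": ev.mean_temp,
            }
            for ev in events
        ],
        columns=["sensor_id", "start", "end", "duration_min", "peak_temp", "mean_temp"],
    )
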