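"""Synthetic study generator: outdoor weather, household cohorts and
physically plausible indoor responses with known ground truth.

The generator emulates a summer deployment of bedroom sensors across a
London borough: a diurnal outdoor cycle peaking mid-afternoon with AR(1)
weather noise and embedded multi-day heatwave episodes, a cohort of
households with Energy Performance Certificate (EPC) bands, deprivation
(IMD) groups, tenure, house type and self-rated condition drawn from
realistic frequencies, and per-household indoor temperature following a
first-order lumped-capacitance (RC) thermal response to the outdoor
drive.  That single time constant per dwelling reproduces the two
phenomena that matter downstream — indoor–outdoor attenuation and the
evening/night lag of indoor heat — without attempting building physics.

The RC update uses the exact exponential integrator for piecewise-
constant forcing, ``T[t+1] = T[t] + (1 − e^(−Δt/τ))·(T_eq[t] − T[t])``,
so the step response matches the continuous closed form exactly at
sample times.

A second, purely linear generator (:func:`gen_cohort_linear`) produces
indoor temperature directly from the pooled regression equation with
chosen gains, for parameter-recovery testing of the OLS module.

All randomness flows from a single integer seed; identical (config,
seed) gives byte-identical fixture bundles.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .io_timeseries import IndoorSeries, OutdoorSeries
from .regression import encode_households

#: Default study span: 2 August – 13 September (43 days), the window with
#: consistent sensor coverage in a typical summer deployment.
DEFAULT_START = "2023-08-02"
DEFAULT_N_DAYS = 43

#: Cohort attribute frequencies (39-household deployment shape).
EPC_PROBS = {"B": 12, "C": 9, "D": 8, "E": 4}
IMD_PROBS = {1: 16, 2: 23}
TENURE_PROBS = {
    "homeowner with mortgage": 14,
    "renting from a local authority/council": 12,
    "renting from a housing association/housing co-operative or charitable trust": 6,
    "renting from a private landlord": 5,
    "shared ownership": 2,
}
HOUSE_TYPE_PROBS = {
    "flat/apartment (high-rise, on a mid to high floor)": 16,
    "flat/apartment (high-rise on a low floor, or low-rise)": 14,
    "terraced house": 9,
}
CONDITION_PROBS = {
    "not new but in reasonable condition": 19,
    "new and/or in good condition": 13,
    "poor condition, in need of repair": 5,
    "very poor condition, in need of urgent repair": 2,
}


@dataclass(frozen=True)
class OutdoorConfig:
    """Outdoor drive: diurnal sine + heatwave episodes + AR(1) noise.

    mean/amplitude in °C; the diurnal peak sits at ``peak_hour`` (15:00,
    matching mid-afternoon maxima).  ``episodes`` are (start_day, n_days,
    boost °C) tuples added as a constant offset across those calendar
    days; the defaults place a 3-day and an 8-day episode whose boosts
    push daily maxima past the 28 °C regional heatwave threshold.
    noise_sd is the stationary standard deviation of the AR(1) noise at
    the native 5-min step with persistence ``noise_phi``.
    """

    mean: float = 21.0
    amplitude: float = 5.0
    noise_sd: float = 1.0
    noise_phi: float = 0.98
    peak_hour: float = 15.0
    episodes: tuple = ((20, 3, 4.0), (33, 8, 6.0))


@dataclass(frozen=True)
class IndoorConfig:
    """Indoor RC response and covariate structure of its equilibrium.

    T_eq(t) = intercept + gain·T_out(t) + Σ coef·encoded covariate, with
    coefficient signs making better-condition / less-deprived homes
    warmer.  time_constant_hours bounds the per-household uniform draw of
    the RC time constant τ.  measurement noise is iid °C at 1 min.
    """

    time_constant_hours: tuple[float, float] = (2.0, 8.0)
    gain: float = 0.45
    intercept: float = 11.2
    covariate_coefs: dict = field(
        default_factory=lambda: {
            "condition": 0.3,
            "epc": 0.1,
            "imd": 0.4,
            "tenure_council": 0.6,
            "tenure_housing_association": -0.5,
            "tenure_private_landlord": -1.3,
            "tenure_shared_ownership": -0.8,
            "htype_highrise_midhigh": -0.4,
            "htype_terraced": 0.2,
        }
    )
    noise_sd: float = 0.1


@dataclass(frozen=True)
class RHConfig:
    """Indoor relative humidity: bounded diurnal signal, peak pre-dawn."""

    mean: float = 55.0
    amplitude: float = 10.0
    noise_sd: float = 3.0


@dataclass(frozen=True)
class SyntheticConfig:
    seed: int = 0
    n_households: int = 39
    n_days: int = DEFAULT_N_DAYS
    start: str = DEFAULT_START
    outdoor: OutdoorConfig = field(default_factory=OutdoorConfig)
    indoor: IndoorConfig = field(default_factory=IndoorConfig)
    rh: RHConfig = field(default_factory=RHConfig)


@dataclass
class GroundTruth:
    """What the generator actually used, for recovery tests."""

    seed: int
    time_constants_min: dict
    gain: float
    intercept: float
    covariate_coefs: dict

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _diurnal(hours: np.ndarray, amplitude: float, peak_hour: float) -> np.ndarray:
    return amplitude * np.sin(2.0 * np.pi * (hours - (peak_hour - 6.0)) / 24.0)


def _ar1(rng: np.random.Generator, n: int, phi: float, sd: float) -> np.ndarray:
    innov_sd = sd * np.sqrt(1.0 - phi**2)
    eps = rng.normal(0.0, innov_sd, size=n)
    eps[0] = rng.normal(0.0, sd)
    return lfilter([1.0], [1.0, -phi], eps)


def gen_outdoor(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> OutdoorSeries:
    """Generate the 5-min outdoor weather-station series."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    oc = config.outdoor
    idx = pd.date_range(
        config.start, periods=config.n_days * 288, freq="5min", name="timestamp"
    )
    hours = idx.hour.to_numpy() + idx.minute.to_numpy() / 60.0
    day = np.arange(len(idx)) // 288
    boost = np.zeros(len(idx))
    for start_day, n_days, b in oc.episodes:
        boost[(day >= start_day) & (day < start_day + n_days)] += b
    temp = (
        oc.mean
        + _diurnal(hours, oc.amplitude, oc.peak_hour)
        + boost
        + _ar1(rng, len(idx), oc.noise_phi, oc.noise_sd)
    )
    rh = np.clip(
        70.0
        - _diurnal(hours, 12.0, 15.0)
        + _ar1(rng, len(idx), oc.noise_phi, 4.0),
        5.0,
        100.0,
    )
    wind = np.clip(3.0 + _ar1(rng, len(idx), oc.noise_phi, 1.0), 0.0, None)
    return OutdoorSeries(
        data=pd.DataFrame(
            {"temperature": temp, "relative_humidity": rh, "wind_speed": wind},
            index=idx,
        )
    )


def gen_households(
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
    *,
    epc_probs: dict | None = None,
    imd_probs: dict | None = None,
    tenure_probs: dict | None = None,
    house_type_probs: dict | None = None,
    condition_probs: dict | None = None,
) -> pd.DataFrame:
    """Sample the household attribute table.

    Category weights default to the module-level frequency tables; any of
    them can be overridden (weights need not be normalized).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    epc_probs = epc_probs or EPC_PROBS
    imd_probs = imd_probs or IMD_PROBS
    tenure_probs = tenure_probs or TENURE_PROBS
    house_type_probs = house_type_probs or HOUSE_TYPE_PROBS
    condition_probs = condition_probs or CONDITION_PROBS

    def draw(probs: dict, n: int):
        keys = list(probs)
        p = np.array([probs[k] for k in keys], dtype=float)
        p /= p.sum()
        return [keys[i] for i in rng.choice(len(keys), size=n, p=p)]

    n = config.n_households
    if n < 1:
        raise ValueError("n_households must be >= 1")
    width = max(2, len(str(n)))
    return pd.DataFrame(
        {
            "sensor_id": [f"S{i+1:0{width}d}" for i in range(n)],
            "epc": draw(epc_probs, n),
            "imd": draw(imd_probs, n),
            "tenure": draw(tenure_probs, n),
            "house_type": draw(house_type_probs, n),
            "condition": draw(condition_probs, n),
        }
    )


def balanced_profiles(n_households: int) -> pd.DataFrame:
    """Deterministic household table cycling through every category level.

    Guarantees that all tenure and house-type levels appear whenever
    ``n_households >= 5``, so dummy-encoded designs are full rank; used
    for parameter-recovery experiments where rank is a precondition
    rather than a finding.
    """
    epc = list(EPC_PROBS)
    imd = list(IMD_PROBS)
    tenure = list(TENURE_PROBS)
    htype = list(HOUSE_TYPE_PROBS)
    cond = list(CONDITION_PROBS)
    width = max(2, len(str(n_households)))
    rows = [
        {
            "sensor_id": f"S{i+1:0{width}d}",
            "epc": epc[i % len(epc)],
            "imd": imd[i % len(imd)],
            "tenure": tenure[i % len(tenure)],
            "house_type": htype[i % len(htype)],
            "condition": cond[i % len(cond)],
        }
        for i in range(n_households)
    ]
    return pd.DataFrame(rows)


def _equilibrium_offset(encoded_row: pd.Series, coefs: dict) -> float:
    return float(sum(coefs.get(k, 0.0) * encoded_row.get(k, 0) for k in coefs))


def rc_response(
    t_eq: np.ndarray, tau_min: float, dt_min: float = 1.0, t0: float | None = None
) -> np.ndarray:
    """First-order relaxation toward a time-varying equilibrium.

    Exact exponential-integrator discretization: with k = 1 − e^(−Δt/τ),
    T[n] = (1−k)·T[n−1] + k·T_eq[n−1].  Initial state defaults to
    T_eq[0].  After a step change in T_eq the response reaches a fraction
    1 − e^(−t/τ) of the step at elapsed time t, exactly.
    """
    if tau_min <= 0:
        raise ValueError("time constant must be positive")
    k = 1.0 - np.exp(-dt_min / tau_min)
    x = np.asarray(t_eq, dtype=float)
    start = x[0] if t0 is None else float(t0)
    # y[n] = (1-k) y[n-1] + k x[n-1]  -> b=[0,k], a=[1,-(1-k)], state seeds y[0]
    y, _ = lfilter([0.0, k], [1.0, -(1.0 - k)], x, zi=[start])
    return y


def gen_indoor(
    outdoor: OutdoorSeries,
    profile: pd.Series,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
    *,
    tau_min: float | None = None,
) -> IndoorSeries:
    """Generate one household's 1-min indoor trace from the outdoor drive.

    The outdoor 5-min temperature is linearly interpolated to 1 min and
    fed through the RC response with the household's time constant; the
    equilibrium adds the covariate offsets for the household's encoded
    attributes.  ``profile`` is one row of the household table (needs
    sensor_id, epc, imd, tenure, house_type, condition).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    ic = config.indoor
    if tau_min is None:
        lo, hi = ic.time_constant_hours
        tau_min = float(rng.uniform(lo * 60.0, hi * 60.0))

    idx1 = pd.date_range(
        outdoor.timestamps[0], outdoor.timestamps[-1], freq="1min", name="timestamp"
    )
    t_out = (
        outdoor.temperature.reindex(outdoor.timestamps.union(idx1))
        .interpolate(method="time")
        .reindex(idx1)
        .to_numpy()
    )
    encoded = encode_households(profile.to_frame().T).iloc[0]
    t_eq = ic.intercept + ic.gain * t_out + _equilibrium_offset(encoded, ic.covariate_coefs)
    temp = rc_response(t_eq, tau_min) + rng.normal(0.0, ic.noise_sd, size=len(idx1))

    hours = idx1.hour.to_numpy() + idx1.minute.to_numpy() / 60.0
    rh = np.clip(
        config.rh.mean
        + config.rh.amplitude * np.sin(2.0 * np.pi * (hours - 23.0) / 24.0)
        + rng.normal(0.0, config.rh.noise_sd, size=len(idx1)),
        0.0,
        100.0,
    )
    return IndoorSeries(
        sensor_id=str(profile["sensor_id"]),
        data=pd.DataFrame({"temperature": temp, "relative_humidity": rh}, index=idx1),
    )


def gen_cohort(
    config: SyntheticConfig,
) -> tuple[OutdoorSeries, pd.DataFrame, dict[str, IndoorSeries], GroundTruth]:
    """Generate the full study: weather, households, indoor traces, truth."""
    rng = np.random.default_rng(config.seed)
    outdoor = gen_outdoor(config, rng)
    profiles = gen_households(config, rng)
    lo, hi = config.indoor.time_constant_hours
    taus = {
        sid: float(rng.uniform(lo * 60.0, hi * 60.0)) for sid in profiles["sensor_id"]
    }
    indoor = {
        str(row["sensor_id"]): gen_indoor(
            outdoor, row, config, rng, tau_min=taus[row["sensor_id"]]
        )
        for _, row in profiles.iterrows()
    }
    truth = GroundTruth(
        seed=config.seed,
        time_constants_min=taus,
        gain=config.indoor.gain,
        intercept=config.indoor.intercept,
        covariate_coefs=dict(config.indoor.covariate_coefs),
    )
    return outdoor, profiles, indoor, truth


def gen_cohort_linear(
    config: SyntheticConfig,
    *,
    gain: float = 0.22,
    lag_gain: float = 0.0,
    lag_steps: int = 72,
    intercept: float = 18.3,
    noise_sd: float = 1.0,
    profiles: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate a 5-min cohort directly from the pooled linear equation.

    T_in = intercept + gain·T_out + lag_gain·T_out(t − lag) + covariate
    effects + iid noise.  Returns (joined long table with sensor_id,
    timestamp, T_in, T_out; raw profiles; truth dict).  Used for OLS
    parameter-recovery testing, where the estimand is the generating
    coefficient itself rather than an RC response.  ``profiles`` defaults
    to :func:`balanced_profiles` so every dummy level is represented and
    the design is full rank.
    """
    rng = np.random.default_rng(config.seed)
    outdoor = gen_outdoor(config, rng)
    if profiles is None:
        profiles = balanced_profiles(config.n_households)
    encoded = encode_households(profiles)
    coefs = config.indoor.covariate_coefs

    t_out = outdoor.temperature.to_numpy()
    frames = []
    for sid in profiles["sensor_id"]:
        offset = _equilibrium_offset(encoded.loc[sid], coefs)
        t_in = intercept + gain * t_out + offset
        if lag_gain != 0.0:
            lagged = np.full_like(t_out, np.nan)
            lagged[lag_steps:] = t_out[:-lag_steps]
            t_in = t_in + lag_gain * lagged
        t_in = t_in + rng.normal(0.0, noise_sd, size=len(t_out))
        frames.append(
            pd.DataFrame(
                {
                    "sensor_id": sid,
                    "timestamp": outdoor.timestamps,
                    "T_in": t_in,
                    "T_out": t_out,
                }
            )
        )
    joined = pd.concat(frames, ignore_index=True).dropna(subset=["T_in"])
    truth = {
        "gain": gain,
        "lag_gain": lag_gain,
        "lag_steps": lag_steps,
        "intercept": intercept,
        "covariate_coefs": dict(coefs),
    }
    return joined, profiles, truth


def make_fixture_bundle(config: SyntheticConfig, out_dir: str | Path) -> dict:
    """Write the whole synthetic study to disk as plain CSV + JSON.

    Produces one ``<sensor_id>.csv`` per household (timestamp,
    temperature, relative_humidity), ``weather.csv``, ``households.csv``
    and ``ground_truth.json``.  Deterministic under (config, seed).
    Returns a manifest of written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outdoor, profiles, indoor, truth = gen_cohort(config)

    manifest = {"sensors": [], "weather": None, "households": None, "ground_truth": None}
    for sid, series in indoor.items():
        p = out_dir / f"{sid}.csv"
        series.data.round(4).to_csv(p, index_label="timestamp")
        manifest["sensors"].append(str(p))
    p = out_dir / "weather.csv"
    outdoor.data.round(4).to_csv(p, index_label="timestamp")
    manifest["weather"] = str(p)
    p = out_dir / "households.csv"
    profiles.to_csv(p, index=False)
    manifest["households"] = str(p)
    p = out_dir / "ground_truth.json"
    p.write_text(truth.to_json())
    manifest["ground_truth"] = str(p)
    return manifest
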