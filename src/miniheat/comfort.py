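"""Heat index, NWS risk categories and psychrometric comfort evaluation.

The heat index is the nine-term Rothfusz regression in its native °F
scale, applied to every reading (including below 80 °F, where the NWS
intended a simpler fallback — an opt-in fallback is provided but off by
default).  Risk categories follow the National Weather Service bands
converted to °C at one-decimal rounding: <26.7 comfortable, 26.7–32.2
caution, 32.2–39.4 extreme caution, 39.4–51.1 danger, ≥51.1 extreme
danger.  Cut points belong to the upper bin.

Psychrometric state (humidity ratio, specific enthalpy) uses the standard
moist-air relations with Hyland–Wexler saturation pressure over liquid
water; comfort-zone membership is a point-in-polygon test in
(dry-bulb °C, humidity ratio kg/kg) coordinates against a fixed,
overridable polygon approximating the ASHRAE-55 graphical summer
(0.5 clo) zone at an indoor air speed of 0.1 m s⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely

CATEGORIES = (
    "comfortable",
    "caution",
    "extreme_caution",
    "danger",
    "extreme_danger",
)

#: Standard sea-level atmospheric pressure, Pa.
STANDARD_PRESSURE = 101325.0

#: Fixed indoor air speed assumed for comfort evaluation, m/s.
INDOOR_AIR_VELOCITY = 0.1

# Summer-clothing comfort zone, vertices (dry-bulb °C, humidity ratio kg/kg).
# Lower humidity bound ~ dew point 2.8 °C; upper bound W = 0.012; warm edge
# slants so that drier air tolerates slightly warmer dry-bulb temperatures.
DEFAULT_COMFORT_ZONE = (
    (23.0, 0.0046),
    (27.0, 0.0046),
    (26.0, 0.012),
    (22.5, 0.012),
)


@dataclass(frozen=True)
class CategoryBoundaries:
    """Ordered NWS heat-index cut points in °C (80/90/103/124 °F origins)."""

    cuts_c: tuple[float, ...] = (26.7, 32.2, 39.4, 51.1)

    def __post_init__(self):
        cuts = tuple(float(c) for c in self.cuts_c)
        if len(cuts) != 4 or any(b <= a for a, b in zip(cuts, cuts[1:])):
            raise ValueError("boundaries must be four strictly increasing cuts")
        object.__setattr__(self, "cuts_c", cuts)


DEFAULT_BOUNDARIES = CategoryBoundaries()


def c_to_f(t_c):
    return np.asarray(t_c, dtype=float) * 9.0 / 5.0 + 32.0


def f_to_c(t_f):
    return (np.asarray(t_f, dtype=float) - 32.0) * 5.0 / 9.0


def heat_index_f(tf, rh, *, low_temp_fallback: bool = False):
    """Rothfusz nine-term heat-index regression, °F in and out.

    Parameters
    ----------
    tf
        Dry-bulb temperature in °F (scalar or array).
    rh
        Relative humidity in percent, 0–100.
    low_temp_fallback
        If True, below 80 °F return the NWS simple average formula
        ``0.5*(TF + 61 + (TF-68)*1.2 + RH*0.094)`` instead of the
        polynomial.  Off by default: the study applies the polynomial to
        every reading.
    """
    tf = np.asarray(tf, dtype=float)
    rh = np.asarray(rh, dtype=float)
    if np.any((rh < 0.0) | (rh > 100.0)):
        raise ValueError("relative humidity must lie in [0, 100]")
    hi = (
        -42.379
        + 2.04901523 * tf
        + 10.14333127 * rh
        - 0.22475541 * tf * rh
        - 6.83783e-3 * tf**2
        - 5.481717e-2 * rh**2
        + 1.22874e-3 * tf**2 * rh
        + 8.5282e-4 * tf * rh**2
        - 1.99e-6 * tf**2 * rh**2
    )
    if low_temp_fallback:
        simple = 0.5 * (tf + 61.0 + (tf - 68.0) * 1.2 + rh * 0.094)
        hi = np.where(tf < 80.0, simple, hi)
    return hi if hi.ndim else float(hi)


def classify_heat_index(hi_c, boundaries: CategoryBoundaries = DEFAULT_BOUNDARIES):
    """Map heat index (°C) onto NWS risk categories.

    Binning is half-open with each cut point belonging to the upper
    category (26.7 °C classifies as caution).
    """
    hi_c = np.asarray(hi_c, dtype=float)
    idx = np.searchsorted(np.asarray(boundaries.cuts_c), hi_c, side="right")
    if np.ndim(idx) == 0:
        return CATEGORIES[int(idx)]
    return np.take(np.asarray(CATEGORIES, dtype=object), idx)


# Hyland–Wexler (ASHRAE) constants for saturation pressure over liquid water.
_HW = (-5800.2206, 1.3914993, -0.048640239, 4.1764768e-5, -1.4452093e-8, 6.5459673)


def saturation_vapour_pressure(t_c):
    """Saturation vapour pressure over liquid water, Pa (Hyland–Wexler).

    Valid for dry-bulb temperatures in −50…100 °C; ≈2339 Pa at 20 °C and
    ≈101325 Pa at 100 °C.
    """
    t_c = np.asarray(t_c, dtype=float)
    if np.any((t_c < -50.0) | (t_c > 100.0)):
        raise ValueError("temperature outside supported range −50…100 °C")
    t_k = t_c + 273.15
    c8, c9, c10, c11, c12, c13 = _HW
    ln_p = c8 / t_k + c9 + c10 * t_k + c11 * t_k**2 + c12 * t_k**3 + c13 * np.log(t_k)
    p = np.exp(ln_p)
    return p if p.ndim else float(p)


def humidity_ratio(t_c, rh, pressure: float = STANDARD_PRESSURE):
    """Humidity ratio W (kg water vapour / kg dry air).

    W = 0.621945 · p_v / (P − p_v) with p_v = (RH/100) · p_ws(T).
    Raises ``ValueError`` if the partial vapour pressure reaches total
    pressure.
    """
    rh = np.asarray(rh, dtype=float)
    p_v = rh / 100.0 * saturation_vapour_pressure(t_c)
    if np.any(p_v >= pressure):
        raise ValueError("vapour pressure must be below total pressure")
    w = 0.621945 * p_v / (pressure - p_v)
    return w if w.ndim else float(w)


def enthalpy(t_c, w):
    """Specific enthalpy of moist air, kJ per kg dry air.

    h = 1.006·T + W·(2501 + 1.86·T); zero at the 0 °C dry-air reference.
    """
    t_c = np.asarray(t_c, dtype=float)
    w = np.asarray(w, dtype=float)
    if np.any(w < 0.0):
        raise ValueError("humidity ratio must be non-negative")
    h = 1.006 * t_c + w * (2501.0 + 1.86 * t_c)
    return h if h.ndim else float(h)


def in_comfort_zone(t_c, w, polygon=None):
    """Membership of (dry-bulb, humidity-ratio) states in the comfort zone.

    Points on the polygon boundary count as inside.  ``polygon`` is a
    sequence of (T, W) vertices overriding :data:`DEFAULT_COMFORT_ZONE`.
    """
    verts = DEFAULT_COMFORT_ZONE if polygon is None else tuple(polygon)
    poly = shapely.Polygon(verts)
    t_c = np.asarray(t_c, dtype=float)
    w = np.asarray(w, dtype=float)
    inside = shapely.intersects_xy(poly, t_c, w)
    return inside if inside.ndim else bool(inside)


def compute_comfort(
    series,
    *,
    boundaries: CategoryBoundaries = DEFAULT_BOUNDARIES,
    polygon=None,
    pressure: float = STANDARD_PRESSURE,
) -> pd.DataFrame:
    """Per-reading comfort table for an indoor series.

    Returns a frame indexed by timestamp with columns T_db, RH, TF, HI_F,
    HI_C, category, W, h, in_comfort_zone.
    """
    t = series.temperature.to_numpy(dtype=float)
    rh = series.relative_humidity.to_numpy(dtype=float)
    tf = c_to_f(t)
    hi_f = heat_index_f(tf, rh)
    hi_c = f_to_c(hi_f)
    w = humidity_ratio(t, rh, pressure)
    return pd.DataFrame(
        {
            "T_db": t,
            "RH": rh,
            "TF": tf,
            "HI_F": hi_f,
            "HI_C": hi_c,
            "category": classify_heat_index(hi_c, boundaries),
            "W": w,
            "h": enthalpy(t, w),
            "in_comfort_zone": in_comfort_zone(t, w, polygon),
        },
        index=series.timestamps,
    )


def exposure_summary(categories, heatwave_mask) -> pd.DataFrame:
    """Category shares (%) inside and outside outdoor-heatwave periods.

    ``categories`` is a sequence of category labels per reading and
    ``heatwave_mask`` an aligned boolean sequence.  Returns a frame with
    one row per category and columns ``heatwave`` / ``non_heatwave``,
    each column summing to 100 within rounding.  Raises ``ValueError`` if
    either partition is empty.
    """
    cats = pd.Series(np.asarray(categories, dtype=object))
    mask = np.asarray(heatwave_mask, dtype=bool)
    if len(cats) != len(mask):
        raise ValueError("mask must align with readings")
    out = {}
    for name, part in (("heatwave", cats[mask]), ("non_heatwave", cats[~mask])):
        if part.empty:
            raise ValueError(f"empty partition: {name}")
        share = part.value_counts(normalize=True) * 100.0
        out[name] = share
    table = pd.DataFrame(out).reindex(list(CATEGORIES)).fillna(0.0)
    table.index.name = "category"
    return table
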