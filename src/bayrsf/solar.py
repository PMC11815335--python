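"""Solar-position calculations (NOAA general solar equations).

Used to split telemetry fixes into day and night at each fix's own timestamp:
a fix is "day" when the sun's altitude exceeds the standard refraction-corrected
sunrise/sunset threshold of -0.833 degrees. Accuracy of the underlying
approximation is a few minutes of sunrise/sunset time, ample for diel
classification of animal telemetry.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["solar_altitude", "is_day", "SUNRISE_ALTITUDE_DEG"]

# refraction-corrected horizon: 50 arcmin below geometric horizon
SUNRISE_ALTITUDE_DEG = -0.833


def _fractional_year(ts: pd.DatetimeIndex) -> np.ndarray:
    doy = ts.dayofyear.to_numpy()
    hour = ts.hour.to_numpy() + ts.minute.to_numpy() / 60 + ts.second.to_numpy() / 3600
    return 2 * np.pi / 365.0 * (doy - 1 + (hour - 12) / 24)


def solar_altitude(timestamps, lon, lat) -> np.ndarray:
    """Solar altitude in degrees for UTC timestamps at (lon, lat) in degrees.

    Vectorised over timestamps; lon/lat may be scalars or arrays of the same
    length.
    """
    ts = pd.DatetimeIndex(pd.to_datetime(timestamps, utc=True)).tz_convert("UTC")
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)

    g = _fractional_year(ts)
    eqtime = 229.18 * (
        0.000075
        + 0.001868 * np.cos(g)
        - 0.032077 * np.sin(g)
        - 0.014615 * np.cos(2 * g)
        - 0.040849 * np.sin(2 * g)
    )
    decl = (
        0.006918
        - 0.399912 * np.cos(g)
        + 0.070257 * np.sin(g)
        - 0.006758 * np.cos(2 * g)
        + 0.000907 * np.sin(2 * g)
        - 0.002697 * np.cos(3 * g)
        + 0.00148 * np.sin(3 * g)
    )

    minutes_utc = (
        ts.hour.to_numpy() * 60.0 + ts.minute.to_numpy() + ts.second.to_numpy() / 60.0
    )
    true_solar_time = minutes_utc + eqtime + 4.0 * lon  # minutes
    hour_angle = np.deg2rad(true_solar_time / 4.0 - 180.0)

    lat_r = np.deg2rad(lat)
    cos_zen = np.sin(lat_r) * np.sin(decl) + np.cos(lat_r) * np.cos(decl) * np.cos(
        hour_angle
    )
    cos_zen = np.clip(cos_zen, -1.0, 1.0)
    return 90.0 - np.rad2deg(np.arccos(cos_zen))


def is_day(timestamps, lon, lat) -> np.ndarray:
    """Boolean day/night classification at the fix's own instant."""
    return solar_altitude(timestamps, lon, lat) > SUNRISE_ALTITUDE_DEG
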