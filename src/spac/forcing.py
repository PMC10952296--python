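"""Meteorological forcing: construction, validation and the percentile day.

A forcing series is a :class:`pandas.DataFrame` with one row per hour and the
columns ``time, Ta, RH, SWdown, Patm, wind, precip, ca, D``:

========  ===========================================  =============
column    meaning                                      units
========  ===========================================  =============
time      hour-beginning timestamp                     datetime
Ta        air temperature                              degC
RH        relative humidity                            0-1
SWdown    downwelling shortwave radiation              W m-2
Patm      atmospheric pressure                         Pa
wind      wind speed                                   m s-1
precip    precipitation                                mm h-1
ca        atmospheric CO2 mixing ratio                 umol mol-1
D         vapour pressure deficit (derived)            Pa
========  ===========================================  =============

The vapour pressure deficit is always derived from temperature and relative
humidity, D = (1 - RH) * esat(Ta), so RH = 1 implies D = 0 exactly.

The module also builds the synthetic "average warm and sunny day" used by the
dry-down experiments: per-hour 75th percentiles of temperature and radiation
over the most active months of a multi-year archive, a chosen relative-humidity
percentile (10% for a high-VPD scenario, 90% for a low-VPD one), and per-hour
medians of everything else.
"""

from __future__ import annotations

import math
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .constants import PAR_FRACTION, UMOL_PER_J_PAR

FORCING_COLUMNS = ["time", "Ta", "RH", "SWdown", "Patm", "wind", "precip", "ca", "D"]

#: Tetens coefficients (611 Pa base)
_TETENS_A = 611.0
_TETENS_B = 17.502
_TETENS_C = 240.97


class ForcingRecord(NamedTuple):
    """One hourly record of meteorological drivers (plain floats, fast access)."""

    Ta: float
    RH: float
    SWdown: float
    Patm: float
    wind: float
    precip: float
    ca: float
    D: float


def esat(ta):
    """Saturation vapour pressure [Pa] at air temperature ``ta`` [degC].

    Tetens formulation, esat(0 degC) = 611 Pa. Accepts scalars or arrays.
    Raises ``ValueError`` outside the meteorological range [-50, 60] degC.
    """
    ta_arr = np.asarray(ta, dtype=float)
    if np.any(ta_arr < -50.0) or np.any(ta_arr > 60.0):
        raise ValueError("air temperature outside [-50, 60] degC")
    out = _TETENS_A * np.exp(_TETENS_B * ta_arr / (_TETENS_C + ta_arr))
    return float(out) if np.isscalar(ta) or ta_arr.ndim == 0 else out


def esat_scalar(ta: float) -> float:
    """Scalar fast path of :func:`esat` (no range check)."""
    return _TETENS_A * math.exp(_TETENS_B * ta / (_TETENS_C + ta))


def vpd_from_rh(ta, rh):
    """Vapour pressure deficit D = (1 - RH) * esat(Ta) [Pa].

    ``rh`` must lie in [0, 1]. Returns 0 exactly at saturation.
    """
    rh_arr = np.asarray(rh, dtype=float)
    if np.any(rh_arr < 0.0) or np.any(rh_arr > 1.0):
        raise ValueError("relative humidity outside [0, 1]")
    out = (1.0 - rh_arr) * esat(ta)
    scalar = np.isscalar(rh) and np.isscalar(ta)
    return float(out) if scalar else out


def par_from_shortwave(swdown):
    """Photosynthetically active radiation [umol photons m-2 s-1] from SW [W m-2]."""
    return PAR_FRACTION * UMOL_PER_J_PAR * np.asarray(swdown, dtype=float)


def make_forcing(df: pd.DataFrame, validate: bool = True) -> pd.DataFrame:
    """Normalise a raw hourly table into a validated forcing series.

    Requires ``time`` plus the driver columns; ``D`` is (re)derived from
    ``Ta`` and ``RH``. If only ``D`` is present, RH is back-computed.
    """
    df = df.copy()
    missing = {"time", "Ta", "SWdown", "Patm", "wind", "precip", "ca"} - set(df.columns)
    if missing:
        raise ValueError(f"missing forcing columns: {sorted(missing)}")
    if "RH" not in df.columns:
        if "D" not in df.columns:
            raise ValueError("forcing needs either an RH or a D column")
        df["RH"] = np.clip(1.0 - df["D"].to_numpy() / esat(df["Ta"].to_numpy()), 0.0, 1.0)
    df["D"] = vpd_from_rh(df["Ta"].to_numpy(), df["RH"].to_numpy())
    df["time"] = pd.to_datetime(df["time"])
    df = df[FORCING_COLUMNS]
    if validate:
        _validate(df)
    return df.reset_index(drop=True)


def _validate(df: pd.DataFrame) -> None:
    t = df["time"]
    if t.duplicated().any():
        raise ValueError("duplicated timestamps in forcing")
    if not t.is_monotonic_increasing:
        raise ValueError("non-monotone timestamps in forcing")
    if len(t) > 1:
        steps = t.diff().dropna().unique()
        if len(steps) != 1 or steps[0] != pd.Timedelta(hours=1):
            raise ValueError("forcing is not hourly-regular (gaps or irregular steps)")
    for col, lo, hi in [
        ("RH", 0.0, 1.0),
        ("SWdown", 0.0, 1500.0),
        ("precip", 0.0, 500.0),
        ("Patm", 3.0e4, 1.2e5),
        ("wind", 0.0, 80.0),
        ("ca", 100.0, 2000.0),
    ]:
        v = df[col]
        if v.isna().any():
            raise ValueError(f"gap (NaN) in forcing column {col}")
        if (v < lo).any() or (v > hi).any():
            raise ValueError(f"forcing column {col} outside declared range [{lo}, {hi}]")
    if df["Ta"].isna().any():
        raise ValueError("gap (NaN) in forcing column Ta")


def iter_records(df: pd.DataFrame):
    """Iterate a forcing series as :class:`ForcingRecord` tuples (fast loop path)."""
    cols = [df[c].to_numpy(dtype=float) for c in FORCING_COLUMNS[1:]]
    for i in range(len(df)):
        yield ForcingRecord(*(col[i] for col in cols))


# ---------------------------------------------------------------------------
# synthetic archive and percentile day


def synthetic_archive(
    n_years: int = 3,
    seed: int = 0,
    ta_mean: float = 24.0,
    ta_diurnal_amp: float = 7.0,
    ta_day_sigma: float = 2.0,
    sw_peak: float = 900.0,
    rh_night: float = 0.85,
    rh_day_drop: float = 0.5,
    rh_sigma: float = 0.10,
    wind_mean: float = 2.0,
    patm: float = 101325.0,
    ca: float = 400.0,
    daylight_hours: float = 14.0,
) -> pd.DataFrame:
    """Generate a multi-year hourly forcing archive for a warm growing season.

    The generator emulates the statistical structure a percentile-day
    composite needs: a sinusoidal diurnal temperature cycle with day-to-day
    anomalies, clear-sky shortwave radiation modulated by a random daily cloud
    factor, relative humidity anti-correlated with temperature, and occasional
    convective rain. Values are for the three most active (summer) months,
    June-August of consecutive years.
    """
    rng = np.random.default_rng(seed)
    days_per_year = 92  # Jun-Aug
    n_days = n_years * days_per_year
    hours = np.arange(24)
    # solar elevation proxy: positive between sunrise and sunset
    sunrise = 12.0 - daylight_hours / 2.0
    elev = np.sin(np.pi * np.clip((hours + 0.5 - sunrise) / daylight_hours, 0.0, 1.0))

    frames = []
    for d in range(n_days):
        year = 2000 + d // days_per_year
        doy = d % days_per_year
        t0 = pd.Timestamp(f"{year}-06-01") + pd.Timedelta(days=int(doy))
        ta_anom = rng.normal(0.0, ta_day_sigma)
        cloud = rng.beta(5.0, 1.5)  # mostly sunny season
        # temperature lags radiation by ~2 h
        ta = ta_mean + ta_anom + ta_diurnal_amp * np.sin(
            np.pi * np.clip((hours + 0.5 - sunrise - 2.0) / daylight_hours, 0.0, 1.0)
        ) - 0.5 * ta_diurnal_amp * (elev == 0)
        sw = sw_peak * cloud * elev
        rh = np.clip(
            rh_night
            - rh_day_drop * (ta - ta.min()) / max(np.ptp(ta), 1e-6)
            + rng.normal(0.0, rh_sigma),
            0.05,
            1.0,
        )
        precip = np.zeros(24)
        if rng.random() < 0.15:  # occasional afternoon shower
            precip[rng.integers(14, 19)] = rng.exponential(4.0)
        frames.append(
            pd.DataFrame(
                {
                    "time": t0 + pd.to_timedelta(hours, unit="h"),
                    "Ta": ta,
                    "RH": rh,
                    "SWdown": sw,
                    "Patm": patm,
                    "wind": rng.normal(wind_mean, 0.3, 24).clip(0.1),
                    "precip": precip,
                    "ca": ca,
                }
            )
        )
    # an archive is a sampling pool, not a simulation driver: it legitimately
    # skips the months outside the growing season, so no regularity check
    return make_forcing(pd.concat(frames, ignore_index=True), validate=False)


def make_percentile_day(
    archive: pd.DataFrame,
    months: Sequence[int],
    rh_percentile: float,
) -> pd.DataFrame:
    """Compose the 24-hour percentile day from a multi-year hourly archive.

    Per hour of day, over all archive days falling in ``months``: temperature
    and shortwave radiation are the 75th percentile, relative humidity the
    requested percentile (0.10 for high VPD, 0.90 for low), and all other
    drivers the median. D is recomputed from the composed Ta and RH, and
    precipitation is zeroed (the composite drives precipitation-free
    dry-downs).
    """
    if not 0.0 < rh_percentile < 1.0:
        raise ValueError("rh_percentile must be in (0, 1)")
    months = list(months)
    if not months:
        raise ValueError("empty month selection")
    sel = archive[archive["time"].dt.month.isin(months)]
    if sel.empty:
        raise ValueError(f"archive has no data in months {months}")
    hod = sel["time"].dt.hour
    grouped = sel.groupby(hod)
    day = pd.DataFrame(
        {
            "Ta": grouped["Ta"].quantile(0.75),
            "SWdown": grouped["SWdown"].quantile(0.75),
            "RH": grouped["RH"].quantile(rh_percentile),
            "Patm": grouped["Patm"].median(),
            "wind": grouped["wind"].median(),
            "ca": grouped["ca"].median(),
        }
    ).sort_index()
    day["precip"] = 0.0
    day["time"] = pd.Timestamp("2001-01-01") + pd.to_timedelta(day.index, unit="h")
    return make_forcing(day.reset_index(drop=True))


def repeat_forcing(day: pd.DataFrame, n_days: int) -> pd.DataFrame:
    """Tile a 24-hour day ``n_days`` times with zero precipitation (dry-down)."""
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    if len(day) != 24:
        raise ValueError("repeat_forcing expects a 24-record day")
    rep = pd.concat([day] * n_days, ignore_index=True)
    rep["precip"] = 0.0
    t0 = day["time"].iloc[0]
    rep["time"] = t0 + pd.to_timedelta(np.arange(24 * n_days), unit="h")
    return make_forcing(rep)


# ---------------------------------------------------------------------------
# I/O


def read_forcing_csv(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read an hourly forcing CSV, optionally renaming via ``column_map``.

    ``column_map`` maps file column names to canonical names (e.g.
    ``{"TA_F": "Ta"}``). Either an RH or a D column must be present; D is
    always rederived from Ta and RH after reading.
    """
    raw = pd.read_csv(path)
    if column_map:
        raw = raw.rename(columns=column_map)
    return make_forcing(raw)


def write_forcing_csv(df: pd.DataFrame, path) -> None:
    """Write a forcing series to CSV (canonical columns, ISO timestamps)."""
    df[FORCING_COLUMNS].to_csv(path, index=False)
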