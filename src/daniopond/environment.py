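"""Environmental forcing: water temperature, photoperiod and season logic.

A scenario is a day-indexed series of water temperature (°C) and
photoperiod (h).  Scenarios can be read from a plain TSV file or generated
for a Kolkata-like tropical monsoon climate (the natural habitat of wild
zebrafish populations in NE India / Bangladesh): a sinusoidal annual water
temperature and astronomical day length at 22.57° N.  Annual series are
extended cyclically; queries between records interpolate linearly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EnvironmentSeries",
    "load_scenario",
    "save_scenario",
    "conditions_at",
    "generate_monsoon_scenario",
    "reproduction_window",
    "monsoon_active",
    "KOLKATA_LATITUDE",
    "MONSOON_WINDOW",
]

KOLKATA_LATITUDE = 22.57
#: default monsoon window, days of year (June-September)
MONSOON_WINDOW = (152, 273)


@dataclass
class EnvironmentSeries:
    """Ordered day → (temperature °C, photoperiod h) records.

    ``period`` is the length of one annual cycle in days; a series whose
    records span at most one period is treated as cyclic beyond its end.
    """

    days: np.ndarray
    temperature: np.ndarray
    photoperiod: np.ndarray
    period: float = 365.0

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.photoperiod = np.asarray(self.photoperiod, dtype=float)
        if self.days.size == 0:
            raise ValueError("scenario must contain at least one record")
        if np.any(np.diff(self.days) <= 0):
            raise ValueError("scenario days must be strictly increasing")
        if np.any((self.photoperiod < 0) | (self.photoperiod > 24)):
            raise ValueError("photoperiod must lie in [0, 24] h")
        if np.any((self.temperature <= 0) | (self.temperature >= 45)):
            raise ValueError("water temperature must lie in (0, 45) °C")

    @property
    def is_annual(self) -> bool:
        return (self.days[-1] - self.days[0]) < self.period

    def __len__(self) -> int:
        return self.days.size


def load_scenario(path, period: float = 365.0) -> EnvironmentSeries:
    """Read a whitespace/tab-delimited scenario file.

    Columns: day, temperature (°C), photoperiod (h).  A non-numeric first
    line is treated as a header; ``#`` starts a comment.  Errors name the
    offending line.
    """
    days, temps, photos = [], [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns (day T photoperiod), got {len(parts)}")
            try:
                d, t, p = (float(x) for x in parts[:3])
            except ValueError:
                if lineno == 1:  # header line
                    continue
                raise ValueError(f"{path}:{lineno}: non-numeric value in {parts[:3]!r}") from None
            if not 0 <= p <= 24:
                raise ValueError(f"{path}:{lineno}: photoperiod {p} outside [0, 24] h")
            days.append(d)
            temps.append(t)
            photos.append(p)
    if not days:
        raise ValueError(f"{path}: no data rows")
    return EnvironmentSeries(np.array(days), np.array(temps), np.array(photos), period=period)


def save_scenario(series: EnvironmentSeries, path) -> None:
    """Write a scenario in the same TSV dialect load_scenario reads."""
    with open(path, "w") as fh:
        fh.write("day\ttemperature\tphotoperiod\n")
        for d, t, p in zip(series.days, series.temperature, series.photoperiod):
            fh.write(f"{d:g}\t{t:.4f}\t{p:.4f}\n")


def conditions_at(series: EnvironmentSeries, day) -> tuple:
    """(temperature, photoperiod) at a (possibly fractional) simulation day.

    Linear interpolation between records; annual series are extended
    cyclically, so day 366 of a 365-day series maps back to day 1.
    """
    day = np.asarray(day, dtype=float)
    if series.is_annual:
        d0 = series.days[0]
        day = d0 + np.mod(day - d0, series.period)
        # wrap-around interpolation: append the first record one period later
        xs = np.concatenate([series.days, [series.days[0] + series.period]])
        ts = np.concatenate([series.temperature, [series.temperature[0]]])
        ps = np.concatenate([series.photoperiod, [series.photoperiod[0]]])
    else:
        xs, ts, ps = series.days, series.temperature, series.photoperiod
    T = np.interp(day, xs, ts)
    P = np.interp(day, xs, ps)
    if T.ndim == 0:
        return float(T), float(P)
    return T, P


def day_length(day_of_year, latitude: float = KOLKATA_LATITUDE) -> np.ndarray:
    """Astronomical day length (h) from the standard solar-declination formula."""
    doy = np.asarray(day_of_year, dtype=float)
    decl = -23.44 * np.cos(np.deg2rad(360.0 / 365.0 * (doy + 10.0)))
    lat = np.deg2rad(latitude)
    cos_h = -np.tan(lat) * np.tan(np.deg2rad(decl))
    cos_h = np.clip(cos_h, -1.0, 1.0)
    out = 24.0 / np.pi * np.arccos(cos_h)
    return out if out.ndim else float(out)


def generate_monsoon_scenario(
    years: int = 3,
    mean_temperature: float = 25.0,
    amplitude: float = 6.0,
    peak_day: int = 160,
    latitude: float = KOLKATA_LATITUDE,
    start_day_of_year: int = 121,
) -> EnvironmentSeries:
    """Deterministic Kolkata-like forcing for ``years`` years.

    Water temperature is sinusoidal (default 19–31 °C, warmest in early
    June) and photoperiod is the astronomical day length at the given
    latitude.  ``start_day_of_year`` sets which calendar day simulation
    day 1 corresponds to (default 1 May, matching a breeding-season start).
    """
    if years < 1:
        raise ValueError("years must be >= 1")
    sim_days = np.arange(1, int(round(years * 365)) + 1, dtype=float)
    doy = np.mod(start_day_of_year - 1 + sim_days - 1, 365.0) + 1.0
    T = mean_temperature + amplitude * np.cos(2 * np.pi * (doy - peak_day) / 365.0)
    P = day_length(doy, latitude)
    return EnvironmentSeries(sim_days, T, P, period=365.0)


def reproduction_window(T, photoperiod, T_threshold: float = 22.5, P_threshold: float = 12.0):
    """True iff both the photoperiod and temperature reproduction gates are open.

    Spawning requires photoperiod ≥ 12 h AND water ≥ 22.5 °C; the
    photoperiod gate dominates juvenile recruitment seasonality.
    """
    out = np.logical_and(np.asarray(photoperiod) >= P_threshold, np.asarray(T) >= T_threshold)
    return out if out.ndim else bool(out)


def monsoon_active(day, window: tuple = MONSOON_WINDOW, start_day_of_year: int = 1):
    """True iff the day falls inside the monsoon day-of-year window.

    ``day`` is interpreted as day-of-year unless ``start_day_of_year``
    offsets simulation day 1 onto another calendar day.
    """
    lo, hi = window
    if hi < lo:
        return np.zeros(np.shape(day), dtype=bool) if np.ndim(day) else False
    doy = np.mod(start_day_of_year - 1 + np.asarray(day, dtype=float) - 1, 365.0) + 1.0
    out = np.logical_and(doy >= lo, doy <= hi)
    return out if out.ndim else bool(out)
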