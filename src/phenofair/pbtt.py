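"""Cumulative photo-beta thermal time (PBTT).

PBTT is a per-environment covariate summarizing how much developmentally
useful time a trial accumulated, combining temperature and day length.  Each
day contributes

    f_photo(P_d) * f_beta(T_d)

where ``f_beta`` is the beta thermal-response function — zero at or below a
base temperature, zero at or above a ceiling, and maximal (1) at the
optimum — and ``f_photo`` is a bounded photoperiod multiplier in [0, 1]
that discounts days shorter than a critical photoperiod.  The cumulative
value is the sum of daily contributions over the trial window.

The functional family and the cardinal-temperature defaults below are
package configuration (documented in docs/methods.md); different crops or
analyses may override any of them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date, timedelta
from typing import Iterable

from .model import PhenofairError, WeatherObservation

__all__ = ["PbttParams", "beta_thermal_response", "photoperiod_response",
           "daily_pbtt", "cumulative_pbtt", "MissingWeather"]


class MissingWeather(PhenofairError):
    """The weather series does not cover the requested window."""

    def __init__(self, station_id: str, missing: list[tuple[date, str]]):
        self.station_id = station_id
        self.missing = missing
        shown = ", ".join(f"{d} ({v})" for d, v in missing[:5])
        more = "" if len(missing) <= 5 else f" (+{len(missing) - 5} more)"
        super().__init__(
            f"station {station_id!r} is missing weather readings for: {shown}{more}")


@dataclass(frozen=True)
class PbttParams:
    """Cardinal temperatures (°C), beta curvature, and photoperiod response.

    Defaults are potato-flavoured: development between 5.5 °C and 34.6 °C
    with an optimum at 23.4 °C, and full photoperiod credit for days of at
    least ``critical_photoperiod`` hours, discounted linearly at
    ``photoperiod_sensitivity`` per hour below it.
    """

    t_base: float = 5.5
    t_opt: float = 23.4
    t_ceil: float = 34.6
    curvature: float = 1.0
    critical_photoperiod: float = 14.0
    photoperiod_sensitivity: float = 0.2

    def __post_init__(self) -> None:
        if not (self.t_base < self.t_opt < self.t_ceil):
            raise ValueError(
                f"cardinal temperatures must satisfy t_base < t_opt < t_ceil, "
                f"got {self.t_base}, {self.t_opt}, {self.t_ceil}")
        for name in ("t_base", "t_opt", "t_ceil", "curvature",
                     "critical_photoperiod", "photoperiod_sensitivity"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


def beta_thermal_response(temperature_c: float, params: PbttParams) -> float:
    """Beta response: 0 at/below t_base and at/above t_ceil, 1 at t_opt."""
    tb, to, tc = params.t_base, params.t_opt, params.t_ceil
    if temperature_c <= tb or temperature_c >= tc:
        return 0.0
    rise = (temperature_c - tb) / (to - tb)
    fall = ((tc - temperature_c) / (tc - to)) ** ((tc - to) / (to - tb))
    return (rise * fall) ** params.curvature


def photoperiod_response(photoperiod_h: float, params: PbttParams) -> float:
    """Saturating multiplier in [0, 1]: 1 for days at/above the critical
    photoperiod, linearly discounted below it."""
    deficit = max(0.0, params.critical_photoperiod - photoperiod_h)
    return min(1.0, max(0.0, 1.0 - params.photoperiod_sensitivity * deficit))


def daily_pbtt(temperature_c: float, photoperiod_h: float,
               params: PbttParams) -> float:
    return photoperiod_response(photoperiod_h, params) * \
        beta_thermal_response(temperature_c, params)


def cumulative_pbtt(
    weather: Iterable[WeatherObservation],
    station_id: str,
    start_date: date,
    end_date: date,
    params: PbttParams = PbttParams(),
    *,
    on_missing: str = "error",
) -> float:
    """Sum of daily PBTT contributions over [start_date, end_date].

    Both the temperature and the photoperiod series of the station must
    cover every day of the window; a gap raises :class:`MissingWeather`
    listing the missing dates, unless ``on_missing='skip'`` (days lacking
    either reading then contribute nothing).  The result is non-negative
    and non-decreasing as the window extends.  An empty window
    (end before start) is 0.
    """
    if on_missing not in ("error", "skip"):
        raise PhenofairError(f"on_missing must be 'error' or 'skip', "
                             f"got {on_missing!r}")
    temp: dict[date, float] = {}
    photo: dict[date, float] = {}
    for o in weather:
        if o.station_id != station_id:
            continue
        if o.variable == "daily_mean_temperature_C":
            temp[o.date] = o.value
        elif o.variable == "photoperiod_hours":
            photo[o.date] = o.value

    total = 0.0
    missing: list[tuple[date, str]] = []
    d = start_date
    while d <= end_date:
        t_ok, p_ok = d in temp, d in photo
        if t_ok and p_ok:
            total += daily_pbtt(temp[d], photo[d], params)
        else:
            if not t_ok:
                missing.append((d, "daily_mean_temperature_C"))
            if not p_ok:
                missing.append((d, "photoperiod_hours"))
        d += timedelta(days=1)
    if missing and on_missing == "error":
        raise MissingWeather(station_id, missing)
    return total
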