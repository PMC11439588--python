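"""Hourly NCP/CR rate extraction from 3-hour closed-mesocosm incubations.

During an incubation the mesocosm is sealed, so the O2 concentration drifts
at the net community production rate.  Each incubation yields one ordinary
least-squares slope per hour (three hourly rates per 3-h incubation),
converted from a volumetric concentration change (umol/L/h) to an areal rate
(mmol O2 m-2 h-1) via the tank volume and footprint area.  Dark incubations
measure community respiration (CR, negative by convention) the same way.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .sensor_io import SensorSeries

__all__ = [
    "IncubationWindow",
    "MesocosmGeometry",
    "RateEstimate",
    "InsufficientData",
    "hourly_rate",
    "to_areal",
    "process_window",
    "process_schedule",
    "rates_to_frame",
    "cr_by_hour",
]

logger = logging.getLogger(__name__)

#: molar mass of O2, g/mol, for mg/L -> umol/L conversion
O2_MOLAR_MASS = 31.998


class InsufficientData(ValueError):
    """An hour window lacks the samples needed for a defensible slope."""


@dataclass(frozen=True)
class IncubationWindow:
    """One closed incubation of one mesocosm."""

    mesocosm_id: str
    treatment: str
    replicate: int
    start: pd.Timestamp
    end: pd.Timestamp
    mode: str  # "light" | "dark"

    def __post_init__(self) -> None:
        if self.end - self.start < pd.Timedelta(hours=1):
            raise ValueError("incubation must span at least 1 h")
        if self.mode not in ("light", "dark"):
            raise ValueError(f"mode must be light or dark, got {self.mode!r}")

    @property
    def n_hours(self) -> int:
        return int((self.end - self.start) / pd.Timedelta(hours=1))


@dataclass(frozen=True)
class MesocosmGeometry:
    """Tank volume (L) and footprint area (m2) for areal normalisation."""

    volume_l: float = 1000.0
    footprint_area_m2: float = float(np.pi * (1.1 / 2) ** 2)

    def __post_init__(self) -> None:
        if self.volume_l <= 0 or self.footprint_area_m2 <= 0:
            raise ValueError("volume and footprint area must be positive")


@dataclass(frozen=True)
class RateEstimate:
    """One hourly NCP/CR rate with its regression SE and driver context."""

    slope: float  # mmol O2 m-2 h-1
    se: float
    r2: float
    n: int
    hour_index: int  # 1..3 within the incubation
    mean_temp: float  # degC over the same hour
    mean_par: float  # mmol photons m-2 h-1 over the same hour
    mode: str
    mesocosm_id: str
    treatment: str
    replicate: int
    window_start: pd.Timestamp


def hourly_rate(segment: pd.Series) -> tuple[float, float, float, int]:
    """OLS slope of O2 concentration against time-in-hours for one hour.

    ``segment`` holds the retained samples inside one [t, t+1h) window.
    Returns ``(slope, se, r2, n)`` in concentration units per hour.  Raises
    :class:`InsufficientData` when fewer than 3 samples remain or they span
    less than 30 minutes of the hour.
    """
    if len(segment) < 3:
        raise InsufficientData(f"only {len(segment)} retained samples")
    span = segment.index[-1] - segment.index[0]
    if span < pd.Timedelta(minutes=30):
        raise InsufficientData(f"samples span only {span}")
    t_h = (segment.index - segment.index[0]) / pd.Timedelta(hours=1)
    y = segment.to_numpy(dtype=float)
    fit = stats.linregress(np.asarray(t_h), y)
    return float(fit.slope), float(fit.stderr), float(fit.rvalue**2), len(segment)


def to_areal(raw_slope: float, geom: MesocosmGeometry,
             units: str = "umol/L") -> float:
    """Convert a volumetric O2 slope to an areal rate (mmol O2 m-2 h-1).

    ``slope[umol/L/h] * volume[L] / 1000 / area[m2]``.  Slopes in mg/L/h are
    first converted to umol/L/h with the molar mass of O2.  Units must be
    declared explicitly; guessing is an error.
    """
    if units in ("umol/L", "umol/L/h"):
        umol = raw_slope
    elif units in ("mg/L", "mg/L/h"):
        umol = raw_slope * 1000.0 / O2_MOLAR_MASS
    else:
        raise ValueError(f"undeclared or unsupported O2 units {units!r}")
    return umol * geom.volume_l / 1000.0 / geom.footprint_area_m2


def _hour_mean(series: SensorSeries | None, t0, t1) -> float:
    if series is None:
        return float("nan")
    sel = series.retained().loc[t0:t1]
    # loc is label-inclusive on the right; drop an exact-boundary sample
    sel = sel[sel.index < t1]
    return float(sel.mean()) if len(sel) else float("nan")


def process_window(window: IncubationWindow, o2: SensorSeries,
                   temp: SensorSeries | None = None,
                   par: SensorSeries | None = None,
                   geom: MesocosmGeometry = MesocosmGeometry()) -> list[RateEstimate]:
    """All hourly rates for one incubation window.

    Hour windows are half-open, non-overlapping and anchored at the
    incubation start -- the only reading that yields exactly three rates per
    3-h incubation.  Hours that fail the sample requirements are skipped
    with a logged reason rather than aborting the whole window.
    """
    out: list[RateEstimate] = []
    o2_retained = o2.retained()
    for h in range(window.n_hours):
        t0 = window.start + pd.Timedelta(hours=h)
        t1 = t0 + pd.Timedelta(hours=1)
        seg = o2_retained.loc[t0:t1]
        seg = seg[seg.index < t1]
        try:
            slope, se, r2, n = hourly_rate(seg)
        except InsufficientData as exc:
            logger.warning(
                "%s %s hour %d skipped: %s", window.mesocosm_id,
                window.start, h + 1, exc,
            )
            continue
        out.append(
            RateEstimate(
                slope=to_areal(slope, geom, units=o2.units),
                se=to_areal(se, geom, units=o2.units),
                r2=r2,
                n=n,
                hour_index=h + 1,
                mean_temp=_hour_mean(temp, t0, t1),
                mean_par=_hour_mean(par, t0, t1),
                mode=window.mode,
                mesocosm_id=window.mesocosm_id,
                treatment=window.treatment,
                replicate=window.replicate,
                window_start=window.start,
            )
        )
    return out


def process_schedule(schedule: pd.DataFrame, series: dict,
                     geom: MesocosmGeometry = MesocosmGeometry()) -> pd.DataFrame:
    """Run :func:`process_window` over a whole incubation schedule.

    ``series`` maps ``(mesocosm_id, variable)`` to :class:`SensorSeries`
    (as produced by the scenario generator or loaded from disk).
    """
    estimates: list[RateEstimate] = []
    for row in schedule.itertuples():
        window = IncubationWindow(
            mesocosm_id=row.mesocosm_id, treatment=row.treatment,
            replicate=int(row.replicate), start=pd.Timestamp(row.start),
            end=pd.Timestamp(row.end), mode=row.mode,
        )
        estimates.extend(
            process_window(
                window,
                series[(row.mesocosm_id, "O2")],
                temp=series.get((row.mesocosm_id, "temperature")),
                par=series.get((row.mesocosm_id, "PAR")),
                geom=geom,
            )
        )
    return rates_to_frame(estimates)


def rates_to_frame(estimates: list[RateEstimate]) -> pd.DataFrame:
    """Rate estimates as a tidy table (one row per hourly rate)."""
    return pd.DataFrame([vars(e) for e in estimates])


def cr_by_hour(dark_rates: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SE community respiration per treatment per hour index.

    Accepts the rate table restricted to (or containing) dark rates and
    aggregates replicate slopes.  SE is the standard error of the mean
    across rates (0 when replicates are identical).
    """
    dark = dark_rates[dark_rates["mode"] == "dark"] if "mode" in dark_rates else dark_rates
    if not len(dark):
        raise ValueError("no dark rates to summarise")

    def _se(x):
        x = np.asarray(x, dtype=float)
        return float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0

    out = (
        dark.groupby(["treatment", "hour_index"])["slope"]
        .agg(mean="mean", se=_se, n="count")
        .reset_index()
    )
    return out
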