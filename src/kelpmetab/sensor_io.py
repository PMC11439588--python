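"""Reading, calibrating, QC-filtering and resampling mesocosm sensor series.

A :class:`SensorSeries` is one variable (O2, temperature, salinity or PAR)
from one mesocosm, as a pandas Series with a strictly increasing UTC
DatetimeIndex plus a per-sample boolean QC mask.  Filters never drop or alter
samples -- they only clear mask bits -- so replicate series stay aligned and
every decision is auditable.

The outlier filters mirror standard practice for moored-sensor QC: a
percentile threshold (0.001 / 0.995) for temperature and salinity, and a
Tukey-style inter-quartile-range fence (1.2 x IQR) for PAR.  Thresholds are
computed from all finite values of the series, which makes both filters
exactly idempotent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SensorSeries",
    "Dialect",
    "SensorIOError",
    "read_series",
    "write_series",
    "filter_percentile",
    "filter_iqr",
    "apply_offset",
    "fill_replicate",
    "hourly_mean",
]

logger = logging.getLogger(__name__)

VARIABLES = ("O2", "temperature", "salinity", "PAR")

#: canonical units per variable; O2 may alternatively be declared as mg/L
DEFAULT_UNITS = {
    "O2": "umol/L",
    "temperature": "degC",
    "salinity": "psu",
    "PAR": "mmol photons/m2/h",
}


class SensorIOError(ValueError):
    """Malformed sensor file (bad row, units, or timestamp ordering)."""


@dataclass
class SensorSeries:
    """One mesocosm sensor variable with QC state.

    ``qc_mask`` is True for retained samples.  ``meta`` accumulates
    provenance (calibrations applied, filters run, replicate fills).
    """

    mesocosm_id: str
    treatment: str
    replicate: int
    variable: str
    data: pd.Series
    qc_mask: np.ndarray
    units: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.variable not in VARIABLES:
            raise ValueError(f"unknown variable {self.variable!r}")
        if not self.data.index.is_monotonic_increasing or self.data.index.has_duplicates:
            raise SensorIOError("timestamps must be strictly increasing")
        self.qc_mask = np.asarray(self.qc_mask, dtype=bool)
        if len(self.qc_mask) != len(self.data):
            raise ValueError("qc_mask length must match data length")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return self.data.index

    def retained(self) -> pd.Series:
        """The samples that survived QC."""
        return self.data[self.qc_mask]

    def n_masked(self) -> int:
        return int((~self.qc_mask).sum())

    def copy_with(self, **changes) -> "SensorSeries":
        out = replace(self, **changes)
        out.meta = dict(self.meta, **changes.get("meta", {}))
        return out


@dataclass(frozen=True)
class Dialect:
    """How a delimited sensor file is laid out."""

    delimiter: str = ","
    timestamp_format: str | None = None  # None -> ISO-8601
    comment: str = "#"


def _parse_timestamp(text: str, fmt: str | None) -> pd.Timestamp:
    if fmt is None:
        return pd.Timestamp(text)
    return pd.Timestamp.strptime(text, fmt)


def read_series(path, dialect: Dialect = Dialect(), *, variable: str | None = None,
                units: str | None = None) -> SensorSeries:
    """Parse a delimited sensor file into a :class:`SensorSeries`.

    Metadata lines (``# key=value``) carry mesocosm id, treatment, replicate,
    variable and units; explicit ``variable``/``units`` arguments override
    them.  Blank lines are tolerated with a logged warning; any other
    malformed row raises :class:`SensorIOError` with its line number.  Units
    must be declared somewhere -- they are never inferred from values.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    times: list[pd.Timestamp] = []
    vals: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                logger.warning("%s:%d: blank line skipped", path.name, lineno)
                continue
            if line.startswith(dialect.comment):
                body = line.lstrip(dialect.comment).strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    meta[key.strip()] = val.strip()
                continue
            parts = line.split(dialect.delimiter)
            if parts[0].strip().lower() in ("timestamp", "time"):
                continue  # header row
            if len(parts) != 2:
                raise SensorIOError(
                    f"{path.name}:{lineno}: expected 2 fields, got {len(parts)}"
                )
            try:
                ts = _parse_timestamp(parts[0].strip(), dialect.timestamp_format)
            except (ValueError, TypeError) as exc:
                raise SensorIOError(
                    f"{path.name}:{lineno}: unparseable timestamp {parts[0]!r}"
                ) from exc
            try:
                val = float(parts[1])
            except ValueError as exc:
                raise SensorIOError(
                    f"{path.name}:{lineno}: unparseable value {parts[1]!r}"
                ) from exc
            times.append(ts)
            vals.append(val)
    if not times:
        raise SensorIOError(f"{path.name}: no data rows")
    idx = pd.DatetimeIndex(times)
    if not idx.is_monotonic_increasing or idx.has_duplicates:
        raise SensorIOError(f"{path.name}: timestamps not strictly increasing")
    var = variable or meta.get("variable")
    if var is None:
        raise SensorIOError(f"{path.name}: variable not declared")
    unit = units or meta.get("units")
    if unit is None:
        raise SensorIOError(f"{path.name}: units not declared (never inferred)")
    return SensorSeries(
        mesocosm_id=meta.get("mesocosm_id", path.stem),
        treatment=meta.get("treatment", "unknown"),
        replicate=int(meta.get("replicate", 0)),
        variable=var,
        data=pd.Series(np.asarray(vals, dtype=float), index=idx),
        qc_mask=np.ones(len(vals), dtype=bool),
        units=unit,
        meta={"source": str(path)},
    )


def write_series(series: SensorSeries, path, dialect: Dialect = Dialect(),
                 float_format: str = "%.4f") -> None:
    """Write a series in the dialect :func:`read_series` accepts."""
    path = Path(path)
    with open(path, "w") as fh:
        for key in ("mesocosm_id", "treatment", "replicate", "variable", "units"):
            fh.write(f"{dialect.comment} {key}={getattr(series, key)}\n")
        fh.write(f"timestamp{dialect.delimiter}value\n")
        for ts, val in series.data.items():
            fh.write(
                f"{ts.strftime('%Y-%m-%dT%H:%M:%S')}{dialect.delimiter}"
                f"{float_format % val}\n"
            )


# ---------------------------------------------------------------------------
# QC filters
# ---------------------------------------------------------------------------


def filter_percentile(series: SensorSeries, lo: float = 0.001,
                      hi: float = 0.995) -> SensorSeries:
    """Mask samples outside the empirical [lo, hi] quantiles.

    Quantiles use linear interpolation over all finite values; samples
    strictly outside the quantile interval are masked.  Values are never
    modified.  Raises if the filter would mask every sample.
    """
    if not (0 <= lo < hi <= 1):
        raise ValueError("need 0 <= lo < hi <= 1")
    vals = series.values
    finite = np.isfinite(vals)
    if not finite.any():
        raise ValueError("series has no finite values")
    q_lo, q_hi = np.quantile(vals[finite], [lo, hi])
    inside = finite & (vals >= q_lo) & (vals <= q_hi)
    new_mask = series.qc_mask & inside
    if not new_mask.any():
        raise ValueError("percentile filter would mask every sample")
    n_masked = int((series.qc_mask & ~inside).sum())
    logger.info(
        "%s/%s: percentile filter (%g, %g) masked %d of %d samples",
        series.mesocosm_id, series.variable, lo, hi, n_masked, len(series),
    )
    out = series.copy_with(qc_mask=new_mask)
    out.meta.setdefault("filters", []).append(
        {"kind": "percentile", "lo": lo, "hi": hi, "n_masked": n_masked}
    )
    return out


def filter_iqr(series: SensorSeries, k: float = 1.2,
               per: str = "series") -> SensorSeries:
    """Mask samples outside the Tukey fence ``[Q1 - k*IQR, Q3 + k*IQR]``.

    Quartiles use linear interpolation over all finite values.  Requires at
    least 4 retained samples afterwards.

    With ``per="day"`` the fence is computed within each calendar day
    instead of over the whole record.  A Tukey fence presumes a roughly
    unimodal sample; diel-cycling irradiance pooled over weeks of mixed
    weather is strongly multimodal, and a whole-record fence would flag
    clear-sky noon as an outlier.  Within one day every sample follows the
    same diel curve, so the per-day fence targets what the filter is meant
    to catch: sensor glitches.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if per not in ("series", "day"):
        raise ValueError(f"per must be 'series' or 'day', got {per!r}")
    vals = series.values
    finite = np.isfinite(vals)
    if not finite.any():
        raise ValueError("series has no finite values")
    inside = np.zeros(len(vals), dtype=bool)
    if per == "series":
        groups = [np.ones(len(vals), dtype=bool)]
    else:
        day = series.timestamps.normalize()
        groups = [np.asarray(day == d) for d in day.unique()]
    for sel in groups:
        g_finite = finite & sel
        if not g_finite.any():
            continue
        q1, q3 = np.quantile(vals[g_finite], [0.25, 0.75])
        iqr = q3 - q1
        inside |= g_finite & (vals >= q1 - k * iqr) & (vals <= q3 + k * iqr)
    new_mask = series.qc_mask & inside
    if new_mask.sum() < 4:
        raise ValueError("IQR filter left fewer than 4 retained samples")
    n_masked = int((series.qc_mask & ~inside).sum())
    logger.info(
        "%s/%s: IQR filter (k=%g) masked %d of %d samples",
        series.mesocosm_id, series.variable, k, n_masked, len(series),
    )
    out = series.copy_with(qc_mask=new_mask)
    out.meta.setdefault("filters", []).append(
        {"kind": "iqr", "k": k, "per": per, "n_masked": n_masked}
    )
    return out


def apply_offset(series: SensorSeries, offset: float) -> SensorSeries:
    """Single-point offset calibration: shift all values by ``offset``."""
    out = series.copy_with(data=series.data + offset)
    out.meta.setdefault("calibrations", []).append({"offset": float(offset)})
    return out


def fill_replicate(series_broken: SensorSeries, donor_a: SensorSeries,
                   donor_b: SensorSeries, from_time) -> SensorSeries:
    """Replace samples at/after ``from_time`` by the mean of two replicates.

    Used when one replicate's sensor fails mid-experiment: its record is
    patched with the per-timestamp average of the two healthy replicates.
    The fill is flagged per sample in ``meta['filled']``.  Raises if a donor
    is missing any needed timestamp.
    """
    from_time = pd.Timestamp(from_time)
    idx = series_broken.timestamps
    need = idx[idx >= from_time]
    for donor in (donor_a, donor_b):
        missing = need.difference(donor.timestamps)
        if len(missing):
            raise ValueError(
                f"donor {donor.mesocosm_id} missing {len(missing)} timestamps, "
                f"first {missing[0]}"
            )
    mean = (donor_a.data.reindex(need) + donor_b.data.reindex(need)) / 2.0
    data = series_broken.data.copy()
    data.loc[need] = mean
    filled = np.asarray(idx >= from_time)
    mask = series_broken.qc_mask.copy()
    mask[filled] = True  # filled values are trusted replicate means
    out = series_broken.copy_with(data=data, qc_mask=mask)
    out.meta["filled"] = filled
    out.meta["filled_from"] = str(from_time)
    out.meta["donors"] = [donor_a.mesocosm_id, donor_b.mesocosm_id]
    return out


def hourly_mean(series: SensorSeries) -> SensorSeries:
    """Mean of retained samples per [t, t+1h) window.

    Windows with no retained samples become NaN and are masked, so downstream
    consumers see them as missing rather than silently interpolated.
    """
    retained = series.retained()
    full_index = pd.date_range(
        series.timestamps[0].floor("h"), series.timestamps[-1].floor("h"), freq="h"
    )
    means = retained.resample("h").mean().reindex(full_index)
    return series.copy_with(
        data=means,
        qc_mask=means.notna().to_numpy(),
        meta={"resampled": "hourly_mean"},
    )
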