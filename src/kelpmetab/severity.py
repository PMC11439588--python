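"""Threshold-exceedance and cumulative-severity metrics for heatwaves.

Given an hourly temperature record and a biological threshold (11 degC here,
the temperature above which kelp-community production coefficients collapse),
these metrics summarise how long and how intensely each treatment exceeded
the threshold:

* :func:`hours_above` -- hours strictly above the threshold.
* :func:`cumulative_severity` -- within each maximal run of consecutive
  exceedance hours ("episode"), the running sum of hourly exceedances
  (degC h).  An alternative reading that divides the running sum by the
  elapsed episode duration (a per-hour severity) is available via
  ``normalize=True``; both are exported because the printed definition of
  this index is ambiguous about the duration term.
* :func:`severity_histogram` -- relative-frequency (%) distribution of the
  severity values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "hours_above",
    "cumulative_severity",
    "severity_histogram",
    "SeveritySummary",
    "summarize",
]

DEFAULT_THRESHOLD = 11.0


def _hourly_values(series) -> np.ndarray:
    if isinstance(series, pd.Series):
        if isinstance(series.index, pd.DatetimeIndex):
            if len(series) > 1:
                deltas = np.diff(series.index.asi8)
                if not np.all(deltas == pd.Timedelta(hours=1).value):
                    raise ValueError(
                        "temperature series must be hourly; resample upstream"
                    )
        return series.to_numpy(dtype=float)
    return np.asarray(series, dtype=float)


def hours_above(series, threshold: float = DEFAULT_THRESHOLD) -> int:
    """Number of hours strictly above ``threshold``.

    Boundary samples exactly at the threshold do not count as exceedance.
    Invariant to adding sub-threshold hours, and nonincreasing in the
    threshold.
    """
    t = _hourly_values(series)
    return int(np.count_nonzero(t > threshold))


def cumulative_severity(series, threshold: float = DEFAULT_THRESHOLD,
                        normalize: bool = False) -> pd.DataFrame:
    """Running exceedance sums per episode.

    Episodes are maximal runs of consecutive hours with T > threshold.  For
    hour ``k`` of an episode the cumulative value is
    ``sum_{i<=k} (T_i - threshold)`` in degC h -- nonnegative and
    nondecreasing within the episode, with the final running value equal to
    the episode's total exceedance.  With ``normalize=True`` the running sum
    is divided by the elapsed hours in the episode instead (degC).

    Returns one row per exceedance hour with columns ``episode``,
    ``exceedance``, ``cumulative`` and ``cumulative_per_hour``; empty when
    nothing exceeds the threshold (a valid outcome).
    """
    t = _hourly_values(series)
    above = t > threshold
    if not above.any():
        return pd.DataFrame(
            columns=["episode", "hour_in_episode", "exceedance", "cumulative",
                     "cumulative_per_hour"]
        )
    episode_id = np.cumsum(np.diff(np.concatenate(([False], above)).astype(int)) == 1)
    rows = []
    for ep in np.unique(episode_id[above]):
        sel = above & (episode_id == ep)
        exc = t[sel] - threshold
        cum = np.cumsum(exc)
        hours = np.arange(1, len(exc) + 1)
        rows.append(
            pd.DataFrame(
                {
                    "episode": ep,
                    "hour_in_episode": hours,
                    "exceedance": exc,
                    "cumulative": cum,
                    "cumulative_per_hour": cum / hours,
                }
            )
        )
    out = pd.concat(rows, ignore_index=True)
    if normalize:
        out["cumulative"] = out["cumulative_per_hour"]
    return out


def severity_histogram(values, bin_width: float = 20.0) -> pd.DataFrame:
    """Relative-frequency (%) distribution of severity values.

    Bins start at 0 with the given width; frequencies sum to 100%.
    """
    if isinstance(values, pd.DataFrame):
        vals = values["cumulative"].to_numpy(dtype=float)
    else:
        vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("no severity values to bin")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    n_bins = max(1, int(np.ceil((vals.max() + 1e-12) / bin_width)))
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(vals, bins=edges)
    return pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "rel_freq_pct": counts / vals.size * 100.0,
        }
    )


@dataclass(frozen=True)
class SeveritySummary:
    """Exceedance summary for one treatment's temperature record."""

    treatment: str
    threshold: float
    hours_above: int
    total_severity: float  # degC h summed over all episodes
    n_episodes: int
    cumulative: pd.DataFrame
    histogram: pd.DataFrame


def summarize(series, treatment: str = "", threshold: float = DEFAULT_THRESHOLD,
              bin_width: float = 20.0, normalize: bool = False) -> SeveritySummary:
    """Full severity summary (hours above, episodes, histogram) in one call."""
    cum = cumulative_severity(series, threshold, normalize=normalize)
    n_ep = int(cum["episode"].nunique()) if len(cum) else 0
    total = (
        float(cum.groupby("episode")["cumulative"].last().sum()) if len(cum) else 0.0
    )
    hist = (
        severity_histogram(cum["cumulative"].to_numpy(), bin_width)
        if len(cum)
        else pd.DataFrame(columns=["bin_left", "bin_right", "rel_freq_pct"])
    )
    return SeveritySummary(
        treatment=treatment,
        threshold=threshold,
        hours_above=hours_above(series, threshold),
        total_severity=total,
        n_episodes=n_ep,
        cumulative=cum,
        histogram=hist,
    )
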