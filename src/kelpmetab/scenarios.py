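"""Synthetic mesocosm experiment generator.

Emulates a 23-day Arctic-summer mesocosm heatwave experiment: twelve 1 m3
tanks (4 treatments x 3 replicates) holding reconstructed kelp communities,
with minute-cadence O2/temperature/salinity sensors, 10-minute PAR loggers,
and 3-hour closed incubations on a fixed schedule.

Treatments are expressed as temperature offsets from ambient (the control):

* ``control`` -- ambient seawater, no offset.
* ``HT``      -- constant +1.8 degC warming, reached by a 3-day ramp after a
  2-day acclimation.
* ``1MH``     -- one long, moderate heatwave: +2.8 degC plateau for 13 days.
* ``2MH``     -- two short, intense heatwaves: +3.9 degC plateaus of 5 days,
  separated by 3 days back at the +1.8 degC base offset.

Every generated O2 incubation trace derives from a known ground-truth
production model (:class:`TruthParams`), so the full analysis chain can be
checked against the parameters that generated the data.

All randomness flows from a single seed through named ``SeedSequence``
children; two runs with the same configuration are byte-identical on disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import signal

from .pi_models import pi_model, temp_model
from .sensor_io import SensorSeries, write_series

__all__ = [
    "ScenarioSpec",
    "AmbientModel",
    "ParModel",
    "TruthParams",
    "ExperimentConfig",
    "Experiment",
    "TREATMENTS",
    "offset_profile",
    "ambient_series",
    "par_series",
    "simulate_incubation",
    "generate_experiment",
    "plateau_segments",
]

TREATMENTS = ("control", "HT", "1MH", "2MH")

#: mesocosm footprint for a 1.1 m diameter circular tank, m2
DEFAULT_AREA_M2 = float(np.pi * (1.1 / 2) ** 2)


# ---------------------------------------------------------------------------
# scenario specification (treatment offset profiles)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScenarioSpec:
    """Parametric description of one treatment's offset-from-ambient profile.

    The profile is continuous piecewise-linear: zero during acclimation, a
    linear ramp over ``ramp_days`` to ``base_offset`` (about 0.6 degC per day
    at the defaults), a ``base_hold_days`` pause, then for heatwave
    treatments ``n_peaks`` excursions to ``peak_offset`` -- ramped at
    ``peak_ramp_rate``, held ``peak_duration_days``, ramped back down --
    separated by ``inter_peak_gap_days`` at the base offset.
    """

    treatment: str
    acclimation_h: float = 48.0
    ramp_days: float = 3.0
    base_offset: float = 1.8
    peak_offset: float = 0.0
    peak_duration_days: float = 0.0
    n_peaks: int = 0
    inter_peak_gap_days: float = 0.0
    peak_ramp_rate: float = 1.0  # degC per day between base and peak
    base_hold_days: float = 2.0

    def __post_init__(self) -> None:
        if min(self.base_offset, self.peak_offset) < 0:
            raise ValueError("offsets must be nonnegative")
        if self.acclimation_h < 0 or self.ramp_days <= 0 or self.peak_ramp_rate <= 0:
            raise ValueError("durations and ramp rates must be positive")
        if self.treatment == "control" and (self.base_offset or self.peak_offset):
            raise ValueError("control must have all offsets zero")
        if self.treatment == "2MH" and self.n_peaks != 2:
            raise ValueError("2MH is defined by exactly two peaks")
        if self.n_peaks > 0:
            if self.peak_duration_days <= 0:
                raise ValueError("peak_duration_days must be positive")
            if self.peak_offset < self.base_offset:
                raise ValueError("peak_offset must be >= base_offset")

    @classmethod
    def for_treatment(cls, treatment: str) -> "ScenarioSpec":
        """Default spec for one of the four experimental treatments.

        The 2MH ramps are steeper (16 h) than the 1MH ramp (24 h) so that two
        5-day peaks plus the 3-day gap complete within the 23-day experiment.
        """
        if treatment == "control":
            return cls("control", base_offset=0.0)
        if treatment == "HT":
            return cls("HT")
        if treatment == "1MH":
            return cls("1MH", peak_offset=2.8, peak_duration_days=13.0, n_peaks=1,
                       peak_ramp_rate=1.0)
        if treatment == "2MH":
            return cls("2MH", peak_offset=3.9, peak_duration_days=5.0, n_peaks=2,
                       inter_peak_gap_days=3.0, peak_ramp_rate=3.15)
        raise ValueError(f"unknown treatment {treatment!r}")

    def nodes(self) -> list[tuple[float, float]]:
        """Piecewise-linear (day, offset) nodes of the profile."""
        t = self.acclimation_h / 24.0
        pts = [(0.0, 0.0), (t, 0.0)]
        t += self.ramp_days
        pts.append((t, self.base_offset))
        if self.n_peaks > 0:
            amp = self.peak_offset - self.base_offset
            ramp_t = amp / self.peak_ramp_rate
            t += self.base_hold_days
            pts.append((t, self.base_offset))
            for k in range(self.n_peaks):
                if k:
                    t += self.inter_peak_gap_days
                    pts.append((t, self.base_offset))
                t += ramp_t
                pts.append((t, self.peak_offset))
                t += self.peak_duration_days
                pts.append((t, self.peak_offset))
                t += ramp_t
                pts.append((t, self.base_offset))
        return pts

    @property
    def duration_days(self) -> float:
        """Days needed for the full profile to return to the base offset."""
        return self.nodes()[-1][0]


def _offset_at(spec: ScenarioSpec, days: np.ndarray) -> np.ndarray:
    pts = spec.nodes()
    xp = np.array([p[0] for p in pts])
    fp = np.array([p[1] for p in pts])
    return np.interp(days, xp, fp, left=0.0, right=fp[-1])


def _check_uniform(timeline: pd.DatetimeIndex, hours: float, what: str) -> None:
    if len(timeline) < 2:
        raise ValueError(f"{what}: timeline too short")
    deltas = np.diff(timeline.asi8)
    step = pd.Timedelta(hours=hours).value
    if not np.all(deltas == step):
        raise ValueError(f"{what}: timeline must be uniform at {hours} h cadence")


def offset_profile(spec: ScenarioSpec, timeline: pd.DatetimeIndex) -> pd.Series:
    """Evaluate a treatment's offset profile on an hourly timeline.

    The timeline must be uniform and hourly, and must span the scenario's
    full duration (so the profile can return to its base offset); otherwise a
    ValueError states the required length.
    """
    _check_uniform(timeline, 1.0, "offset_profile")
    span_d = (timeline[-1] - timeline[0]) / pd.Timedelta(days=1)
    if span_d < spec.duration_days:
        need_h = int(np.ceil(spec.duration_days * 24)) + 1
        raise ValueError(
            f"timeline spans {span_d * 24:.0f} h but the {spec.treatment} "
            f"scenario requires at least {need_h} hourly samples "
            f"({spec.duration_days:.2f} days)"
        )
    days = (timeline - timeline[0]) / pd.Timedelta(days=1)
    return pd.Series(_offset_at(spec, np.asarray(days)), index=timeline)


def plateau_segments(values, level: float, atol: float = 1e-9) -> list[tuple[int, int, float]]:
    """Run-length scan for maximal runs at ``level``.

    Returns ``(start_index, end_index_inclusive, duration_h)`` per run, where
    duration counts the span between first and last sample of the run (an
    hourly plateau sampled at both endpoints of a 5-day hold spans 120 h).
    """
    at = np.isclose(np.asarray(values, dtype=float), level, atol=atol)
    runs = []
    i = 0
    n = len(at)
    while i < n:
        if at[i]:
            j = i
            while j + 1 < n and at[j + 1]:
                j += 1
            runs.append((i, j, float(j - i)))
            i = j + 1
        else:
            i += 1
    return runs


# ---------------------------------------------------------------------------
# ambient temperature
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AmbientModel:
    """Ambient (control) seawater temperature: trend + diel cycle + AR(1).

    Defaults emulate an early-summer, lower-Arctic fjord intake: ~8 degC
    rising slowly through the experiment, a small late-afternoon diel peak,
    and weakly autocorrelated sensor-scale noise.  The generated median is
    expected to fall inside ``target_band``.
    """

    mean_temp: float = 7.75  # degC at the experiment start
    seasonal_trend: float = 0.08  # degC per day
    diel_amplitude: float = 0.2  # degC, peak at ~15:00
    noise_sd: float = 0.1  # stationary sd of the AR(1) component, degC
    ar1_coef: float = 0.6  # lag-1 h autocorrelation
    seed: int = 0
    target_band: tuple[float, float] = (8.5, 11.4)

    def __post_init__(self) -> None:
        if not 0 <= self.ar1_coef < 1:
            raise ValueError("ar1_coef must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def ambient_series(model: AmbientModel, timeline: pd.DatetimeIndex,
                   seed: int | None = None) -> pd.Series:
    """Generate ambient temperature on a uniform timeline (any cadence).

    The AR(1) coefficient is interpreted at 1-hour lag and rescaled to the
    timeline's step so sub-hourly timelines keep the same stationary noise
    level.  Reproducible for a fixed seed.
    """
    if len(timeline) < 2:
        raise ValueError("timeline too short")
    step_h = (timeline[1] - timeline[0]) / pd.Timedelta(hours=1)
    _check_uniform(timeline, step_h, "ambient_series")
    rng = np.random.default_rng(model.seed if seed is None else seed)
    days = np.asarray((timeline - timeline[0]) / pd.Timedelta(days=1))
    hours = timeline.hour + timeline.minute / 60.0
    base = (
        model.mean_temp
        + model.seasonal_trend * days
        + model.diel_amplitude * np.sin(2 * np.pi * (hours - 9.0) / 24.0)
    )
    if model.noise_sd > 0:
        phi = model.ar1_coef ** step_h if model.ar1_coef > 0 else 0.0
        innov_sd = model.noise_sd * np.sqrt(1.0 - phi**2)
        eps = rng.normal(0.0, innov_sd, size=len(timeline))
        # AR(1) recursion as an IIR filter; start at stationary draw
        eps[0] = rng.normal(0.0, model.noise_sd)
        noise = signal.lfilter([1.0], [1.0, -phi], eps)
        base = base + noise
    return pd.Series(base, index=timeline)


# ---------------------------------------------------------------------------
# PAR
# ---------------------------------------------------------------------------

#: Default daily PAR integrals (mol photons m-2 d-1) for days 0..22: a
#: synoptic weather sequence with overcast spells during both simulated
#: heatwave peak windows and clear skies in the inter-peak gap, plus a mixed
#: first week.  See docs/methods.md for why this covariance is part of the
#: emulated conditions.
DEFAULT_DAILY_PATTERN: tuple[float, ...] = (
    40.0, 50.0, 58.0, 35.0, 16.0, 40.0, 35.0,   # days 0-6: mixed early week
    16.0, 15.0, 16.0, 15.0, 16.0, 16.0,         # days 7-12: overcast (peak 1)
    60.0, 65.0, 62.0, 62.0,                     # days 13-16: clear (gap)
    16.0, 58.0, 15.0, 15.0, 15.0, 16.0,         # days 17-22: overcast (peak 2,
                                                #   one clear day for sampling)
)


@dataclass(frozen=True)
class ParModel:
    """Diel PAR under midnight sun with prescribed daily integrals.

    Each day's integral target comes from ``daily_pattern`` (tiled if the
    timeline is longer) plus day-level noise, clipped into
    ``daily_integral_range``; replicate mesocosms additionally jitter the
    target by ``replicate_sd``.  The diel shape is a raised cosine peaking at
    local noon with a small positive floor (midnight sun never goes fully
    dark); hourly values are in mmol photons m-2 h-1 and one day's integral
    is their sum / 1000 in mol photons m-2 d-1.
    """

    daily_integral_range: tuple[float, float] = (14.0, 65.0)
    photoperiod_h: float = 24.0
    replicate_sd: float = 1.4  # mol m-2 d-1, between-replicate jitter
    day_noise_sd: float = 1.5  # mol m-2 d-1, day-level weather noise
    hourly_noise_sd: float = 0.35  # log-scale within-day cloudiness
    floor_frac: float = 0.05
    daily_pattern: tuple[float, ...] = DEFAULT_DAILY_PATTERN
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.daily_integral_range
        if lo < 0 or hi < 0:
            raise ValueError("daily integral bounds must be nonnegative")
        if lo > hi:
            raise ValueError("daily_integral_range must be ordered")
        if not 0 < self.photoperiod_h <= 24:
            raise ValueError("photoperiod_h must be in (0, 24]")

    def day_targets(self, n_days: int, rng: np.random.Generator | None = None,
                    extra_sd: float = 0.0) -> np.ndarray:
        """Clipped daily integral targets for ``n_days`` (mol m-2 d-1)."""
        lo, hi = self.daily_integral_range
        pattern = np.resize(np.asarray(self.daily_pattern, dtype=float), n_days)
        sd = float(np.hypot(self.day_noise_sd, extra_sd))
        if rng is not None and sd > 0:
            pattern = pattern + rng.normal(0.0, sd, size=n_days)
        return np.clip(pattern, lo, hi)


def _diel_shape(hours: np.ndarray, model: ParModel) -> np.ndarray:
    """Relative within-day light shape, evaluated at hour-interval midpoints."""
    mid = hours + 0.5
    if model.photoperiod_h >= 24:
        s = 0.5 * (1.0 + np.cos(2 * np.pi * (mid - 12.0) / 24.0))
    else:
        half = model.photoperiod_h / 2.0
        s = np.where(
            np.abs(mid - 12.0) < half,
            np.cos(np.pi * (mid - 12.0) / model.photoperiod_h),
            0.0,
        )
    return model.floor_frac + (1.0 - model.floor_frac) * s


def par_series(model: ParModel, timeline: pd.DatetimeIndex,
               seed: int | None = None,
               day_targets: np.ndarray | None = None) -> pd.Series:
    """Generate an hourly PAR series (mmol photons m-2 h-1).

    The clear-sky diel shape is modulated by hour-scale lognormal
    "cloudiness" (``hourly_noise_sd`` on the log scale) and then renormalised
    within each day, so the series is nonnegative everywhere and each
    complete day's integral (sum of hourly values / 1000) equals its clipped
    target exactly, hence lies within ``daily_integral_range``.
    ``day_targets`` overrides the internal target draw (used for replicate
    jitter).
    """
    _check_uniform(timeline, 1.0, "par_series")
    rng = np.random.default_rng(model.seed if seed is None else seed)
    day_idx = np.asarray((timeline - timeline[0].normalize()) // pd.Timedelta(days=1))
    n_days = int(day_idx.max()) + 1
    if day_targets is None:
        day_targets = model.day_targets(n_days, rng)
    day_targets = np.asarray(day_targets, dtype=float)
    shape = _diel_shape(timeline.hour.to_numpy().astype(float), model)
    if model.hourly_noise_sd > 0:
        cloud = np.exp(rng.normal(0.0, model.hourly_noise_sd, size=len(timeline)))
        shape = shape * cloud
    values = np.empty(len(timeline))
    for d in range(n_days):
        sel = day_idx == d
        s = shape[sel]
        # scale so the day's integral (sum/1000 mol) matches its target
        values[sel] = day_targets[d] * 1000.0 * s / s.sum()
    return pd.Series(values, index=timeline)


# ---------------------------------------------------------------------------
# ground truth and incubation traces
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TruthParams:
    """Ground-truth production model used to synthesise O2 traces.

    ``temp_modified`` uses the temperature-modified tanh model (warming
    lowers the asymptote and raises the saturating irradiance);
    ``binned_tanh`` is the plain P-I curve with ``rd`` as its intercept.
    Units: Pmax and Rd in mmol O2 m-2 h-1; alpha in mmol O2 m-2 h-1 per
    mmol photons m-2 h-1; o2_noise_sd in the O2 concentration unit (umol/L).
    """

    pmax: float = 22.0
    alpha: float = 0.015
    rd: float = -5.0
    model_form: str = "temp_modified"
    o2_noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.pmax <= 0 or self.alpha <= 0:
            raise ValueError("Pmax and alpha must be positive")
        if self.model_form not in ("binned_tanh", "temp_modified"):
            raise ValueError(f"unknown model_form {self.model_form!r}")

    def ncp(self, irradiance, temperature=None):
        """Areal NCP (mmol O2 m-2 h-1) under this ground truth."""
        if self.model_form == "binned_tanh":
            return pi_model(irradiance, self.pmax, self.alpha, self.rd)
        if temperature is None:
            raise ValueError("temp_modified truth needs a temperature")
        return temp_model(irradiance, temperature, self.pmax, self.alpha, self.rd)


def simulate_incubation(truth: TruthParams, temperature, par, *,
                        duration_h: int = 3, dt_min: int = 1,
                        volume_l: float = 1000.0, area_m2: float = DEFAULT_AREA_M2,
                        seed: int | None = None,
                        start="2022-06-30 09:00:00",
                        o2_start: float = 300.0) -> pd.Series:
    """Synthesise a closed-incubation O2 concentration trace (umol/L).

    ``temperature`` and ``par`` are scalars or per-hour arrays of length
    ``duration_h``.  The noiseless trace is piecewise linear: within hour
    ``j`` its slope is ``NCP(I_j, T_j) * area / volume * 1000`` umol/L/h,
    the exact inverse of the areal conversion applied during analysis.
    Gaussian sensor noise with sd ``truth.o2_noise_sd`` is added on top.
    """
    if duration_h < 1:
        raise ValueError("duration_h must be >= 1")
    if dt_min <= 0 or 60 % dt_min:
        raise ValueError("dt_min must divide 60")
    if volume_l <= 0 or area_m2 <= 0:
        raise ValueError("volume and area must be positive")
    temp = np.broadcast_to(np.asarray(temperature, dtype=float), (duration_h,))
    irr = np.broadcast_to(np.asarray(par, dtype=float), (duration_h,))
    rates = np.asarray(truth.ncp(irr, temp), dtype=float)  # mmol m-2 h-1
    conc_slopes = rates * area_m2 * 1000.0 / volume_l  # umol/L/h
    n = duration_h * 60 // dt_min
    t_h = np.arange(n) * dt_min / 60.0
    conc = np.full(n, float(o2_start))
    for j, slope in enumerate(conc_slopes):
        conc += slope * np.clip(t_h - j, 0.0, 1.0)
    if truth.o2_noise_sd > 0:
        rng = np.random.default_rng(seed)
        conc = conc + rng.normal(0.0, truth.o2_noise_sd, size=n)
    idx = pd.date_range(pd.Timestamp(start), periods=n, freq=f"{dt_min}min")
    return pd.Series(conc, index=idx)


# ---------------------------------------------------------------------------
# full experiment
# ---------------------------------------------------------------------------

#: Incubation days (mid-morning 09:00-12:00) per treatment: weekly-cadence
#: sampling for control/HT and peak+remission sampling for the heatwave
#:  treatments, plus two dark incubations of all mesocosms.
DEFAULT_LIGHT_DAYS: dict[str, tuple[int, ...]] = {
    "control": (2, 4, 6, 16),
    "HT": (2, 7, 12, 16),
    "1MH": (3, 9, 13, 16, 20, 22),
    "2MH": (3, 9, 12, 13, 14, 15, 18, 22),
}
DEFAULT_DARK_DAYS: tuple[int, ...] = (1, 10)


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything the experiment generator needs, in one place."""

    start: str = "2022-06-30"
    days: int = 23
    treatments: tuple[str, ...] = TREATMENTS
    n_replicates: int = 3
    ambient: AmbientModel = field(default_factory=AmbientModel)
    par: ParModel = field(default_factory=ParModel)
    truth: TruthParams = field(default_factory=TruthParams)
    volume_l: float = 1000.0
    area_m2: float = DEFAULT_AREA_M2
    o2_baseline: float = 310.0
    temp_sensor_sd: float = 0.02
    salinity_mean: float = 34.0
    salinity_sd: float = 0.05
    incubation_h: int = 3
    incubation_start_hour: int = 9
    light_days: dict = field(default_factory=lambda: dict(DEFAULT_LIGHT_DAYS))
    dark_days: tuple[int, ...] = DEFAULT_DARK_DAYS
    seed: int = 20220630


@dataclass
class Experiment:
    """A generated experiment: sensor series, schedule and ground truth."""

    config: ExperimentConfig
    schedule: pd.DataFrame
    series: dict  # (mesocosm_id, variable) -> SensorSeries
    seeds: dict  # name -> integer seed actually used

    def mesocosms(self) -> list[str]:
        return sorted({mid for mid, _ in self.series})

    def get(self, mesocosm_id: str, variable: str) -> SensorSeries:
        return self.series[(mesocosm_id, variable)]

    def write(self, out_dir) -> None:
        """Write one delimited file per mesocosm-variable, the incubation
        schedule, and a ground-truth manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for (mid, var), ser in sorted(self.series.items()):
            write_series(ser, out / f"{mid}_{var}.csv")
        sched = self.schedule.copy()
        for col in ("start", "end"):
            sched[col] = sched[col].dt.strftime("%Y-%m-%dT%H:%M:%S")
        sched.to_csv(out / "schedule.csv", index=False)
        truth = self.config.truth
        manifest = {
            "truth": {
                "pmax": truth.pmax,
                "alpha": truth.alpha,
                "rd": truth.rd,
                "model_form": truth.model_form,
                "o2_noise_sd": truth.o2_noise_sd,
            },
            "seeds": {k: int(v) for k, v in self.seeds.items()},
            "geometry": {"volume_l": self.config.volume_l,
                         "area_m2": self.config.area_m2},
            "start": self.config.start,
            "days": self.config.days,
        }
        with open(out / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)


def _build_schedule(config: ExperimentConfig) -> pd.DataFrame:
    start = pd.Timestamp(config.start)
    rows = []
    for treatment in config.treatments:
        days_light = config.light_days.get(treatment, ())
        for rep in range(1, config.n_replicates + 1):
            mid = f"{treatment}-{rep}"
            for day, mode in sorted(
                [(d, "light") for d in days_light]
                + [(d, "dark") for d in config.dark_days]
            ):
                t0 = start + pd.Timedelta(days=day, hours=config.incubation_start_hour)
                rows.append(
                    {
                        "mesocosm_id": mid,
                        "treatment": treatment,
                        "replicate": rep,
                        "start": t0,
                        "end": t0 + pd.Timedelta(hours=config.incubation_h),
                        "mode": mode,
                    }
                )
    return pd.DataFrame(rows)


def generate_experiment(config: ExperimentConfig = ExperimentConfig(),
                        seed: int | None = None,
                        out_dir=None) -> Experiment:
    """Generate the full synthetic experiment.

    One shared ambient-temperature realisation and one shared daily-weather
    sequence drive all twelve mesocosms; treatments add their offset
    profiles, replicates add small sensor/irradiance jitter.  O2 series sit
    at a flow-through baseline except inside scheduled incubation windows,
    where the trace follows the ground-truth production model for that
    mesocosm's temperature and PAR.

    Returns the in-memory :class:`Experiment`; also writes it to ``out_dir``
    when given.
    """
    master = config.seed if seed is None else seed
    # fixed draw order => reproducible; derived seeds stay below 2**31
    seed_rng = np.random.default_rng(np.random.SeedSequence(master))

    def next_seed() -> int:
        return int(seed_rng.integers(0, 2**31 - 1))

    seeds: dict[str, int] = {"master": int(master)}
    start = pd.Timestamp(config.start)
    minute_tl = pd.date_range(start, periods=config.days * 1440, freq="1min")
    hourly_tl = pd.date_range(start, periods=config.days * 24, freq="1h")
    par_tl = pd.date_range(start, periods=config.days * 144, freq="10min")
    minute_days = np.asarray((minute_tl - start) / pd.Timedelta(days=1))

    seeds["ambient"] = next_seed()
    ambient = ambient_series(config.ambient, minute_tl, seed=seeds["ambient"])

    seeds["weather"] = next_seed()
    weather_rng = np.random.default_rng(seeds["weather"])
    day_targets = config.par.day_targets(config.days, weather_rng)

    schedule = _build_schedule(config)
    series: dict[tuple[str, str], SensorSeries] = {}

    for treatment in config.treatments:
        spec = ScenarioSpec.for_treatment(treatment)
        if spec.duration_days > config.days:
            raise ValueError(
                f"{treatment} scenario needs {spec.duration_days:.2f} days; "
                f"experiment has {config.days}"
            )
        offset_min = _offset_at(spec, minute_days)
        true_temp = ambient.to_numpy() + offset_min
        true_temp_hourly = true_temp.reshape(-1, 60).mean(axis=1)

        for rep in range(1, config.n_replicates + 1):
            mid = f"{treatment}-{rep}"
            seeds[mid] = next_seed()
            rng = np.random.default_rng(seeds[mid])

            temp_vals = true_temp + rng.normal(0, config.temp_sensor_sd,
                                               len(minute_tl))
            sal_vals = config.salinity_mean + rng.normal(
                0, config.salinity_sd, len(minute_tl))

            rep_targets = np.clip(
                day_targets + rng.normal(0, config.par.replicate_sd, config.days),
                *config.par.daily_integral_range,
            )
            par_hourly = par_series(
                config.par, hourly_tl,
                seed=int(rng.integers(0, 2**31 - 1)),
                day_targets=rep_targets,
            )
            par_hourly_vals = par_hourly.to_numpy()
            # 10-min logger samples: piecewise constant within the hour
            par_vals = np.repeat(par_hourly_vals, 6).astype(float)

            o2_vals = config.o2_baseline + rng.normal(
                0, config.truth.o2_noise_sd, len(minute_tl))

            win = schedule[schedule["mesocosm_id"] == mid]
            for row in win.itertuples():
                i0 = int((row.start - start) / pd.Timedelta(minutes=1))
                n_h = int((row.end - row.start) / pd.Timedelta(hours=1))
                h0 = i0 // 60
                irr = par_hourly_vals[h0:h0 + n_h].copy()
                if row.mode == "dark":
                    irr[:] = 0.0
                    par_vals[i0 // 10: (i0 + n_h * 60) // 10] = 0.0
                t_arr = true_temp_hourly[h0:h0 + n_h]
                trace = simulate_incubation(
                    config.truth, t_arr, irr, duration_h=n_h, dt_min=1,
                    volume_l=config.volume_l, area_m2=config.area_m2,
                    seed=int(rng.integers(0, 2**31 - 1)),
                    start=row.start, o2_start=float(o2_vals[i0]),
                )
                o2_vals[i0:i0 + n_h * 60] = trace.to_numpy()

            def mk(var, tl, vals, units):
                return SensorSeries(
                    mesocosm_id=mid, treatment=treatment, replicate=rep,
                    variable=var, data=pd.Series(vals, index=tl),
                    qc_mask=np.ones(len(vals), dtype=bool), units=units,
                )

            series[(mid, "O2")] = mk("O2", minute_tl, o2_vals, "umol/L")
            series[(mid, "temperature")] = mk("temperature", minute_tl,
                                              temp_vals, "degC")
            series[(mid, "salinity")] = mk("salinity", minute_tl, sal_vals, "psu")
            series[(mid, "PAR")] = mk("PAR", par_tl, par_vals,
                                      "mmol photons/m2/h")

    exp = Experiment(config=config, schedule=schedule, series=series, seeds=seeds)
    if out_dir is not None:
        exp.write(out_dir)
    return exp
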