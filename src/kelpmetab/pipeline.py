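"""End-to-end workflow: QC -> hourly rates -> P-I fits -> accumulation -> severity.

Every stage reads its settings from one :class:`PipelineConfig` (no hidden
constants), logs how many samples/rates enter and leave, and writes a
delimited report.  ``run_analyze`` returns the in-memory
:class:`AnalysisReport` so the same machinery serves scripts, tests and the
command line.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import incubations, pi_models, production, sensor_io, severity
from .scenarios import Experiment, ExperimentConfig, generate_experiment

__all__ = [
    "PipelineConfig",
    "AnalysisReport",
    "run_simulate",
    "run_analyze",
    "load_experiment",
]

logger = logging.getLogger(__name__)

REPORT_FILES = (
    "rates.csv",
    "pi_bins.csv",
    "temp_model.csv",
    "accumulated.csv",
    "severity.csv",
)


@dataclass(frozen=True)
class PipelineConfig:
    """All analysis knobs: filters, bins, model choices, MC and severity."""

    percentile_lo: float = 0.001
    percentile_hi: float = 0.995
    iqr_k: float = 1.2
    iqr_per: str = "day"  # fence scope for PAR; diel data are multimodal
    volume_l: float = 1000.0
    area_m2: float = incubations.MesocosmGeometry().footprint_area_m2
    interpretation: str = "shifted"  # temperature-model algebra reading
    robust_bins: bool = True
    robust_temp: bool = False
    mc_iterations: int = 1000
    mc_sampling: str = "normal"
    severity_threshold: float = 11.0
    severity_bin_width: float = 20.0
    severity_normalize: bool = False
    accumulation_treatments: tuple[str, ...] = ("control", "1MH", "2MH")
    severity_treatments: tuple[str, ...] = ("1MH", "2MH")
    driver_max_gap_h: int = 2
    seed: int = 1234
    scenario: ExperimentConfig = field(default_factory=ExperimentConfig)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        scenario_raw = raw.pop("scenario", {})
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        scenario_known = {f.name for f in dataclasses.fields(ExperimentConfig)}
        bad = set(scenario_raw) - scenario_known
        if bad:
            raise ValueError(f"unknown scenario keys: {sorted(bad)}")
        for key in ("accumulation_treatments", "severity_treatments"):
            if key in raw:
                raw[key] = tuple(raw[key])
        scenario = ExperimentConfig(**scenario_raw)
        return cls(scenario=scenario, **raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["scenario"] = {
            "start": self.scenario.start,
            "days": self.scenario.days,
            "n_replicates": self.scenario.n_replicates,
            "seed": self.scenario.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @property
    def geometry(self) -> incubations.MesocosmGeometry:
        return incubations.MesocosmGeometry(self.volume_l, self.area_m2)


@dataclass
class AnalysisReport:
    """Everything the analysis produced, stage by stage."""

    rates: pd.DataFrame
    bin_fits: dict  # bin label -> PICurveResults
    bin_table: pd.DataFrame
    temp_fit: pi_models.TemperaturePIResults
    accumulation: dict  # treatment -> AccumulationResult
    comparison: pd.DataFrame
    severities: dict  # treatment -> SeveritySummary
    counts: dict  # stage bookkeeping

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rates = self.rates.copy()
        rates["window_start"] = pd.to_datetime(rates["window_start"]).dt.strftime(
            "%Y-%m-%dT%H:%M:%S"
        )
        rates.to_csv(out / "rates.csv", index=False, float_format="%.6g")
        self.bin_table.to_csv(out / "pi_bins.csv", index=False, float_format="%.6g")
        tm = self.temp_fit.coef_table().reset_index(names="param")
        tm["n"] = self.temp_fit.nobs
        tm["rmse"] = self.temp_fit.rmse
        tm["f_statistic"] = self.temp_fit.f_statistic
        tm.to_csv(out / "temp_model.csv", index=False, float_format="%.6g")
        acc = pd.DataFrame(
            [
                {
                    "treatment": r.treatment,
                    "accumulated_mmol_m2": r.accumulated,
                    "accumulated_mol_m2": r.accumulated_mol,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                    "n_iterations": r.n_iterations,
                    "seed": r.seed,
                }
                for r in self.accumulation.values()
            ]
        )
        acc = acc.merge(
            self.comparison[["pct_decrease_vs_control", "ci_overlaps_control"]],
            left_on="treatment", right_index=True, how="left",
        )
        acc.to_csv(out / "accumulated.csv", index=False, float_format="%.6g")
        sev = pd.DataFrame(
            [
                {
                    "treatment": s.treatment,
                    "threshold": s.threshold,
                    "hours_above": s.hours_above,
                    "total_severity_degC_h": s.total_severity,
                    "n_episodes": s.n_episodes,
                }
                for s in self.severities.values()
            ]
        )
        sev.to_csv(out / "severity.csv", index=False, float_format="%.6g")


def run_simulate(config: PipelineConfig, out_dir, seed: int | None = None) -> Experiment:
    """Generate the synthetic experiment and write it (with its manifest)."""
    exp = generate_experiment(config.scenario, seed=seed, out_dir=out_dir)
    logger.info("simulated %d mesocosm series to %s", len(exp.series), out_dir)
    return exp


def load_experiment(data_dir) -> tuple[pd.DataFrame, dict]:
    """Load a written experiment directory back into schedule + series."""
    data_dir = Path(data_dir)
    sched_path = data_dir / "schedule.csv"
    if not sched_path.exists():
        raise sensor_io.SensorIOError(f"no schedule.csv in {data_dir}")
    schedule = pd.read_csv(sched_path, parse_dates=["start", "end"])
    series = {}
    for path in sorted(data_dir.glob("*_*.csv")):
        if path.name == "schedule.csv":
            continue
        ser = sensor_io.read_series(path)
        series[(ser.mesocosm_id, ser.variable)] = ser
    if not series:
        raise sensor_io.SensorIOError(f"no sensor series found in {data_dir}")
    return schedule, series


def _qc(series: dict, config: PipelineConfig) -> tuple[dict, dict]:
    """Percentile-filter T and salinity, IQR-filter PAR; O2 passes through."""
    out = {}
    counts = {}
    for key, ser in series.items():
        _, var = key
        if var in ("temperature", "salinity"):
            filt = sensor_io.filter_percentile(
                ser, config.percentile_lo, config.percentile_hi
            )
        elif var == "PAR":
            filt = sensor_io.filter_iqr(ser, config.iqr_k, per=config.iqr_per)
        else:
            filt = ser
        out[key] = filt
        counts[key] = {"n": len(filt), "masked": filt.n_masked()}
    total_masked = sum(c["masked"] for c in counts.values())
    logger.info("QC masked %d samples across %d series", total_masked, len(counts))
    return out, counts


def _replicate_mean_hourly(series: dict, treatment: str, variable: str) -> pd.Series:
    cols = [
        sensor_io.hourly_mean(ser).data
        for (mid, var), ser in series.items()
        if var == variable and ser.treatment == treatment
    ]
    if not cols:
        raise ValueError(f"no {variable} series for treatment {treatment}")
    return pd.concat(cols, axis=1).mean(axis=1)


def run_analyze(source, config: PipelineConfig = PipelineConfig(),
                out_dir=None) -> AnalysisReport:
    """Run the full analysis on an :class:`Experiment` or a data directory.

    Stages: sensor QC -> hourly incubation rates -> per-bin P-I fits ->
    temperature-modified model fit -> accumulated production with
    Monte-Carlo CI per treatment -> severity metrics.  Writes the five
    report files when ``out_dir`` is given.
    """
    if isinstance(source, Experiment):
        schedule, series = source.schedule, source.series
    else:
        schedule, series = load_experiment(source)

    counts: dict = {}
    series, counts["qc"] = _qc(series, config)

    rates = incubations.process_schedule(schedule, series, geom=config.geometry)
    n_hours_scheduled = int(
        ((schedule["end"] - schedule["start"]) / pd.Timedelta(hours=1)).sum()
    )
    counts["rates"] = {
        "scheduled_hours": n_hours_scheduled,
        "estimated": len(rates),
        "skipped": n_hours_scheduled - len(rates),
    }
    logger.info(
        "rates: %d of %d scheduled incubation hours yielded estimates",
        len(rates), n_hours_scheduled,
    )

    light = rates[rates["mode"] == "light"]
    bin_fits = {}
    bin_rows = []
    for b in pi_models.DEFAULT_BINS:
        n_in = int(b.contains(light["mean_temp"].to_numpy()).sum())
        n_min = 5 if b.include_respiration else 3
        if n_in < n_min:
            logger.warning("bin %s: only %d rates, skipped", b.label, n_in)
            continue
        try:
            fit = pi_models.fit_bin(light, b, robust=config.robust_bins)
        except pi_models.FitError as exc:
            logger.warning("bin %s: fit failed (%s), skipped", b.label, exc)
            continue
        bin_fits[b.label] = fit
        ic, ic_se = fit.compensation_irradiance()
        row = {"bin": b.label, "t_min": b.t_min, "t_max": b.t_max,
               "n": fit.nobs, "rmse": fit.rmse, "Ic": ic, "Ic_se": ic_se}
        for name in fit.model.param_names:
            row[name] = fit.params[name]
            row[f"se_{name}"] = fit.bse[name]
        bin_rows.append(row)
    counts["bins"] = {label: fit.nobs for label, fit in bin_fits.items()}
    bin_table = pd.DataFrame(bin_rows)

    temp_fit = pi_models.TemperaturePICurve.from_rates(
        light, interpretation=config.interpretation
    ).fit(robust=config.robust_temp)
    logger.info("temperature model: n=%d rmse=%.3f", temp_fit.nobs, temp_fit.rmse)

    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    accumulation = {}
    for treatment in config.accumulation_treatments:
        drivers = production.make_drivers(
            _replicate_mean_hourly(series, treatment, "temperature"),
            _replicate_mean_hourly(series, treatment, "PAR"),
            treatment=treatment,
            max_gap_h=config.driver_max_gap_h,
        )
        accumulation[treatment] = production.accumulate_with_ci(
            temp_fit, drivers,
            n_iter=config.mc_iterations,
            seed=int(rng.integers(0, 2**31 - 1)),
            sampling=config.mc_sampling,
        )
    comparison = production.compare_treatments(accumulation)

    severities = {}
    for treatment in config.severity_treatments:
        temp_hourly = _replicate_mean_hourly(series, treatment, "temperature")
        severities[treatment] = severity.summarize(
            temp_hourly.interpolate(limit_area="inside"),
            treatment=treatment,
            threshold=config.severity_threshold,
            bin_width=config.severity_bin_width,
            normalize=config.severity_normalize,
        )

    report = AnalysisReport(
        rates=rates, bin_fits=bin_fits, bin_table=bin_table, temp_fit=temp_fit,
        accumulation=accumulation, comparison=comparison, severities=severities,
        counts=counts,
    )
    if out_dir is not None:
        report.write(out_dir)
    return report
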