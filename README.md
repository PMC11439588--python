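# kelpmetab

Mesocosm kelp-community metabolism: from high-frequency O₂ / temperature /
PAR sensor records of closed incubations to net community production (NCP)
rates, photosynthesis–irradiance (P–I) model fits, accumulated production
with Monte-Carlo uncertainty, and marine-heatwave severity metrics.

## The problem

Arctic fjord kelp communities are increasingly exposed to marine heatwaves
(MHWs). A standard way to quantify the community-level metabolic response is
a mesocosm experiment: reconstructed kelp assemblages in ~1 m³ flow-through
tanks are exposed to prescribed temperature-offset scenarios — a constant
warming (+1.8 °C), one long moderate heatwave (+2.8 °C for 13 days), or two
short intense heatwaves (two 5-day peaks at +3.9 °C, 3 days apart) — while
O₂, temperature, salinity (1-min) and PAR (10-min) are logged continuously.
Closing a tank for 3 h turns it into a respirometry chamber: the O₂ drift
gives one NCP rate per hour (dark incubations give community respiration,
CR).

`kelpmetab` implements that full analysis, plus a seeded scenario generator
that reproduces the experiment's designs from known ground-truth parameters
so the entire chain is testable end to end.

## Models

Rates pooled within a narrow temperature bin follow the hyperbolic-tangent
P–I curve

    NCP(I) = Pmax · tanh(α·I / Pmax) + CR

with light-saturated rate `Pmax` (mmol O₂ m⁻² h⁻¹), photosynthetic
efficiency `α`, respiration intercept `CR`, and compensation irradiance
`Ic = (Pmax/α)·atanh(−CR/Pmax)`. Pooling across temperatures, a
temperature-modified form lowers the asymptote and shifts light saturation
upward as the water warms:

    NCP(I, T) = (Pmax − T) · tanh((α·I − T)/Pmax) + Rd

Fits are (optionally bisquare-robust) nonlinear least squares in the
statsmodels style: `PICurve(...).fit()` and
`TemperaturePICurve(...).fit()` return results objects with coefficients,
standard errors, covariance, diagnostics and `summary()`. Accumulated
production is the sum of *positive* predicted hourly rates over the
experiment, with a 1000-iteration Monte-Carlo CI obtained by resampling
each hourly prediction within its delta-method 95 % band. Severity of a
temperature record is the time above a biological threshold (11 °C) and the
per-episode running sum of hourly exceedances (°C·h).

## Worked example

The published accumulated totals for control / long-heatwave (1MH) /
double-heatwave (2MH) are 915, 736 and 798 mol O₂ m⁻²; the percent changes
follow directly:

```python
>>> from kelpmetab import production as prod
>>> prod.compare_treatments({"control": 915.0, "1MH": 736.0, "2MH": 798.0})
           accumulated  ...  pct_decrease_vs_control
treatment
control          915.0  ...                        0
1MH              736.0  ...                       20
2MH              798.0  ...                       13
```

— a 20 % decrease for the long heatwave and 13 % for the two short ones.

Running the whole pipeline on the default synthetic experiment (ground
truth: Pmax = 22, α = 0.015, Rd = −5, temperature-modified form):

```python
>>> from kelpmetab import generate_experiment, run_analyze
>>> report = run_analyze(generate_experiment())
>>> print(report.temp_fit.summary())
Temperature-modified P-I model (shifted interpretation)
  n: 175   rmse: 0.483   F: 7744.9 (p=3.16e-169)
  param       estimate        SE         t           p
  Pmax         21.8501    0.1622   134.718  2.678e-176
  alpha         0.0149    0.0003    49.577  8.687e-104
  Rd           -4.8959    0.1744   -28.071    4.05e-66
```

The fit recovers the generating coefficients, accumulated production orders
control (1.060 mol O₂ m⁻²) > 2MH (0.778) > 1MH (0.766), and the long
heatwave spends 366 h above 11 °C against 303 h for the two short peaks —
the duration-over-magnitude pattern the experiment was designed to probe.

A thin CLI wraps the same pipeline:

```bash
kelpmetab simulate --out data/ --seed 1
kelpmetab all --data data/ --out run1/
```

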