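# thermofate

A tested Python pipeline for field thermal ecology of radio-tracked
ectotherms: it turns raw biologging files (temperature loggers on animals
and copper operative models, two-axis accelerometers, daily telemetry
fates) into calibrated body temperatures, thermoregulation indices,
field thermal performance curves, activity budgets, and known-fate
survival estimates — and ships a synthetic-data generator with known
ground truth so every stage can be verified end to end without any field
data.

## Who it is for

Thermal ecologists and movement ecologists who track lizards (or other
ectotherms) with temperature-sensitive transmitters and accelerometers
and want the standard analysis chain as reusable, tested code rather
than one-off scripts.

## What it computes

**Calibration.** Preferred body temperature T_set is the interquartile
range of body temperatures selected on a laboratory thermal gradient
(per individual after a 12 h acclimation period, averaged within sex).
Field body temperature is predicted from externally logged surface
temperature by OLS: `T_b,Predict = a + b · T_surf`.

**Thermoregulation (Hertz indices).** With deviations d(T) from T_set
(0 inside the range), d_b is the hourly mean deviation of body
temperatures and d_e the hourly mean deviation of copper-model operative
temperatures averaged across models. Effectiveness per individual and
season is

```
E = 1 − d̄_b / d̄_e
```

(1 = precise thermoregulation, 0 = thermoconformity, negative =
avoidance of the preferred range).

**Activity.** Resultant acceleration √(x² + y²) is averaged per calendar
minute; a minute counts as "moved" when its mean changed from the
previous minute's by more than a configurable epsilon; activity is
minutes moved per hour (min/h), stored with its log(x+1) transform.

**Thermal performance curves.** Performance at a body temperature is
the 95th percentile of minute-mean acceleration per 1 °C bin; a
penalized cubic B-spline (second-difference penalty, smoothing parameter
by GCV) fitted to the binned points gives the curve whose maximum is
P_max at temperature T_opt.

**Survival.** Known-fate encounter histories (weekly occasions,
staggered entry, censoring for lost transmitters) enter a
product-of-binomials likelihood with logit-linked individual covariates,
`logit(φ_i) = x_iᵀβ`; models are fitted by maximum likelihood and ranked
by AICc (support at ΔAICc < 2); seasonal survival is φ̂ⁿ with
delta-method standard errors.

## Worked example

The numbered drivers under `analysis/` run a complete synthetic study
(generate → calibrate → thermoregulate → activity/TPC → survival):

```
python analysis/01_simulate.py
python analysis/02_calibrate.py
python analysis/03_thermoregulation.py
python analysis/04_activity_tpc.py
python analysis/05_survival.py
```

Stage 02 recovers the calibration and the sex-specific T_set bounds from
the simulated gradient trials:

```
calibration: body = 1.866 + 1.055 * surface (R^2 = 0.993, n = 5000)
T_set female: [29.79, 33.73] degC (n = 10; generator truth upper: 33.8)
T_set male: [25.01, 29.04] degC (n = 10; generator truth upper: 29.0)
```

Stage 03 scores the simulated thermoregulator high and the
thermoconformers low on the E index, as designed:

```
lizard_id season  mean_db  mean_de  e_index  n_hours
 liz_con1 spring    2.236    3.385    0.340       16
 liz_con2 spring    2.695    3.349    0.195       16
  liz_reg spring    0.445    3.385    0.868       16
```

Stage 05 collapses daily fates into 13 weekly occasions, ranks an
intercept-only against a sex model by AICc, and recovers cumulative
spring survival per sex:

```
27 encounter histories, 9 deaths, 295 at-risk weekly intervals
cumulative 13-week survival (male): 0.75 +- 0.10 (generator truth 0.75)
cumulative 13-week survival (female): 0.44 +- 0.18 (generator truth 0.33)
```

Each stage writes its tables under `results/`. A thin CLI mirrors the
stages for use on your own files (`thermofate ingest|calibrate|thermoreg|
activity|tpc|survive --help`).

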