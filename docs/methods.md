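# Methods

This note documents the models and procedures implemented in
`thermofate`, the assumptions behind them, and the choices made where the
design was genuinely open.

## Temporal conventions

All analyses use Southern-Hemisphere meteorological seasons assigned by
calendar month (Sep–Nov spring, Dec–Feb summer, Mar–May autumn, Jun–Aug
winter) and a daily analysis window of [05:00, 21:00) local time. The
window is half-open: a record stamped exactly 21:00 is excluded. Local
time is taken as recorded; no timezone conversion is attempted. Minutes
and hours are calendar-aligned (floor), not rolling.

## Preferred temperature and calibration

T_set is estimated per individual as the 25th/75th percentiles of
gradient body temperatures after discarding a 12 h acclimation block;
sex-level bounds are means of the per-individual bounds. Percentiles use
linear interpolation between order statistics (the numpy default); no
quantile rule is canonical here and the choice is tested against a
sort-based oracle. Individuals with constant post-acclimation traces
give degenerate (equal) bounds and are excluded with a warning rather
than silently shifting the sex mean.

The surface→body correction is a single pooled OLS fit of body on
surface temperature (per-individual fits are available but off by
default); orthogonal/Deming regression is deliberately not used. The
paired surface-vs-body bias is reported as mean difference ± SE with the
paired t statistic; when every difference is identical the SE is zero
and the t statistic is reported as undefined rather than infinite.

## Thermoregulation indices

Deviations follow the Hertz convention: 0 inside T_set, distance to the
nearer bound outside. d_b aggregates body-temperature deviations to
hourly means; d_e computes each copper model's hourly mean deviation
first and then averages across models, so a model sitting inside T_set
pulls d_e down even when another model is far outside. Sex-specific
T_set is applied to both d_b and d_e.

E is computed per individual-season as the **ratio of seasonal means**,
E = 1 − mean(d_b)/mean(d_e), not as a mean of hourly ratios: hourly
ratios are numerically unstable whenever an hour's d_e approaches zero
(benign thermal environments), and the season-level ratio is the
estimand the downstream survival covariate uses. Hours present in only
one of the two series are dropped from both means to keep the ratio
coherent. When a season's mean d_e is exactly zero the index is
undefined and reported as null with a reason, never ±∞.

## Activity

Movement is assessed on minute-averaged resultant magnitudes, not raw
6 Hz samples, matching the minute averaging used for temperature
pairing. "Any change from the previous value" taken literally would
flag floating-point jitter, so the movement threshold epsilon is
explicit (default 10⁻⁶ ms⁻²) and configurable; activity per hour is
non-increasing in epsilon, which the property suite checks. Gaps longer
than one minute reset the predecessor, leaving the first minute after a
gap unassessed (null) rather than comparing across the gap. Hours with
fewer than 30 observed minutes are flagged incomplete and excluded from
seasonal means by default. The raw-count→ms⁻² conversion is exposed as a
per-axis affine map with identity defaults; inputs are assumed to
already be in ms⁻² unless a transform is supplied.

## Thermal performance curves

Performance is defined *before* smoothing: the 95th percentile
(interpolated order statistic) of minute-mean acceleration within each
1 °C bin, with bins below 10 minutes dropped to stabilise the upper
percentile. For group curves the default computes the percentile per
individual per bin and averages across individuals; a pooled path is
available. The percentile-then-fit order is intentional — the smooth is
fitted to the binned upper envelope, not to raw minutes (a raw-minute
flag exists).

The smooth is a P-spline: 10 uniform cubic B-spline basis functions over
the observed temperature range with a second-order difference penalty on
the coefficients, so the infinite-penalty limit is exactly the
least-squares line. The smoothing parameter is selected by generalized
cross-validation over a 33-point log grid on λ ∈ 10^[−4, 4]; a test
checks the selection against a 10× denser grid. Per-individual intercept
offsets shrunk by a fixed ridge penalty (default 1.0) stand in for a
full random-effects smooth; the quantities the pipeline carries forward
are P_max and T_opt of the group curve, for which this simplification is
adequate, and curve-for-curve equality with a full GAMM is not claimed.

P_max/T_opt extraction is restricted to the observed temperature range
(no extrapolated maxima), ties break toward the lower temperature at
0.1 °C grid resolution, maxima on the range edge carry a boundary flag,
and flat curves are flagged indeterminate rather than reported.

Known estimator property: with thin per-individual bins the
per-individual 95th percentile mixes sedentary minutes into the upper
tail and attenuates P_max toward the baseline; T_opt, an argmax, is
unaffected because bout probability does not depend on temperature. The
pooled path recovers P_max to within a few per cent on synthetic data
and is preferred when P_max itself is the quantity of interest.

## Known-fate survival

Detection probability is 1, so each at-risk interval is a Bernoulli
trial: the log-likelihood is Σᵢ [sᵢ log φᵢ + dᵢ log(1 − φᵢ)] with sᵢ
survived intervals and dᵢ ∈ {0,1}; censored intervals contribute only
through the intervals already survived, and censoring is treated as
non-informative (transmitter loss). φ is constant across occasions
within an individual and logit-linked to individual covariates.
Optimisation is quasi-Newton (BFGS) from a zero start with the analytic
gradient; the covariance matrix is the inverse observed information;
likelihoods clip φ at 10⁻¹² for numerical safety. With zero deaths the
MLE sits on the boundary (φ̂ = 1): the fit is flagged, Wald SEs are
suppressed, and a one-sided profile-likelihood lower bound is available
instead.

Daily telemetry records are collapsed to 13 weekly occasions by default
(occasion structure is a documented assumption, not a data property):
entry at the occasion containing first tracking, death assigned to the
occasion containing the death date, censoring at the occasion containing
the last record without counting it as survived. Continuous covariates
are z-scored before fitting (binary 0/1 codes left alone) and
coefficients can be mapped back to the natural scale. AICc uses
n_eff = number of at-risk intervals (switchable to number of animals);
seasonal survival is φ̂ⁿ with the delta-method SE propagated through the
logit link and the power, which a test checks against the Monte-Carlo
sampling SD.

## Synthetic-data generator

The generator emulates: a shared diel sinusoid (default mean 28 °C,
amplitude 8 °C, peak 15:00) with additive microhabitat offsets for five
habitat categories (full_shade, partial_shade, open, tree, burrow) and
Gaussian sensor noise; thermoregulator vs thermoconformer body
temperatures (conformer = habitat mean; regulator = habitat mean pulled
toward the T_set midpoint by a gain in [0,1], clamped to the
instantaneous envelope of available operative temperatures — behavioural
thermoregulation cannot beat the best available microhabitat); a linear
surface→body relation with Gaussian noise over a 20–40 °C gradient;
bout-structured acceleration whose bout-level magnitude follows a
Gaussian performance curve of body temperature (default peak 36.6 °C,
breadth 5 °C, maximum 4 ms⁻² over a 0.2 ms⁻² sedentary baseline); and
per-occasion mortality with logit-linear covariate effects, death ending
the history, optional random censoring and staggered entry.

The bout process assigns each calendar minute independently to a 1-min
bout with probability bout_rate/60 (default 6 bouts/h ≈ 10% active
minutes, leaving abundant sedentary periods). This is a thinning of a
Poisson bout process onto minute boundaries: bouts that straddle minute
boundaries would dilute minute means as a generator artefact unrelated
to the estimators under test, so bout starts are minute-aligned. Axis
decomposition uses a uniform random angle; only the resultant is
meaningful.

The pull-and-clamp behaviour rule is a stand-in: real lizards do not
follow it, and passing recovery tests shows the estimators work under
this data-generating process, not that they capture real behavioural
decision-making. Other simplifications relative to real data: no
biophysical heat-flux modelling for the copper models, no autocorrelated
weather, no sensor drift or dropout (gaps must be injected explicitly),
i.i.d. Gaussian gradient temperatures rather than autocorrelated
movement along the gradient, and mortality with time-constant hazards.

## Problem sizes

The recovery analyses use: calibration — 100 replicates of 5,000 pairs
(noise SD 0.5 °C); survival — 200 replicates of 20 (male-like) or 8
(female-like) intercept-only histories over 13 weekly occasions; TPC —
50 replicates of 10 individuals × 480 minutes spanning 15–42 °C at 6 Hz;
T_set — 100 simulated gradient trials of 720 post-acclimation readings.
These sizes give Monte-Carlo standard errors comfortably inside the
tolerances asserted in the tests while keeping the full suite fast
enough for routine use.
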