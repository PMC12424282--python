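"""Synthetic field-study generator with known ground truth.

Every pipeline input can be generated here: operative-temperature traces
for copper models in five microhabitats (shared diel sinusoid plus habitat
offsets), lizard body-temperature traces under a thermoregulator or
thermoconformer behaviour rule, bout-structured two-axis accelerometer
streams whose intensity follows a Gaussian thermal performance curve,
laboratory gradient (surface, body) calibration pairs, and known-fate
encounter histories with logit-linear covariate effects on per-occasion
survival.

The thermoregulator rule — pull body temperature from the habitat mean
toward the preferred-range midpoint by a gain in [0, 1], clamped to the
instantaneous envelope of available operative temperatures — is a
deliberately simple stand-in for real behaviour: it encodes only that
behavioural thermoregulation cannot beat the best available microhabitat.

All randomness flows from one ``numpy.random.Generator`` seeded per call;
no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_ingest import AccelTrace, TemperatureTrace
from .survival import EncounterHistory

DEFAULT_HABITATS = ("full_shade", "partial_shade", "open", "tree", "burrow")


@dataclass
class EnvConfig:
    """Shared diel sinusoid + additive microhabitat offsets + noise.

    The sinusoid peaks at 15:00 and bottoms at 03:00 local time:
    ``T(t) = season_mean + day_mean_amp * sin(2*pi*(hour - 9)/24)``.
    """

    season_length_days: int = 30
    day_mean_amp: float = 8.0        # degC
    season_mean: float = 28.0        # degC
    microhabitat_offsets: dict[str, float] = field(
        default_factory=lambda: {
            "full_shade": -4.0, "partial_shade": -2.0, "open": 4.0,
            "tree": 0.0, "burrow": -6.0,
        }
    )
    noise_sd: float = 0.5            # degC
    time_step: int = 60              # minutes
    models_per_habitat: int = 2
    start: str = "2018-10-01"
    rng_seed: int = 0

    def __post_init__(self):
        if self.season_length_days < 1:
            raise ValueError("season_length_days must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        unknown = set(self.microhabitat_offsets) - set(DEFAULT_HABITATS)
        if unknown:
            raise ValueError(f"unknown habitat names {sorted(unknown)}")


@dataclass
class BehaviourConfig:
    """Body-temperature behaviour relative to the preferred range."""

    mode: str = "thermoregulator"    # or "thermoconformer"
    tset_low: float = 27.0           # degC
    tset_high: float = 33.8          # degC
    tracking_gain: float = 1.0       # 0 = conformer-like, 1 = perfect tracking
    tb_noise_sd: float = 0.0         # degC

    def __post_init__(self):
        if self.mode not in ("thermoregulator", "thermoconformer"):
            raise ValueError(f"bad mode {self.mode!r}")
        if not self.tset_low < self.tset_high:
            raise ValueError("tset_low must be < tset_high")
        if not 0 <= self.tracking_gain <= 1:
            raise ValueError("tracking_gain must be in [0, 1]")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.tset_low + self.tset_high)


@dataclass
class TruePerformance:
    """Ground-truth Gaussian thermal performance curve for acceleration.

    Bout-level acceleration magnitude at body temperature T is
    ``baseline + (pmax_true - baseline) * exp(-(T - topt_true)^2 / (2 breadth^2))``.
    """

    topt_true: float = 36.6          # degC
    pmax_true: float = 4.0           # ms^-2
    breadth: float = 5.0             # degC (Gaussian SD)
    baseline: float = 0.2            # ms^-2, sedentary magnitude
    bout_rate: float = 6.0           # bouts per hour

    def __post_init__(self):
        if not self.pmax_true > self.baseline >= 0:
            raise ValueError("need pmax_true > baseline >= 0")
        if self.breadth <= 0:
            raise ValueError("breadth must be > 0")

    def curve(self, temp):
        t = np.asarray(temp, dtype=float)
        return self.baseline + (self.pmax_true - self.baseline) * np.exp(
            -((t - self.topt_true) ** 2) / (2 * self.breadth**2)
        )


@dataclass
class SurvivalTruth:
    """Logit-scale coefficients for per-occasion survival."""

    betas: dict[str, float] = field(default_factory=lambda: {"intercept": 3.0})
    n_occasions: int = 13
    occasion_length_days: int = 7

    def __post_init__(self):
        if self.n_occasions < 1:
            raise ValueError("n_occasions must be >= 1")
        if "intercept" not in self.betas:
            raise ValueError("betas must include 'intercept'")


# ---------------------------------------------------------------------------


def _diel_sinusoid(timestamps: pd.DatetimeIndex, mean: float, amp: float) -> np.ndarray:
    hours = timestamps.hour + timestamps.minute / 60.0
    return mean + amp * np.sin(2 * np.pi * (hours - 9.0) / 24.0)


def gen_environment(cfg: EnvConfig) -> list[TemperatureTrace]:
    """Operative-temperature traces, one per copper model per microhabitat."""
    rng = np.random.default_rng(cfg.rng_seed)
    n_steps = cfg.season_length_days * 24 * 60 // cfg.time_step
    timestamps = pd.date_range(cfg.start, periods=n_steps, freq=f"{cfg.time_step}min")
    base = _diel_sinusoid(timestamps, cfg.season_mean, cfg.day_mean_amp)
    traces = []
    for hab in sorted(cfg.microhabitat_offsets):
        offset = cfg.microhabitat_offsets[hab]
        for k in range(cfg.models_per_habitat):
            noise = rng.normal(0.0, cfg.noise_sd, n_steps) if cfg.noise_sd > 0 else 0.0
            traces.append(
                TemperatureTrace(
                    sensor_id=f"cu_{hab}_{k:02d}",
                    entity="copper_model",
                    microhabitat=hab,
                    timestamps=timestamps,
                    values=base + offset + noise,
                )
            )
    return traces


def gen_lizard_tb(
    env: list[TemperatureTrace],
    beh: BehaviourConfig,
    seed: int,
    lizard_id: str = "liz_00",
) -> TemperatureTrace:
    """Body-temperature trace from environment traces under a behaviour rule.

    Thermoconformer: T_b = mean available T_e (+ noise).  Thermoregulator:
    T_b = mean T_e pulled toward the T_set midpoint by ``tracking_gain``,
    clamped to the instantaneous [min T_e, max T_e] envelope.
    """
    if not env:
        raise ValueError("need at least one environment trace")
    rng = np.random.default_rng(seed)
    vals = np.vstack([t.values for t in env])
    timestamps = env[0].timestamps
    te_mean = vals.mean(axis=0)
    if beh.mode == "thermoconformer":
        tb = te_mean.copy()
    else:
        lo, hi = vals.min(axis=0), vals.max(axis=0)
        tb = np.clip(te_mean + beh.tracking_gain * (beh.midpoint - te_mean), lo, hi)
    if beh.tb_noise_sd > 0:
        tb = tb + rng.normal(0.0, beh.tb_noise_sd, len(tb))
    return TemperatureTrace(
        sensor_id=lizard_id, entity="lizard", microhabitat=None,
        timestamps=timestamps, values=tb,
    )


def gen_accel(
    tb: TemperatureTrace,
    perf: TruePerformance,
    hz: int = 6,
    seed: int = 0,
    noise_sd: float = 0.05,
) -> AccelTrace:
    """Bout-structured two-axis accelerometer stream over a tb trace.

    Each calendar minute of the tb trace independently becomes a 1-min
    activity bout with probability ``bout_rate / 60`` (a Bernoulli thinning
    of a Poisson bout process onto minute boundaries, which keeps
    minute-mean magnitudes clean for the downstream percentile binning).
    Within a bout, sample magnitudes are the performance curve at that
    minute's body temperature plus Gaussian noise; outside bouts the
    magnitude is the sedentary baseline.  Magnitude is decomposed onto the
    two axes by a uniform random angle per sample; only the resultant is
    contractually meaningful.
    """
    if hz < 1:
        raise ValueError("hz must be >= 1")
    rng = np.random.default_rng(seed)
    n_min = len(tb)
    per_min = 60 * hz
    p_bout = min(1.0, perf.bout_rate / 60.0)
    is_bout = rng.random(n_min) < p_bout

    q = perf.curve(tb.values)
    target = np.where(is_bout, q, perf.baseline)
    mag = np.repeat(target, per_min)
    noise = rng.normal(0.0, noise_sd, n_min * per_min)
    mag = np.maximum(mag + np.repeat(is_bout, per_min) * noise, 0.0)

    offsets = np.tile(np.arange(per_min) * (1e9 / hz), n_min).astype("int64")
    base = np.repeat(tb.timestamps.asi8, per_min)
    timestamps = pd.DatetimeIndex(base + offsets)

    theta = rng.uniform(0.0, 2 * np.pi, len(mag))
    return AccelTrace(
        lizard_id=tb.sensor_id,
        timestamps=timestamps,
        x_heave=mag * np.cos(theta),
        y_surge=mag * np.sin(theta),
    )


def gen_gradient_pairs(
    intercept: float,
    slope: float,
    n: int,
    noise_sd: float,
    seed: int,
    surface_range: tuple[float, float] = (20.0, 40.0),
) -> pd.DataFrame:
    """Paired (surface, body) laboratory calibration table.

    ``body = intercept + slope * surface + N(0, noise_sd)`` with surface
    drawn uniformly over ``surface_range`` (the span of the laboratory
    thermal gradient).
    """
    if n < 2:
        raise ValueError("need n >= 2 pairs")
    rng = np.random.default_rng(seed)
    surface = rng.uniform(*surface_range, n)
    body = intercept + slope * surface
    if noise_sd > 0:
        body = body + rng.normal(0.0, noise_sd, n)
    return pd.DataFrame({"surface": surface, "body": body})


def gen_gradient_traces(
    n_individuals: int,
    sex: str,
    tb_mean: float,
    tb_sd: float,
    n_readings: int = 720,
    acclimation_h: float = 12.0,
    step_min: int = 2,
    seed: int = 0,
    start: str = "2018-08-01",
) -> tuple[dict[str, TemperatureTrace], dict[str, str]]:
    """Simulated thermal-gradient trials for preferred-temperature estimation.

    Each individual gets an acclimation block (readings that the estimator
    must discard) followed by ``n_readings`` post-acclimation body
    temperatures drawn i.i.d. Gaussian(tb_mean, tb_sd), logged every
    ``step_min`` minutes.  Returns traces and a lizard_id -> sex map.
    """
    rng = np.random.default_rng(seed)
    n_acc = int(acclimation_h * 60 / step_min)
    traces, sexes = {}, {}
    for i in range(n_individuals):
        lid = f"{sex[0]}{i:03d}"
        ts = pd.date_range(start, periods=n_acc + n_readings, freq=f"{step_min}min")
        vals = rng.normal(tb_mean, tb_sd, n_acc + n_readings)
        traces[lid] = TemperatureTrace(
            sensor_id=lid, entity="lizard", microhabitat=None, timestamps=ts, values=vals
        )
        sexes[lid] = sex
    return traces, sexes


def gen_encounter_histories(
    truth: SurvivalTruth,
    covariates: pd.DataFrame,
    seed: int,
    censor_rate: float = 0.0,
    first_occasion: dict[str, int] | None = None,
) -> list[EncounterHistory]:
    """Simulate known-fate encounter histories.

    Per-occasion survival is ``phi_i = expit(beta_0 + sum_k beta_k x_ik)``,
    constant across occasions within an individual.  Death terminates the
    history; each remaining occasion may independently censor the animal
    with probability ``censor_rate`` (before the survival draw).
    ``first_occasion`` supports staggered entry.
    """
    from scipy.special import expit

    names = [k for k in truth.betas if k != "intercept"]
    missing = [k for k in names if k not in covariates.columns]
    if missing:
        raise ValueError(f"covariate table missing columns {missing}")
    rng = np.random.default_rng(seed)
    histories = []
    for lid, row in covariates.iterrows():
        eta = truth.betas["intercept"] + sum(truth.betas[k] * float(row[k]) for k in names)
        phi = float(expit(eta))
        first = (first_occasion or {}).get(lid, 0)
        states = []
        for _ in range(first, truth.n_occasions):
            if censor_rate > 0 and rng.random() < censor_rate:
                states.append("censored")
                break
            if rng.random() < phi:
                states.append("survived")
            else:
                states.append("died")
                break
        if states:
            histories.append(
                EncounterHistory(
                    lizard_id=str(lid), first_occasion=first, states=states,
                    covariates={k: float(row[k]) for k in covariates.columns},
                )
            )
    return histories


def write_truth(rows: list[dict], path) -> None:
    """Ground-truth sidecar: one row per generated entity with true parameters."""
    pd.DataFrame(rows).to_csv(path, index=False)
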