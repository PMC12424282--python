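#!/usr/bin/env python
"""Generate the synthetic field study all later stages consume.

Writes, under results/sim/:
  gradient_pairs.csv    paired (surface, body) laboratory calibration data
  gradient_traces.csv   thermal-gradient trials for T_set estimation
  env.csv               copper-model operative temperatures, five microhabitats
  tb_surface.csv        lizard surface-temperature traces (uncalibrated)
  accel.csv             two-axis accelerometer streams
  lizards.csv, fates.csv  cohort metadata and daily telemetry fates
  truth.csv             ground-truth sidecar (one row per generated entity)

Ground truth echoes the published field estimates: calibration
body = 1.770 + 1.058 * surface, female upper T_set 33.8 degC, performance
peak T_opt 36.6 degC, and weekly survival whose 13-occasion products are
0.75 (males) and 0.33 (females).
"""

import numpy as np
import pandas as pd
from pathlib import Path
from scipy.special import expit, logit
from scipy.stats import norm

from thermofate import io_ingest as io
from thermofate import synthetic as syn

OUT = Path(__file__).resolve().parents[1] / "results" / "sim"
OUT.mkdir(parents=True, exist_ok=True)
SEED = 20181001

CAL_INTERCEPT, CAL_SLOPE = 1.770, 1.058
TSET = {"female": (27.0, 33.8), "male": (25.5, 29.0)}

rng = np.random.default_rng(SEED)
truth_rows = []

# --- laboratory calibration pairs -----------------------------------------
pairs = syn.gen_gradient_pairs(CAL_INTERCEPT, CAL_SLOPE, n=5000, noise_sd=0.5,
                               seed=int(rng.integers(2**31)))
pairs.to_csv(OUT / "gradient_pairs.csv", index=False)
truth_rows.append({"entity": "calibration", "param": "intercept", "value": CAL_INTERCEPT})
truth_rows.append({"entity": "calibration", "param": "slope", "value": CAL_SLOPE})

# --- thermal-gradient trials (10 per sex) ----------------------------------
all_traces = []
for sex, (lo, hi) in TSET.items():
    sd = 3.0
    mu = hi - norm.ppf(0.75) * sd  # Gaussian whose 75th percentile is the upper bound
    traces, _ = syn.gen_gradient_traces(10, sex, mu, sd, n_readings=720,
                                        seed=int(rng.integers(2**31)))
    all_traces += list(traces.values())
    truth_rows.append({"entity": f"tset_{sex}", "param": "upper_true", "value": hi})
io.write_traces(all_traces, OUT / "gradient_traces.csv")

# --- field season: environment + 3 focal lizards ---------------------------
env_cfg = syn.EnvConfig(season_length_days=14, time_step=60, rng_seed=int(rng.integers(2**31)))
env = syn.gen_environment(env_cfg)
io.write_traces(env, OUT / "env.csv")

# minute-resolution environment drives the lizard body-temperature traces
env_min = syn.gen_environment(
    syn.EnvConfig(season_length_days=1, time_step=1, rng_seed=env_cfg.rng_seed)
)
behaviours = {
    "liz_reg": syn.BehaviourConfig(mode="thermoregulator", tset_low=27.0,
                                   tset_high=33.8, tracking_gain=0.9, tb_noise_sd=0.3),
    "liz_con1": syn.BehaviourConfig(mode="thermoconformer", tset_low=27.0,
                                    tset_high=33.8, tb_noise_sd=0.3),
    "liz_con2": syn.BehaviourConfig(mode="thermoconformer", tset_low=25.5,
                                    tset_high=29.0, tb_noise_sd=0.3),
}
perf = syn.TruePerformance(topt_true=36.6, pmax_true=4.0, breadth=5.0, bout_rate=6.0)
truth_rows += [{"entity": "performance", "param": "topt_true", "value": 36.6},
               {"entity": "performance", "param": "pmax_true", "value": 4.0}]

tb_traces, accel_traces = [], []
for lid, beh in behaviours.items():
    tb = syn.gen_lizard_tb(env_min, beh, seed=int(rng.integers(2**31)), lizard_id=lid)
    # store the *surface* trace: invert the calibration so stage 02's fitted
    # model maps it back to body temperature
    surface = io.TemperatureTrace(
        lid, "lizard", None, tb.timestamps, (tb.values - CAL_INTERCEPT) / CAL_SLOPE
    )
    tb_traces.append(surface)
    accel_traces.append(syn.gen_accel(tb, perf, hz=2, seed=int(rng.integers(2**31))))
    truth_rows.append({"entity": lid, "param": "mode", "value": beh.mode})
io.write_traces(tb_traces, OUT / "tb_surface.csv")
io.write_traces(accel_traces, OUT / "accel.csv")

# --- survival cohort: 20 males + 7 females, daily fates over spring --------
season_start = pd.Timestamp("2018-10-01")
phi_week = {"male": 0.75 ** (1 / 13), "female": 0.33 ** (1 / 13)}
liz_rows, fate_rows = [], []
for sex, n in [("male", 20), ("female", 7)]:
    p_day = phi_week[sex] ** (1 / 7)
    for i in range(n):
        lid = f"sv_{sex[0]}{i:02d}"
        liz_rows.append(io.LizardRecord(lid, sex, float(rng.normal(380, 40)),
                                        season_start, season_start + pd.Timedelta(days=120)))
        day = 0
        dead = False
        while day < 13 * 7:
            date = season_start + pd.Timedelta(days=day)
            if rng.random() > p_day:
                fate_rows.append(io.FateRecord(lid, date, "dead"))
                dead = True
                break
            fate_rows.append(io.FateRecord(lid, date, "alive"))
            day += 1
        truth_rows.append({"entity": lid, "param": "phi_week_true",
                           "value": phi_week[sex]})
io.write_traces(liz_rows, OUT / "lizards.csv")
io.write_traces(fate_rows, OUT / "fates.csv")

syn.write_truth(truth_rows, OUT / "truth.csv")
n_dead = sum(r.status == "dead" for r in fate_rows)
print(f"simulated study written to {OUT}")
print(f"  {len(all_traces)} gradient trials, {len(pairs)} calibration pairs")
print(f"  {len(env)} copper models, {len(behaviours)} focal lizards with accelerometers")
print(f"  survival cohort: 27 lizards, {n_dead} deaths over 13 weeks")
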