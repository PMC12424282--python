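#!/usr/bin/env python
"""Seasonal thermoregulation indices (d_b, d_e, E) for the focal lizards.

Applies the stage-02 calibration to the surface traces, windows everything
to 05:00-21:00, and writes results/thermo_indices.csv (one row per lizard x
season).  The regulator should score E near 1 and the conformers near 0.
"""

from pathlib import Path

import pandas as pd

from thermofate import calibration as cal
from thermofate import io_ingest as io
from thermofate import thermoregulation as tr

ROOT = Path(__file__).resolve().parents[1] / "results"
SIM = ROOT / "sim"

model = cal.CalibrationModel.from_json(ROOT / "calibration_model.json")
tset_tab = pd.read_csv(ROOT / "tset.csv").set_index("sex")

# behaviour configs in stage 01: the regulator and first conformer use the
# female range, the second conformer the male range
sex_of = {"liz_reg": "female", "liz_con1": "female", "liz_con2": "male"}

env = [io.window_filter(t) for t in io.read_traces(SIM / "env.csv", "temperature")]
rows = []
for surf in io.read_traces(SIM / "tb_surface.csv", "temperature"):
    tb = io.window_filter(cal.apply_calibration(surf, model))
    sex = sex_of[surf.sensor_id]
    tset = cal.TsetRange(sex, tset_tab.loc[sex, "lower"], tset_tab.loc[sex, "upper"],
                         int(tset_tab.loc[sex, "n_individuals"]))
    db = tr.hourly_db(tb, tset)
    de = tr.hourly_de(env, tset)
    rows += tr.seasonal_indices(db, de, lizard_id=surf.sensor_id)

tab = tr.indices_frame(rows)
tab.to_csv(ROOT / "thermo_indices.csv", index=False)
print(tab.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
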