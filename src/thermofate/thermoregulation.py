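"""Thermoregulation indices following the Hertz deviation convention.

d_b (accuracy of thermoregulation) is the mean deviation of body
temperatures from the preferred range T_set; d_e (thermal quality of
habitat) is the mean deviation of operative-model temperatures from T_set.
The effectiveness of thermoregulation is

    E = 1 - mean(d_b) / mean(d_e)

computed per individual and season from hourly deviation series.  E = 1
means body temperatures sit inside T_set despite an unfavourable
environment; E = 0 means the animal does no better than its environment
(thermoconformity); negative E means active avoidance of T_set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import TsetRange
from .io_ingest import TemperatureTrace, assign_season


def deviation(temp, tset: TsetRange):
    """Deviation of a temperature from the T_set range (0 inside the range).

    Below the range: lower - temp; above: temp - upper.  Vectorised.
    """
    t = np.asarray(temp, dtype=float)
    d = np.where(t < tset.lower, tset.lower - t, np.where(t > tset.upper, t - tset.upper, 0.0))
    return float(d) if np.isscalar(temp) else d


def _hourly_mean_deviation(trace: TemperatureTrace, tset: TsetRange) -> pd.Series:
    dev = deviation(trace.values, tset)
    key = trace.timestamps.floor("h")
    return pd.Series(dev, index=key).groupby(level=0).mean()


def hourly_db(tb: TemperatureTrace, tset: TsetRange) -> pd.Series:
    """Hourly mean deviation of predicted body temperature from T_set.

    Index: hour timestamps; hours with no readings are simply absent.
    The trace should already be restricted to the daily analysis window.
    """
    if len(tb) == 0:
        return pd.Series(dtype=float)
    return _hourly_mean_deviation(tb, tset).rename("db")


def hourly_de(env: list[TemperatureTrace], tset: TsetRange) -> pd.Series:
    """Hourly thermal quality of habitat d_e.

    Per copper model, readings are reduced to hourly mean deviations from
    T_set; models are then averaged within each hour.  Hours with no model
    data are absent.
    """
    if not env:
        raise ValueError("need at least one copper-model trace")
    per_model = [_hourly_mean_deviation(t, tset) for t in env if len(t)]
    if not per_model:
        return pd.Series(dtype=float)
    return pd.concat(per_model, axis=1).mean(axis=1).rename("de")


def e_index(mean_db: float, mean_de: float) -> float | None:
    """Effectiveness of thermoregulation E = 1 - mean_db/mean_de.

    Undefined (None) when mean_de == 0: the environment never left T_set so
    effectiveness has no meaning.
    """
    if mean_db < 0 or mean_de < 0:
        raise ValueError("mean deviations must be >= 0")
    if mean_de == 0:
        return None
    return 1.0 - mean_db / mean_de


@dataclass(frozen=True)
class ThermoIndices:
    """Season-level thermoregulation summary for one individual."""

    lizard_id: str
    season: str
    mean_db: float
    mean_de: float
    e_index: float | None
    n_hours: int


def seasonal_indices(
    db: pd.Series, de: pd.Series, lizard_id: str = ""
) -> list[ThermoIndices]:
    """Season-level mean_db, mean_de and E for one individual.

    Hourly series are intersected (hours present in only one series are
    dropped from both, keeping the ratio coherent), assigned to seasons by
    calendar month, and averaged; E is the ratio-of-means
    1 - mean_db/mean_de per season.  Seasons with no overlapping hours
    yield no row.
    """
    joined = pd.concat([db.rename("db"), de.rename("de")], axis=1, join="inner").dropna()
    if joined.empty:
        return []
    seasons = pd.Index([assign_season(ts) for ts in joined.index], name="season")
    out = []
    for season, grp in joined.groupby(seasons):
        mdb = float(grp["db"].mean())
        mde = float(grp["de"].mean())
        out.append(
            ThermoIndices(
                lizard_id=lizard_id,
                season=season,
                mean_db=mdb,
                mean_de=mde,
                e_index=e_index(mdb, mde),
                n_hours=len(grp),
            )
        )
    return out


def indices_frame(indices: list[ThermoIndices]) -> pd.DataFrame:
    """Tabulate ThermoIndices rows (one per lizard x season)."""
    return pd.DataFrame(
        [
            {
                "lizard_id": i.lizard_id,
                "season": i.season,
                "mean_db": i.mean_db,
                "mean_de": i.mean_de,
                "e_index": np.nan if i.e_index is None else i.e_index,
                "n_hours": i.n_hours,
            }
            for i in indices
        ]
    )
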