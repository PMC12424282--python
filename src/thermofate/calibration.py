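"""Preferred-temperature (T_set) estimation and the surface->body calibration.

T_set is the interquartile range of body temperatures selected on a
laboratory thermal gradient (lower = 25th, upper = 75th percentile),
estimated per individual after discarding an acclimation period, then
averaged within sex.

Field body temperature (T_b,Predict) is predicted from externally logged
surface temperature through an ordinary-least-squares affine calibration
fitted on paired laboratory (surface, body) measurements.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io_ingest import TemperatureTrace


@dataclass(frozen=True)
class TsetRange:
    """Sex-level preferred body-temperature range (interquartile bounds)."""

    sex: str
    lower: float  # 25th percentile, degC
    upper: float  # 75th percentile, degC
    n_individuals: int

    def __post_init__(self):
        if not self.lower < self.upper:
            raise ValueError(f"degenerate T_set range [{self.lower}, {self.upper}]")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.lower + self.upper)


@dataclass(frozen=True)
class CalibrationModel:
    """OLS surface->body affine calibration: body = intercept + slope*surface."""

    intercept: float
    slope: float
    r_squared: float
    n_pairs: int
    residual_sd: float

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "CalibrationModel":
        with open(path) as fh:
            return cls(**json.load(fh))


def individual_tset_bounds(values, lower_q: float = 25.0, upper_q: float = 75.0):
    """25th/75th percentile bounds of one individual's gradient temperatures.

    Percentiles use linear interpolation between order statistics.
    """
    v = np.asarray(values, dtype=float)
    lo = float(np.percentile(v, lower_q))
    hi = float(np.percentile(v, upper_q))
    return lo, hi


def estimate_tset(
    traces: dict[str, TemperatureTrace],
    sexes: dict[str, str],
    acclimation_h: float = 12.0,
) -> dict[str, TsetRange]:
    """Estimate sex-specific T_set ranges from per-individual gradient traces.

    Per individual the first ``acclimation_h`` hours are dropped and the
    25th/75th percentiles of the remaining readings taken; sex-level bounds
    are the means of the per-individual bounds.  Individuals whose trace
    does not extend past the acclimation window, or whose post-acclimation
    readings are constant (degenerate bounds), are excluded with a warning.
    """
    per_sex: dict[str, list[tuple[float, float]]] = {}
    for lid, trace in traces.items():
        sex = sexes[lid]
        if len(trace) == 0:
            warnings.warn(f"{lid}: empty gradient trace, excluded")
            continue
        cutoff = trace.timestamps[0] + pd.Timedelta(hours=acclimation_h)
        keep = trace.timestamps >= cutoff
        if not keep.any():
            warnings.warn(f"{lid}: trace shorter than {acclimation_h} h acclimation, excluded")
            continue
        vals = trace.values[keep]
        lo, hi = individual_tset_bounds(vals)
        if not lo < hi:
            warnings.warn(f"{lid}: degenerate (constant) gradient trace, excluded")
            continue
        per_sex.setdefault(sex, []).append((lo, hi))

    if not per_sex:
        raise ValueError("no usable gradient traces after acclimation filtering")

    out = {}
    for sex, bounds in per_sex.items():
        arr = np.asarray(bounds)
        out[sex] = TsetRange(
            sex=sex,
            lower=float(arr[:, 0].mean()),
            upper=float(arr[:, 1].mean()),
            n_individuals=len(bounds),
        )
    return out


def fit_surface_calibration(pairs: pd.DataFrame) -> CalibrationModel:
    """OLS of body on surface temperature.

    ``pairs`` needs columns ``surface`` and ``body``.  Raises on fewer than
    two pairs or zero variance in surface temperature.
    """
    surface = pairs["surface"].to_numpy(dtype=float)
    body = pairs["body"].to_numpy(dtype=float)
    n = len(surface)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    if np.ptp(surface) == 0:
        raise ValueError("zero variance in surface temperature")
    res = sm.OLS(body, sm.add_constant(surface)).fit()
    resid_df = max(n - 2, 1)
    return CalibrationModel(
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        r_squared=float(res.rsquared),
        n_pairs=n,
        residual_sd=float(np.sqrt(res.ssr / resid_df)),
    )


def apply_calibration(surf: TemperatureTrace, model: CalibrationModel) -> TemperatureTrace:
    """Map a surface-temperature trace to predicted body temperature.

    Applies ``body = intercept + slope * surface`` value-wise and marks the
    output trace as predicted.
    """
    return TemperatureTrace(
        sensor_id=surf.sensor_id,
        entity=surf.entity,
        microhabitat=surf.microhabitat,
        timestamps=surf.timestamps,
        values=model.intercept + model.slope * surf.values,
        predicted=True,
    )


@dataclass(frozen=True)
class PairedBias:
    """Mean paired difference (surface - body), its SE, and paired t."""

    mean_diff: float
    se: float
    t: float | None  # None when SE == 0 with non-zero mean (degenerate)
    df: int


def paired_bias(pairs: pd.DataFrame) -> PairedBias:
    """Paired comparison of surface vs body temperature.

    Reports mean(surface - body), its standard error, and the paired
    t statistic mean/SE with df = n - 1.  With zero SE the t statistic is
    undefined (reported as None) unless the mean is also zero.
    """
    d = pairs["surface"].to_numpy(dtype=float) - pairs["body"].to_numpy(dtype=float)
    n = len(d)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    mean = float(d.mean())
    se = float(d.std(ddof=1) / np.sqrt(n))
    if se == 0:
        t = 0.0 if mean == 0 else None
    else:
        t = mean / se
    return PairedBias(mean_diff=mean, se=se, t=t, df=n - 1)
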