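"""Reading, validation and assembly of logger and metadata tables.

All pipeline inputs are delimited text (comma-separated, UTF-8, ISO-8601
timestamps).  Four schemas are supported:

``temperature``
    ``sensor_id, entity, microhabitat, timestamp, temp_c`` — one row per
    reading from either a lizard-borne logger (``entity=lizard``,
    microhabitat empty) or a copper operative model
    (``entity=copper_model``, microhabitat set).
``acceleration``
    ``lizard_id, timestamp, x, y`` — two-axis (heave/surge) accelerometer
    samples, nominally 6 Hz.
``lizards``
    ``lizard_id, sex, mass_g, tracked_from, tracked_to``.
``fates``
    ``lizard_id, date, status`` with status in {alive, dead, censored}.

This module also owns the small temporal conventions the rest of the
pipeline relies on: Southern-Hemisphere meteorological seasons, the
half-open daily analysis window, and calendar-minute pairing of body
temperature with acceleration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Season = Literal["spring", "summer", "autumn", "winter"]

#: month -> Southern-Hemisphere meteorological season
_SEASON_BY_MONTH = {
    9: "spring", 10: "spring", 11: "spring",
    12: "summer", 1: "summer", 2: "summer",
    3: "autumn", 4: "autumn", 5: "autumn",
    6: "winter", 7: "winter", 8: "winter",
}


class ValidationError(ValueError):
    """A file or record set violates its documented schema."""


@dataclass
class TemperatureTrace:
    """Time-stamped temperature series from one sensor.

    ``entity`` is ``"lizard"`` for animal-borne loggers (surface or
    predicted body temperature) and ``"copper_model"`` for operative
    models; ``microhabitat`` is set only for copper models.
    """

    sensor_id: str
    entity: str  # "lizard" | "copper_model"
    microhabitat: str | None
    timestamps: pd.DatetimeIndex
    values: np.ndarray
    predicted: bool = False  # True once a surface->body calibration is applied

    def __post_init__(self) -> None:
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.timestamps) != len(self.values):
            raise ValidationError(
                f"{self.sensor_id}: {len(self.timestamps)} timestamps vs "
                f"{len(self.values)} values"
            )
        if len(self.timestamps) > 1:
            deltas = np.diff(self.timestamps.asi8)
            if (deltas <= 0).any():
                bad = int(np.argmax(deltas <= 0)) + 1
                raise ValidationError(
                    f"{self.sensor_id}: timestamps not strictly increasing "
                    f"at position {bad} ({self.timestamps[bad]})"
                )
        if len(self.values) and not np.isfinite(self.values).all():
            raise ValidationError(f"{self.sensor_id}: non-finite temperature values")
        if self.entity == "lizard" and self.microhabitat is not None:
            raise ValidationError(f"{self.sensor_id}: lizard trace with microhabitat set")
        if self.entity == "copper_model" and self.microhabitat is None:
            raise ValidationError(f"{self.sensor_id}: copper model without microhabitat")

    def __len__(self) -> int:
        return len(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sensor_id": self.sensor_id,
                "entity": self.entity,
                "microhabitat": self.microhabitat if self.microhabitat is not None else "",
                "timestamp": self.timestamps,
                "temp_c": self.values,
            }
        )


@dataclass
class AccelTrace:
    """Two-axis accelerometer stream (X-heave, Y-surge) for one lizard."""

    lizard_id: str
    timestamps: pd.DatetimeIndex
    x_heave: np.ndarray
    y_surge: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.x_heave = np.asarray(self.x_heave, dtype=float)
        self.y_surge = np.asarray(self.y_surge, dtype=float)
        if not (len(self.timestamps) == len(self.x_heave) == len(self.y_surge)):
            raise ValidationError(f"{self.lizard_id}: axis/timestamp length mismatch")
        if len(self.timestamps) > 1 and (np.diff(self.timestamps.asi8) <= 0).any():
            raise ValidationError(f"{self.lizard_id}: timestamps not strictly increasing")

    def __len__(self) -> int:
        return len(self.timestamps)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lizard_id": self.lizard_id,
                "timestamp": self.timestamps,
                "x": self.x_heave,
                "y": self.y_surge,
            }
        )


@dataclass
class LizardRecord:
    lizard_id: str
    sex: str  # "male" | "female"
    mass_g: float
    tracked_from: pd.Timestamp
    tracked_to: pd.Timestamp

    def __post_init__(self) -> None:
        self.tracked_from = pd.Timestamp(self.tracked_from)
        self.tracked_to = pd.Timestamp(self.tracked_to)
        if self.sex not in ("male", "female"):
            raise ValidationError(f"{self.lizard_id}: sex must be male/female, got {self.sex!r}")
        if self.mass_g <= 0:
            raise ValidationError(f"{self.lizard_id}: mass_g must be positive")
        if self.tracked_from > self.tracked_to:
            raise ValidationError(f"{self.lizard_id}: tracked_from after tracked_to")


@dataclass
class FateRecord:
    lizard_id: str
    date: pd.Timestamp
    status: str  # "alive" | "dead" | "censored"

    def __post_init__(self) -> None:
        self.date = pd.Timestamp(self.date)
        if self.status not in ("alive", "dead", "censored"):
            raise ValidationError(f"{self.lizard_id}: bad status {self.status!r}")


@dataclass
class MinuteRecord:
    """Per-minute paired mean acceleration and mean predicted body temperature."""

    lizard_id: str
    minute: pd.Timestamp
    accel_mean: float
    tb_mean: float | None = None
    moved: bool | None = None


@dataclass
class MinuteTable:
    """Ordered minute records plus pairing bookkeeping."""

    frame: pd.DataFrame  # columns: lizard_id, minute, accel_mean, tb_mean
    n_dropped_minutes: int = 0

    def __len__(self) -> int:
        return len(self.frame)


# ---------------------------------------------------------------------------
# readers

_SCHEMAS = {
    "temperature": ["sensor_id", "entity", "microhabitat", "timestamp", "temp_c"],
    "acceleration": ["lizard_id", "timestamp", "x", "y"],
    "lizards": ["lizard_id", "sex", "mass_g", "tracked_from", "tracked_to"],
    "fates": ["lizard_id", "date", "status"],
}


def _read_csv(path, schema: str) -> pd.DataFrame:
    cols = _SCHEMAS[schema]
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    return df


def _parse_times(raw: pd.Series, path, column: str) -> pd.Series:
    parsed = pd.to_datetime(raw, errors="coerce", format="ISO8601")
    bad = parsed.isna() & (raw != "")
    if bad.any():
        lines = (np.flatnonzero(bad.to_numpy()) + 2).tolist()  # +2: header + 1-based
        raise ValidationError(f"{path}: unparseable {column} at lines {lines[:10]}")
    return parsed


def read_traces(path, schema: str):
    """Read one delimited-text file of the given schema into typed records.

    Returns a list of :class:`TemperatureTrace` / one or more
    :class:`AccelTrace` / a list of :class:`LizardRecord` /
    :class:`FateRecord` depending on ``schema``.  Malformed rows raise
    :class:`ValidationError` naming the offending lines.
    """
    if schema not in _SCHEMAS:
        raise ValidationError(f"unknown schema {schema!r}; expected one of {sorted(_SCHEMAS)}")
    df = _read_csv(path, schema)
    if df.empty:
        logger.warning("%s: empty %s file (header only)", path, schema)

    if schema == "temperature":
        df = df.assign(timestamp=_parse_times(df["timestamp"], path, "timestamp"))
        traces = []
        for sensor_id, grp in df.groupby("sensor_id", sort=True):
            dup = grp["timestamp"].duplicated()
            if dup.any():
                lines = (grp.index[dup].to_numpy() + 2).tolist()
                raise ValidationError(
                    f"{path}: duplicated timestamp for sensor {sensor_id} at lines {lines[:10]}"
                )
            grp = grp.sort_values("timestamp")
            entity = grp["entity"].iloc[0]
            hab = grp["microhabitat"].iloc[0] or None
            traces.append(
                TemperatureTrace(
                    sensor_id=str(sensor_id),
                    entity=entity,
                    microhabitat=hab,
                    timestamps=pd.DatetimeIndex(grp["timestamp"]),
                    values=grp["temp_c"].astype(float).to_numpy(),
                )
            )
        return traces

    if schema == "acceleration":
        df = df.assign(timestamp=_parse_times(df["timestamp"], path, "timestamp"))
        traces = []
        for lid, grp in df.groupby("lizard_id", sort=True):
            grp = grp.sort_values("timestamp")
            dup = grp["timestamp"].duplicated()
            if dup.any():
                lines = (grp.index[dup].to_numpy() + 2).tolist()
                raise ValidationError(
                    f"{path}: duplicated timestamp for lizard {lid} at lines {lines[:10]}"
                )
            traces.append(
                AccelTrace(
                    lizard_id=str(lid),
                    timestamps=pd.DatetimeIndex(grp["timestamp"]),
                    x_heave=grp["x"].astype(float).to_numpy(),
                    y_surge=grp["y"].astype(float).to_numpy(),
                )
            )
        return traces

    if schema == "lizards":
        return [
            LizardRecord(
                lizard_id=row.lizard_id,
                sex=row.sex,
                mass_g=float(row.mass_g),
                tracked_from=pd.Timestamp(row.tracked_from),
                tracked_to=pd.Timestamp(row.tracked_to),
            )
            for row in df.itertuples()
        ]

    # fates
    records = [
        FateRecord(lizard_id=row.lizard_id, date=pd.Timestamp(row.date), status=row.status)
        for row in df.itertuples()
    ]
    _check_fate_ordering(records)
    return records


def _check_fate_ordering(records: list[FateRecord]) -> None:
    by_id: dict[str, list[FateRecord]] = {}
    for r in records:
        by_id.setdefault(r.lizard_id, []).append(r)
    for lid, recs in by_id.items():
        recs.sort(key=lambda r: r.date)
        terminal_seen = False
        for r in recs:
            if terminal_seen:
                raise ValidationError(f"{lid}: fate record after terminal state")
            if r.status in ("dead", "censored"):
                terminal_seen = True


def write_traces(objs: Iterable, path) -> None:
    """Write typed records back to their delimited-text schema (round-trip)."""
    objs = list(objs)
    if not objs:
        raise ValidationError("nothing to write")
    first = objs[0]
    if isinstance(first, TemperatureTrace):
        pd.concat([t.to_frame() for t in objs]).to_csv(path, index=False)
    elif isinstance(first, AccelTrace):
        pd.concat([t.to_frame() for t in objs]).to_csv(path, index=False)
    elif isinstance(first, LizardRecord):
        pd.DataFrame(
            [
                {
                    "lizard_id": r.lizard_id,
                    "sex": r.sex,
                    "mass_g": r.mass_g,
                    "tracked_from": r.tracked_from.date(),
                    "tracked_to": r.tracked_to.date(),
                }
                for r in objs
            ]
        ).to_csv(path, index=False)
    elif isinstance(first, FateRecord):
        pd.DataFrame(
            [{"lizard_id": r.lizard_id, "date": r.date.date(), "status": r.status} for r in objs]
        ).to_csv(path, index=False)
    else:
        raise ValidationError(f"cannot write objects of type {type(first).__name__}")


# ---------------------------------------------------------------------------
# temporal conventions


def assign_season(date) -> Season:
    """Southern-Hemisphere meteorological season for a date.

    Sep-Nov spring, Dec-Feb summer, Mar-May autumn, Jun-Aug winter.
    """
    return _SEASON_BY_MONTH[pd.Timestamp(date).month]


def window_filter(trace, start_hour: int = 5, end_hour: int = 21):
    """Restrict a trace to the half-open daily window [start_hour, end_hour).

    The daily analysis window follows the field protocol of analysing
    records between 05:00 and 21:00 local time; 21:00 itself is excluded.
    """
    if not (0 <= start_hour < end_hour <= 24):
        raise ValueError(f"bad window [{start_hour}, {end_hour})")
    hours = trace.timestamps.hour
    keep = (hours >= start_hour) & (hours < end_hour)
    if isinstance(trace, TemperatureTrace):
        return TemperatureTrace(
            sensor_id=trace.sensor_id,
            entity=trace.entity,
            microhabitat=trace.microhabitat,
            timestamps=trace.timestamps[keep],
            values=trace.values[keep],
            predicted=trace.predicted,
        )
    if isinstance(trace, AccelTrace):
        return AccelTrace(
            lizard_id=trace.lizard_id,
            timestamps=trace.timestamps[keep],
            x_heave=trace.x_heave[keep],
            y_surge=trace.y_surge[keep],
        )
    raise TypeError(f"cannot window {type(trace).__name__}")


def minute_table(tb: TemperatureTrace, accel: AccelTrace,
                 accel_transform=None) -> MinuteTable:
    """Pair body temperature with acceleration on calendar minutes.

    Acceleration samples are reduced to their resultant magnitude
    (optionally through a raw-count affine conversion, see
    :mod:`thermofate.activity`), then both streams are averaged on
    floor-to-minute bins.  Minutes missing either stream are dropped and
    counted in ``n_dropped_minutes``.
    """
    from .activity import resultant

    if len(tb) == 0 or len(accel) == 0:
        raise ValidationError("minute_table requires non-empty traces")

    mag = resultant(accel.x_heave, accel.y_surge, transform=accel_transform)
    acc = (
        pd.Series(mag, index=accel.timestamps.floor("min"))
        .groupby(level=0)
        .mean()
        .rename("accel_mean")
    )
    tbm = (
        pd.Series(tb.values, index=tb.timestamps.floor("min"))
        .groupby(level=0)
        .mean()
        .rename("tb_mean")
    )
    joined = pd.concat([acc, tbm], axis=1, join="outer")
    complete = joined.dropna()
    if complete.empty:
        raise ValidationError(
            f"no overlapping minutes between {accel.lizard_id} acceleration and "
            f"{tb.sensor_id} temperature"
        )
    frame = complete.reset_index(names="minute")
    frame.insert(0, "lizard_id", accel.lizard_id)
    return MinuteTable(frame=frame, n_dropped_minutes=int(len(joined) - len(complete)))
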