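"""Sensor export ingestion and stabilized-window averaging.

Low-cost rapid-response monitors log one reading per minute per analyte.
The assessment does not consume raw traces: it needs a *steady-state mean*
per analyte, taken after the sensor has warmed up and the room has settled.
The protocol modelled here is: wait at least 10 minutes for readings to
stabilize, then average a further 10-minute window.

"Stabilized" is judged by a scale-free sliding-window test: the fitted
linear slope of the window, relative to the window mean, must not exceed
``slope_tol`` per minute (default 0.1 %/min).  The source protocol only
asks for "relatively constant" readings; the slope test is this package's
concrete, configurable rendering of that requirement.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Union

import numpy as np
import pandas as pd

from .errors import FormatError, StabilizationError, ValidationError
from .reference_data import ANALYTE_UNITS, Analyte, Side

__all__ = [
    "SensorSeries",
    "SteadyWindow",
    "DEFAULT_SCHEMA",
    "read_sensor_export",
    "write_sensor_export",
    "stable_window_mean",
    "volume_from_dimensions",
]

logger = logging.getLogger(__name__)

#: Default column → analyte map for the delimited export layout.
DEFAULT_SCHEMA: dict[str, Analyte] = {
    "co2_ppm": Analyte.CO2,
    "no2_ppb": Analyte.NO2,
    "voc_ppb": Analyte.VOC,
    "pm10_ugm3": Analyte.PM10,
    "pm25_ugm3": Analyte.PM25,
}

#: Cadence gaps up to this many minutes are tolerated as sensor dropouts;
#: longer gaps split the trace into separate series.
MAX_GAP_MINUTES = 2.0


@dataclass(frozen=True)
class SensorSeries:
    """One analyte's timestamped trace at one location."""

    location: Side
    analyte: Analyte
    unit: str
    timestamps: pd.DatetimeIndex = field(repr=False)
    values: np.ndarray = field(repr=False)
    space_id: str | None = None
    latitude: float | None = None
    longitude: float | None = None

    def __post_init__(self):
        ts = pd.DatetimeIndex(self.timestamps)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "timestamps", ts)
        object.__setattr__(self, "values", vals)
        if len(ts) != len(vals):
            raise ValidationError("timestamps and values must have equal length")
        if len(ts) > 1 and not ts.is_monotonic_increasing or ts.has_duplicates:
            raise ValidationError("timestamps must be strictly increasing")
        if np.any(vals < 0):
            raise ValidationError("concentrations must be non-negative")
        expected = ANALYTE_UNITS[Analyte(self.analyte)]
        if self.unit != expected:
            raise ValidationError(
                f"unit {self.unit!r} inconsistent with {self.analyte.value} "
                f"(expected {expected!r})"
            )

    def __len__(self) -> int:
        return len(self.values)

    @property
    def minutes(self) -> np.ndarray:
        """Elapsed minutes since the first sample."""
        return (self.timestamps - self.timestamps[0]).total_seconds() / 60.0


@dataclass(frozen=True)
class SteadyWindow:
    """A stabilized averaging window and its summary statistics."""

    start: pd.Timestamp
    end: pd.Timestamp
    mean: float
    sd: float
    n_points: int
    stability_metric: float  # |slope| / |mean|, per minute


def _split_on_gaps(ts: pd.DatetimeIndex) -> list[np.ndarray]:
    """Index chunks separated by cadence gaps longer than MAX_GAP_MINUTES."""
    if len(ts) == 0:
        return []
    gaps = np.diff(ts.view("int64")) / 60e9  # minutes
    breaks = np.nonzero(gaps > MAX_GAP_MINUTES)[0]
    return np.split(np.arange(len(ts)), breaks + 1)


def read_sensor_export(
    source: Union[str, Path, IO[str]],
    schema: dict[str, Analyte] | None = None,
    timestamp_col: str = "timestamp",
    location: Side | str = Side.INDOOR,
    space_id: str | None = None,
    sep: str = ",",
) -> list[SensorSeries]:
    """Parse a delimited sensor export into one series per analyte column.

    ``schema`` maps column names to analytes (default :data:`DEFAULT_SCHEMA`;
    only columns actually present are read).  Rows with a missing value in a
    column are dropped from that analyte's series, with a logged count.
    Cadence gaps longer than two minutes split a series into chunks.
    """
    schema = dict(DEFAULT_SCHEMA) if schema is None else dict(schema)
    location = Side(location)
    df = pd.read_csv(source, sep=sep)
    if timestamp_col not in df.columns:
        raise FormatError(f"missing timestamp column {timestamp_col!r}")
    try:
        ts_all = pd.to_datetime(df[timestamp_col])
    except (ValueError, TypeError) as exc:
        raise FormatError(f"unparseable timestamps: {exc}") from exc
    diffs = ts_all.diff().dropna()
    bad = diffs[diffs <= pd.Timedelta(0)]
    if not bad.empty:
        raise FormatError(f"non-monotone timestamp at row {bad.index[0]}")

    present = [c for c in df.columns if c in schema]
    if not present:
        raise FormatError(
            f"no analyte columns found; expected any of {sorted(schema)}"
        )

    out: list[SensorSeries] = []
    for col in present:
        analyte = Analyte(schema[col])
        vals = pd.to_numeric(df[col], errors="coerce")
        keep = vals.notna()
        dropped = int((~keep).sum())
        if dropped:
            logger.info("dropped %d rows with missing %s values", dropped, col)
        ts = pd.DatetimeIndex(ts_all[keep])
        v = vals[keep].to_numpy(dtype=float)
        for idx in _split_on_gaps(ts):
            out.append(
                SensorSeries(
                    location=location,
                    analyte=analyte,
                    unit=ANALYTE_UNITS[analyte],
                    timestamps=ts[idx],
                    values=v[idx],
                    space_id=space_id,
                )
            )
    return out


def write_sensor_export(
    series: Iterable[SensorSeries],
    dest: Union[str, Path, IO[str], None] = None,
    timestamp_col: str = "timestamp",
    sep: str = ",",
) -> str | None:
    """Write series sharing one timestamp axis back to the export layout.

    Inverse of :func:`read_sensor_export` for the default schema; returns
    the text when ``dest`` is None.
    """
    series = list(series)
    if not series:
        raise ValidationError("nothing to write")
    col_by_analyte = {a: c for c, a in DEFAULT_SCHEMA.items()}
    frame = pd.DataFrame({timestamp_col: series[0].timestamps})
    for s in series:
        if not s.timestamps.equals(series[0].timestamps):
            raise ValidationError("all series must share one timestamp axis")
        frame[col_by_analyte[s.analyte]] = s.values
    text = frame.to_csv(index=False, sep=sep)
    if dest is None:
        return text
    if isinstance(dest, (str, Path)):
        Path(dest).write_text(text)
    else:
        dest.write(text)
    return None


def stable_window_mean(
    series: SensorSeries,
    warmup_min: float = 10.0,
    window_min: float = 10.0,
    slope_tol: float = 0.001,
) -> SteadyWindow:
    """First stabilized window after warm-up, with its mean and sd.

    Slides a ``window_min``-long window (inclusive of both endpoints, so a
    1-minute cadence yields 11 points) across the trace starting no earlier
    than ``warmup_min`` after the first sample; accepts the first window
    whose fitted |slope|/|mean| is at most ``slope_tol`` per minute.
    Raises :class:`StabilizationError` if no window qualifies — pass
    ``slope_tol=float("inf")`` to force acceptance of the first window.
    """
    minutes = series.minutes
    span = minutes[-1] - minutes[0] if len(series) else 0.0
    if span < warmup_min + window_min:
        raise StabilizationError(
            f"series spans {span:.1f} min; need at least warmup+window = "
            f"{warmup_min + window_min:.1f} min"
        )
    starts = np.nonzero(minutes >= warmup_min)[0]
    tol = 1e-9
    for i in starts:
        t0 = minutes[i]
        in_win = (minutes >= t0 - tol) & (minutes <= t0 + window_min + tol)
        idx = np.nonzero(in_win)[0]
        if len(idx) < 2 or minutes[idx[-1]] - t0 < window_min - tol:
            continue
        y = series.values[idx]
        x = minutes[idx] - t0
        slope = np.polyfit(x, y, 1)[0]
        mean = float(np.mean(y))
        metric = abs(slope) / abs(mean) if mean != 0 else abs(slope)
        if metric <= slope_tol:
            return SteadyWindow(
                start=series.timestamps[idx[0]],
                end=series.timestamps[idx[-1]],
                mean=mean,
                sd=float(np.std(y, ddof=1)),
                n_points=len(idx),
                stability_metric=float(metric),
            )
    raise StabilizationError(
        f"no window of {window_min:.0f} min with relative slope <= "
        f"{slope_tol:g}/min found after {warmup_min:.0f} min warm-up"
    )


def volume_from_dimensions(width: float, length: float, height: float) -> float:
    """Air volume (m³) of a rectangular space from its dimensions (m)."""
    if width <= 0 or length <= 0 or height <= 0:
        raise ValidationError("all dimensions must be positive")
    return width * length * height
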