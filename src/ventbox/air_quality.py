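"""Indoor/outdoor pollutant screening.

Each analyte's stabilized indoor and outdoor means are (a) compared against
the regulatory exposure limits and (b) combined into the indoor-to-outdoor
ratio I/O = Ci/Co.  An I/O ratio strictly above 1 indicates indoor emission
sources; exceedance of a limit is strict (values exactly at the limit are
compliant).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .errors import UndefinedRatioError, ValidationError
from .reference_data import Analyte, GuidelineSet, Side, load_guidelines

__all__ = ["AirQualityRecord", "io_ratio", "assess_pollutant", "flag_matrix"]


def io_ratio(ci: float, co: float) -> float:
    """Indoor-to-outdoor concentration ratio Ci/Co (same units)."""
    if ci < 0:
        raise ValidationError("indoor concentration must be non-negative")
    if co <= 0:
        raise UndefinedRatioError(
            "outdoor concentration is zero or negative; the I/O ratio is undefined"
        )
    return ci / co


@dataclass(frozen=True)
class AirQualityRecord:
    """Screening result for one analyte in one space."""

    analyte: Analyte
    ci: float                      # indoor mean, native unit
    co: float                      # outdoor mean, native unit
    io: float                      # Ci/Co
    indoor_limit: float
    outdoor_limit: float
    indoor_exceeds: bool           # Ci > indoor limit (strict)
    outdoor_exceeds: bool          # Co > outdoor limit (strict)
    indoor_source_suspected: bool  # I/O > 1 (strict)


def assess_pollutant(
    analyte: Analyte | str,
    ci: float,
    co: float,
    limits: GuidelineSet | None = None,
) -> AirQualityRecord:
    """Build the screening record for one analyte from stabilized means."""
    try:
        analyte = Analyte(analyte)
    except ValueError as exc:
        raise ValidationError(f"unknown analyte: {analyte!r}") from exc
    if analyte is Analyte.CO2:
        raise ValidationError("CO2 is assessed by the ventilation pathway, not limits")
    guide = limits if limits is not None else load_guidelines()
    lim_in = guide.lookup_pollutant_limit(analyte, Side.INDOOR)
    lim_out = guide.lookup_pollutant_limit(analyte, Side.OUTDOOR)
    ratio = io_ratio(ci, co)
    return AirQualityRecord(
        analyte=analyte,
        ci=ci,
        co=co,
        io=ratio,
        indoor_limit=lim_in,
        outdoor_limit=lim_out,
        indoor_exceeds=ci > lim_in,
        outdoor_exceeds=co > lim_out,
        indoor_source_suspected=ratio > 1,
    )


def flag_matrix(
    records_by_space: Mapping[str, Iterable[AirQualityRecord]],
) -> pd.DataFrame:
    """Exceedance grid: spaces × (analyte, side) boolean marks.

    Purely mechanical limit comparisons — a cell is True exactly when the
    corresponding mean strictly exceeds its regulatory limit.
    """
    rows = {}
    for space, records in records_by_space.items():
        row = {}
        for rec in records:
            row[(rec.analyte.value, Side.INDOOR.value)] = rec.indoor_exceeds
            row[(rec.analyte.value, Side.OUTDOOR.value)] = rec.outdoor_exceeds
        rows[space] = row
    frame = pd.DataFrame.from_dict(rows, orient="index").fillna(False).astype(bool)
    frame.columns = pd.MultiIndex.from_tuples(frame.columns, names=["analyte", "side"])
    return frame.sort_index(axis=1)
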