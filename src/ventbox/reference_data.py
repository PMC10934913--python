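"""Packaged guideline tables and lookup operations.

The guideline numbers the assessment relies on — per-person CO2 exhalation
rates by activity, recommended respiration flow rates per person (Fb),
design air-changes-per-hour intervals for common space types, CO2 ceilings
for the anti-contagion (700 ppm) and air-quality (1000 ppm) goals, and
regulatory indoor/outdoor pollutant limits — ship as human-readable CSV/JSON
files under ``ventbox/tables/``.  They are loaded (not hard-coded) so a user
can audit them or point the loaders at an override directory.

Units: exhalation and respiration flow rates in l s⁻¹, ACH in h⁻¹,
CO2 ceilings in ppm v/v, particulate limits in µg m⁻³ and gas limits in
ppb v/v (the native units of the source tables; no conversions applied).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import TableLookupError, ValidationError

__all__ = [
    "Activity",
    "Analyte",
    "Side",
    "SpaceClass",
    "SpaceType",
    "Goal",
    "ExhalationTable",
    "GuidelineSet",
    "load_guidelines",
    "lookup_fb",
    "lookup_design_ach",
    "lookup_pollutant_limit",
]


class Activity(str, Enum):
    """Metabolic activity level driving the per-person CO2 exhalation rate."""

    REST = "rest"
    WALKING = "walking"
    PHYSICAL = "physical"


class SpaceClass(str, Enum):
    """Space classes keyed to the recommended respiration flow rate Fb."""

    HIGH_AEROSOL = "high_aerosol"       # singing, loud speaking, exercise, close distance
    LIBRARY_OFFICE = "library_office"   # libraries, study rooms, offices
    ORDINARY_PUBLIC = "ordinary_public"  # other ordinary workplaces / public spaces
    MINIMUM = "minimum"                 # minimum required ventilation, any space


class SpaceType(str, Enum):
    """Space types carrying a recommended design ACH interval."""

    AUDITORIUM = "auditorium"
    LECTURE_ROOM = "lecture_room"
    LIBRARY = "library"
    OFFICE = "office"
    RESTAURANT = "restaurant"
    CINEMA_ROOM = "cinema_room"
    GYM = "gym"


class Analyte(str, Enum):
    CO2 = "CO2"
    PM25 = "PM2.5"
    PM10 = "PM10"
    VOC = "VOC"
    NO2 = "NO2"


class Side(str, Enum):
    INDOOR = "indoor"
    OUTDOOR = "outdoor"


class Goal(str, Enum):
    """Ventilation goal: prevent airborne contagion, or plain air quality."""

    ANTI_COVID = "anti_covid"
    MINIMUM_VENTILATION = "minimum_ventilation"


#: Native measurement unit per analyte.
ANALYTE_UNITS: dict[Analyte, str] = {
    Analyte.CO2: "ppm",
    Analyte.PM25: "ug/m3",
    Analyte.PM10: "ug/m3",
    Analyte.VOC: "ppb",
    Analyte.NO2: "ppb",
}


def _table_path(name: str, directory: str | Path | None) -> Path:
    if directory is not None:
        return Path(directory) / name
    return Path(str(resources.files("ventbox").joinpath("tables", name)))


@dataclass(frozen=True)
class ExhalationTable:
    """Per-person CO2 exhalation rates (l s⁻¹) by age group, gender, activity.

    The rows keyed by ``("average", "person")`` are the authoritative
    aggregate values used at runtime; per-age rows are retained for
    documentation and auditability but never re-aggregated.
    """

    rows: pd.DataFrame = field(repr=False)

    @classmethod
    def load(cls, directory: str | Path | None = None) -> "ExhalationTable":
        df = pd.read_csv(_table_path("exhalation_rates.csv", directory))
        if (df["rate_l_s"] <= 0).any():
            raise ValidationError("exhalation rates must all be positive")
        return cls(rows=df)

    def rate(self, age_group: str, gender: str, activity: Activity | str) -> float:
        activity = Activity(activity)
        sel = self.rows[
            (self.rows.age_group == age_group)
            & (self.rows.gender == gender)
            & (self.rows.activity == activity.value)
        ]
        if sel.empty:
            raise TableLookupError(
                f"no exhalation rate for ({age_group!r}, {gender!r}, {activity.value!r})"
            )
        return float(sel["rate_l_s"].iloc[0])

    def average_person_rate(self, activity: Activity | str) -> float:
        """Aggregate 'average person' rate for one activity, l s⁻¹."""
        return self.rate("average", "person", activity)


@dataclass(frozen=True)
class GuidelineSet:
    """All guideline values consumed by the assessment, loaded from disk."""

    fb_values: dict[SpaceClass, float]
    co2_ceilings: dict[Goal, float]
    design_ach: dict[SpaceType, tuple[float, float]]
    pollutant_limits: dict[tuple[Analyte, Side], float]
    pollutant_units: dict[tuple[Analyte, Side], str]
    exhalation: ExhalationTable

    @classmethod
    def load(cls, directory: str | Path | None = None) -> "GuidelineSet":
        fb_df = pd.read_csv(_table_path("respiration_flow.csv", directory))
        fb = {SpaceClass(r.space_class): float(r.fb_l_s) for r in fb_df.itertuples()}
        if any(v <= 0 for v in fb.values()):
            raise ValidationError("every Fb value must be positive")

        ach_df = pd.read_csv(_table_path("design_ach.csv", directory))
        design = {
            SpaceType(r.space_type): (float(r.ach_min), float(r.ach_max))
            for r in ach_df.itertuples()
        }
        for st, (lo, hi) in design.items():
            if lo > hi:
                raise ValidationError(f"design ACH interval inverted for {st.value}")

        with open(_table_path("co2_ceilings.json", directory)) as fh:
            raw = json.load(fh)
        ceilings = {
            Goal.ANTI_COVID: float(raw["anti_covid"]),
            Goal.MINIMUM_VENTILATION: float(raw["air_quality"]),
        }
        if not ceilings[Goal.ANTI_COVID] < ceilings[Goal.MINIMUM_VENTILATION]:
            raise ValidationError("anti-contagion CO2 ceiling must lie below the air-quality ceiling")

        lim_df = pd.read_csv(_table_path("pollutant_limits.csv", directory))
        limits: dict[tuple[Analyte, Side], float] = {}
        units: dict[tuple[Analyte, Side], str] = {}
        for r in lim_df.itertuples():
            key = (Analyte(r.analyte), Side(r.side))
            limits[key] = float(r.limit)
            units[key] = str(r.unit)

        return cls(
            fb_values=fb,
            co2_ceilings=ceilings,
            design_ach=design,
            pollutant_limits=limits,
            pollutant_units=units,
            exhalation=ExhalationTable.load(directory),
        )

    # -- lookups ---------------------------------------------------------

    def lookup_fb(self, space_class: SpaceClass | str) -> float:
        """Recommended respiration flow rate per person, l s⁻¹."""
        try:
            space_class = SpaceClass(space_class)
        except ValueError as exc:
            raise TableLookupError(f"unknown space class: {space_class!r}") from exc
        return self.fb_values[space_class]

    def lookup_design_ach(self, space_type: SpaceType | str) -> tuple[float, float]:
        """Recommended (min, max) design ACH interval, h⁻¹."""
        try:
            space_type = SpaceType(space_type)
        except ValueError as exc:
            raise TableLookupError(f"unknown space type: {space_type!r}") from exc
        return self.design_ach[space_type]

    def lookup_pollutant_limit(self, analyte: Analyte | str, side: Side | str) -> float:
        """Regulatory exposure limit for an analyte on one side, native units."""
        try:
            analyte = Analyte(analyte)
            side = Side(side)
        except ValueError as exc:
            raise TableLookupError(f"unknown analyte/side: {analyte!r}/{side!r}") from exc
        if analyte is Analyte.CO2:
            raise TableLookupError(
                "CO2 has no regulatory limit row; use co2_ceilings for the 700/1000 ppm rules"
            )
        return self.pollutant_limits[(analyte, side)]


_DEFAULT: GuidelineSet | None = None


def load_guidelines(directory: str | Path | None = None) -> GuidelineSet:
    """Load a :class:`GuidelineSet`; the packaged tables are cached."""
    global _DEFAULT
    if directory is not None:
        return GuidelineSet.load(directory)
    if _DEFAULT is None:
        _DEFAULT = GuidelineSet.load()
    return _DEFAULT


def lookup_fb(space_class: SpaceClass | str) -> float:
    return load_guidelines().lookup_fb(space_class)


def lookup_design_ach(space_type: SpaceType | str) -> tuple[float, float]:
    return load_guidelines().lookup_design_ach(space_type)


def lookup_pollutant_limit(analyte: Analyte | str, side: Side | str) -> float:
    return load_guidelines().lookup_pollutant_limit(analyte, side)
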