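"""Synthetic sensor traces and the packaged case-study fixtures.

The generator reproduces the statistical structure the pipeline expects
from a minute-cadence CO2 monitor in a well-mixed room: the box-model
first-order approach to steady state, sampled every minute, with additive
zero-mean Gaussian sensor noise.  Pollutant channels are modelled as a
steady level plus the same noise model.  A single integer seed makes every
trace reproducible.

``case_study_fixtures`` returns seven worked scenarios — two study rooms, a
coffee shop, a restaurant, a cinema room, a gym and a car-repair office —
with their measured volumes, occupancies, indoor/outdoor CO2 means and
pollutant means, so every pipeline stage can be exercised without any
external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .assessment import Space
from .box_model import CO2Scenario, transient_profile
from .errors import ValidationError
from .occupancy import OccupancyState
from .reference_data import ANALYTE_UNITS, Activity, Analyte, Side, SpaceClass, SpaceType
from .sensor_io import SensorSeries

__all__ = ["TraceSpec", "simulate_co2_trace", "simulate_steady_trace", "CaseStudy", "case_study_fixtures"]

#: Arbitrary fixed epoch for synthetic timestamps (keeps traces stable).
_EPOCH = pd.Timestamp("2021-10-01 09:00:00")


@dataclass(frozen=True)
class TraceSpec:
    """Specification of one synthetic minute-cadence trace."""

    scenario: CO2Scenario
    noise_sd: float          # ppm, additive Gaussian
    duration_min: float
    cadence_min: float = 1.0
    seed: int = 0
    location: Side = Side.INDOOR
    space_id: str | None = None

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValidationError("noise sd must be non-negative")
        if self.cadence_min <= 0:
            raise ValidationError("cadence must be positive")
        if self.duration_min < self.cadence_min:
            raise ValidationError("duration must cover at least one cadence step")


def _timestamps(duration_min: float, cadence_min: float) -> pd.DatetimeIndex:
    n = int(np.floor(duration_min / cadence_min)) + 1
    return _EPOCH + pd.to_timedelta(np.arange(n) * cadence_min, unit="min")


def simulate_co2_trace(spec: TraceSpec) -> SensorSeries:
    """CO2 trace: closed-form box-model concentration plus sensor noise."""
    ts = _timestamps(spec.duration_min, spec.cadence_min)
    minutes = np.arange(len(ts)) * spec.cadence_min
    clean = transient_profile(spec.scenario, spec.scenario.tinit + minutes / 60.0)
    rng = np.random.default_rng(spec.seed)
    noisy = clean + rng.normal(0.0, spec.noise_sd, size=clean.shape) if spec.noise_sd else clean
    return SensorSeries(
        location=spec.location,
        analyte=Analyte.CO2,
        unit=ANALYTE_UNITS[Analyte.CO2],
        timestamps=ts,
        values=np.clip(noisy, 0.0, None),
        space_id=spec.space_id,
    )


def simulate_steady_trace(
    analyte: Analyte | str,
    level: float,
    noise_sd: float,
    duration_min: float,
    cadence_min: float = 1.0,
    seed: int = 0,
    location: Side = Side.INDOOR,
    space_id: str | None = None,
) -> SensorSeries:
    """Non-CO2 channel: a steady pollutant level plus Gaussian noise."""
    analyte = Analyte(analyte)
    if level < 0 or noise_sd < 0:
        raise ValidationError("level and noise sd must be non-negative")
    ts = _timestamps(duration_min, cadence_min)
    rng = np.random.default_rng(seed)
    vals = np.clip(level + rng.normal(0.0, noise_sd, size=len(ts)), 0.0, None)
    return SensorSeries(
        location=Side(location),
        analyte=analyte,
        unit=ANALYTE_UNITS[analyte],
        timestamps=ts,
        values=vals,
        space_id=space_id,
    )


@dataclass(frozen=True)
class CaseStudy:
    """One worked space: inputs for both assessment pathways."""

    space: Space
    occupancy: OccupancyState
    css: float  # stabilized indoor CO2 mean, ppm
    co: float   # stabilized outdoor CO2 mean, ppm
    pollutants: Mapping[Analyte, tuple[float, float]] = field(default_factory=dict)

    def scenario(self, ach: float, cinit: float | None = None) -> CO2Scenario:
        """Box-model scenario at a given air-change rate.

        By default the episode starts already equilibrated (cinit = css),
        matching the measurement protocol of deploying sensors into an
        occupied space; pass ``cinit`` explicitly to model the approach
        from another starting concentration.
        """
        return CO2Scenario(
            v=self.space.volume,
            co=self.co,
            fext=ach * self.space.volume,
            g=self.occupancy.generation,
            cinit=self.css if cinit is None else cinit,
        )


_REST = {Activity.REST: 1.0}
_REST_WALK = {Activity.REST: 0.8, Activity.WALKING: 0.2}
_PHYSICAL = {Activity.PHYSICAL: 1.0}

_P = Analyte  # brevity in the fixture table


def case_study_fixtures() -> dict[str, CaseStudy]:
    """The seven measured spaces with every input value they carry.

    Pollutant tuples are (indoor mean, outdoor mean) in the analyte's
    native unit.  Design-ACH intervals are attached per space as used in
    the capacity studies (the coffee shop carries the 10-12 h⁻¹ interval
    of its study even though the generic design table has no coffee-shop
    row).
    """

    def cs(space_id, v, space_class, design, space_type, n, mix, css, co, pm25, pm10, voc, no2):
        return CaseStudy(
            space=Space(
                space_id=space_id,
                volume=v,
                space_class=space_class,
                space_type=space_type,
                design_ach=design,
            ),
            occupancy=OccupancyState(n=n, activity_mix=mix),
            css=css,
            co=co,
            pollutants={_P.PM25: pm25, _P.PM10: pm10, _P.VOC: voc, _P.NO2: no2},
        )

    LO, HA, OP = SpaceClass.LIBRARY_OFFICE, SpaceClass.HIGH_AEROSOL, SpaceClass.ORDINARY_PUBLIC
    return {
        "city_study_room": cs(
            "city_study_room", 77.4, LO, (4, 5), SpaceType.LIBRARY,
            2, _REST, 628, 447,
            (2.04, 2.12), (6.71, 14.75), (519.7, 183.3), (20.6, 25.6),
        ),
        "university_study_room": cs(
            "university_study_room", 742.2, LO, (4, 5), SpaceType.LIBRARY,
            18, _REST, 529, 489,
            (2.0, 2.02), (8.25, 8.76), (81.33, 50.75), (12.56, 26.13),
        ),
        "coffee_shop": cs(
            "coffee_shop", 255.5, HA, (10, 12), None,
            9, _REST_WALK, 558, 507,
            (3.65, 2.0), (9.52, 8.6), (106.11, 93.78), (46.78, 14.33),
        ),
        "restaurant": cs(
            "restaurant", 509.2, HA, (8, 12), SpaceType.RESTAURANT,
            17, _REST_WALK, 624, 374,
            (2.0, 2.11), (4.84, 7.74), (96.21, 68.0), (42.71, 32.67),
        ),
        "cinema_room": cs(
            "cinema_room", 2155.9, OP, (5, 8), SpaceType.CINEMA_ROOM,
            20, _REST, 697, 474,
            (2.19, 2.86), (5.37, 29.07), (839.55, 174.18), (14.73, 37.18),
        ),
        "gym": cs(
            "gym", 2543.1, HA, (4, 6), SpaceType.GYM,
            6, _PHYSICAL, 502, 475,
            (2.0, 2.0), (5.69, 5.1), (311.11, 170.0), (7.44, 15.0),
        ),
        "office": cs(
            "office", 64.9, LO, (4, 8), SpaceType.OFFICE,
            2, _REST, 548, 545,
            (2.62, 20.17), (19.46, 55.16), (118.5, 78.38), (274.5, 82.75),
        ),
    }
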