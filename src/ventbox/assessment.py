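"""End-to-end ventilation + air-quality assessment of a space.

The procedure for one space and one ventilation goal:

a. obtain the air volume V (measured directly or from dimensions);
b. estimate the occupants' CO2 generation rate G from head count and
   activity;
c. take stabilized indoor (Css) and outdoor (Co) CO2 means;
d. estimate the real air-change rate ACHreal = 10⁶·G/(V·(Css − Co));
e. compute the guideline objective ACH for the same occupancy;
f. verdict: ventilation is adequate when ACHreal meets the (ceiled)
   objective **and** Css stays at or below the goal's CO2 ceiling
   (700 ppm anti-contagion, 1000 ppm air quality).

The verdict distinguishes which condition failed (air-change shortfall,
ceiling breach, or both) since the remediation differs; the coarse
adequate/inadequate reading is ``verdict is Verdict.ADEQUATE``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from enum import Enum
from typing import Mapping

from .air_quality import AirQualityRecord, assess_pollutant, flag_matrix
from .box_model import VentilationEstimate, ach_real
from .errors import ValidationError
from .occupancy import OccupancyCapacity, OccupancyState, ach_objective, capacity_table
from .reference_data import (
    Analyte,
    Goal,
    GuidelineSet,
    SpaceClass,
    SpaceType,
    load_guidelines,
)
from .sensor_io import volume_from_dimensions

__all__ = ["Space", "Verdict", "VentilationAssessment", "assess_ventilation", "full_report", "Report"]


@dataclass(frozen=True)
class Space:
    """A ventilated space: geometry plus guideline classification."""

    space_id: str
    volume: float | None = None                 # m³; or give dimensions
    dimensions: tuple[float, float, float] | None = None  # width, length, height (m)
    space_class: SpaceClass = SpaceClass.ORDINARY_PUBLIC
    space_type: SpaceType | None = None         # for design-ACH lookups
    design_ach: tuple[float, float] | None = None  # explicit (min, max) override

    def __post_init__(self):
        if self.volume is None and self.dimensions is None:
            raise ValidationError("a space needs a volume or dimensions")
        if self.volume is None:
            object.__setattr__(self, "volume", volume_from_dimensions(*self.dimensions))
        elif self.volume <= 0:
            raise ValidationError("air volume must be positive")

    def design_interval(self, guidelines: GuidelineSet | None = None) -> tuple[float, float]:
        """Design (min, max) ACH: explicit override, else by space type."""
        if self.design_ach is not None:
            return self.design_ach
        if self.space_type is None:
            raise ValidationError(f"space {self.space_id!r} has no design-ACH information")
        guide = guidelines if guidelines is not None else load_guidelines()
        return guide.lookup_design_ach(self.space_type)


class Verdict(str, Enum):
    ADEQUATE = "adequate"
    INADEQUATE_ACH = "inadequate_ach"
    INADEQUATE_CO2 = "inadequate_co2"
    INADEQUATE_BOTH = "inadequate_both"
    VACANT = "vacant"  # n = 0: the ACH estimate is undefined, not adequate-by-default


@dataclass(frozen=True)
class VentilationAssessment:
    space_id: str
    goal: Goal
    estimate: VentilationEstimate | None  # None when the space is vacant
    ach_objective_raw: float
    ach_objective_ceiled: int
    co2_ceiling: float
    verdict: Verdict
    capacity: OccupancyCapacity | None = None

    @property
    def ach_real(self) -> float | None:
        return self.estimate.ach_real if self.estimate else None


def assess_ventilation(
    space: Space,
    occupancy: OccupancyState,
    css: float,
    co: float,
    goal: Goal | str,
    guidelines: GuidelineSet | None = None,
    with_capacity: bool = True,
) -> VentilationAssessment:
    """Run steps (a)–(f) for one space, occupancy and goal.

    ``css`` and ``co`` are stabilized steady-state means in ppm.  Raises
    :class:`~ventbox.errors.EstimationError` when css ≤ co (the estimate is
    then undefined; ventilate less or re-measure).  A vacant space (n = 0)
    yields the ``VACANT`` verdict instead of an estimate.
    """
    goal = Goal(goal)
    guide = guidelines if guidelines is not None else load_guidelines()
    ceiling = guide.co2_ceilings[goal]
    fb = guide.lookup_fb(
        space.space_class if goal is Goal.ANTI_COVID else SpaceClass.MINIMUM
    )
    raw, ceiled = ach_objective(fb, occupancy.n, space.volume)

    if occupancy.n == 0:
        return VentilationAssessment(
            space_id=space.space_id,
            goal=goal,
            estimate=None,
            ach_objective_raw=raw,
            ach_objective_ceiled=ceiled,
            co2_ceiling=ceiling,
            verdict=Verdict.VACANT,
            capacity=None,
        )

    est = ach_real(occupancy.generation, space.volume, css, co)
    ach_ok = est.ach_real >= ceiled
    co2_ok = css <= ceiling
    if ach_ok and co2_ok:
        verdict = Verdict.ADEQUATE
    elif not ach_ok and not co2_ok:
        verdict = Verdict.INADEQUATE_BOTH
    elif not ach_ok:
        verdict = Verdict.INADEQUATE_ACH
    else:
        verdict = Verdict.INADEQUATE_CO2

    capacity = None
    if with_capacity:
        capacity = capacity_table(
            v=space.volume,
            co=co,
            exh_rate=occupancy.exh_rate,
            fb_ac=guide.lookup_fb(space.space_class),
            fb_mv=guide.lookup_fb(SpaceClass.MINIMUM),
            ach_available=est.ach_real,
            ceilings=guide.co2_ceilings,
        )
    return VentilationAssessment(
        space_id=space.space_id,
        goal=goal,
        estimate=est,
        ach_objective_raw=raw,
        ach_objective_ceiled=ceiled,
        co2_ceiling=ceiling,
        verdict=verdict,
        capacity=capacity,
    )


@dataclass(frozen=True)
class Report:
    """Combined ventilation + air-quality report for one space."""

    space_id: str
    ventilation: dict[Goal, VentilationAssessment] | None
    air_quality: list[AirQualityRecord] = field(default_factory=list)
    gaps: list[str] = field(default_factory=list)

    def notes(self) -> list[str]:
        """Mechanical findings: failed conditions, exceeded limits, I/O > 1."""
        out: list[str] = []
        if self.ventilation:
            for goal, va in self.ventilation.items():
                if va.verdict is Verdict.ADEQUATE:
                    out.append(f"{goal.value}: ventilation adequate")
                elif va.verdict is Verdict.VACANT:
                    out.append(f"{goal.value}: vacant - not assessable for real ACH")
                else:
                    out.append(f"{goal.value}: {va.verdict.value}")
                if va.estimate and va.estimate.low_confidence:
                    out.append(
                        f"{goal.value}: indoor-outdoor CO2 difference is only "
                        f"{va.estimate.delta_ppm:g} ppm; ACH estimate is sensor-noise "
                        "sensitive"
                    )
        for rec in self.air_quality:
            if rec.indoor_exceeds:
                out.append(f"{rec.analyte.value}: indoor level {rec.ci:g} exceeds limit {rec.indoor_limit:g}")
            if rec.outdoor_exceeds:
                out.append(f"{rec.analyte.value}: outdoor level {rec.co:g} exceeds limit {rec.outdoor_limit:g}")
            if rec.indoor_source_suspected:
                out.append(f"{rec.analyte.value}: I/O = {rec.io:.2f} > 1 suggests indoor sources")
        out.extend(f"missing input: {g}" for g in self.gaps)
        return out

    def to_dict(self) -> dict:
        def enc(x):
            if isinstance(x, Enum):
                return x.value
            return x

        vent = None
        if self.ventilation:
            vent = {
                goal.value: json.loads(json.dumps(asdict(va), default=enc))
                for goal, va in self.ventilation.items()
            }
        return {
            "space_id": self.space_id,
            "ventilation": vent,
            "air_quality": [json.loads(json.dumps(asdict(r), default=enc)) for r in self.air_quality],
            "notes": self.notes(),
            "gaps": list(self.gaps),
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)


def full_report(
    space: Space,
    occupancy: OccupancyState,
    css: float | None = None,
    co: float | None = None,
    pollutants: Mapping[Analyte | str, tuple[float, float]] | None = None,
    guidelines: GuidelineSet | None = None,
) -> Report:
    """Combined report; partial inputs yield a partial report with gaps.

    ``pollutants`` maps analyte → (indoor mean, outdoor mean).
    """
    guide = guidelines if guidelines is not None else load_guidelines()
    gaps: list[str] = []
    ventilation = None
    if css is not None and co is not None:
        ventilation = {
            goal: assess_ventilation(space, occupancy, css, co, goal, guide)
            for goal in Goal
        }
    else:
        gaps.append("indoor/outdoor CO2 pair (ventilation section omitted)")

    records: list[AirQualityRecord] = []
    if pollutants:
        for analyte, (ci_val, co_val) in pollutants.items():
            records.append(assess_pollutant(analyte, ci_val, co_val, guide))
    else:
        gaps.append("pollutant measurements (air-quality section omitted)")

    return Report(space_id=space.space_id, ventilation=ventilation, air_quality=records, gaps=gaps)


def batch_flag_matrix(reports: Mapping[str, Report]):
    """Exceedance grid across several spaces' reports."""
    return flag_matrix({sid: rep.air_quality for sid, rep in reports.items()})
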