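"""Occupancy-side computations and maximum-occupancy inversion.

Two guideline families constrain how many people a space can hold:

* the *objective air-change rate*: ACHobj = Fb·n·3.6/V (Fb the per-person
  respiration flow in l s⁻¹), conventionally rounded **up** to the next
  integer before comparison with the available ACH;
* the *steady-state CO2 ceiling*: Co + 10⁶·G(n)/(ACH·V) ≤ 700 ppm
  (anti-contagion) or 1000 ppm (air quality), where G(n) = n·Exh·3.6 is the
  occupants' CO2 generation in m³ h⁻¹.

Both are inverted for the largest compliant integer head count.  Comparisons
are inclusive; steady states within half a display unit (0.005 ppm) of the
ceiling count as compliant, so exact-boundary cases land on the boundary
head count rather than one below it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .box_model import steady_state_concentration
from .errors import DomainError, ValidationError
from .reference_data import Activity, Goal, load_guidelines

__all__ = [
    "OccupancyState",
    "ConstraintResult",
    "GoalCapacity",
    "OccupancyCapacity",
    "exhalation_rate",
    "generation_rate",
    "ach_objective",
    "max_occupancy_ach_constraint",
    "max_occupancy_css_constraint",
    "capacity_table",
]

#: l s⁻¹ → m³ h⁻¹ conversion: 3600 s h⁻¹ × 0.001 m³ l⁻¹.
LS_TO_M3H = 3.6

#: Half of the 2-decimal display resolution used for ppm values; steady
#: states within this of a ceiling are treated as sitting on the ceiling.
CSS_BOUNDARY_TOL_PPM = 0.005

_REL_EPS = 1e-9  # guards integer floors/ceils against float representation


def exhalation_rate(activity_mix: dict[Activity | str, float]) -> float:
    """Per-person CO2 exhalation rate (l s⁻¹) for a mix of activities.

    Weighted mean of the "average person" rates (rest / walking / physical)
    by the mix fractions, which must sum to 1.
    """
    if not activity_mix:
        raise ValidationError("activity mix must not be empty")
    mix = {Activity(k): float(v) for k, v in activity_mix.items()}
    if any(not 0 <= f <= 1 for f in mix.values()):
        raise ValidationError("activity fractions must lie in [0, 1]")
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ValidationError(f"activity fractions must sum to 1 (got {total})")
    table = load_guidelines().exhalation
    return sum(f * table.average_person_rate(act) for act, f in mix.items())


@dataclass(frozen=True)
class OccupancyState:
    """Head count plus activity mix, resolving to a per-person CO2 rate."""

    n: int
    activity_mix: dict = field(default_factory=lambda: {Activity.REST: 1.0})
    exh_rate: float | None = None  # l s⁻¹ override; derived from mix if None

    def __post_init__(self):
        if self.n < 0 or int(self.n) != self.n:
            raise ValidationError("head count must be a non-negative integer")
        if self.exh_rate is None:
            object.__setattr__(self, "exh_rate", exhalation_rate(self.activity_mix))
        elif self.exh_rate <= 0:
            raise ValidationError("exhalation rate must be positive")

    @property
    def generation(self) -> float:
        """Total CO2 generation rate, m³ h⁻¹."""
        return generation_rate(self.n, self.exh_rate)


def generation_rate(n: int, exh_rate: float) -> float:
    """Total CO2 generation G = n·Exh·3600·0.001, m³ h⁻¹."""
    if n < 0:
        raise ValidationError("head count must be non-negative")
    if exh_rate <= 0:
        raise ValidationError("exhalation rate must be positive")
    return n * exh_rate * LS_TO_M3H


def ach_objective(fb: float, n: int, v: float) -> tuple[float, int]:
    """Guideline objective ACH for n occupants: (raw, ceiled-to-integer).

    raw = Fb·n·3.6/V; the ceiled value is what guidelines compare against
    (zero stays zero for an empty space).
    """
    if v <= 0:
        raise DomainError("air volume V must be positive")
    if fb <= 0:
        raise DomainError("respiration flow Fb must be positive")
    if n < 0:
        raise ValidationError("head count must be non-negative")
    raw = fb * n * LS_TO_M3H / v
    ceiled = int(math.ceil(raw - _REL_EPS * max(raw, 1.0))) if n > 0 else 0
    return raw, ceiled


def max_occupancy_ach_constraint(ach_available: float, fb: float, v: float) -> int:
    """Largest n whose ceiled objective ACH stays within the available ACH.

    Returns 0 when even a single occupant's requirement exceeds the
    available air-change rate.
    """
    if ach_available < 0:
        raise DomainError("available ACH must be non-negative")

    def ok(n: int) -> bool:
        return n == 0 or ach_objective(fb, n, v)[1] <= ach_available + _REL_EPS

    # Analytic start: raw(n) ≤ floor(ach_available) ⇔ ceil(raw) ≤ ach_available.
    floor_ach = math.floor(ach_available + _REL_EPS)
    n = max(0, math.floor(floor_ach * v / (fb * LS_TO_M3H) + _REL_EPS))
    while n > 0 and not ok(n):
        n -= 1
    while ok(n + 1):
        n += 1
    return n


def max_occupancy_css_constraint(
    ach_available: float,
    v: float,
    co: float,
    exh_rate: float,
    c_limit: float,
    css_tol: float = CSS_BOUNDARY_TOL_PPM,
) -> int:
    """Largest n keeping the steady-state CO2 at or below the ceiling.

    The comparison is inclusive with a half-display-unit allowance
    (``css_tol``), so exact boundary cases count as compliant.
    """
    if ach_available <= 0:
        raise DomainError("available ACH must be positive")
    if v <= 0:
        raise DomainError("air volume V must be positive")
    if exh_rate <= 0:
        raise ValidationError("exhalation rate must be positive")
    if co >= c_limit:
        return 0
    fext = ach_available * v

    def ok(n: int) -> bool:
        return steady_state_concentration(co, generation_rate(n, exh_rate), fext) <= c_limit + css_tol

    n = max(0, math.floor((c_limit - co) * fext / (1e6 * exh_rate * LS_TO_M3H) + _REL_EPS))
    while n > 0 and not ok(n):
        n -= 1
    while ok(n + 1):
        n += 1
    return n


@dataclass(frozen=True)
class ConstraintResult:
    """One constraint's capacity: head count plus the implied G and Css."""

    constraint: str  # "ach_ceiling" | "concentration_limit"
    n_max: int
    g_at_nmax: float   # m³ h⁻¹
    css_at_nmax: float  # ppm at the available ventilation


@dataclass(frozen=True)
class GoalCapacity:
    """Both constraints for one ventilation goal; the smaller n binds."""

    goal: Goal
    ach_constraint: ConstraintResult
    css_constraint: ConstraintResult

    @property
    def binding(self) -> ConstraintResult:
        if self.css_constraint.n_max <= self.ach_constraint.n_max:
            return self.css_constraint
        return self.ach_constraint

    @property
    def n_max(self) -> int:
        return self.binding.n_max


@dataclass(frozen=True)
class OccupancyCapacity:
    """Capacity table for one space at one available air-change rate."""

    ach_available: float
    anti_covid: GoalCapacity
    minimum_ventilation: GoalCapacity

    def for_goal(self, goal: Goal) -> GoalCapacity:
        return self.anti_covid if Goal(goal) is Goal.ANTI_COVID else self.minimum_ventilation


def _goal_capacity(
    goal: Goal,
    ach_available: float,
    v: float,
    co: float,
    exh_rate: float,
    fb: float,
    c_limit: float,
) -> GoalCapacity:
    fext = ach_available * v
    n_ach = max_occupancy_ach_constraint(ach_available, fb, v)
    n_css = max_occupancy_css_constraint(ach_available, v, co, exh_rate, c_limit)
    results = []
    for name, n in (("ach_ceiling", n_ach), ("concentration_limit", n_css)):
        g = generation_rate(n, exh_rate)
        css = steady_state_concentration(co, g, fext)
        results.append(ConstraintResult(constraint=name, n_max=n, g_at_nmax=g, css_at_nmax=css))
    return GoalCapacity(goal=goal, ach_constraint=results[0], css_constraint=results[1])


def capacity_table(
    v: float,
    co: float,
    exh_rate: float,
    fb_ac: float,
    fb_mv: float,
    ach_available: float,
    ceilings: dict[Goal, float] | None = None,
) -> OccupancyCapacity:
    """Maximum occupancy under both goals at a given available ACH.

    Anti-contagion pairs ``fb_ac`` with the 700 ppm ceiling; minimum
    ventilation pairs ``fb_mv`` with 1000 ppm.  ``ach_available`` may be a
    measured real ACH or a design-guideline value.
    """
    if ceilings is None:
        ceilings = load_guidelines().co2_ceilings
    ac = _goal_capacity(
        Goal.ANTI_COVID, ach_available, v, co, exh_rate, fb_ac, ceilings[Goal.ANTI_COVID]
    )
    mv = _goal_capacity(
        Goal.MINIMUM_VENTILATION,
        ach_available, v, co, exh_rate, fb_mv, ceilings[Goal.MINIMUM_VENTILATION],
    )
    return OccupancyCapacity(ach_available=ach_available, anti_covid=ac, minimum_ventilation=mv)
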