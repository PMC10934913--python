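"""Well-mixed single-zone CO2 mass balance.

The room is modelled as one perfectly mixed compartment of constant air
volume V (m³) ventilated by a constant external-air flow Fext (m³ h⁻¹),
with outdoor CO2 concentration Co (ppm v/v) and an indoor generation rate
G(t) (m³ h⁻¹ of pure CO2, scaled by 10⁶ to ppm).  Balance of matter gives

    dC/dt = (Fext/V)·(Co − C) + 10⁶·G(t)/V,    C(t_init) = C_init,

whose closed-form solution (a = Fext/V) is

    C(t) = Co + (C_init − Co)·e^(−a·(t−t_init))
               + (10⁶/V) ∫ G(s)·e^(−a·(t−s)) ds.

With constant G the solution relaxes exponentially to the steady state
Css = Co + 10⁶·G/Fext, which inverted for the air-change rate gives the
estimator ACH = 10⁶·G / (V·(Css − Co)).

Key assumptions: inflow equals outflow, exhaust air carries the room
concentration (perfect mixing), Co constant during the measurement, and
the only CO2 source is occupants' exhalation.

Time is in hours and flows in m³ h⁻¹ throughout; conversions from
per-person l s⁻¹ rates happen in :mod:`ventbox.occupancy`.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Callable, Sequence, Union

import numpy as np
from scipy.integrate import quad

from .errors import DomainError, EstimationError, InfeasibleLimitError

__all__ = [
    "PiecewiseConstantRate",
    "CO2Scenario",
    "VentilationEstimate",
    "transient_concentration",
    "steady_state_concentration",
    "ach_real",
    "long_term_bounds",
    "required_fext",
    "DEFAULT_DELTA_WARN_PPM",
]

#: Below this Css − Co difference (ppm) the ACH estimate is flagged as
#: low-confidence: still mathematically valid but dominated by sensor noise.
DEFAULT_DELTA_WARN_PPM = 25.0

RateLike = Union[float, "PiecewiseConstantRate", Callable[[float], float]]


@dataclass(frozen=True)
class PiecewiseConstantRate:
    """Piecewise-constant generation rate G(t).

    ``times`` are the strictly increasing segment start times (h); segment i
    holds ``rates[i]`` on [times[i], times[i+1]), the last one extending to
    +infinity.  Evaluation before ``times[0]`` returns ``rates[0]``.
    """

    times: tuple[float, ...]
    rates: tuple[float, ...]

    def __post_init__(self):
        if len(self.times) != len(self.rates) or not self.times:
            raise DomainError("times and rates must be equal-length, non-empty")
        if any(t1 >= t2 for t1, t2 in zip(self.times, self.times[1:])):
            raise DomainError("segment start times must be strictly increasing")
        if any(r < 0 for r in self.rates):
            raise DomainError("generation rates must be non-negative")

    def __call__(self, t: float) -> float:
        i = bisect_right(self.times, t) - 1
        return self.rates[max(i, 0)]

    def segments(self, t0: float, t1: float):
        """Yield (start, end, rate) covering [t0, t1]."""
        bounds = [t0] + [t for t in self.times if t0 < t < t1] + [t1]
        for a, b in zip(bounds, bounds[1:]):
            yield a, b, self(a)


@dataclass(frozen=True)
class CO2Scenario:
    """Parameters of one box-model episode.

    V in m³, co/cinit in ppm v/v, fext in m³ h⁻¹, g constant (m³ h⁻¹),
    piecewise-constant, or an arbitrary callable of time (h).
    """

    v: float
    co: float
    fext: float
    g: RateLike
    cinit: float
    tinit: float = 0.0
    quad_rtol: float = field(default=1e-8)

    def __post_init__(self):
        if self.v <= 0:
            raise DomainError("air volume V must be positive")
        if self.fext < 0:
            raise DomainError("external flow Fext must be non-negative")
        if self.co < 0 or self.cinit < 0:
            raise DomainError("concentrations must be non-negative")
        if isinstance(self.g, (int, float)) and self.g < 0:
            raise DomainError("generation rate G must be non-negative")


@dataclass(frozen=True)
class VentilationEstimate:
    """Result of inverting the steady state for the air-change rate."""

    ach_real: float          # h⁻¹
    fext: float              # m³ h⁻¹, = ach_real · V
    css: float               # ppm
    co: float                # ppm
    g_co2: float             # m³ h⁻¹
    delta_ppm: float         # css − co
    low_confidence: bool     # delta below the sensor-resolution threshold
    delta_warn_ppm: float = DEFAULT_DELTA_WARN_PPM


def _segment_step(c0: float, co: float, a: float, g: float, v: float, dt: float) -> float:
    """Advance the constant-G solution by dt from concentration c0."""
    if a > 0:
        css = co + 1e6 * g / (a * v)
        return css + (c0 - css) * math.exp(-a * dt)
    # No ventilation: pure accumulation.
    return c0 + 1e6 * g * dt / v


def transient_concentration(scenario: CO2Scenario, t: float) -> float:
    """Indoor CO2 concentration C(t) in ppm from the closed-form solution.

    Constant G evaluates the exponential relaxation directly; a
    piecewise-constant G chains exact per-segment solutions (no quadrature
    error); a general callable G is integrated by adaptive quadrature to
    relative tolerance ``scenario.quad_rtol``.
    """
    if t < scenario.tinit:
        raise DomainError(f"t={t} precedes the initial time {scenario.tinit}")
    if t == scenario.tinit:
        return scenario.cinit

    a = scenario.fext / scenario.v
    g = scenario.g

    if isinstance(g, (int, float)):
        return _segment_step(scenario.cinit, scenario.co, a, float(g), scenario.v, t - scenario.tinit)

    if isinstance(g, PiecewiseConstantRate):
        c = scenario.cinit
        for s0, s1, rate in g.segments(scenario.tinit, t):
            c = _segment_step(c, scenario.co, a, rate, scenario.v, s1 - s0)
        return c

    # General callable: C = Co + (Cinit−Co)e^{−aΔ} + (1e6/V)∫ G(s) e^{−a(t−s)} ds.
    # The damped integrand keeps the quadrature well-scaled for large a·Δt.
    integral, _ = quad(
        lambda s: g(s) * math.exp(-a * (t - s)),
        scenario.tinit,
        t,
        epsrel=scenario.quad_rtol,
        epsabs=0.0,
        limit=500,
    )
    homogeneous = (scenario.cinit - scenario.co) * math.exp(-a * (t - scenario.tinit))
    return scenario.co + homogeneous + 1e6 * integral / scenario.v


def steady_state_concentration(co: float, g: float, fext: float) -> float:
    """Steady-state indoor CO2, ppm: Css = Co + 10⁶·G/Fext."""
    if fext <= 0:
        raise DomainError("no steady state exists without ventilation (Fext must be > 0)")
    if g < 0:
        raise DomainError("generation rate G must be non-negative")
    if co < 0:
        raise DomainError("outdoor concentration must be non-negative")
    return co + 1e6 * g / fext


def ach_real(
    g: float,
    v: float,
    css: float,
    co: float,
    delta_warn_ppm: float = DEFAULT_DELTA_WARN_PPM,
) -> VentilationEstimate:
    """Estimate the real air-change rate from a measured steady state.

    ACH = 10⁶·G / (V·(Css − Co)).  When the indoor/outdoor difference is
    below ``delta_warn_ppm`` the estimate is flagged low-confidence: a few
    ppm of sensor noise then swings the estimate wildly.
    """
    if v <= 0:
        raise DomainError("air volume V must be positive")
    if g <= 0:
        raise DomainError("generation rate G must be positive to estimate ACH")
    delta = css - co
    if delta <= 0:
        raise EstimationError(
            f"indoor steady state ({css} ppm) does not exceed the outdoor level "
            f"({co} ppm); the air-change rate is unbounded or the measurement is "
            "inconsistent"
        )
    ach = 1e6 * g / (v * delta)
    return VentilationEstimate(
        ach_real=ach,
        fext=ach * v,
        css=css,
        co=co,
        g_co2=g,
        delta_ppm=delta,
        low_confidence=delta < delta_warn_ppm,
        delta_warn_ppm=delta_warn_ppm,
    )


def long_term_bounds(
    g_min: float,
    g_max: float,
    q: float,
    co: float,
    tolerance: float = 0.0,
) -> tuple[float, float]:
    """Asymptotic envelope of C(t) for a bounded generation rate.

    For Gmin ≤ G(t) ≤ Gmax every solution eventually satisfies
    Co + 10⁶·Gmin/Q − ε ≤ C(t) ≤ Co + 10⁶·Gmax/Q + ε; ``tolerance`` is the
    explicit transient allowance ε (ppm, default 0).
    """
    if not 0 <= g_min <= g_max:
        raise DomainError("need 0 <= Gmin <= Gmax")
    if q <= 0:
        raise DomainError("ventilation flow Q must be positive")
    if tolerance < 0:
        raise DomainError("tolerance must be non-negative")
    lo = co + 1e6 * g_min / q - tolerance
    hi = co + 1e6 * g_max / q + tolerance
    return lo, hi


def required_fext(co: float, g: float, c_limit: float) -> float:
    """External flow (m³ h⁻¹) whose steady state sits exactly at ``c_limit``.

    Inverts Css = Co + 10⁶·G/Fext for Fext; used with the 700/1000 ppm
    ceilings to size the ventilation a space needs.
    """
    if g <= 0:
        raise DomainError("generation rate G must be positive")
    if c_limit <= co:
        raise InfeasibleLimitError(
            f"ceiling {c_limit} ppm is not above the outdoor level {co} ppm; "
            "no finite ventilation can achieve it"
        )
    return 1e6 * g / (c_limit - co)


def transient_profile(scenario: CO2Scenario, times: Sequence[float]) -> np.ndarray:
    """Vector of C(t) over ``times`` (h), convenience for plotting/simulation."""
    return np.array([transient_concentration(scenario, float(t)) for t in times])
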