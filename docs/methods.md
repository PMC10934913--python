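# Methods

## Model and assumptions

`ventbox` treats a ventilated space as a single perfectly mixed zone. Four
assumptions define the model's validity envelope:

1. **Balanced flow** — air extracted equals air supplied, so a single
   external flow `Fext` (m³ h⁻¹) characterizes the exchange.
2. **Perfect mixing** — exhaust air carries the room concentration; there
   are no gradients or short-circuiting. In practice this requires the
   sensor to sit centrally, away from people, doors and supply vents.
3. **Constant outdoor concentration** — `Co` does not drift over the
   measurement. Drifting outdoor CO₂ is outside the model.
4. **Exhalation is the only CO₂ source** — no combustion appliances or
   other indoor CO₂ sources or sinks.

Under these, indoor CO₂ obeys `dC/dt = (Fext/V)(Co − C) + 1e6·G(t)/V` with
the closed-form solution implemented in `ventbox.box_model`. For constant
generation the solution is a pure exponential relaxation toward
`Css = Co + 1e6·G/Fext`; the relaxation time constant is `V/Fext` hours, so
a space at 2 ACH needs ~1.5 h (three time constants) to equilibrate while
one at 10 ACH needs ~18 min. For a bounded, time-varying `G`, long-run
concentrations stay inside `[Co + 1e6·Gmin/Q − ε, Co + 1e6·Gmax/Q + ε]`;
the transient allowance ε is an explicit parameter (default 0 ppm) rather
than an implicit fudge.

The ACH estimator inverts the steady state:
`ACHreal = 1e6·G / (V·(Css − Co))`. It is exact when the room has
equilibrated and degrades gracefully otherwise (an under-relaxed `Css`
biases ACH upward). Because the estimate scales as `1/(Css − Co)`, small
indoor/outdoor differences amplify sensor noise; estimates with
`Css − Co` below a configurable threshold (default 25 ppm, roughly ten
times a 2–3 ppm sensor noise floor) carry a `low_confidence` flag instead
of failing — the arithmetic is still valid, as the office case (Δ = 3 ppm,
ACH ≈ 144 h⁻¹) shows, but a ±2 ppm error there moves the estimate by
roughly ±70 %.

## Units

Hours and m³ h⁻¹ throughout the core model. Per-person rates enter in
l s⁻¹ and are converted once at the occupancy boundary
(`×3600 s/h × 0.001 m³/l = ×3.6`). Concentrations: CO₂ in ppm v/v, NO₂ and
VOCs in ppb v/v, particulates in µg m⁻³ — the native units of the guideline
tables; no conversions are applied to the gravimetric equivalents quoted in
regulations.

## Numerical choices

* **Transient evaluation.** Constant `G`: direct closed form.
  Piecewise-constant `G`: exact per-segment closed forms chained across
  segments — no quadrature error. Arbitrary callable `G`: adaptive
  quadrature (relative tolerance 1e-8) on the damped integrand
  `G(s)·e^{−a(t−s)}`, which stays well-scaled even for large `a·t` where
  the naive growing-exponential form overflows.
* **Capacity inversion.** Both constraint families are solved for the
  largest compliant integer head count via an analytic starting guess
  (the closed-form real-valued bound, floored) followed by a local
  up/down scan, so the returned `n` always satisfies the constraint while
  `n+1` violates it regardless of float rounding.
* **Boundary convention.** Comparisons are inclusive (≥ for ACH, ≤ for
  ppm). Steady states within half a display unit (0.005 ppm) of a ceiling
  count as compliant: capacity boundaries frequently land *exactly* on the
  ceiling in exact arithmetic (the gym's 50-person, 700.00-ppm case), and
  without the allowance a rounded ACH input or one float ulp would push
  the answer one person low.
* **Objective-ACH rounding.** The raw `Fb·n·3.6/V` is rounded up to the
  next integer before comparison, with an epsilon guard so raw values
  landing exactly on an integer are not bumped a full unit higher. The
  ceiled value — not the raw one — is what capacity inversion compares
  against the available ACH; this is what makes a 0.584-ACH cinema unable
  to host even one person under the contagion goal (raw 0.0167 ceils
  to 1).
* **Display rounding.** ACH prints to 3 decimals, concentrations and
  generation rates to 2; all comparisons use full precision (plus the
  boundary allowance above).

## Stabilized-window detection

The guidance protocol asks for a 10-minute warm-up and a further 10-minute
recording "once the levels remain relatively constant", without defining
*relatively constant*. `ventbox.sensor_io` renders that as a sliding-window
test: the first window (default 10 min, endpoints inclusive — 11 points at
1-minute cadence) starting after warm-up whose fitted linear slope, as a
fraction of the window mean, is at most 0.1 %/min. The criterion is
scale-free, so the same default serves analytes with different units and
magnitudes; it is configurable, and `slope_tol=inf` forces the first
window when a caller wants the protocol's fixed timing regardless of
drift. Cadence gaps up to 2 minutes are tolerated as dropouts; longer gaps
split the trace. A CO₂ meter that already reports a 10-minute average can
bypass this module entirely.

## Synthetic data: what it does and does not emulate

`ventbox.synthetic` generates minute-cadence traces as the box-model
closed-form concentration plus independent zero-mean Gaussian noise
(default 2 ppm for CO₂, configurable per analyte), seeded by a single
integer. This captures the features the pipeline is sensitive to — the
first-order approach to steady state, the steady-state level, stationary
sensor noise — and deliberately omits others: drift and autocorrelation in
sensor error, outdoor-concentration variation, imperfect mixing, and
occupancy churn beyond piecewise-constant generation. Passing the
parameter-recovery tests therefore demonstrates correctness of the
estimation chain under the model's own assumptions, not robustness to
violations of them.

Recovery studies start the simulated episode already equilibrated
(`cinit = css`), mirroring the field protocol of carrying a sensor into an
occupied, already-settled space; the warm-up then covers sensor
stabilization rather than room dynamics. Starting from `cinit = co`
instead exercises the transient path (used in the dynamics tests): the
slope test correctly rejects windows taken before equilibration, and for
slowly ventilated rooms a 90-minute trace then yields a few-percent upward
ACH bias — the documented cost of measuring before steady state.

At 2-ppm noise and 100 seeds the median ACH recovery error is below 5 %
for every case-study scenario with a CO₂ excess of at least 100 ppm, and
an order of magnitude worse for the office's 3-ppm excess — the regression
that motivates the low-confidence flag.

## Reference tables

Guideline values ship as CSV/JSON under `ventbox/tables/` and are pinned
by tests: per-activity exhalation rates (the aggregate "average person"
rows are authoritative; per-age rows are documentation and are never
re-aggregated — notably the male at-rest aggregate, 0.0042 l s⁻¹, is not
the mean of the per-age male values and is used as printed), per-class
respiration flows, design-ACH intervals per space type, the 700/1000 ppm
CO₂ ceilings, and indoor/outdoor pollutant limits. Users may load an
override directory with the same schema. The packaged case-study fixtures
carry their study's per-space design intervals directly (the coffee shop
uses 10–12 h⁻¹, which has no row in the generic design table).

## Known limitations

* Single-zone only: no multi-zone coupling, no CFD, no
  infiltration/exfiltration asymmetry.
* Exhalation rates reflect a European/American reference population;
  correction factors for other populations are not included.
* The air-quality flag grid is purely mechanical (strict limit
  exceedance); it attributes no sources and ranks no remedies. One cell of
  the published summary it reproduces was marked on grounds other than a
  limit exceedance (office outdoor NO₂ at 82.75 ppb vs a 106 ppb limit);
  the mechanical grid intentionally leaves that cell unmarked.
* A vacant space (n = 0) yields no ACH estimate and is reported as
  not-assessable rather than adequate.
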