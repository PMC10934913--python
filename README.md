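# ventbox

Ventilation assessment and indoor air-quality screening for occupied public
spaces, from low-cost rapid-response sensor measurements.

Building managers rarely know the *actual* air-exchange their ventilation
strategy delivers — only what the system was designed for. `ventbox`
estimates the real air changes per hour (ACH) of a space from nothing more
than its air volume, its occupancy and activity, and stabilized indoor and
outdoor CO₂ readings, then compares the result against health guidelines,
inverts the model for the maximum compliant occupancy, and screens other
pollutants (PM₂.₅, PM₁₀, VOCs, NO₂) against regulatory limits.

## The model

The space is a single well-mixed zone of volume $V$ (m³) ventilated by an
external-air flow $F_{ext}$ (m³ h⁻¹), with outdoor CO₂ concentration $C_o$
(ppm v/v) and an indoor CO₂ generation rate $G$ (m³ h⁻¹) from occupants'
exhalation. Mass balance gives

$$\frac{dC}{dt} = \frac{F_{ext}}{V}(C_o - C) + \frac{10^6\,G(t)}{V},$$

which relaxes exponentially to the steady state
$C_{ss} = C_o + 10^6 G/F_{ext}$. Writing $F_{ext} = \mathrm{ACH}\cdot V$
and inverting:

$$\mathrm{ACH}_{real} = \frac{10^6\,G_{CO_2}}{V\,(C_{ss} - C_o)},
\qquad G_{CO_2} = n \cdot \mathrm{Exh}_{rate} \cdot 3600 \cdot 0.001,$$

with $n$ occupants exhaling $\mathrm{Exh}_{rate}$ l s⁻¹ each (tabulated by
activity: 0.00390 at rest, 0.00675 walking, 0.01352 exercising). The
guideline side computes the objective
$\mathrm{ACH}_{obj} = F_b\,n\,3.6/V$ (rounded up to the next integer),
where $F_b$ is the recommended per-person respiration flow (15/14/10 l s⁻¹
by space class for contagion prevention, 5 l s⁻¹ for minimum ventilation).
Ventilation is adequate for a goal when
$\mathrm{ACH}_{real} \ge \lceil\mathrm{ACH}_{obj}\rceil$ **and** $C_{ss}$
stays at or below the goal's ceiling (700 ppm anti-contagion, 1000 ppm air
quality). The same relations, solved for $n$, give the maximum occupancy a
space supports at its measured or design ACH.

Air quality is screened per analyte by comparing stabilized indoor and
outdoor means with regulatory limits and by the indoor/outdoor ratio
$I/O = C_i/C_o$; a ratio above 1 points to indoor emission sources.

## Worked example

A 77.4 m³ study room holding 2 people at rest measured 628 ppm CO₂ indoors
against 447 ppm outdoors:

```bash
$ ventbox ach --volume 77.4 --occupants 2 --css 628 --co 447
G_CO2   = 0.028080 m3/h
ACHreal = 2.004 1/h  (Fext = 155.14 m3/h)
```

The two occupants generate 0.0281 m³ of CO₂ per hour; sustaining a 181-ppm
excess over outdoor air requires 2.004 air changes per hour — above the
ceiled anti-contagion objective of 2 for this occupancy, so the current
ventilation is adequate *for two people*. How many people could it hold?

```bash
$ ventbox capacity --volume 77.4 --co 447 --exh-rate 0.0039 \
      --ach 2.004 --space-class library_office
space,goal,constraint,n_max,g_co2_m3h,css_ppm,binding
space,anti_covid,ach_ceiling,3,0.04,718.55,False
space,anti_covid,concentration_limit,2,0.03,628.03,True
space,minimum_ventilation,ach_ceiling,8,0.11,1171.13,False
space,minimum_ventilation,concentration_limit,6,0.08,990.1,True
```

The 700-ppm ceiling binds before the air-change requirement: 2 people for
the anti-contagion goal, 6 if only air quality matters. A same-volume space
with, say, a measured 548-vs-545 ppm pair would report ACH with a warning —
a 3-ppm excess is inside sensor noise, and the estimate is flagged
low-confidence.

The seven packaged case-study spaces (two study rooms, coffee shop,
restaurant, cinema, gym, office) run end to end with
`ventbox assess --fixtures`, which flags the cinema as the one space whose
real ACH (0.584 h⁻¹) misses even the minimum-ventilation objective.

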