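# wellflux

Serial multiwell-to-microfluidic fluid delivery, as software.

A low-cost robotic platform can deliver dozens of fluids from a standard
multiwell plate into a microfluidic device through a single inlet tube: a
servo raises the tube, steppers move the plate to the next well, the tube is
lowered back in, and a hydrostatic backpressure reservoir keeps the open tube
tip bubble-free while it is up. One such system automates odor dose–response
measurements and optogenetic chemical screens on *C. elegans* neurons, and
multi-step cell staining protocols — all from a 96-well plate.

`wellflux` implements that workflow end to end with no hardware attached:

- **plates** — plate geometry and well naming, snake/typewriter traversal
  orders, alternating and screen plate maps, serial dilutions, and the
  serial command codec (`A1-;A2-`, `0` to home).
- **scheduler** — compiles per-well protocols (fill delay, flow or paused
  incubation, stimulus pulses, camera acquisitions) into a timed event
  stream with the full valve/servo transition choreography, validated
  against valve-safety and per-well volume budgets.
- **fluidics** — the digital twin: tube volumes, Taylor–Aris breakthrough
  of a fluid switch, residual carryover with wash steps, and
  bubble/droplet classification of the backpressure balance.
- **synthetic** — seed-deterministic generators for every fixture: dye
  carryover plate scans, GCaMP ΔF/F0 trace sets with Hill-type
  concentration dependence, pulse-wise adaptation and optogenetic
  suppression, and staining intensity time-courses.
- **analysis** — the quantification pipelines: carryover %, ΔF/F0 and
  peak extraction, four-parameter Hill (EC50) fitting, paired one-sample
  t screen statistics with Bonferroni correction, staining curve
  summaries.
- **cli** — the `wellflux` command (`plate` / `protocol` / `simulate` /
  `analyze` subcommands).

## The models at the core

**Fluid switching.** Each new fluid must flush the previous one from the
inlet tube (length $L$, radius $a$, mean velocity $U = Q/\pi a^2$). The
cross-section-averaged concentration of the new fluid at the tube exit is

$$c(t) = \tfrac12\,\mathrm{erfc}\!\left(\frac{L - Ut}{2\sqrt{Kt}}\right),
\qquad K = D + \frac{a^2U^2}{48\,D},$$

the advection–dispersion solution with the Taylor–Aris effective
dispersivity. At exactly one tube volume of flow, $c = 1/2$; at the default
geometry (22 cm × 250 µm, ≈11 µL, 2 µL/s) the 99.9% point falls at ≈4.5
tube volumes — the familiar rule that about five tube volumes (≈30 s)
complete a switch.

**Carryover.** The measured residual contamination per switch exceeds the
ideal dispersion tail, so carryover is a separately calibrated residual
fraction $f$ (default 0.32%), reduced geometrically by wash steps
($f \cdot r^{\text{washes}}$, $r = 0.1$). Analysis follows the
baseline-subtract-and-ratio convention:
$100\,(I_\text{water} - I_\text{base}) / (I_\text{dye} - I_\text{base})$
per dye→water switch.

**Dose–response.** Peak ΔF/F0 versus concentration follows a Hill curve
$r_\text{max}\, c^h / (c^h + \mathrm{EC50}^h)$, fitted by least squares on
a log10 concentration scale with a fitted bottom (noise-floor) term.

**Screen statistics.** Per animal, each solvent peak is paired with the
immediately prior buffer-control peak; the differences are tested against
zero with a one-sample t ($t = \bar d \sqrt{n} / s_d$), Bonferroni-corrected
over the 28 solvent×concentration comparisons at α = 0.001.

## Worked example

Simulate the alternating fluorescein/water 96-well scan and quantify
carryover, then ask the dispersion model how long a switch takes:

```
$ wellflux simulate carryover --seed 0 -o demo
96 wells scanned -> demo/scan.csv
$ wellflux analyze carryover demo/scan.csv --map demo/map.csv \
    --order demo/order.txt -o demo/table.csv
48 switches: carryover 0.315% ± 0.051% SD -> demo/table.csv
$ wellflux simulate switch -o demo
99.9% completeness at 4.49 tube volumes -> demo/breakthrough.csv
```

The first run scans the plate in a snake pattern (fluorescein and water
alternating) and records 150 frames per well; the analysis averages the
first/middle/last frames per well, subtracts the camera baseline, and
expresses each water well as a percentage of its preceding dye well — here
0.315% mean carryover over the 48 switches, with the scan-to-scan spread
(±0.051% SD) coming from the per-switch residual variability and camera
noise. The breakthrough run reports that 99.9% fluid replacement needs 4.49
tube volumes of flow, which at 2 µL/s through the ≈11 µL tube is ~24 s —
the reason a 30 s fill delay is programmed between wells.

The same pattern drives the other workflows, e.g.
`wellflux simulate doseresponse --seed 0 -o demo` followed by
`wellflux analyze doseresponse demo/traces.csv --neuron AWA -o demo/fit.json`
prints the fitted EC50 with its 95% CI, and `wellflux protocol staining`
plus `wellflux protocol compile` emits the ten-step, 85.5-minute staining
timeline and its serial command stream.

In Python the same objects are available directly:

```python
import wellflux as wf

tube, flow = wf.TubeSpec(), wf.FlowSpec()
wf.tube_volume(tube)                         # 10.80 µL
wf.volumes_to_completeness(tube, flow)       # 4.486 tube volumes to 99.9%
wf.well_flow_budget(2000, flow)              # 16.7 min of flow per 2 mL well
```

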