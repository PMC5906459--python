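# Methods

This note documents the models, conventions, defaults, and limitations of
`wellflux` — what each component assumes, which knobs matter, and what the
synthetic-data closed loops do and do not demonstrate.

## Plate addressing and the command grammar

Wells are addressed by uppercase row letter (A–P) and 1-based column,
canonical string form `A1`; storage is row-major. Named formats carry the
supported geometries: 6-well (16.8 mL), 24-well (10 mL), 48-well (5 mL),
`96-medium` (600 µL), `96-deep` (2 mL), `384` (225 µL); named formats must
have a well depth in the 5–30 mm range the servo stroke covers. Custom
row×column plates are allowed for testing.

The serial command grammar is `[row][column][+|-]` — raise the tube, move
the plate, leave the tube raised (`+`) or lower it (`-`) — with `0` homing
the system and semicolons chaining commands. The parser is
case-insensitive and accepts multi-digit columns (up to 24 for 384-well
plates); the encoder always emits canonical uppercase. Parsing and encoding
are exact inverses, property-tested over random token lists.

Two traversal orders are provided: `snake`, which reverses column direction
on every row to minimise plate travel, and `typewriter`, which restarts
each row at column 1. The snake starts left-to-right on row A by default;
both orientations are supported (`reverse_first_row`) since either is a
valid serpentine.

### The carryover scan order

The default carryover scenario alternates fluorescein and water along the
snake order **with fluorescein first**. This is the only arrangement of a
full 96-well alternating plate that yields 48 dye→water switches (water
first yields 47), matching the experiment's 48 measured switches. Because
A1 then holds dye, the camera baseline cannot be read from well A1; the
generator instead emits a pre-run buffer acquisition (physically, frames
recorded while the channel still holds plain buffer, before the first
well's fluid arrives), and the analysis averages that whole
acquisition (baseline error is common-mode across every well's percentage,
so it is estimated far more tightly than per-well intensities) and also
accepts a designated baseline well for plates where A1 is a water well.

## Transition choreography and the scheduler

A well-to-well transition is the fixed seven-phase sequence: close outlet →
open backpressure → raise tube → move plate → lower tube → close
backpressure → open outlet. Default phase durations are
0.2/0.1/0.5/0.4/0.5/0.1/0.2 s (2.0 s total for a one-well move); only the
total is constrained by the hardware's ~2 s figure, so each phase is
configurable. Plate moves take `t_move_per_well` × Chebyshev well distance,
since the x and y steppers run concurrently.

The central safety invariant — while the tube is raised, the outlet valve is
closed, so no forward flow can pull an air bubble into the open tube tip —
holds by construction in compiled timelines and is checked by
`validate_timeline` on any timeline, along with non-decreasing timestamps
and per-well volume budgets.

Volume accounting: flow runs during every fill delay, and during the
exposure only if the step is not paused. Steps of ≥30 min default to paused
flow (both valves closed after the fill delay), because a 2 mL well
supports only ≈17 min of continuous flow at 2 µL/s; the threshold and flag
are overridable per step. Timestamps are float seconds from protocol start.

Stimulus pulses are scheduled at offsets after fill-delay completion;
camera acquisitions start a configurable `pre_stim_s` before each pulse
(2.5 s for the screen's 15 s window with light from 2.5–7.5 s; 5 s for the
dose–response's 30 s window around each 10 s odor pulse).

The canonical staining protocol is the ten-step sequence (PBS 30 s, PFA
10 min, PBS 30 s, Triton X-100 10 min, PBS 30 s, BSA 30 min, phalloidin
30 min, PBS 30 s, Hoechst 3 min, PBS 30 s): 85.5 min of summed exposure;
the compiler reports the exact sum rather than a rounded figure.

## Fluidic twin

**Breakthrough.** The switch front is modelled with the classical
Taylor–Aris effective dispersivity $K = D + a^2U^2/(48D)$ in the 1-D
advection–dispersion solution $c(t) = \frac12\,\mathrm{erfc}((L-Ut)/2\sqrt{Kt})$.
Defaults: 22 cm × 250 µm tube, 2 µL/s, $D = 4.25\times10^{-10}$ m²/s
(fluorescein in water, literature value). The Taylor regime requires the
transit time to exceed the radial equilibration time $a^2/(3.8^2 D)$ by a
wide margin; at the defaults the ratio is only ≈2.1, so the model is
applied at the edge of its validity and a warning is logged. The "switch
complete" threshold defaults to 0.999; at the defaults that point falls at
4.49 tube volumes, consistent with the five-tube-volume working rule.

**Carryover.** Deliberately *not* derived from the dispersion tail: the
measured residual (≈0.32% after a 30 s fill) exceeds what the ideal model
predicts (surface adsorption and dead volume are plausible causes, not
resolved here). Carryover is a calibrated residual fraction per switch
(default 0.0032 with switch-to-switch SD 4.7e-4, matching the reported
0.32% ± 0.047%), and wash wells reduce it by a factor `wash_reduction`
(default 0.1, one order of magnitude per wash) — a geometric model, since
per-wash values are a calibration rather than a first-principles quantity.

**Backpressure.** The hydrostatic pressure ρgh of the elevated reservoir is
compared with a capillary setpoint ± tolerance (defaults 200 ± 40 Pa, i.e.
≈2 cm of water — a calibration parameter; the contact angle of wetted
Teflon is too ill-characterised to compute it). Below the window the raised
tube risks ingesting a bubble, above it a droplet is expelled.

## Synthetic data

All generators take an integer seed and are bit-reproducible. The core
closed-loop property: with noise terms set to zero, the matching analysis
recovers the generating parameters exactly (residual fraction, EC50, Hill
slope up to a common smoothing scale factor, suppression structure).

- **Carryover scan**: dye wells at `dye_intensity` (default 1100 counts),
  water-after-dye wells at baseline + residual·span with the residual drawn
  per switch, other water wells at baseline (100 counts); Gaussian
  per-frame noise (SD 0.5 counts), 150 frames/well (15 s at 10 fps). Tiny
  64×64 image stacks with a bright 25×25 region can be rendered for
  image-path tests; scalar tables are the primary fixture.
- **Dose–response traces**: difference-of-exponentials pulse kernel (rise
  1 s, decay 5 s, sampled at 10 fps) scaled by a Hill amplitude. AWA preset:
  EC50 1.15 µM, slope 1.5, no adaptation. ASH preset: EC50 1.15 mM, slope 3
  (threshold-like), amplitude halving per pulse (adaptation 0.5). The EC50s
  follow the measured values; slopes and adaptation rate are calibration
  stand-ins, since the source curves are not tabulated — accordingly the
  tests assert parameter *recovery*, not curve shapes point by point. An
  optional `coupling` coefficient suppresses AWA amplitude in proportion to
  the normalised ASH response (the observed negative correlation at high
  odor concentrations); it is off by default. Animal-to-animal variability
  is a multiplicative lognormal factor (SD 0.2); trace noise is additive
  Gaussian on ΔF/F0 (SD 0.05). Raw fluorescence is emitted as
  F0·(1 + ΔF/F0) with F0 = 100.
- **Screen traces**: one stimulated trace per animal per well; evoked peak
  = baseline_peak × suppression(fluid) × animal factor. The fourteen-solvent
  default panel and its suppression factors are stand-ins chosen so that
  isopropanol, methanol and acetonitrile suppress at both 1% and 5% and
  ethanol at 5% only, with the remaining ten solvents inert — the
  qualitative structure the screen should recover.
- **Staining time-course**: background until 15 min (default onset lag)
  after phalloidin exposure begins, then a saturating exponential rise
  (τ = 5 min) to plateau; 90 samples at one frame per minute, the first
  frame one minute into the protocol.

What passing these loops shows: the pipelines implement their stated
arithmetic and statistics correctly, at realistic noise levels and sample
sizes. What they do not show: robustness to real-imaging pathologies
(motion, photobleaching, segmentation error, non-Gaussian noise), which the
generators deliberately do not model.

## Analysis conventions

- **Well intensity**: mean of the first, middle, and last frames
  (noise reduction without processing full stacks), over a 25×25 ROI for
  image stacks.
- **ΔF/F0**: F0 is the mean of the final 2 s before stimulus onset; the
  peak is the maximum over the stimulus span + 5 s. Both windows are
  configurable. Raw traces are smoothed with a trailing (causal) 0.5 s
  boxcar before normalisation: the maximum of an unsmoothed noisy trace
  carries a positive noise floor (the expected maximum of ~150 noise
  samples) that flattens dose–response curves; a causal window is used so
  no post-stimulus signal leaks into F0.
- **Hill fit**: four-parameter logistic (bottom, span, log10 EC50, slope).
  The bottom term absorbs the residual peak-statistic floor; `r_max`
  reports the span above it. Initialisation: EC50 at the first
  concentration whose mean peak exceeds half the maximum, slope 1; EC50 is
  bounded within the tested span ±1 decade and flagged if it lands outside
  the tested span. Buffer (c = 0) enters the fit as zero Hill response.
  95% intervals come from the asymptotic covariance. A degree-3 polynomial
  of mean peak vs log10 concentration (buffer excluded — log of 0) is
  provided for display. Per-concentration summaries are emitted at both n
  conventions (per-animal, n = 18; per-trace, n = 72), labelled by n.
  Non-convergence raises with diagnostics; there is no silent fallback.
- **Screen**: the t statistic is computed from its definition
  ($\bar d\sqrt{n}/s_d$, two-sided p from the t distribution), not
  delegated; zero-variance differences are reported as degenerate rather
  than significant. Bonferroni m defaults to the number of
  solvent×concentration comparisons (28). A one-way repeated-measures F
  across wells is available as a secondary report. Type-I control under
  the null is regression-tested over 200 reduced-size simulated screens.
- **Staining curve**: the series is segmented by step windows (transition
  start to exposure end, a partition of the timeline); the label onset is
  the first sampled minute exceeding the pre-phalloidin background mean by
  3 background SDs, reported relative to phalloidin exposure start. The
  series must cover the start of every step (a 90-min record of the
  90.8-min timeline qualifies; each step contains at least one sample).

## Problem sizes

The test suite and acceptance script use the experiments' native sizes —
96-well scans, 18 animals × 8 concentrations × 4 pulses × 2 neuron types
(1,152 traces), 20 animals × 57 wells (1,140 peaks), 90-minute staining
records — since all are comfortably desk-scale. The null-calibration test
alone uses a reduced screen (4 solvents, 6 animals) × 200 replicates to
keep its runtime proportionate.

## Known limitations

- The gap between the ideal Taylor–Aris tail and the measured 0.32%
  residual is represented, not explained; the twin makes no attempt to
  model adsorption or dead volume.
- The dispersion model is used in a marginal regime (see above); treat
  sub-1% tails from the closed form as qualitative.
- No two-phase (air slug) dynamics, no temperature dependence of viscosity
  or diffusivity, no CFD of the device interior.
- Timelines are compiled and validated, never executed: there is no serial
  transport, motor calibration, or camera I/O.
- The screen's solvent panel and suppression magnitudes are synthetic
  calibration choices; only the identity of the active set and the paired
  test behaviour are meaningful test surfaces.
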