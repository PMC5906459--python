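"""Synthetic fixtures for the quantification pipelines.

Every experiment the system automates has a generator here with explicit
statistical structure and a fixed seed: the alternating dye/water carryover
scan, GCaMP ΔF/F0 trace sets for the odor dose–response and the optogenetic
solvent screen, and the staining intensity time-course. Noiseless settings
make the matching analysis recover the generating parameters exactly, which
is the backbone of the test suite.

The generators emulate per-well/per-frame intensities and per-animal
fluorescence traces — not worm bodies, motion artifacts, or photobleaching.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .fluidics import CarryoverModel
from .plates import (FluidLabel, PlateMap, PlateSpec, WellId, alternating_map,
                     screen_map, snake_order)
from .scheduler import Timeline


class SyntheticError(ValueError):
    pass


# ---------------------------------------------------------------------------
# TraceSet container
# ---------------------------------------------------------------------------

@dataclass
class TraceSet:
    """Long-format fluorescence traces: one row per sample, grouped by the id
    columns present (subset of neuron/animal/well/solvent/conc/pulse), with
    ``time_s``/``value`` samples and per-trace stimulus annotations
    (``stim_onset_s``, ``stim_duration_s``)."""

    frame: pd.DataFrame
    fps: float

    GROUP_COLS = ("neuron", "animal", "well", "solvent", "conc", "pulse")

    def group_cols(self) -> list[str]:
        return [c for c in self.GROUP_COLS if c in self.frame.columns]

    def n_traces(self) -> int:
        return self.frame.groupby(self.group_cols(), sort=False).ngroups

    def traces(self):
        """Iterate (key dict, per-trace DataFrame sorted by time)."""
        cols = self.group_cols()
        for key, df in self.frame.groupby(cols, sort=False):
            yield dict(zip(cols, key if isinstance(key, tuple) else (key,))), \
                df.sort_values("time_s")

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, fps: Optional[float] = None) -> "TraceSet":
        df = pd.read_csv(path)
        if fps is None:
            t = np.sort(df["time_s"].unique())
            if len(t) < 2:
                raise SyntheticError("cannot infer fps from a single time point")
            fps = 1.0 / float(np.min(np.diff(t)))
        return cls(df, fps)


def _pulse_kernel(t: np.ndarray, rise_tau: float, decay_tau: float) -> np.ndarray:
    """Difference-of-exponentials response kernel, normalised to peak 1."""
    if decay_tau <= rise_tau:
        raise SyntheticError("decay time constant must exceed rise time constant")
    t_peak = rise_tau * decay_tau / (decay_tau - rise_tau) * math.log(decay_tau / rise_tau)
    norm = math.exp(-t_peak / decay_tau) - math.exp(-t_peak / rise_tau)
    k = np.where(t >= 0, np.exp(-np.maximum(t, 0) / decay_tau)
                 - np.exp(-np.maximum(t, 0) / rise_tau), 0.0)
    return k / norm


def _hill(c: float, r_max: float, ec50: float, hill: float) -> float:
    if c <= 0:
        return 0.0
    return r_max * c ** hill / (c ** hill + ec50 ** hill)


# ---------------------------------------------------------------------------
# Carryover scan
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CarryoverPreset:
    """Generator settings for the alternating dye/water plate scan.

    Intensities are camera counts: ``dye_intensity`` for 5 µg/mL fluorescein,
    ``baseline_intensity`` the camera/water background. Each well is recorded
    for ``frames_per_well`` frames (15 s at 10 fps) with per-frame Gaussian
    noise; image rendering places a bright ``roi``-sized region at the channel
    convergence.
    """

    model: CarryoverModel = field(default_factory=CarryoverModel)
    dye_intensity: float = 1100.0
    baseline_intensity: float = 100.0
    noise_sd: float = 0.5
    frames_per_well: int = 150
    roi: tuple[int, int] = (25, 25)

    def __post_init__(self) -> None:
        if not self.dye_intensity > self.baseline_intensity >= 0:
            raise SyntheticError("need dye_intensity > baseline_intensity >= 0")
        if self.noise_sd < 0:
            raise SyntheticError("noise_sd must be >= 0")


DYE_NAME = "fluorescein"
WATER_NAME = "water"


def carryover_scenario(plate: Optional[PlateSpec] = None) -> tuple[PlateMap, list[WellId]]:
    """The default carryover test plate: a 96-well medium plate scanned in a
    snake pattern with fluorescein and water alternating, dye first, giving
    48 dye→water switches."""
    plate = plate or PlateSpec.from_format("96-medium")
    order = snake_order(plate, "snake")
    dye = FluidLabel(DYE_NAME, concentration=5.0, conc_units="µg/mL",
                     volume_ul=plate.well_capacity_ul)
    water = FluidLabel(WATER_NAME, volume_ul=plate.well_capacity_ul)
    return alternating_map(plate, dye, water, order), order


@dataclass
class CarryoverScan:
    """Per-well frame intensities from a scan, plus a pre-run buffer
    acquisition (``baseline_frames``) recorded before the first well —
    physically, the camera baseline while the channel still holds plain
    buffer."""

    frames: dict[str, np.ndarray]  # well -> (n_frames,) intensities
    baseline_frames: np.ndarray
    plate_map: PlateMap
    order: list[WellId]
    preset: CarryoverPreset

    def to_csv(self, path: str | Path) -> None:
        rows = [("baseline", i, v) for i, v in enumerate(self.baseline_frames)]
        for well in self.order:
            for i, v in enumerate(self.frames[str(well)]):
                rows.append((str(well), i, v))
        pd.DataFrame(rows, columns=["well", "frame", "value"]).to_csv(path, index=False)

    @staticmethod
    def frames_from_csv(path: str | Path) -> tuple[dict[str, np.ndarray], np.ndarray]:
        df = pd.read_csv(path)
        frames: dict[str, np.ndarray] = {}
        for well, g in df.groupby("well", sort=False):
            frames[str(well)] = g.sort_values("frame")["value"].to_numpy(float)
        baseline = frames.pop("baseline", np.array([]))
        return frames, baseline

    def to_tiff(self, path: str | Path, well: str,
                shape: tuple[int, int] = (64, 64), seed: int = 0) -> None:
        """Write one well's rendered image stack as a multi-frame TIFF."""
        import tifffile

        tifffile.imwrite(path, self.render_frames(well, shape, seed)
                         .astype(np.float32))

    def render_frames(self, well: str, shape: tuple[int, int] = (64, 64),
                      seed: int = 0) -> np.ndarray:
        """Tiny image stack for one well: dark background with a bright ROI
        at the channel convergence (for image-path tests)."""
        rng = np.random.default_rng(seed)
        vals = self.frames[well]
        h, w = self.preset.roi
        r0 = (shape[0] - h) // 2
        c0 = (shape[1] - w) // 2
        stack = np.zeros((len(vals), *shape), dtype=float)
        stack += rng.normal(0.0, self.preset.noise_sd, size=stack.shape)
        for i, v in enumerate(vals):
            stack[i, r0:r0 + h, c0:c0 + w] += v
        return stack


def gen_carryover_scan(plate_map: PlateMap, order: Sequence[WellId],
                       preset: CarryoverPreset, seed: int = 0) -> CarryoverScan:
    """Simulate the alternating-plate scan.

    Dye wells read ``dye_intensity``; a water well immediately following a dye
    well reads baseline plus a residual fraction of the dye span, the residual
    drawn per switch around the carryover model's mean; other water wells read
    baseline. Per-frame Gaussian noise is added throughout.
    """
    rng = np.random.default_rng(seed)
    m = preset.model
    span = preset.dye_intensity - preset.baseline_intensity
    frames: dict[str, np.ndarray] = {}
    baseline_frames = preset.baseline_intensity + rng.normal(
        0.0, preset.noise_sd, size=preset.frames_per_well)
    prev: Optional[str] = None
    for well in order:
        name = plate_map[well].name
        if name == DYE_NAME:
            level = preset.dye_intensity
        elif prev == DYE_NAME:
            residual = max(0.0, rng.normal(m.residual_fraction, m.residual_sd))
            level = preset.baseline_intensity + residual * span
        else:
            level = preset.baseline_intensity
        frames[str(well)] = level + rng.normal(0.0, preset.noise_sd,
                                               size=preset.frames_per_well)
        prev = name
    return CarryoverScan(frames, baseline_frames, plate_map, list(order), preset)


# ---------------------------------------------------------------------------
# Dose–response trace sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NeuronPreset:
    """Response model for one GCaMP-expressing sensory neuron class.

    Peak ΔF/F0 follows a Hill curve in stimulus concentration (``r_max``,
    ``ec50`` molar, ``hill``); successive pulses scale by ``adaptation`` per
    pulse (1 = no adaptation); ``coupling`` optionally suppresses this
    neuron's peak in proportion to the partner neuron's normalised response
    (cross-inhibition at high concentrations). Trace shape is a
    difference-of-exponentials with the given rise/decay constants.
    """

    name: str
    ec50: float
    hill: float
    r_max: float = 1.0
    adaptation: float = 1.0
    coupling: Optional[float] = None
    noise_sd: float = 0.05
    animal_sd: float = 0.2
    rise_tau: float = 1.0
    decay_tau: float = 5.0

    def __post_init__(self) -> None:
        if self.r_max <= 0 or self.ec50 <= 0 or self.hill <= 0:
            raise SyntheticError("r_max, ec50 and hill must be positive")
        if not (0.0 < self.adaptation <= 1.0):
            raise SyntheticError("adaptation must be in (0, 1]")
        if self.noise_sd < 0 or self.animal_sd < 0:
            raise SyntheticError("noise/animal sd must be >= 0")

    @classmethod
    def awa(cls, **overrides) -> "NeuronPreset":
        """AWA: low-threshold diacetyl attraction, consistent across pulses
        (EC50 1.15 µM)."""
        return replace(cls("AWA", ec50=1.15e-6, hill=1.5), **overrides) if overrides \
            else cls("AWA", ec50=1.15e-6, hill=1.5)

    @classmethod
    def ash(cls, **overrides) -> "NeuronPreset":
        """ASH: high-threshold aversion (EC50 ≈ 1.15 mM), adapting rapidly
        across repeated pulses."""
        base = cls("ASH", ec50=1.15e-3, hill=3.0, adaptation=0.5)
        return replace(base, **overrides) if overrides else base


#: Seven ten-fold diacetyl dilutions, 11.5 mM down to 11.5 nM (molar).
DEFAULT_DILUTIONS: tuple[float, ...] = tuple(11.5e-3 / 10 ** k for k in range(6, -1, -1))


def gen_dose_response(awa: Optional[NeuronPreset] = None,
                      ash: Optional[NeuronPreset] = None,
                      n_animals: int = 18,
                      dilutions: Sequence[float] = DEFAULT_DILUTIONS,
                      pulses: int = 4, seed: int = 0,
                      fps: float = 10.0, acquisition_s: float = 30.0,
                      stim_onset_s: float = 5.0, stim_duration_s: float = 10.0,
                      f0: float = 100.0) -> TraceSet:
    """Per-animal GCaMP traces for the odor dose–response experiment.

    Buffer plus each dilution in increasing order (wells A1, A2, ...), four
    10 s pulses once per minute per concentration, 30 s of recording at
    10 fps around each pulse. With 18 animals and 4 pulses there are 72
    traces per concentration per neuron type. Raw fluorescence is
    ``f0·(1 + ΔF/F0)``.
    """
    if n_animals < 1:
        raise SyntheticError("need at least one animal")
    awa = awa or NeuronPreset.awa()
    ash = ash or NeuronPreset.ash()
    rng = np.random.default_rng(seed)
    concs = [0.0] + sorted(dilutions)
    n_samp = int(round(acquisition_s * fps))
    t = np.arange(n_samp) / fps
    kern = {p.name: _pulse_kernel(t - stim_onset_s, p.rise_tau, p.decay_tau)
            for p in (awa, ash)}
    rows = []
    for preset in (awa, ash):
        partner = ash if preset.name == awa.name else awa
        animal_factors = np.exp(rng.normal(0.0, preset.animal_sd, size=n_animals))
        for a in range(n_animals):
            for ci, c in enumerate(concs):
                well = str(WellId("A", ci + 1))
                amp0 = _hill(c, preset.r_max, preset.ec50, preset.hill)
                if preset.coupling is not None:
                    partner_norm = _hill(c, 1.0, partner.ec50, partner.hill)
                    amp0 *= max(0.0, 1.0 - preset.coupling * partner_norm)
                for pulse in range(1, pulses + 1):
                    amp = amp0 * preset.adaptation ** (pulse - 1) * animal_factors[a]
                    dff = amp * kern[preset.name]
                    if preset.noise_sd > 0:
                        dff = dff + rng.normal(0.0, preset.noise_sd, size=n_samp)
                    value = f0 * (1.0 + dff)
                    rows.append(pd.DataFrame({
                        "neuron": preset.name, "animal": a, "well": well,
                        "conc": c, "pulse": pulse, "time_s": t, "value": value,
                        "stim_onset_s": stim_onset_s,
                        "stim_duration_s": stim_duration_s,
                    }))
    return TraceSet(pd.concat(rows, ignore_index=True), fps)


# ---------------------------------------------------------------------------
# Solvent screen trace sets
# ---------------------------------------------------------------------------

#: Default panel of fourteen solvents/carriers screened at 1% and 5%.
DEFAULT_SOLVENTS: tuple[str, ...] = (
    "DMSO", "ethanol", "methanol", "isopropanol", "acetonitrile", "acetone",
    "glycerol", "dimethylformamide", "ethylene glycol", "PEG-400",
    "Tween-20", "Triton X-100", "1-butanol", "propylene glycol",
)

CONTROL_NAME = "buffer"


def _default_suppression() -> dict[tuple[str, float], float]:
    s: dict[tuple[str, float], float] = {}
    for name in DEFAULT_SOLVENTS:
        for conc in (1.0, 5.0):
            s[(name, conc)] = 1.0
    s.update({
        ("isopropanol", 1.0): 0.40, ("isopropanol", 5.0): 0.30,
        ("methanol", 1.0): 0.50, ("methanol", 5.0): 0.35,
        ("acetonitrile", 1.0): 0.45, ("acetonitrile", 5.0): 0.30,
        ("ethanol", 5.0): 0.55,  # ethanol affects responses at 5% only
    })
    return s


@dataclass(frozen=True)
class ScreenPreset:
    """Optogenetic screen generator: evoked peak ΔF/F0 per well equals
    ``baseline_peak`` times the fluid's suppression factor (1 = no effect)
    times a per-animal lognormal factor, plus trace noise. Suppression is
    transient (``recovery``): control wells always respond at baseline."""

    solvents: tuple[str, ...] = DEFAULT_SOLVENTS
    concentrations: tuple[float, ...] = (1.0, 5.0)
    suppression: dict[tuple[str, float], float] = field(default_factory=_default_suppression)
    baseline_peak: float = 1.0
    recovery: bool = True
    animal_sd: float = 0.2
    noise_sd: float = 0.05
    rise_tau: float = 1.0
    decay_tau: float = 5.0

    def __post_init__(self) -> None:
        for k, v in self.suppression.items():
            if not (0.0 <= v <= 1.0):
                raise SyntheticError(f"suppression factor for {k} must be in [0, 1]")

    def factor(self, fluid: FluidLabel) -> float:
        if fluid.name == CONTROL_NAME or fluid.concentration is None:
            return 1.0
        return self.suppression.get((fluid.name, fluid.concentration), 1.0)


def screen_scenario(preset: Optional[ScreenPreset] = None,
                    plate: Optional[PlateSpec] = None) -> tuple[PlateMap, list[WellId]]:
    """Default screen plate: 14 solvents × {1%, 5%} alternating with buffer
    controls — 57 wells delivered sequentially."""
    preset = preset or ScreenPreset()
    plate = plate or PlateSpec.from_format("96-medium")
    vol = plate.well_capacity_ul
    control = FluidLabel(CONTROL_NAME, volume_ul=vol)
    return screen_map(list(preset.solvents), list(preset.concentrations), control,
                      plate, volume_ul=vol)


def gen_screen(preset: Optional[ScreenPreset] = None, n_animals: int = 20,
               plate_map: Optional[PlateMap] = None,
               sequence: Optional[Sequence[WellId]] = None,
               seed: int = 0, fps: float = 10.0, acquisition_s: float = 15.0,
               stim_onset_s: float = 2.5, stim_duration_s: float = 5.0,
               f0: float = 100.0) -> TraceSet:
    """Per-animal traces for the solvent screen: one red-light-stimulated
    trace per animal per well (20 animals × 57 wells → 1,140 peaks)."""
    if n_animals < 1:
        raise SyntheticError("need at least one animal")
    preset = preset or ScreenPreset()
    if plate_map is None or sequence is None:
        plate_map, sequence = screen_scenario(preset)
    rng = np.random.default_rng(seed)
    n_samp = int(round(acquisition_s * fps))
    t = np.arange(n_samp) / fps
    kern = _pulse_kernel(t - stim_onset_s, preset.rise_tau, preset.decay_tau)
    animal_factors = np.exp(rng.normal(0.0, preset.animal_sd, size=n_animals))
    rows = []
    for a in range(n_animals):
        for well in sequence:
            fluid = plate_map[well]
            amp = preset.baseline_peak * preset.factor(fluid) * animal_factors[a]
            dff = amp * kern
            if preset.noise_sd > 0:
                dff = dff + rng.normal(0.0, preset.noise_sd, size=n_samp)
            rows.append(pd.DataFrame({
                "animal": a, "well": str(well), "solvent": fluid.name,
                "conc": 0.0 if fluid.concentration is None else fluid.concentration,
                "pulse": 1, "time_s": t, "value": f0 * (1.0 + dff),
                "stim_onset_s": stim_onset_s, "stim_duration_s": stim_duration_s,
            }))
    return TraceSet(pd.concat(rows, ignore_index=True), fps)


# ---------------------------------------------------------------------------
# Staining time-course
# ---------------------------------------------------------------------------

def gen_staining_timecourse(timeline: Timeline, onset_min: float = 15.0,
                            plateau: float = 1000.0, background: float = 100.0,
                            tau_min: float = 5.0, noise_sd: float = 2.0,
                            n_minutes: int = 90, seed: int = 0) -> pd.DataFrame:
    """Mean image fluorescence sampled once per minute through the staining
    protocol: flat background, then a saturating exponential rise beginning
    ``onset_min`` minutes after phalloidin exposure starts.

    Returns a DataFrame with ``minute`` and ``value`` columns (``n_minutes``
    samples). Raises if the timeline has no phalloidin step.
    """
    phall = [r for r in timeline.step_records if "phalloidin" in r.fluid.lower()]
    if not phall:
        raise SyntheticError("timeline contains no phalloidin step")
    rng = np.random.default_rng(seed)
    t_on = phall[0].t_fill_end / 60.0 + onset_min
    minutes = np.arange(1, n_minutes + 1, dtype=float)  # first frame after 1 min
    rise = np.where(minutes >= t_on,
                    1.0 - np.exp(-(minutes - t_on) / tau_min), 0.0)
    values = background + (plateau - background) * rise
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=n_minutes)
    return pd.DataFrame({"minute": minutes, "value": values})
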