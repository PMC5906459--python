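"""Compile per-well protocols into timed, validated event streams.

A protocol is a list of fluid-exposure steps (well, fill delay, flow or
incubation duration, optional stimulus and acquisition schedules). Each
well-to-well switch expands into the fixed transition choreography:

    close outlet valve → open backpressure valve → raise inlet tube →
    move plate → lower inlet tube → close backpressure valve → open outlet

which takes ~2 s with the default timing profile. While the tube is raised
the outlet valve must be closed — otherwise forward flow would draw an air
bubble into the open tube tip — and :func:`validate_timeline` checks that
invariant on any compiled (or hand-built) timeline, along with per-well
volume budgets.

Long incubation steps (≥30 min by default) pause flow by closing both valves
after the fill delay, so 2 mL wells (≈17 min of continuous flow at 2 µL/s)
are never overdrawn.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

from .fluidics import FlowSpec, FluidicsError, TubeSpec, tube_volume
from .plates import FluidLabel, PlateMap, WellId, command_stream

#: Default threshold above which a step's flow is paused (seconds).
PAUSE_FLOW_THRESHOLD_S = 1800.0


class ProtocolError(ValueError):
    """Invalid protocol step, volume overdraw, or unassigned well."""


@dataclass(frozen=True)
class TimingProfile:
    """Durations (s) of the seven transition phases. The defaults total 2.0 s
    for a one-well move, matching the ~2 s transition of the real system;
    the plate-move phase scales with the Chebyshev well distance (x and y
    steppers run concurrently)."""

    t_close_out: float = 0.2
    t_open_bp: float = 0.1
    t_raise: float = 0.5
    t_move_per_well: float = 0.4
    t_lower: float = 0.5
    t_close_bp: float = 0.1
    t_open_out: float = 0.2

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if v < 0:
                raise ProtocolError(f"{name} must be >= 0")

    def transition_duration(self, wells_moved: int) -> float:
        return (self.t_close_out + self.t_open_bp + self.t_raise
                + self.t_move_per_well * wells_moved
                + self.t_lower + self.t_close_bp + self.t_open_out)


@dataclass(frozen=True)
class StimulusSpec:
    """Pulse train delivered during a step. ``onset_s`` is the offset of the
    first pulse after fill-delay completion; ``channel`` selects the odor
    valve or the red (optogenetic) light."""

    channel: str = "odor-valve"
    onset_s: float = 5.0
    pulse_duration_s: float = 10.0
    period_s: float = 60.0
    count: int = 1

    def __post_init__(self) -> None:
        if self.onset_s < 0 or self.pulse_duration_s < 0 or self.period_s < 0:
            raise ProtocolError("stimulus times must be >= 0")
        if self.count < 1:
            raise ProtocolError("stimulus count must be >= 1")


@dataclass(frozen=True)
class AcquisitionSpec:
    """Camera acquisition per stimulus pulse (or once per step if the step has
    no stimulus), starting ``pre_stim_s`` before each pulse onset."""

    fps: float = 10.0
    duration_s: float = 30.0
    excitation_pulse_ms: float = 10.0
    pre_stim_s: float = 5.0

    def __post_init__(self) -> None:
        if self.fps <= 0 or self.duration_s < 0:
            raise ProtocolError("acquisition fps must be > 0 and duration >= 0")


@dataclass(frozen=True)
class ProtocolStep:
    """One fluid exposure: move to ``well``, wait ``fill_delay_s`` for the new
    fluid to flush the tube, then flow (or incubate with flow paused) for
    ``flow_duration_s``."""

    well: WellId
    flow_duration_s: float
    fill_delay_s: float = 0.0
    fluid: str = ""
    pause_flow: Optional[bool] = None  # None = auto by threshold
    stimulus: Optional[StimulusSpec] = None
    acquisition: Optional[AcquisitionSpec] = None

    def __post_init__(self) -> None:
        if self.flow_duration_s < 0 or self.fill_delay_s < 0:
            raise ProtocolError("durations must be >= 0")


@dataclass(frozen=True)
class Event:
    t: float
    actor: str  # out_valve | bp_valve | servo | plate | stim | camera
    action: str


@dataclass
class StepRecord:
    """Bookkeeping for one compiled step: timing windows and volume draw."""

    index: int
    well: str
    fluid: str
    t_start: float        # transition begins
    t_fill_start: float   # tube lowered, new fluid flowing
    t_fill_end: float     # fluid switch complete; incubation/recording begins
    t_end: float
    paused: bool
    drawn_ul: float
    loaded_ul: Optional[float]


HOMED_STATE = {"servo": "raised", "out_valve": "closed", "bp_valve": "open", "plate": "A1"}


@dataclass
class Timeline:
    """Ordered event stream plus per-step records."""

    events: list[Event] = field(default_factory=list)
    step_records: list[StepRecord] = field(default_factory=list)
    total_duration_s: float = 0.0
    initial_state: dict = field(default_factory=lambda: dict(HOMED_STATE))

    @property
    def total_exposure_s(self) -> float:
        """Summed fluid-exposure (incubation) time across steps, excluding
        transitions and fill delays."""
        return sum(r.t_end - r.t_fill_end for r in self.step_records)

    def command_string(self) -> str:
        """Serial command stream for the plate/servo actor."""
        wells = [WellId.parse(r.well) for r in self.step_records]
        return command_stream(wells, lower=True)

    # ---- serialization ----

    def to_dict(self) -> dict:
        return {
            "initial_state": self.initial_state,
            "total_duration_s": self.total_duration_s,
            "events": [asdict(e) for e in self.events],
            "step_records": [asdict(r) for r in self.step_records],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "Timeline":
        return cls(
            events=[Event(**e) for e in d["events"]],
            step_records=[StepRecord(**r) for r in d["step_records"]],
            total_duration_s=d["total_duration_s"],
            initial_state=dict(d["initial_state"]),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "Timeline":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_event_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("timestamp_s,actor,action\n")
            for e in self.events:
                fh.write(f"{e.t:.6f},{e.actor},{e.action}\n")


def _well_distance(a: WellId, b: WellId) -> int:
    return max(abs(a.row_index - b.row_index), abs(a.col - b.col))


def transition_sequence(from_well: WellId, to_well: WellId, profile: TimingProfile,
                        t0: float = 0.0) -> tuple[list[Event], float]:
    """The seven-event well-to-well transition starting at ``t0``.

    Returns the events (each stamped at its phase start) and the total
    transition duration. Moving to the same well has a zero-length move phase
    but keeps all seven events.
    """
    dist = _well_distance(from_well, to_well)
    p = profile
    t = t0
    events = []
    for actor, action, dur in (
        ("out_valve", "close", p.t_close_out),
        ("bp_valve", "open", p.t_open_bp),
        ("servo", "raise", p.t_raise),
        ("plate", f"move:{to_well}", p.t_move_per_well * dist),
        ("servo", "lower", p.t_lower),
        ("bp_valve", "close", p.t_close_bp),
        ("out_valve", "open", p.t_open_out),
    ):
        events.append(Event(t, actor, action))
        t += dur
    return events, t - t0


def compile_protocol(plate_map: PlateMap, steps: Sequence[ProtocolStep],
                     flow: FlowSpec, profile: Optional[TimingProfile] = None,
                     pause_threshold_s: float = PAUSE_FLOW_THRESHOLD_S) -> Timeline:
    """Compile steps into a full timeline of valve/servo/plate/stim/camera
    events. Deterministic: identical inputs yield identical timelines.

    Raises :class:`ProtocolError` for steps targeting unassigned wells, fluid
    mismatches against the plate map, or cumulative volume overdraw of a well.
    """
    profile = profile or TimingProfile()
    tl = Timeline()
    t = 0.0
    current = WellId.parse(HOMED_STATE["plate"])
    drawn: dict[WellId, float] = {}

    for i, step in enumerate(steps):
        if step.well not in plate_map:
            raise ProtocolError(f"step {i}: well {step.well} is not assigned in the plate map")
        fluid = plate_map[step.well]
        if step.fluid and step.fluid != fluid.name:
            raise ProtocolError(
                f"step {i}: step fluid {step.fluid!r} does not match plate map "
                f"{fluid.name!r} at {step.well}"
            )

        t_start = t
        ev, dur = transition_sequence(current, step.well, profile, t0=t)
        tl.events.extend(ev)
        t += dur
        current = step.well

        t_fill_start = t
        t_fill_end = t + step.fill_delay_s
        t_end = t_fill_end + step.flow_duration_s

        paused = (step.pause_flow if step.pause_flow is not None
                  else step.flow_duration_s >= pause_threshold_s)

        # volume bookkeeping: flow runs during the fill delay always, and
        # during the exposure only if not paused
        vol = flow.flowrate_ul_s * (step.fill_delay_s
                                    + (0.0 if paused else step.flow_duration_s))
        drawn[step.well] = drawn.get(step.well, 0.0) + vol
        if fluid.volume_ul is not None and drawn[step.well] > fluid.volume_ul + 1e-9:
            raise ProtocolError(
                f"step {i}: well {step.well} overdrawn "
                f"({drawn[step.well]:.1f} µL needed, {fluid.volume_ul:.1f} µL loaded)"
            )

        if paused:
            tl.events.append(Event(t_fill_end, "out_valve", "close"))
            tl.events.append(Event(t_fill_end, "bp_valve", "close"))
            tl.events.append(Event(t_end, "out_valve", "open"))

        if step.stimulus is not None:
            s = step.stimulus
            for k in range(s.count):
                on = t_fill_end + s.onset_s + k * s.period_s
                tl.events.append(Event(on, "stim", f"on:{s.channel}"))
                tl.events.append(Event(on + s.pulse_duration_s, "stim", f"off:{s.channel}"))
                if step.acquisition is not None:
                    a = step.acquisition
                    start = on - a.pre_stim_s
                    tl.events.append(Event(start, "camera", f"start:fps={a.fps:g}"))
                    tl.events.append(Event(start + a.duration_s, "camera", "stop"))
        elif step.acquisition is not None:
            a = step.acquisition
            tl.events.append(Event(t_fill_end, "camera", f"start:fps={a.fps:g}"))
            tl.events.append(Event(t_fill_end + a.duration_s, "camera", "stop"))

        tl.step_records.append(StepRecord(
            index=i, well=str(step.well), fluid=fluid.name,
            t_start=t_start, t_fill_start=t_fill_start,
            t_fill_end=t_fill_end, t_end=t_end,
            paused=paused, drawn_ul=vol, loaded_ul=fluid.volume_ul,
        ))
        t = t_end

    tl.events.sort(key=lambda e: e.t)
    tl.total_duration_s = t
    return tl


def fill_delay_for(tube: TubeSpec, flow: FlowSpec, k_volumes: float = 5.0) -> float:
    """Fill delay (s) for ``k_volumes`` tube volumes at the working flowrate
    — the programmed wait for the new fluid to flush the inlet tube."""
    if flow.flowrate_ul_s <= 0:
        raise FluidicsError("flowrate must be positive")
    if k_volumes < 0:
        raise ProtocolError("k_volumes must be >= 0")
    return k_volumes * tube_volume(tube) / flow.flowrate_ul_s


def well_flow_budget(well_volume_ul: float, flow: FlowSpec) -> float:
    """Minutes of continuous flow a well supports (volume / flowrate).

    A 2 mL deep well at 2 µL/s supports ≈16.7 min — about 17 min — which is
    why longer incubations pause the flow.
    """
    if flow.flowrate_ul_s <= 0:
        raise FluidicsError("flowrate must be positive")
    if well_volume_ul < 0:
        raise ProtocolError("well volume must be >= 0")
    return well_volume_ul / flow.flowrate_ul_s / 60.0


def validate_timeline(tl: Timeline) -> list[str]:
    """Scan a timeline for invariant violations; empty list iff valid.

    Checks: timestamps non-decreasing; the outlet valve is never open while
    the servo (inlet tube) is raised; no step overdraws its well's loaded
    volume.
    """
    report: list[str] = []
    servo = tl.initial_state.get("servo", "raised")
    out = tl.initial_state.get("out_valve", "closed")
    if servo == "raised" and out == "open":
        report.append("t=initial: outlet valve open while inlet tube raised")
    prev_t = float("-inf")
    for e in tl.events:
        if e.t < prev_t:
            report.append(f"t={e.t:g}: timestamps decrease")
        prev_t = e.t
        if e.actor == "servo":
            servo = "raised" if e.action == "raise" else "lowered"
        elif e.actor == "out_valve":
            out = e.action  # open | close
        if servo == "raised" and out == "open":
            report.append(f"t={e.t:g}: outlet valve open while inlet tube raised")
    drawn: dict[str, float] = {}
    for r in tl.step_records:
        drawn[r.well] = drawn.get(r.well, 0.0) + r.drawn_ul
        if r.loaded_ul is not None and drawn[r.well] > r.loaded_ul + 1e-9:
            report.append(
                f"step {r.index}: well {r.well} overdrawn "
                f"({drawn[r.well]:.1f} µL > {r.loaded_ul:.1f} µL loaded)"
            )
    return report


# ---------------------------------------------------------------------------
# Canonical protocols
# ---------------------------------------------------------------------------

#: The ten-step cell fixation and staining sequence: (fluid, exposure s).
STAINING_SEQUENCE: tuple[tuple[str, float], ...] = (
    ("PBS", 30.0),
    ("PFA 4%", 600.0),
    ("PBS", 30.0),
    ("Triton X-100 0.25%", 600.0),
    ("PBS", 30.0),
    ("BSA 1%", 1800.0),
    ("AF488 phalloidin 2.5%", 1800.0),
    ("PBS", 30.0),
    ("Hoechst 33342", 180.0),
    ("PBS", 30.0),
)


def staining_plate_map(plate: Optional[PlateMap] = None) -> PlateMap:
    """Deep-well plate with the ten staining solutions in wells A1–A10
    (2 mL each)."""
    from .plates import PlateSpec  # local to avoid cycle noise

    spec = PlateSpec.from_format("96-deep")
    pm = PlateMap(spec)
    for i, (fluid, _dur) in enumerate(STAINING_SEQUENCE):
        pm.assign(WellId("A", i + 1), FluidLabel(fluid, volume_ul=spec.well_capacity_ul))
    return pm


def staining_steps(fill_delay_s: float = 30.0) -> list[ProtocolStep]:
    """The canonical ten fluid-exposure steps (fix, permeabilize, block,
    stain actin and nuclei, with PBS washes): 85.5 min of summed exposure."""
    return [
        ProtocolStep(well=WellId("A", i + 1), fluid=fluid,
                     flow_duration_s=dur, fill_delay_s=fill_delay_s)
        for i, (fluid, dur) in enumerate(STAINING_SEQUENCE)
    ]


def dose_response_steps(sequence: Sequence[WellId], fill_delay_s: float = 45.0,
                        pulses: int = 4, period_s: float = 60.0,
                        pulse_duration_s: float = 10.0,
                        acquisition_s: float = 30.0, fps: float = 10.0) -> list[ProtocolStep]:
    """Per-well odor dose–response steps: fill delay, then ``pulses`` odor
    pulses once per ``period_s`` with an acquisition around each pulse.
    Per-well duration is fill_delay + pulses·period (285 s at defaults)."""
    stim = StimulusSpec(channel="odor-valve", onset_s=5.0,
                        pulse_duration_s=pulse_duration_s, period_s=period_s, count=pulses)
    acq = AcquisitionSpec(fps=fps, duration_s=acquisition_s, pre_stim_s=5.0)
    return [
        ProtocolStep(well=w, flow_duration_s=pulses * period_s,
                     fill_delay_s=fill_delay_s, stimulus=stim, acquisition=acq)
        for w in sequence
    ]


def screen_steps(sequence: Sequence[WellId], fill_delay_s: float = 30.0,
                 acquisition_s: float = 15.0, fps: float = 10.0) -> list[ProtocolStep]:
    """Per-well optogenetic screen steps: 30 s fill delay, then a 15 s
    acquisition with a single 5 s red-light pulse from 2.5 to 7.5 s."""
    stim = StimulusSpec(channel="red-light", onset_s=2.5, pulse_duration_s=5.0,
                        period_s=acquisition_s, count=1)
    acq = AcquisitionSpec(fps=fps, duration_s=acquisition_s,
                          excitation_pulse_ms=5.0, pre_stim_s=2.5)
    return [
        ProtocolStep(well=w, flow_duration_s=acquisition_s, fill_delay_s=fill_delay_s,
                     stimulus=stim, acquisition=acq)
        for w in sequence
    ]


# ---- protocol JSON round-trip ----

def steps_to_json(steps: Sequence[ProtocolStep], path: str | Path) -> None:
    out = []
    for s in steps:
        d: dict = {"well": str(s.well), "flow_duration_s": s.flow_duration_s,
                   "fill_delay_s": s.fill_delay_s}
        if s.fluid:
            d["fluid"] = s.fluid
        if s.pause_flow is not None:
            d["pause_flow"] = s.pause_flow
        if s.stimulus is not None:
            d["stimulus"] = asdict(s.stimulus)
        if s.acquisition is not None:
            d["acquisition"] = asdict(s.acquisition)
        out.append(d)
    Path(path).write_text(json.dumps({"steps": out}, indent=1))


def steps_from_json(path: str | Path) -> list[ProtocolStep]:
    data = json.loads(Path(path).read_text())
    steps = []
    for d in data["steps"]:
        steps.append(ProtocolStep(
            well=WellId.parse(d["well"]),
            flow_duration_s=d["flow_duration_s"],
            fill_delay_s=d.get("fill_delay_s", 0.0),
            fluid=d.get("fluid", ""),
            pause_flow=d.get("pause_flow"),
            stimulus=StimulusSpec(**d["stimulus"]) if "stimulus" in d else None,
            acquisition=AcquisitionSpec(**d["acquisition"]) if "acquisition" in d else None,
        ))
    return steps
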