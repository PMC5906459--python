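"""Multiwell plate geometry, well naming, fluid maps, traversal orders, and the
serial command codec used to position the plate and inlet tube.

The robot addresses wells by row letter and 1-based column ("A1"). Serial
commands follow the grammar ``[row][column][+|-]``: the servo raises the inlet
tube, the plate moves to the named well, and the tube is left raised (``+``) or
lowered into the well (``-``). ``0`` homes the system (tube raised, plate at
A1). Commands are chained with semicolons, e.g. ``"A1-;A2-"``.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence

ROW_LETTERS = "ABCDEFGHIJKLMNOP"  # up to 16 rows (384-well)

#: Named plate formats: (rows, cols, well capacity µL, well depth mm).
#: Capacities follow the vendor geometries the system supports: 96-medium
#: 600 µL, 96-deep 2 mL, 384-well 225 µL, and the larger-well formats
#: (48-well 5 mL, 24-well 10 mL, 6-well 16.8 mL).
PLATE_FORMATS: dict[str, tuple[int, int, float, float]] = {
    "6": (2, 3, 16800.0, 18.0),
    "24": (4, 6, 10000.0, 17.5),
    "48": (6, 8, 5000.0, 17.5),
    "96-medium": (8, 12, 600.0, 11.0),
    "96-deep": (8, 12, 2000.0, 30.0),
    "384": (16, 24, 225.0, 11.5),
}

_NAMED_WELL_COUNTS = {6, 24, 48, 96, 384}


class PlateError(ValueError):
    """Invalid plate geometry, well address, or map."""


class CommandError(ValueError):
    """Malformed serial command string."""


@dataclass(frozen=True, order=True)
class WellId:
    """A single well address: row letter (A–P) and 1-based column."""

    row: str
    col: int

    def __post_init__(self) -> None:
        if self.row not in ROW_LETTERS:
            raise PlateError(f"row letter must be one of {ROW_LETTERS!r}, got {self.row!r}")
        if self.col < 1:
            raise PlateError(f"column must be >= 1, got {self.col}")

    @classmethod
    def parse(cls, s: str) -> "WellId":
        m = re.fullmatch(r"([A-Pa-p])(\d{1,2})", s.strip())
        if not m:
            raise PlateError(f"cannot parse well id {s!r}")
        return cls(m.group(1).upper(), int(m.group(2)))

    @property
    def row_index(self) -> int:
        return ROW_LETTERS.index(self.row)

    def __str__(self) -> str:
        return f"{self.row}{self.col}"


@dataclass(frozen=True)
class PlateSpec:
    """Geometry of a multiwell plate.

    ``rows`` × ``cols`` wells of ``well_capacity_ul`` µL each; named formats
    must have a standard well count (6–384) and a depth in the 5–30 mm range
    the servo stroke supports.
    """

    rows: int
    cols: int
    well_capacity_ul: float
    well_depth_mm: float
    format_name: str = "custom"

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise PlateError("plate must have at least one row and one column")
        if self.rows > len(ROW_LETTERS):
            raise PlateError(f"at most {len(ROW_LETTERS)} rows supported")
        if self.well_capacity_ul <= 0:
            raise PlateError("well capacity must be positive")
        if self.format_name != "custom":
            if self.rows * self.cols not in _NAMED_WELL_COUNTS:
                raise PlateError(
                    f"named format {self.format_name!r} must have a standard well count"
                )
            if not (5.0 <= self.well_depth_mm <= 30.0):
                raise PlateError("well depth must be within 5-30 mm for named formats")

    @classmethod
    def from_format(cls, name: str) -> "PlateSpec":
        try:
            rows, cols, cap, depth = PLATE_FORMATS[name]
        except KeyError:
            raise PlateError(
                f"unknown plate format {name!r}; known: {sorted(PLATE_FORMATS)}"
            ) from None
        return cls(rows, cols, cap, depth, format_name=name)

    @classmethod
    def custom(cls, rows: int, cols: int, well_capacity_ul: float = 600.0,
               well_depth_mm: float = 11.0) -> "PlateSpec":
        return cls(rows, cols, well_capacity_ul, well_depth_mm, format_name="custom")

    @property
    def n_wells(self) -> int:
        return self.rows * self.cols

    def contains(self, well: WellId) -> bool:
        return well.row_index < self.rows and well.col <= self.cols

    def wells(self) -> list[WellId]:
        """All wells in row-major (typewriter) order."""
        return [WellId(ROW_LETTERS[r], c + 1) for r in range(self.rows) for c in range(self.cols)]


@dataclass(frozen=True)
class FluidLabel:
    """A fluid identity: name, optional concentration (with units), and the
    volume loaded per well (µL)."""

    name: str
    concentration: Optional[float] = None
    conc_units: str = ""
    volume_ul: Optional[float] = None

    def key(self) -> tuple[str, Optional[float]]:
        """Identity used when counting fluid switches (name + concentration)."""
        return (self.name, self.concentration)

    def __str__(self) -> str:
        if self.concentration is None:
            return self.name
        return f"{self.name}@{self.concentration:g}{self.conc_units}"


@dataclass
class PlateMap:
    """Assignment of fluids to wells of a plate."""

    plate: PlateSpec
    assignments: dict[WellId, FluidLabel] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for well, fluid in self.assignments.items():
            self._check(well, fluid)

    def _check(self, well: WellId, fluid: FluidLabel) -> None:
        if not self.plate.contains(well):
            raise PlateError(f"well {well} out of bounds for {self.plate.format_name} plate")
        if fluid.volume_ul is not None and fluid.volume_ul > self.plate.well_capacity_ul:
            raise PlateError(
                f"well {well}: loaded volume {fluid.volume_ul} µL exceeds capacity "
                f"{self.plate.well_capacity_ul} µL"
            )

    def assign(self, well: WellId, fluid: FluidLabel) -> None:
        self._check(well, fluid)
        self.assignments[well] = fluid

    def __getitem__(self, well: WellId) -> FluidLabel:
        return self.assignments[well]

    def __contains__(self, well: WellId) -> bool:
        return well in self.assignments

    def fluid_names(self) -> set[str]:
        return {f.name for f in self.assignments.values()}

    # ---- CSV round-trip (columns: well,fluid,concentration,volume_ul) ----

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["well", "fluid", "concentration", "volume_ul", "conc_units"])
            for well in sorted(self.assignments):
                f = self.assignments[well]
                conc = "" if f.concentration is None else repr(f.concentration)
                vol = "" if f.volume_ul is None else repr(f.volume_ul)
                w.writerow([str(well), f.name, conc, vol, f.conc_units])

    @classmethod
    def from_csv(cls, path: str | Path, plate: PlateSpec) -> "PlateMap":
        assignments: dict[WellId, FluidLabel] = {}
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            required = {"well", "fluid", "concentration", "volume_ul"}
            if reader.fieldnames is None or not required.issubset(reader.fieldnames):
                raise PlateError(f"plate map CSV must have columns {sorted(required)}")
            for row in reader:
                conc = float(row["concentration"]) if row["concentration"] else None
                vol = float(row["volume_ul"]) if row["volume_ul"] else None
                assignments[WellId.parse(row["well"])] = FluidLabel(
                    row["fluid"], concentration=conc,
                    conc_units=row.get("conc_units") or "", volume_ul=vol,
                )
        return cls(plate, assignments)


# ---------------------------------------------------------------------------
# Traversal orders
# ---------------------------------------------------------------------------

def snake_order(plate: PlateSpec, pattern: Literal["snake", "typewriter"] = "snake",
                reverse_first_row: bool = False) -> list[WellId]:
    """Well visiting order across the whole plate.

    ``snake`` reverses column direction on each successive row (minimising
    plate travel); ``typewriter`` restarts every row at column 1. The snake
    starts left-to-right on row A unless ``reverse_first_row`` is set.
    """
    if pattern not in ("snake", "typewriter"):
        raise PlateError(f"unknown traversal pattern {pattern!r}")
    order: list[WellId] = []
    for r in range(plate.rows):
        cols = list(range(1, plate.cols + 1))
        if pattern == "snake" and (r % 2 == 1) != reverse_first_row:
            cols.reverse()
        order.extend(WellId(ROW_LETTERS[r], c) for c in cols)
    return order


def alternating_map(plate: PlateSpec, fluid_a: FluidLabel, fluid_b: FluidLabel,
                    order: Sequence[WellId]) -> PlateMap:
    """Assign ``fluid_a`` and ``fluid_b`` alternately along ``order``
    (``fluid_a`` first), as in the dye/buffer carryover test plate."""
    if not order:
        raise PlateError("well order must not be empty")
    pm = PlateMap(plate)
    for i, well in enumerate(order):
        pm.assign(well, fluid_a if i % 2 == 0 else fluid_b)
    return pm


def count_transitions(plate_map: PlateMap, order: Sequence[WellId],
                      from_name: str, to_name: str) -> int:
    """Number of adjacent steps in ``order`` that switch from one named fluid
    to another (e.g. dye→buffer switches along a scan)."""
    n = 0
    for a, b in zip(order, order[1:]):
        if plate_map[a].name == from_name and plate_map[b].name == to_name:
            n += 1
    return n


def screen_map(solvents: Sequence[str], concentrations: Sequence[float],
               control: FluidLabel, plate: PlateSpec,
               pattern: Literal["snake", "typewriter"] = "snake",
               volume_ul: Optional[float] = None,
               conc_units: str = "%") -> tuple[PlateMap, list[WellId]]:
    """Build the solvent-screen plate: each solvent at each concentration,
    interleaved with buffer control wells, delivered sequentially.

    The delivery sequence is control, s1@c1, control, s1@c2, control, ...,
    ending with control: ``2·n_solvents·n_conc + 1`` wells in total (57 for
    14 solvents at two concentrations).
    """
    if not solvents:
        raise PlateError("need at least one solvent")
    if not concentrations:
        raise PlateError("need at least one concentration")
    fluids: list[FluidLabel] = [control]
    for s in solvents:
        for c in concentrations:
            fluids.append(FluidLabel(s, concentration=c, conc_units=conc_units,
                                     volume_ul=volume_ul))
            fluids.append(control)
    order = snake_order(plate, pattern)
    if len(fluids) > len(order):
        raise PlateError(
            f"screen needs {len(fluids)} wells but plate has only {len(order)}"
        )
    sequence = order[: len(fluids)]
    pm = PlateMap(plate)
    for well, fluid in zip(sequence, fluids):
        pm.assign(well, fluid)
    return pm, sequence


def dilution_series(top: float, factor: float, n: int, name: str = "diacetyl",
                    conc_units: str = "M", volume_ul: Optional[float] = None) -> list[FluidLabel]:
    """Serial dilution: ``n`` fluids at top, top/factor, top/factor², ...

    The odor dose–response plate used 10-fold dilutions of diacetyl from
    11.5 mM down to 11.5 nM (seven steps).
    """
    if top <= 0:
        raise PlateError("top concentration must be positive")
    if factor <= 1:
        raise PlateError("dilution factor must exceed 1")
    if n < 1:
        raise PlateError("need at least one dilution")
    return [
        FluidLabel(name, concentration=top / factor ** k, conc_units=conc_units,
                   volume_ul=volume_ul)
        for k in range(n)
    ]


# ---------------------------------------------------------------------------
# Serial command codec
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CommandToken:
    """One serial command: ``home`` (raise tube, plate to A1) or ``move`` to a
    well, ending with the tube raised ('+') or lowered ('-')."""

    kind: Literal["home", "move"]
    well: Optional[WellId] = None
    end_state: Optional[Literal["+", "-"]] = None

    def __post_init__(self) -> None:
        if self.kind == "home":
            if self.well is not None or self.end_state is not None:
                raise CommandError("home token takes no well or end state")
        elif self.kind == "move":
            if self.well is None or self.end_state not in ("+", "-"):
                raise CommandError("move token needs a well and an end state '+' or '-'")
        else:
            raise CommandError(f"unknown token kind {self.kind!r}")

    @classmethod
    def home(cls) -> "CommandToken":
        return cls("home")

    @classmethod
    def move(cls, well: WellId, end_state: Literal["+", "-"] = "-") -> "CommandToken":
        return cls("move", well, end_state)


_SEGMENT_RE = re.compile(r"([A-Pa-p])(\d{1,2})([+\-−])")


def encode_commands(tokens: Sequence[CommandToken]) -> str:
    """Render tokens as a semicolon-delimited command string ("A1-;A2-")."""
    parts = []
    for tok in tokens:
        if tok.kind == "home":
            parts.append("0")
        else:
            parts.append(f"{tok.well}{tok.end_state}")
    return ";".join(parts)


def parse_commands(s: str) -> list[CommandToken]:
    """Parse a command string back to tokens (round-trip inverse of
    :func:`encode_commands`). Case-insensitive; '−' (minus sign) accepted for
    '-'. Raises :class:`CommandError` naming the offending segment."""
    tokens: list[CommandToken] = []
    for segment in s.split(";"):
        seg = segment.strip()
        if not seg:
            raise CommandError(f"empty command segment in {s!r}")
        if seg == "0":
            tokens.append(CommandToken.home())
            continue
        m = _SEGMENT_RE.fullmatch(seg)
        if not m:
            raise CommandError(f"malformed command segment {seg!r}")
        suffix = "-" if m.group(3) in ("-", "−") else "+"
        try:
            wid = WellId(m.group(1).upper(), int(m.group(2)))
        except PlateError as e:
            raise CommandError(f"malformed command segment {seg!r}: {e}") from None
        tokens.append(CommandToken.move(wid, suffix))
    return tokens


def command_stream(order: Sequence[WellId], lower: bool = True) -> str:
    """Command string visiting ``order`` in sequence, lowering the tube into
    each well (the usual delivery pattern)."""
    suffix: Literal["+", "-"] = "-" if lower else "+"
    return encode_commands([CommandToken.move(w, suffix) for w in order])
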