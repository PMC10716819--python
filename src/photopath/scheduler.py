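"""Direction-aware LED scheduling.

The photo-cross-linking head carries four LED couples at 90° around the
needle. To polymerize the freshly deposited filament while keeping stray
light off the needle tip (clogging), only the couple(s) *behind* the motion
are lit: for each path segment the XY-projected unit direction (versor) is
computed, its polar angle is classified into one of eight 45° sectors, and
the sector selects which couple(s) to switch on — one couple for cardinal
directions, the two adjacent couples for diagonals. Each sector maps to a
numeric code 1–8 carried into the G-code as ``M102 P<code>``.

Dialect extensions (not part of the sector map): code 0 = all LEDs off,
code 9 = all LEDs on (the control configuration that clogs the needle).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .gcode import emit_gcode
from .toolpath import Move, Toolpath

__all__ = [
    "SectorConvention",
    "DirectionSegment",
    "xy_direction",
    "classify_sector",
    "sector_to_leds",
    "schedule_path",
    "all_on_schedule",
    "off_schedule",
    "code_to_azimuths",
    "inject_led_commands",
]

ALL_OFF = 0
ALL_ON = 9

#: below this XY length (mm) a segment has no usable direction
DEGENERATE_TOL = 1e-9


@dataclass(frozen=True)
class SectorConvention:
    """Sector layout and sector→code/LED mapping.

    Sectors are centred on the eight principal directions ``k*45°``
    (k = 0..7, sector 0 = +x) with half-width 22.5° and half-open
    boundaries ``[center - 22.5°, center + 22.5°)``. The code map is a
    bijection sectors→{1..8}; the default is ``code = sector + 1`` but it
    can be re-mapped to match a particular wiring of the physical device.
    ``couple_azimuths`` are the mounting azimuths of the four LED couples.
    """

    half_width: float = 22.5
    code_map: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8)
    couple_azimuths: tuple[float, float, float, float] = (0.0, 90.0, 180.0, 270.0)

    def __post_init__(self) -> None:
        if sorted(self.code_map) != list(range(1, 9)):
            raise ValueError("code_map must be a bijection onto 1..8")
        if len(self.couple_azimuths) != 4:
            raise ValueError("exactly 4 LED couples expected")

    @property
    def centers(self) -> tuple[float, ...]:
        return tuple(k * 45.0 for k in range(8))

    def code_for(self, sector: int) -> int:
        return self.code_map[sector]

    def sector_for_code(self, code: int) -> int:
        return self.code_map.index(code)


@dataclass(frozen=True)
class DirectionSegment:
    """Scheduling result for one move of the path.

    For print moves with a usable XY direction ``versor``/``theta``/
    ``sector`` are set; travel and degenerate (pure-Z, zero-XY) moves hold
    the previous LED state and carry only the inherited ``code``.
    """

    move_index: int
    code: int
    versor: tuple[float, float] | None = None
    theta: float | None = None
    sector: int | None = None
    inherited: bool = field(default=False)


def xy_direction(move: Move) -> tuple[tuple[float, float], float] | None:
    """XY-projected unit direction and polar angle (degrees) of a print move.

    Returns ``None`` for degenerate segments (pure-Z or zero XY length).
    theta is measured counterclockwise from the machine +x axis, in
    ``[0, 360)``.
    """
    if move.kind != "print":
        raise ValueError("direction is defined for print moves only")
    dx, dy, _ = move.delta()
    norm = math.hypot(dx, dy)
    if norm <= DEGENERATE_TOL:
        return None
    theta = math.degrees(math.atan2(dy, dx)) % 360.0
    return (dx / norm, dy / norm), theta


def classify_sector(theta: float, conv: SectorConvention | None = None) -> int:
    """Map a polar angle (degrees, [0, 360)) to its 45° sector index 0..7.

    Sector k covers ``[k*45 - 22.5, k*45 + 22.5)`` modulo 360: a boundary
    angle belongs to the sector whose lower boundary it is.
    """
    if not 0.0 <= theta < 360.0:
        raise ValueError(f"theta must lie in [0, 360), got {theta}")
    return int(math.floor((theta + 22.5) / 45.0)) % 8


def sector_to_leds(
    sector: int, conv: SectorConvention | None = None
) -> tuple[frozenset[float], int]:
    """Active LED couple azimuths and numeric code for a sector.

    Cardinal sectors (even k) light the single couple opposite the motion,
    at azimuth ``(k*45 + 180) % 360``; diagonal sectors (odd k) light the
    two cardinal couples adjacent to the opposite direction.
    """
    conv = conv or SectorConvention()
    if not 0 <= sector <= 7:
        raise ValueError(f"sector {sector} outside 0..7")
    opposite = (sector * 45.0 + 180.0) % 360.0
    if sector % 2 == 0:
        azimuths = frozenset({opposite})
    else:
        azimuths = frozenset({(opposite - 45.0) % 360.0, (opposite + 45.0) % 360.0})
    if not azimuths <= set(conv.couple_azimuths):
        raise ValueError("convention couple azimuths must be the 4 cardinals")
    return azimuths, conv.code_for(sector)


def code_to_azimuths(code: int, conv: SectorConvention | None = None) -> frozenset[float]:
    """Active couple azimuths for any dialect code (0=off, 9=all on)."""
    conv = conv or SectorConvention()
    if code == ALL_OFF:
        return frozenset()
    if code == ALL_ON:
        return frozenset(conv.couple_azimuths)
    return sector_to_leds(conv.sector_for_code(code), conv)[0]


def schedule_path(
    path: Toolpath, conv: SectorConvention | None = None
) -> list[DirectionSegment]:
    """Assign an LED code to every move of the path.

    Print moves with a usable XY direction are classified; travel moves and
    degenerate segments hold the previous LED state (no switching between
    strands or on pure-Z hops). Leading segments before the first directed
    print move get code 0 (LEDs off).
    """
    conv = conv or SectorConvention()
    out: list[DirectionSegment] = []
    current = ALL_OFF
    for i, mv in enumerate(path.moves):
        if mv.kind == "print":
            d = xy_direction(mv)
            if d is not None:
                versor, theta = d
                sector = classify_sector(theta, conv)
                current = conv.code_for(sector)
                out.append(DirectionSegment(i, current, versor, theta, sector))
                continue
        out.append(DirectionSegment(i, current, inherited=True))
    return out


def all_on_schedule(path: Toolpath) -> list[DirectionSegment]:
    """Control schedule: every LED couple lit for the whole path."""
    return [DirectionSegment(i, ALL_ON, inherited=True) for i in range(len(path.moves))]


def off_schedule(path: Toolpath) -> list[DirectionSegment]:
    return [DirectionSegment(i, ALL_OFF, inherited=True) for i in range(len(path.moves))]


def inject_led_commands(
    path: Toolpath,
    schedule: list[DirectionSegment] | None = None,
    conv: SectorConvention | None = None,
    *,
    all_on: bool = False,
    off_on_travel: bool = False,
    trailing_off: bool = True,
    header: str | None = None,
) -> str:
    """Annotate a toolpath with ``M102`` LED commands and serialize it.

    The command for a move precedes its motion line; duplicates are
    suppressed by :func:`~photopath.gcode.emit_gcode`, so the document
    carries one ``M102`` per code change (plus, by default, a trailing
    ``M102 P0`` switching the LEDs off at path end).
    """
    if all_on:
        schedule = all_on_schedule(path)
    elif schedule is None:
        schedule = schedule_path(path, conv)
    if len(schedule) != len(path.moves):
        raise ValueError("schedule does not cover the path")
    commands: list[tuple[int, int]] = []
    for seg, mv in zip(schedule, path.moves):
        code = seg.code
        if off_on_travel and mv.kind == "travel":
            code = ALL_OFF
        commands.append((seg.move_index, code))
    if trailing_off:
        commands.append((len(path.moves), ALL_OFF))
    return emit_gcode(path, commands, header=header)
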