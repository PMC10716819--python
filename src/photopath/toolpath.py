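"""Core toolpath containers.

All lengths are millimetres; feeds are stored in mm/s (G-code carries
mm/min on the wire, the parser converts). A :class:`Toolpath` is an ordered,
chained sequence of linear moves: the start of every move equals the end of
the previous one, so the path is fully described by an ordered list of
Cartesian coordinates plus a print/travel flag per segment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Literal

__all__ = ["Point3", "Move", "Toolpath", "ToolpathStats", "toolpath_stats"]

#: geometric tolerance used for chaining / degeneracy checks, in mm
GEOM_TOL = 1e-9


@dataclass(frozen=True)
class Point3:
    """A point in the machine frame, mm."""

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        for v in (self.x, self.y, self.z):
            if not math.isfinite(v):
                raise ValueError(f"non-finite coordinate in {self!r}")

    def dist(self, other: "Point3") -> float:
        return math.dist((self.x, self.y, self.z), (other.x, other.y, other.z))

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)


MoveKind = Literal["print", "travel"]


@dataclass(frozen=True)
class Move:
    """One linear segment of the toolpath.

    ``kind`` distinguishes extruding moves ("print") from repositioning
    moves ("travel"). ``feed`` is the programmed speed in mm/s; ``None``
    means "inherit from the previous move" (G-code modal F).
    """

    kind: MoveKind
    start: Point3
    end: Point3
    feed: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("print", "travel"):
            raise ValueError(f"unknown move kind {self.kind!r}")
        if self.feed is not None and not self.feed > 0:
            raise ValueError(f"feed must be positive, got {self.feed}")
        if self.kind == "print" and self.length() <= GEOM_TOL:
            raise ValueError("print move must have positive length")

    def length(self) -> float:
        return self.start.dist(self.end)

    def xy_length(self) -> float:
        return math.hypot(self.end.x - self.start.x, self.end.y - self.start.y)

    def delta(self) -> tuple[float, float, float]:
        return (
            self.end.x - self.start.x,
            self.end.y - self.start.y,
            self.end.z - self.start.z,
        )


@dataclass
class Toolpath:
    """Chained sequence of moves plus layer metadata."""

    moves: list[Move] = field(default_factory=list)
    layer_thickness: float = 0.2
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.layer_thickness > 0:
            raise ValueError("layer_thickness must be > 0")
        self._check_chained()

    def _check_chained(self) -> None:
        for i in range(1, len(self.moves)):
            prev, cur = self.moves[i - 1], self.moves[i]
            if prev.end.dist(cur.start) > 1e-6:
                raise ValueError(
                    f"moves {i - 1} and {i} are not chained: "
                    f"{prev.end} != {cur.start}"
                )

    def __len__(self) -> int:
        return len(self.moves)

    def __iter__(self) -> Iterator[Move]:
        return iter(self.moves)

    @property
    def print_moves(self) -> list[tuple[int, Move]]:
        return [(i, m) for i, m in enumerate(self.moves) if m.kind == "print"]

    def with_feeds_resolved(self, default: float | None = None) -> "Toolpath":
        """Return a copy with modal feeds made explicit on every move."""
        current = default
        resolved = []
        for m in self.moves:
            if m.feed is not None:
                current = m.feed
            resolved.append(replace(m, feed=current))
        return Toolpath(resolved, self.layer_thickness, dict(self.meta))

    @classmethod
    def from_points(
        cls,
        points: Iterable[tuple[float, float, float]],
        kinds: Iterable[MoveKind] | None = None,
        feed: float | None = None,
        layer_thickness: float = 0.2,
        meta: dict | None = None,
    ) -> "Toolpath":
        """Build a chained path from an ordered list of Cartesian coordinates.

        ``kinds[i]`` labels the segment ending at ``points[i + 1]``; by
        default every segment is a print move.
        """
        pts = [Point3(*p) for p in points]
        if len(pts) < 2:
            return cls([], layer_thickness, meta or {})
        if kinds is None:
            kind_list: list[MoveKind] = ["print"] * (len(pts) - 1)
        else:
            kind_list = list(kinds)
            if len(kind_list) != len(pts) - 1:
                raise ValueError("need one kind per segment")
        moves = [
            Move(kind_list[i], pts[i], pts[i + 1], feed)
            for i in range(len(pts) - 1)
        ]
        return cls(moves, layer_thickness, meta or {})


@dataclass(frozen=True)
class ToolpathStats:
    total_print_length: float
    total_travel_length: float
    bbox_min: Point3
    bbox_max: Point3
    z_levels: tuple[float, ...]
    moves_per_level: dict[float, int]


def toolpath_stats(path: Toolpath, z_decimals: int = 6) -> ToolpathStats:
    """Euclidean length totals, bounding box and per-layer print-move counts.

    Z levels are the distinct (rounded) end-point heights of print moves.
    """
    if not path.moves:
        zero = Point3(0.0, 0.0, 0.0)
        return ToolpathStats(0.0, 0.0, zero, zero, (), {})
    xs, ys, zs = [], [], []
    for m in path.moves:
        for p in (m.start, m.end):
            xs.append(p.x)
            ys.append(p.y)
            zs.append(p.z)
    print_len = sum(m.length() for m in path.moves if m.kind == "print")
    travel_len = sum(m.length() for m in path.moves if m.kind == "travel")
    per_level: dict[float, int] = {}
    for _, m in path.print_moves:
        z = round(m.end.z, z_decimals)
        per_level[z] = per_level.get(z, 0) + 1
    return ToolpathStats(
        total_print_length=print_len,
        total_travel_length=travel_len,
        bbox_min=Point3(min(xs), min(ys), min(zs)),
        bbox_max=Point3(max(xs), max(ys), max(zs)),
        z_levels=tuple(sorted(per_level)),
        moves_per_level=per_level,
    )
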