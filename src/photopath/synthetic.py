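"""Synthetic toolpath generators.

Stand-ins for the slicer output the platform consumes, covering the three
geometries exercised in practice:

* a single-layer crosshatch grid (the parameter-optimization print:
  bounding box 20 × 20 × 0.2 mm),
* a multi-layer square with alternating 0°/90° rectilinear infill (the
  characterization sample: 6 layers of 20 × 20 mm at 0.2 mm layer
  thickness, 50% infill),
* a spherical-cap conformal infill — a simple non-planar stand-in for
  anatomical-defect paths, with layers following the cap surface.

Infill spacing for a given infill percentage is
``line_width / (infill / 100)``: 50% infill with the 0.4 mm needle gives
0.8 mm spacing. Row-end connectors are print moves (continuous
extrusion).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .toolpath import Toolpath

__all__ = [
    "FixtureSpec",
    "infill_pitch",
    "gen_grid_monolayer",
    "gen_multilayer_square",
    "gen_spherical_cap_infill",
]

#: nozzle internal diameter and hence nominal strand width, mm
LINE_WIDTH = 0.4
#: maximum depth the LED slider can follow on non-planar prints, mm
MAX_NONPLANAR_DEPTH = 15.0


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a generated fixture (lengths mm, feed mm/s)."""

    width: float = 20.0
    height: float = 20.0
    layer_thickness: float = 0.2
    n_layers: int = 1
    infill: float = 50.0
    line_width: float = LINE_WIDTH
    feed: float = 5.0
    cap_radius: float = 60.0  # spherical-cap fixtures only

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("extents must be positive")
        if not 0 < self.infill <= 100:
            raise ValueError("infill must lie in (0, 100]")
        if self.n_layers < 1 or self.layer_thickness <= 0 or self.feed <= 0:
            raise ValueError("invalid layer/feed specification")


def infill_pitch(spec: FixtureSpec) -> float:
    """Line spacing realizing the spec's infill percentage, mm."""
    return spec.line_width / (spec.infill / 100.0)


def _serpentine(
    x0: float, x1: float, rows: list[float], start_forward: bool = True
) -> list[tuple[float, float]]:
    """XY waypoints of a serpentine raster along x over the given y rows."""
    pts: list[tuple[float, float]] = []
    forward = start_forward
    for y in rows:
        a, b = (x0, x1) if forward else (x1, x0)
        pts.extend([(a, y), (b, y)])
        forward = not forward
    return pts


def _dedup(points: list[tuple[float, float, float]]):
    out = [points[0]]
    for p in points[1:]:
        if math.dist(p, out[-1]) > 1e-12:
            out.append(p)
    return out


def _from_origin(points, kinds):
    """Prepend the travel from the machine origin to the path start.

    Keeps generated paths anchored at (0, 0, 0), the implicit start
    position of a G-code document, so serialization is lossless.
    """
    first = points[0]
    if math.dist(first, (0.0, 0.0, 0.0)) > 1e-12:
        points = [(0.0, 0.0, 0.0)] + points
        kinds = ["travel"] + kinds
    return points, kinds


def gen_grid_monolayer(
    spec: FixtureSpec | None = None, pitch: float | None = None
) -> Toolpath:
    """Single-layer crosshatch grid covering the spec's bounding box.

    An x-serpentine (rows) followed by a y-serpentine (columns) at the
    same Z level; all segments axis-aligned, one continuous extrusion.
    With a 20 × 20 mm box at 1 mm pitch the fixture has 20 full-width
    rows and 20 full-height columns.
    """
    spec = spec or FixtureSpec(n_layers=1, infill=40.0)  # 1 mm pitch default
    p = pitch if pitch is not None else infill_pitch(spec)
    z = spec.layer_thickness
    n_rows = max(1, int(round(spec.height / p)))
    n_cols = max(1, int(round(spec.width / p)))
    rows = [k * p for k in range(n_rows)]
    xy = _serpentine(0.0, spec.width, rows, start_forward=True)
    # column phase: serpentine along y; columns swept from the side the
    # row phase ended on, so the path stays continuous
    last_x = xy[-1][0]
    cols = [k * p for k in range(n_cols)]
    if abs(last_x - spec.width) < abs(last_x):
        cols = cols[::-1]
    forward = xy[-1][1] < spec.height / 2
    for x in cols:
        a, b = (0.0, spec.height) if forward else (spec.height, 0.0)
        xy.extend([(x, a), (x, b)])
        forward = not forward
    pts = _dedup([(x, y, z) for x, y in xy])
    pts, kinds = _from_origin(pts, ["print"] * (len(pts) - 1))
    path = Toolpath.from_points(
        pts, kinds, feed=spec.feed, layer_thickness=spec.layer_thickness
    )
    path.meta.update(kind="grid_monolayer", pitch=p, n_rows=n_rows, n_cols=n_cols)
    return path


def _infill_layers(spec: FixtureSpec, p: float):
    """Per-layer serpentine waypoints with alternating 0°/90° direction."""
    layers = []
    for k in range(spec.n_layers):
        along_x = k % 2 == 0
        if along_x:
            n = max(2, int(round(spec.height / p)) + 1)
            rows = [min(i * p, spec.height) for i in range(n)]
            xy = _serpentine(0.0, spec.width, rows, start_forward=k % 4 == 0)
        else:
            n = max(2, int(round(spec.width / p)) + 1)
            cols = [min(i * p, spec.width) for i in range(n)]
            xy = [
                (y, x)
                for x, y in _serpentine(0.0, spec.height, cols, start_forward=k % 4 == 1)
            ]
        layers.append(xy)
    return layers


def gen_multilayer_square(spec: FixtureSpec | None = None) -> Toolpath:
    """Multi-layer square with alternating 0°/90° rectilinear infill.

    Layer k sits at ``z = (k + 1) * layer_thickness``; layer changes are
    travel moves. Defaults follow the characterization sample: 6 layers,
    20 × 20 mm, 0.2 mm layers, 50% infill.
    """
    spec = spec or FixtureSpec(n_layers=6)
    p = infill_pitch(spec)
    points: list[tuple[float, float, float]] = []
    kinds: list[str] = []
    for k, xy in enumerate(_infill_layers(spec, p)):
        z = (k + 1) * spec.layer_thickness
        layer_pts = _dedup([(x, y, z) for x, y in xy])
        if not points:
            points.extend(layer_pts)
            kinds.extend(["print"] * (len(layer_pts) - 1))
        else:
            points.extend(layer_pts)
            kinds.append("travel")  # hop up to the next layer's start
            kinds.extend(["print"] * (len(layer_pts) - 1))
    points, kinds = _from_origin(points, kinds)
    path = Toolpath.from_points(
        points, kinds, feed=spec.feed, layer_thickness=spec.layer_thickness
    )
    path.meta.update(kind="multilayer_square", pitch=p, n_layers=spec.n_layers)
    return path


def gen_spherical_cap_infill(
    spec: FixtureSpec | None = None, segment_length: float = 1.0
) -> Toolpath:
    """Conformal infill over a spherical cap (non-planar stand-in).

    The XY pattern is identical to :func:`gen_multilayer_square`; each
    straight strand is subdivided (about every ``segment_length`` mm) and
    Z follows the cap surface of radius ``spec.cap_radius`` centred over
    the square, offset vertically by the layer height. The cap apex sits
    over the square's centre, so Z is highest mid-print and lowest at the
    corners. XY-projected segment directions are unchanged with respect
    to the flat fixture. If the resulting depth exceeds the 15 mm the
    slider can follow, the path is still generated but flagged in
    ``meta["depth_warning"]``.
    """
    spec = spec or FixtureSpec(n_layers=2)
    R = spec.cap_radius
    half_diag = math.hypot(spec.width / 2.0, spec.height / 2.0)
    if not R > half_diag:
        raise ValueError("cap radius must exceed half the box diagonal")
    cx, cy = spec.width / 2.0, spec.height / 2.0

    def surf(x: float, y: float) -> float:
        rho2 = (x - cx) ** 2 + (y - cy) ** 2
        # zero at the corners, rising toward the apex
        return math.sqrt(R * R - rho2) - math.sqrt(R * R - half_diag**2)

    p = infill_pitch(spec)
    points: list[tuple[float, float, float]] = []
    kinds: list[str] = []
    for k, xy in enumerate(_infill_layers(spec, p)):
        z_layer = (k + 1) * spec.layer_thickness
        layer_pts: list[tuple[float, float, float]] = []
        prev = None
        for x, y in xy:
            if prev is not None:
                d = math.hypot(x - prev[0], y - prev[1])
                n_sub = max(1, int(math.ceil(d / segment_length)))
                for j in range(1, n_sub + 1):
                    xs = prev[0] + (x - prev[0]) * j / n_sub
                    ys = prev[1] + (y - prev[1]) * j / n_sub
                    layer_pts.append((xs, ys, z_layer + surf(xs, ys)))
            else:
                layer_pts.append((x, y, z_layer + surf(x, y)))
            prev = (x, y)
        layer_pts = _dedup(layer_pts)
        if not points:
            points.extend(layer_pts)
            kinds.extend(["print"] * (len(layer_pts) - 1))
        else:
            points.extend(layer_pts)
            kinds.append("travel")
            kinds.extend(["print"] * (len(layer_pts) - 1))
    points, kinds = _from_origin(points, kinds)
    path = Toolpath.from_points(
        points, kinds, feed=spec.feed, layer_thickness=spec.layer_thickness
    )
    zs = [pt[2] for pt in points]
    depth = max(zs) - min(zs)
    path.meta.update(
        kind="spherical_cap", pitch=p, n_layers=spec.n_layers,
        depth=depth, depth_warning=depth > MAX_NONPLANAR_DEPTH,
    )
    return path
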