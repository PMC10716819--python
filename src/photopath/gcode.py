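"""Reader/writer for the machine's G-code dialect.

The dialect is the LinuxCNC-flavoured subset the printing platform consumes:
linear motion only (``G0``/``G1`` with ``X Y Z F E`` words), ``;`` comments,
absolute coordinates (``G90``), and the custom ``M102 P<n>`` command that
selects the LED combination to switch on before the following move.

Conventions
-----------
* Feed ``F`` is mm/min on the wire and mm/s in memory.
* A ``G1`` line whose ``E`` word advances the (absolute) extruder axis is a
  print move; ``G0`` and non-extruding ``G1`` are travel moves.
* Arcs (``G2``/``G3``) and relative mode (``G91``) are rejected with an error
  naming the offending line: the upstream path planner emits linear
  segments only.
* ``M102`` lines are attached, as ``(next_move_index, code)`` pairs, to the
  move that follows them, and :func:`emit_gcode` writes them back the same
  way (command before motion). Consecutive duplicate codes are never
  emitted.
"""

from __future__ import annotations

import io
import re
from typing import Sequence, TextIO

import pandas as pd

from .toolpath import Move, Point3, Toolpath

__all__ = ["GCodeError", "parse_gcode", "emit_gcode", "read_csv", "write_csv"]

_WORD_RE = re.compile(r"([A-Za-z])\s*([-+]?[0-9]*\.?[0-9]+)")

#: G words accepted and ignored (units/mode boilerplate)
_IGNORED_G = {20, 21, 90, 94}


class GCodeError(ValueError):
    """Raised on unsupported or malformed G-code input."""


def _words(body: str, lineno: int) -> dict[str, float]:
    out: dict[str, float] = {}
    cursor = 0
    for m in _WORD_RE.finditer(body):
        if body[cursor : m.start()].strip():
            raise GCodeError(f"line {lineno}: cannot parse {body!r}")
        out[m.group(1).upper()] = float(m.group(2))
        cursor = m.end()
    if body[cursor:].strip():
        raise GCodeError(f"line {lineno}: cannot parse {body!r}")
    return out


def parse_gcode(text: str) -> Toolpath:
    """Parse a G-code document into a chained :class:`Toolpath`.

    The machine origin ``(0, 0, 0)`` is the implicit start position.
    ``M102 P<n>`` lines are preserved in ``Toolpath.meta["m102"]``.
    """
    pos = Point3(0.0, 0.0, 0.0)
    feed: float | None = None  # mm/s
    e_axis = 0.0
    moves: list[Move] = []
    m102: list[tuple[int, int]] = []

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split(";", 1)[0].strip()
        if not line:
            continue
        first = line[0].upper()
        if first == "M":
            w = _words(line, lineno)
            if int(w.get("M", -1)) == 102:
                if "P" not in w:
                    raise GCodeError(f"line {lineno}: M102 requires a P word")
                m102.append((len(moves), int(w["P"])))
            # other M codes (spindle, fans…) are outside the dialect: ignored
            continue
        if first != "G":
            raise GCodeError(f"line {lineno}: unsupported command {line!r}")
        w = _words(line, lineno)
        gnum = int(w["G"])
        if gnum in (2, 3):
            raise GCodeError(
                f"line {lineno}: arc move G{gnum} is not supported "
                "(linear segments only)"
            )
        if gnum == 91:
            raise GCodeError(
                f"line {lineno}: relative mode G91 is not supported "
                "(absolute coordinates assumed)"
            )
        if gnum in _IGNORED_G:
            continue
        if gnum not in (0, 1):
            raise GCodeError(f"line {lineno}: unsupported motion word G{gnum}")

        if "F" in w:
            if w["F"] <= 0:
                raise GCodeError(f"line {lineno}: non-positive feed")
            feed = w["F"] / 60.0  # mm/min -> mm/s
        new = Point3(w.get("X", pos.x), w.get("Y", pos.y), w.get("Z", pos.z))
        extruding = False
        if "E" in w:
            extruding = w["E"] > e_axis + 1e-12
            e_axis = w["E"]
        if new.dist(pos) <= 1e-12:
            continue  # feed/extruder-only line: modal state updated above
        kind = "print" if (gnum == 1 and extruding) else "travel"
        moves.append(Move(kind, pos, new, feed))
        pos = new

    return Toolpath(moves, meta={"m102": m102} if m102 else {})


def _fmt(v: float) -> str:
    return f"{v:.3f}"


def emit_gcode(
    path: Toolpath,
    commands: Sequence[tuple[int, int]] = (),
    header: str | None = None,
) -> str:
    """Serialize a toolpath, injecting ``M102 P<code>`` LED commands.

    ``commands`` is a list of ``(move_index, code)`` pairs; each command line
    is written immediately before the addressed move. An index equal to
    ``len(path)`` addresses the end of the document (trailing command).
    Consecutive duplicate codes are suppressed. Codes must lie in 0..9
    (1–8: LED combinations; 0: all off; 9: all on).
    """
    cmd_map: dict[int, int] = {}
    for idx, code in commands:
        if not 0 <= idx <= len(path.moves):
            raise ValueError(f"command addresses missing move {idx}")
        if not isinstance(code, int) or not 0 <= code <= 9:
            raise ValueError(f"LED code {code!r} outside 0..9")
        cmd_map[idx] = code

    lines: list[str] = []
    if header:
        lines.extend(f"; {h}" for h in header.splitlines())
    lines.append("G21 ; units: mm")
    lines.append("G90 ; absolute coordinates")

    # emitted (rounded) modal state
    cur = (_fmt(0.0), _fmt(0.0), _fmt(0.0))
    cur_feed: float | None = None
    e_axis = 0.0
    last_code: int | None = None

    for i, mv in enumerate(path.moves):
        if i in cmd_map and cmd_map[i] != last_code:
            lines.append(f"M102 P{cmd_map[i]}")
            last_code = cmd_map[i]
        new = (_fmt(mv.end.x), _fmt(mv.end.y), _fmt(mv.end.z))
        words = [
            f"{axis}{val}"
            for axis, val, old in zip("XYZ", new, cur)
            if val != old
        ]
        if not words:
            continue  # sub-resolution move, nothing to write
        if mv.kind == "print":
            e_axis += mv.length()
            words.append(f"E{e_axis:.4f}")
        if mv.feed is not None and mv.feed != cur_feed:
            words.append(f"F{_fmt(mv.feed * 60.0)}")
            cur_feed = mv.feed
        g = "G1" if mv.kind == "print" else "G0"
        lines.append(f"{g} " + " ".join(words))
        cur = new
    n = len(path.moves)
    if n in cmd_map and cmd_map[n] != last_code:
        lines.append(f"M102 P{cmd_map[n]}")
    return "\n".join(lines) + "\n"


def read_csv(source: str | TextIO) -> Toolpath:
    """Load a toolpath from ordered ``x,y,z[,kind]`` rows.

    Row *i*'s ``kind`` labels the segment ending at row *i* (the first
    row's kind, if any, is ignored); missing kinds default to print.
    """
    df = pd.read_csv(source)
    cols = {c.strip().lower(): c for c in df.columns}
    for req in ("x", "y", "z"):
        if req not in cols:
            raise ValueError(f"CSV is missing required column {req!r}")
    pts = df[[cols["x"], cols["y"], cols["z"]]].to_numpy(dtype=float)
    if "kind" in cols:
        kinds = [str(k).strip() for k in df[cols["kind"]].tolist()][1:]
    else:
        kinds = ["print"] * (len(pts) - 1)
    return Toolpath.from_points([tuple(p) for p in pts], kinds)


def write_csv(path: Toolpath, dest: str | TextIO | None = None) -> str:
    """Write the ordered coordinate list (inverse of :func:`read_csv`)."""
    rows = []
    if path.moves:
        first = path.moves[0].start
        rows.append((first.x, first.y, first.z, "print"))
        for m in path.moves:
            rows.append((m.end.x, m.end.y, m.end.z, m.kind))
    df = pd.DataFrame(rows, columns=["x", "y", "z", "kind"])
    if dest is None:
        buf = io.StringIO()
        df.to_csv(buf, index=False)
        return buf.getvalue()
    df.to_csv(dest, index=False)
    return ""
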