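"""Cure-depth model for in-printing photopolymerization.

The working-curve model of vat photopolymerization relates the depth of
cured material to the areal light exposure ``E``:

    C_d = D_p * ln(E / E_c)

where ``D_p`` (mm) is the resin's penetration depth and ``E_c`` (mJ/mm²)
its critical gelation energy. For 5% w/v GelMA + 0.5% w/v LAP cured at
405 nm, ``D_p = 0.61 mm`` and ``E_c = 0.48 mJ/mm²``.

For a light spot of diameter ``w_0`` scanning at speed ``v_s`` with optical
power ``P_L``, the exposure scales as ``P_L / (w_0 * v_s)``; the
dimensionless prefactor ``kappa`` absorbs the spot's irradiance profile and
dwell geometry. :func:`calibrate_kappa` solves ``kappa`` from a known
operating point of the physical device — the package default reproduces a
cure depth of 0.34 mm at the device's worst case (``w_0 = 20 mm``,
``v_s = 5 mm/s``, one couple at 60 mW), the shallowest curing the hardware
produces across its configuration envelope.

A print is verified by requiring ``C_d >= layer thickness`` on every
segment (:func:`check_cure_path`).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

from .scheduler import ALL_OFF, ALL_ON, DirectionSegment, SectorConvention
from .toolpath import Toolpath

__all__ = [
    "ResinParams",
    "SourceParams",
    "CureReport",
    "SegmentCure",
    "spot_diameter",
    "peak_exposure",
    "cure_depth",
    "calibrate_kappa",
    "check_cure_path",
    "DEFAULT_KAPPA",
]

#: slider travel limits of the LED carriage, mm above the substrate
MIN_DISTANCE = 1.0
MAX_DISTANCE = 15.0
#: measured spot diameters at the slider limits, mm
SPOT_AT_MIN = 10.0
SPOT_AT_MAX = 20.0

#: optical power of one LED couple (two 30 mW LEDs in parallel), mW
COUPLE_POWER_MW = 60.0

#: worst-case (shallowest-cure) operating point used for calibration:
#: max distance (w_0 = 20 mm), max printing speed 5 mm/s, one couple,
#: and the cure depth the device produces there, mm
WORST_CASE = {"P_L": COUPLE_POWER_MW, "w_0": SPOT_AT_MAX, "v_s": 5.0}
WORST_CASE_CURE_DEPTH = 0.34


@dataclass(frozen=True)
class ResinParams:
    """Working-curve parameters of the photoresin."""

    D_p: float = 0.61  # penetration depth, mm
    E_c: float = 0.48  # critical energy, mJ/mm^2

    def __post_init__(self) -> None:
        if not (self.D_p > 0 and self.E_c > 0):
            raise ValueError("resin parameters must be positive")


def spot_diameter(distance: float) -> float:
    """Spot diameter on the substrate, mm, for a slider distance in [1, 15].

    Linear between the measured endpoints: 10 mm at 1 mm distance, 20 mm at
    15 mm distance.
    """
    if not MIN_DISTANCE <= distance <= MAX_DISTANCE:
        raise ValueError(
            f"distance {distance} mm outside slider range "
            f"[{MIN_DISTANCE}, {MAX_DISTANCE}] mm"
        )
    frac = (distance - MIN_DISTANCE) / (MAX_DISTANCE - MIN_DISTANCE)
    return SPOT_AT_MIN + frac * (SPOT_AT_MAX - SPOT_AT_MIN)


def calibrate_kappa(
    resin: ResinParams | None = None,
    cure_depth_ref: float = WORST_CASE_CURE_DEPTH,
    P_L: float = WORST_CASE["P_L"],
    w_0: float = WORST_CASE["w_0"],
    v_s: float = WORST_CASE["v_s"],
) -> float:
    """Solve the exposure prefactor from one known (operating point, C_d) pair.

    Inverts ``C_d = D_p ln(kappa P_L / (w_0 v_s E_c))`` for ``kappa``.
    """
    resin = resin or ResinParams()
    return resin.E_c * math.exp(cure_depth_ref / resin.D_p) * w_0 * v_s / P_L


#: prefactor calibrated on the device's worst-case operating point
DEFAULT_KAPPA = calibrate_kappa()


@dataclass(frozen=True)
class SourceParams:
    """Optical source and scan parameters for one exposure condition."""

    P_L: float = COUPLE_POWER_MW  # active optical power, mW
    v_s: float = 5.0  # scanning (printing) speed, mm/s
    distance: float = MAX_DISTANCE  # LED-substrate distance, mm
    w_0: float | None = None  # spot diameter, mm; derived from distance
    kappa: float = DEFAULT_KAPPA  # dimensionless exposure prefactor

    def __post_init__(self) -> None:
        if self.P_L < 0 or self.v_s <= 0 or self.kappa <= 0:
            raise ValueError("source parameters must be positive (P_L >= 0)")
        if self.w_0 is None:
            object.__setattr__(self, "w_0", spot_diameter(self.distance))
        elif not self.w_0 > 0:
            raise ValueError("spot diameter must be positive")


def peak_exposure(src: SourceParams) -> float:
    """Areal exposure delivered to the deposited filament, mJ/mm²."""
    return src.kappa * src.P_L / (src.w_0 * src.v_s)


def cure_depth(resin: ResinParams, src: SourceParams) -> float:
    """Cure depth C_d = D_p ln(E/E_c), mm, clamped at 0 below gelation."""
    E = peak_exposure(src)
    if E <= 0:
        raise ValueError("exposure must be positive to evaluate the working curve")
    return max(0.0, resin.D_p * math.log(E / resin.E_c))


@dataclass(frozen=True)
class SegmentCure:
    move_index: int
    code: int
    n_couples: int
    v_s: float
    exposure: float  # mJ/mm^2
    cure_depth: float  # mm, clamped at 0
    cured: bool  # exposure reached gelation (E > E_c)
    passes: bool  # cure_depth >= layer thickness


@dataclass
class CureReport:
    """Per-segment curing verification of a scheduled toolpath."""

    layer_thickness: float
    segments: list[SegmentCure] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return all(s.passes for s in self.segments)

    @property
    def worst(self) -> SegmentCure | None:
        segs = self.segments
        return min(segs, key=lambda s: s.cure_depth) if segs else None

    def to_json(self) -> str:
        worst = self.worst
        return json.dumps(
            {
                "schema_version": 1,
                "layer_thickness_mm": self.layer_thickness,
                "passed": self.passed,
                "worst_move_index": None if worst is None else worst.move_index,
                "worst_cure_depth_mm": None if worst is None else worst.cure_depth,
                "segments": [vars(s) for s in self.segments],
            },
            indent=2,
        )

    def to_table(self) -> str:
        lines = [
            f"{'move':>5} {'code':>4} {'couples':>7} {'v_s':>6} "
            f"{'E':>8} {'C_d':>7} pass"
        ]
        for s in self.segments:
            lines.append(
                f"{s.move_index:>5} {s.code:>4} {s.n_couples:>7} "
                f"{s.v_s:>6.2f} {s.exposure:>8.3f} {s.cure_depth:>7.3f} "
                f"{'yes' if s.passes else 'NO'}"
            )
        return "\n".join(lines)


def _n_couples(code: int, conv: SectorConvention) -> int:
    if code == ALL_OFF:
        return 0
    if code == ALL_ON:
        return 4
    return 1 if conv.sector_for_code(code) % 2 == 0 else 2


def check_cure_path(
    path: Toolpath,
    schedule: list[DirectionSegment],
    resin: ResinParams | None = None,
    distance: float = MAX_DISTANCE,
    kappa: float = DEFAULT_KAPPA,
    conv: SectorConvention | None = None,
) -> CureReport:
    """Verify that every print segment cures through its layer.

    Diagonal segments are lit by two couples, doubling the active power;
    the scanning speed of a segment is its feed. A segment passes iff its
    cure depth reaches the path's layer thickness.
    """
    resin = resin or ResinParams()
    conv = conv or SectorConvention()
    if len(schedule) != len(path.moves):
        raise ValueError("schedule does not cover the path")
    w_0 = spot_diameter(distance)
    resolved = path.with_feeds_resolved()
    report = CureReport(layer_thickness=path.layer_thickness)
    for seg, mv in zip(schedule, resolved.moves):
        if mv.kind != "print":
            continue
        if mv.feed is None:
            raise ValueError(f"move {seg.move_index} has no feed (scanning speed)")
        n = _n_couples(seg.code, conv)
        src_power = n * COUPLE_POWER_MW if seg.code != ALL_ON else 4 * COUPLE_POWER_MW
        if n == 0:
            E, cd, cured = 0.0, 0.0, False
        else:
            src = SourceParams(
                P_L=src_power, v_s=mv.feed, distance=distance, kappa=kappa
            )
            E = peak_exposure(src)
            cured = E > resin.E_c
            cd = cure_depth(resin, src)
        report.segments.append(
            SegmentCure(
                move_index=seg.move_index,
                code=seg.code,
                n_couples=n,
                v_s=mv.feed,
                exposure=E,
                cure_depth=cd,
                cured=cured,
                passes=cd >= path.layer_thickness,
            )
        )
    return report
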