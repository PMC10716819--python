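"""Hardware configuration of the photo-cross-linking head.

One declarative object collects the device geometry (four 405 nm LED
couples at 90° around the needle, mounted 10.6 mm from it, on a slider
1–15 mm above the substrate), the optical power, the resin working-curve
parameters and the scheduling convention. It can be loaded from a TOML
file with top-level keys matching the field names.
"""

from __future__ import annotations

import tomllib
from pathlib import Path

from pydantic import BaseModel, Field, field_validator

from .cure import (
    COUPLE_POWER_MW,
    DEFAULT_KAPPA,
    MAX_DISTANCE,
    MIN_DISTANCE,
    ResinParams,
    SourceParams,
)
from .scheduler import SectorConvention

__all__ = ["HardwareConfig", "load_config"]

#: mechanical distance between each LED couple and the needle axis, mm
LED_OFFSET_MM = 10.6
#: default horizontal offset of a couple's light spot centre from the
#: needle, toward the couple's azimuth, mm (converging-beam model: the
#: beams are aimed at the deposition zone, so the spot lands just behind
#: the needle on the active side)
SPOT_CENTER_OFFSET_MM = 3.0


class HardwareConfig(BaseModel):
    """Device + resin parameters; all lengths mm, powers mW."""

    wavelength_nm: float = 405.0
    led_offset_mm: float = LED_OFFSET_MM
    spot_center_offset_mm: float = Field(default=SPOT_CENTER_OFFSET_MM, ge=0)
    slider_distance_mm: float = Field(
        default=MAX_DISTANCE, ge=MIN_DISTANCE, le=MAX_DISTANCE
    )
    couple_power_mW: float = Field(default=COUPLE_POWER_MW, gt=0)
    couple_azimuths: tuple[float, float, float, float] = (0.0, 90.0, 180.0, 270.0)
    code_map: tuple[int, int, int, int, int, int, int, int] = (1, 2, 3, 4, 5, 6, 7, 8)
    needle_radius_mm: float = Field(default=0.0, ge=0)
    D_p: float = Field(default=0.61, gt=0)
    E_c: float = Field(default=0.48, gt=0)
    kappa: float = Field(default=DEFAULT_KAPPA, gt=0)

    @field_validator("code_map")
    @classmethod
    def _bijective(cls, v: tuple[int, ...]) -> tuple[int, ...]:
        if sorted(v) != list(range(1, 9)):
            raise ValueError("code_map must be a bijection onto 1..8")
        return v

    def sector_convention(self) -> SectorConvention:
        return SectorConvention(
            code_map=self.code_map, couple_azimuths=self.couple_azimuths
        )

    def resin_params(self) -> ResinParams:
        return ResinParams(D_p=self.D_p, E_c=self.E_c)

    def source_params(self, v_s: float, n_couples: int = 1) -> SourceParams:
        return SourceParams(
            P_L=n_couples * self.couple_power_mW,
            v_s=v_s,
            distance=self.slider_distance_mm,
            kappa=self.kappa,
        )


def load_config(path: str | Path | None) -> HardwareConfig:
    """Load a :class:`HardwareConfig` from TOML (``None`` → defaults)."""
    if path is None:
        return HardwareConfig()
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    return HardwareConfig.model_validate(data)
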