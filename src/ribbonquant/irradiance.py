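"""Photodiode-to-flux calibration and CCD irradiance mapping.

The light path of the freezing chamber was characterized with a bare
photodiode behind a 5 %-transmission neutral-density filter; the diode
voltage maps to radiant flux through an affine calibration.  A CCD image
of the illumination spot (in arbitrary gray values) is turned into a
spatial irradiance map by distributing the measured total flux over the
background-subtracted gray values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import InvalidVoltage, NoSignal

__all__ = [
    "FluxCalibration",
    "IrradianceMap",
    "radiant_flux",
    "irradiance_map",
    "peak_irradiance",
]


@dataclass(frozen=True)
class FluxCalibration:
    """Affine photodiode calibration Φe(U) with an ND-filter factor.

    The printed calibration ``Φe(U) = 0.67 + 0.64 [mW/V] · U [V] · 20``
    is ambiguous about whether the ND factor (×20, for 5 % transmission)
    multiplies only the slope term (``literal``, left-to-right as
    printed) or the whole affine expression (``scaled_sum``).  Both are
    supported; ``literal`` is the default.
    """

    offset_mW: float = 0.67
    slope_mW_per_V: float = 0.64
    nd_factor: float = 20.0
    interpretation: Literal["literal", "scaled_sum"] = "literal"

    def __post_init__(self) -> None:
        if self.nd_factor <= 0:
            raise ValueError("nd_factor must be > 0")
        if self.interpretation not in ("literal", "scaled_sum"):
            raise ValueError(f"unknown interpretation {self.interpretation!r}")


@dataclass
class IrradianceMap:
    """Spatial flux map of the sample plane.

    ``pixel_flux`` holds mW per pixel; dividing by the pixel area
    (``pixel_pitch_mm``²) gives irradiance in mW/mm².
    """

    pixel_flux: np.ndarray
    pixel_pitch_mm: float
    total_flux_mW: float

    def __post_init__(self) -> None:
        self.pixel_flux = np.asarray(self.pixel_flux, dtype=float)
        if np.any(self.pixel_flux < 0):
            raise ValueError("pixel_flux must be non-negative")
        if self.total_flux_mW > 0 and not np.isclose(
            self.pixel_flux.sum(), self.total_flux_mW, rtol=1e-9, atol=0.0
        ):
            raise ValueError("sum(pixel_flux) must equal total_flux_mW")

    @property
    def irradiance_mW_mm2(self) -> np.ndarray:
        return self.pixel_flux / self.pixel_pitch_mm**2

    @property
    def centroid_px(self) -> tuple[float, float]:
        """Flux-weighted centroid (row, col) in pixel coordinates."""
        total = self.pixel_flux.sum()
        rows, cols = np.indices(self.pixel_flux.shape)
        return (
            float((rows * self.pixel_flux).sum() / total),
            float((cols * self.pixel_flux).sum() / total),
        )


def radiant_flux(U_volts: float, cal: FluxCalibration = FluxCalibration()) -> float:
    """Radiant flux (mW) from photodiode output voltage."""
    if U_volts < 0:
        raise InvalidVoltage(f"photodiode voltage must be >= 0, got {U_volts}")
    if cal.interpretation == "literal":
        return cal.offset_mW + cal.slope_mW_per_V * U_volts * cal.nd_factor
    return (cal.offset_mW + cal.slope_mW_per_V * U_volts) * cal.nd_factor


def irradiance_map(
    image: np.ndarray,
    background: float | np.ndarray,
    flux_mW: float,
    pixel_pitch_mm: float,
) -> IrradianceMap:
    """Distribute a measured radiant flux over a gray-value image.

    Gray values are background-subtracted (clipped at zero) and scaled so
    their sum equals ``flux_mW``; flux is conserved exactly.
    """
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise NoSignal("empty image")
    gv = np.clip(img - background, 0.0, None)
    total_gv = gv.sum()
    if total_gv <= 0:
        raise NoSignal("no gray value above background")
    pixel_flux = gv * (flux_mW / total_gv)
    return IrradianceMap(pixel_flux, pixel_pitch_mm, float(flux_mW))


def peak_irradiance(irr_map: IrradianceMap) -> float:
    """Peak irradiance (mW/mm²) of a map."""
    if irr_map.pixel_pitch_mm <= 0:
        raise ValueError("pixel_pitch_mm must be > 0")
    if irr_map.pixel_flux.size == 0:
        raise NoSignal("empty map")
    return float(irr_map.pixel_flux.max() / irr_map.pixel_pitch_mm**2)
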