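"""Optical characterization calculations for the fiber-bundle endoscope.

Covers the bench-side numbers that describe the instrument: theoretical and
shift-measured magnification, sample-plane pixel size, circular FOV area,
core density, the center-to-center spacing of an ideal hexagonal core
lattice, the Rayleigh diffraction limit, and FWHM measurement of intensity
profiles.  Rounding follows the reporting precision conventional for these
quantities (two decimals for magnification and spacing, three significant
figures for areas, nearest 10 nm for the diffraction limit).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "OpticalCalibration",
    "theoretical_magnification",
    "magnification_from_shift",
    "fov_area",
    "core_density",
    "hex_spacing",
    "rayleigh_resolution",
    "fwhm",
]


def _round_sig(x: float, sig: int) -> float:
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + sig - 1)


def theoretical_magnification(
    f_objective_mm: float, f_tube_mm: float, grin_magnification: float = 1.0
) -> float:
    """4f magnification f_tube / f_objective times |GRIN magnification|."""
    if f_objective_mm <= 0 or f_tube_mm <= 0:
        raise ValueError("focal lengths must be positive")
    return round(f_tube_mm / f_objective_mm * abs(grin_magnification), 2)


def magnification_from_shift(
    shift_um: float, dpx: tuple[float, float], camera_pixel_um: float
) -> tuple[float, float]:
    """Magnification and sample-plane pixel size from a calibrated stage
    shift: the sample moves ``shift_um`` and the image moves ``hypot(dpx)``
    camera pixels.  Returns ``(magnification, pixel_size_um)``."""
    if shift_um <= 0:
        raise ValueError("shift must be positive")
    d = math.hypot(*dpx)
    if d == 0:
        raise ValueError("zero pixel displacement")
    return d * camera_pixel_um / shift_um, shift_um / d


def fov_area(diameter_um: float) -> float:
    """Circular FOV area pi (D/2)^2 in um^2, to three significant figures."""
    if diameter_um <= 0:
        raise ValueError("diameter must be positive")
    return _round_sig(math.pi * (diameter_um / 2.0) ** 2, 3)


def core_density(area_um2: float, n_cores: int) -> float:
    """Area per core in um^2, to one decimal."""
    if n_cores < 1 or area_um2 <= 0:
        raise ValueError("need positive area and at least one core")
    return round(area_um2 / n_cores, 1)


def hex_spacing(n_cores: int, fov_diameter_um: float) -> float:
    """Center-to-center distance of an ideal hexagonal lattice of
    ``n_cores`` cores filling a circle of the given diameter.

    Hexagonal packing assigns each core an area of (sqrt(3)/2) d^2, so
    d = sqrt(2 A / (sqrt(3) N)); reported to two decimals.
    """
    if n_cores < 1:
        raise ValueError("need at least one core")
    area = math.pi * (fov_diameter_um / 2.0) ** 2
    return round(math.sqrt(2.0 * area / (math.sqrt(3.0) * n_cores)), 2)


def rayleigh_resolution(wavelength_nm: float, numerical_aperture: float) -> float:
    """Rayleigh diffraction limit 0.61 lambda / NA, to the nearest 10 nm."""
    if wavelength_nm <= 0 or numerical_aperture <= 0:
        raise ValueError("wavelength and NA must be positive")
    return round(0.61 * wavelength_nm / numerical_aperture, -1)


def fwhm(profile: np.ndarray, pixel_size_um: float = 1.0) -> float:
    """Full width at half maximum of a 1-D intensity profile.

    The half-maximum crossings on either side of the (unique) peak are
    located by linear interpolation between samples; the width between them
    is scaled by the pixel size.
    """
    v = np.asarray(profile, dtype=float).ravel()
    if len(v) < 3:
        raise ValueError("profile too short")
    peak = int(np.argmax(v))
    if peak == 0 or peak == len(v) - 1:
        raise ValueError("profile maximum must lie strictly inside")
    base = v.min()
    half = base + (v[peak] - base) / 2.0

    def cross(idx_range) -> float:
        prev = peak
        for i in idx_range:
            if v[i] < half:
                # interpolate between i and prev
                return i + (half - v[i]) / (v[prev] - v[i]) * (prev - i)
            prev = i
        raise ValueError("no half-maximum crossing on one side of the peak")

    left = cross(range(peak - 1, -1, -1))
    right = cross(range(peak + 1, len(v)))
    return (right - left) * pixel_size_um


@dataclass
class OpticalCalibration:
    """Bundle of instrument constants and the quantities derived from them."""

    f_objective_mm: float = 3.6
    f_tube_mm: float = 200.0
    grin_magnification: float = 1.0
    camera_pixel_um: float = 16.0
    numerical_aperture: float = 0.4
    wavelength_nm: float = 475.0
    fov_diameter_um: float = 147.5
    n_cores: int = 1460

    @property
    def magnification(self) -> float:
        return theoretical_magnification(
            self.f_objective_mm, self.f_tube_mm, self.grin_magnification
        )

    @property
    def pixel_size_um(self) -> float:
        return self.camera_pixel_um / self.magnification

    def report(self) -> dict[str, float]:
        area = fov_area(self.fov_diameter_um)
        return {
            "magnification": self.magnification,
            "pixel_size_um": self.pixel_size_um,
            "fov_area_um2": area,
            "um2_per_core": core_density(area, self.n_cores),
            "hex_spacing_um": hex_spacing(self.n_cores, self.fov_diameter_um),
            "rayleigh_limit_nm": rayleigh_resolution(
                self.wavelength_nm, self.numerical_aperture
            ),
        }
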