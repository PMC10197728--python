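"""Resolution metrology: USAF-1951 conversions, bar contrast, spectral resolution.

Spatial resolution is quantified against a USAF-1951 three-bar chart: element
``e`` of group ``g`` carries 2^(g + (e-1)/6) line pairs per mm, and the full
line-pair period in micrometers is 1000 over that frequency. A bar profile is
called resolvable when its Michelson contrast (Imax - Imin)/(Imax + Imin)
reaches the 0.4 threshold (ties count as resolvable).

Spectral resolution follows from the prism calibration: the smallest coded
feature spans ``feature_px`` (normally 2) camera pixels, so within a
calibrated band the resolution is ``feature_px`` times the local dispersion
in nm per pixel. Reported values are truncated (not rounded) to one decimal,
which is the convention the calibrated table is printed with.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import UndefinedContrastError
from .optics import DEFAULT_DISPERSION, DispersionModel

__all__ = [
    "USAFSpec",
    "ResolutionReport",
    "usaf_frequency",
    "frequency_to_period",
    "contrast",
    "is_resolvable",
    "spectral_resolution",
    "average_spectral_resolution",
    "resolution_report",
    "truncate_1dp",
]

#: Contrast threshold above which a bar pattern counts as resolved.
RESOLVABLE_CONTRAST = 0.4


def truncate_1dp(x: float) -> float:
    """Truncate toward zero at one decimal place (reporting convention)."""
    return math.trunc(x * 10.0) / 10.0


@dataclass(frozen=True)
class USAFSpec:
    """One element of a USAF-1951 resolution chart."""

    group: int
    element: int

    def __post_init__(self) -> None:
        if not 1 <= self.element <= 6:
            raise ValueError(f"USAF element must be in 1..6, got {self.element}")


def usaf_frequency(spec: USAFSpec) -> float:
    """Spatial frequency of a chart element in line pairs per mm."""
    return 2.0 ** (spec.group + (spec.element - 1) / 6.0)


def frequency_to_period(freq_lp_per_mm: float) -> float:
    """Full line-pair period in micrometers, truncated to one decimal."""
    if freq_lp_per_mm <= 0:
        raise ValueError(f"spatial frequency must be positive, got {freq_lp_per_mm}")
    return truncate_1dp(1000.0 / freq_lp_per_mm)


def contrast(profile) -> float:
    """Michelson contrast (Imax - Imin)/(Imax + Imin) of an intensity profile."""
    profile = np.asarray(profile, dtype=float)
    if profile.size == 0:
        raise UndefinedContrastError("contrast of an empty profile is undefined")
    if np.any(profile < 0):
        raise ValueError("intensity profile must be non-negative")
    hi, lo = float(profile.max()), float(profile.min())
    if hi + lo == 0:
        raise UndefinedContrastError("contrast of an all-zero profile is undefined")
    return (hi - lo) / (hi + lo)


def is_resolvable(c: float, threshold: float = RESOLVABLE_CONTRAST) -> bool:
    """True when the contrast reaches the threshold (ties are resolvable)."""
    if not 0.0 <= c <= 1.0:
        raise ValueError(f"contrast must lie in [0, 1], got {c}")
    return c >= threshold


def spectral_resolution(nm_per_pixel: float, feature_px: int = 2) -> float:
    """Spectral resolution: dispersion over one coded feature, to one decimal.

    With 2-pixel features this is double the pixel dispersion.
    """
    if nm_per_pixel < 0:
        raise ValueError("dispersion must be non-negative")
    if feature_px < 1:
        raise ValueError("feature_px must be >= 1")
    return truncate_1dp(feature_px * nm_per_pixel)


def average_spectral_resolution(
    table: list[tuple[float, float, float]],
) -> tuple[int, float]:
    """Bandwidth-weighted mean resolution over ``(start_nm, end_nm, res_nm)`` rows.

    Returns ``(rounded_nm, exact_nm)``; the headline figure is the integer.
    """
    if not table:
        raise ValueError("resolution table is empty")
    widths = np.array([end - start for start, end, _ in table], dtype=float)
    if widths.sum() <= 0:
        raise ValueError("total bandwidth must be positive")
    res = np.array([r for _, _, r in table], dtype=float)
    exact = float((widths * res).sum() / widths.sum())
    return int(math.floor(exact + 0.5)), exact


@dataclass(frozen=True)
class ResolutionReport:
    """System resolution summary derived from the dispersion calibration.

    ``bands`` rows are ``(start_nm, end_nm, nm_per_pixel, resolution_nm)``.
    Spatial resolutions are line-pair periods of the minimally resolvable
    chart elements along each axis.
    """

    bands: tuple[tuple[float, float, float, float], ...]
    horizontal_um: float
    vertical_um: float
    average_resolution_nm: int
    average_resolution_exact_nm: float
    contrast_threshold: float
    feature_px: int

    def to_dict(self) -> dict:
        return {
            "bands": [
                {
                    "range_nm": [start, end],
                    "nm_per_pixel": rate,
                    "spectral_resolution_nm": res,
                }
                for start, end, rate, res in self.bands
            ],
            "average_spectral_resolution_nm": self.average_resolution_nm,
            "average_spectral_resolution_exact_nm": self.average_resolution_exact_nm,
            "horizontal_resolution_um": self.horizontal_um,
            "vertical_resolution_um": self.vertical_um,
            "contrast_threshold": self.contrast_threshold,
            "feature_px": self.feature_px,
        }

    def to_text(self) -> str:
        lines = ["Wavelength-dependent spectral resolution"]
        for start, end, rate, res in self.bands:
            lines.append(f"  {start:.0f} nm - {end:.0f} nm   {rate:.2f} nm/pixel   {res:.1f} nm")
        lines += [
            f"Average spectral resolution: {self.average_resolution_nm} nm "
            f"({self.average_resolution_exact_nm:.2f} nm unrounded)",
            f"Spatial resolution: {self.horizontal_um:.1f} um (horizontal), "
            f"{self.vertical_um:.1f} um (vertical) at contrast >= {self.contrast_threshold}",
        ]
        return "\n".join(lines)


def resolution_report(
    model: DispersionModel = DEFAULT_DISPERSION,
    feature_px: int = 2,
    horizontal_limit: USAFSpec = USAFSpec(5, 6),
    vertical_limit: USAFSpec = USAFSpec(6, 1),
    threshold: float = RESOLVABLE_CONTRAST,
) -> ResolutionReport:
    """Build the full resolution report from a dispersion calibration.

    The spatial limits default to the minimally resolvable chart elements of
    the assembled system (group 5 element 6 and group 6 element 1).
    """
    bands = tuple(
        (start, end, rate, spectral_resolution(rate, feature_px))
        for start, end, rate in model.segments
    )
    avg, exact = average_spectral_resolution([(s, e, r) for s, e, _, r in bands])
    return ResolutionReport(
        bands=bands,
        horizontal_um=frequency_to_period(usaf_frequency(horizontal_limit)),
        vertical_um=frequency_to_period(usaf_frequency(vertical_limit)),
        average_resolution_nm=avg,
        average_resolution_exact_nm=exact,
        contrast_threshold=threshold,
        feature_px=feature_px,
    )
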