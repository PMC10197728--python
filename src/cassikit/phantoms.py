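"""Synthetic spectral scenes for end-to-end exercise of the imaging pipeline.

Three phantom families mirror the bench experiments the system is validated
on, so every stage (coding, dispersion, reconstruction, metrology) can be
tested without any measured data:

* ``rainbow_letter`` — a letter silhouette illuminated through a linear
  variable filter (LVF): each column carries a narrow Gaussian passband whose
  center sweeps linearly across the wavelength range.
* ``usaf`` — three-bar USAF-1951 chart elements (horizontal and vertical) at
  exact chart geometry (bar length five times bar width), spectrally flat
  under broadband illumination.
* ``eye`` — a fundus-like phantom: a smooth background with seeded random
  branching vessel-like curves carrying an absorbing spectrum, emulating a
  vasculature pattern painted on the back surface of a model eye.

All phantoms are non-negative and bit-reproducible under their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, special

from .errors import DimensionError, ResolutionError
from .metrology import USAFSpec, frequency_to_period, usaf_frequency
from .optics import SpectralDataCube

__all__ = [
    "PhantomConfig",
    "rainbow_letter",
    "usaf_cube",
    "eye_phantom",
    "generate",
    "field_average_spectrum",
    "uniform_bands",
    "GLYPHS",
]

# 5x7 bitmap glyphs, scaled up at render time
GLYPHS: dict[str, tuple[str, ...]] = {
    "A": ("01110", "10001", "10001", "11111", "10001", "10001", "10001"),
    "E": ("11111", "10000", "10000", "11110", "10000", "10000", "11111"),
    "H": ("10001", "10001", "10001", "11111", "10001", "10001", "10001"),
    "T": ("11111", "00100", "00100", "00100", "00100", "00100", "00100"),
    "W": ("10001", "10001", "10001", "10101", "10101", "11011", "10001"),
}


@dataclass(frozen=True)
class PhantomConfig:
    """Shared knobs for every phantom kind; unknown kinds are rejected.

    Wavelengths default to the system's 445-602 nm operating range; phantoms
    are laid on uniform bands unless explicit centers/edges are supplied to
    the generator.
    """

    kind: str = "eye"
    rows: int = 64
    cols: int = 64
    n_bands: int = 8
    lambda_min_nm: float = 445.0
    lambda_max_nm: float = 602.0
    seed: int = 0
    intensity: float = 1.0
    # rainbow-letter knobs
    letter: str = "A"
    lvf_fwhm_nm: float = 12.0
    # USAF knobs
    um_per_pixel: float = 5.8
    elements: tuple[tuple[int, int], ...] = ((5, 6), (6, 1))
    # eye-phantom knobs
    vessel_count: int = 3
    vessel_width_px: float = 3.0
    vessel_blur_px: float = 1.0
    background_reflectance: float = 0.6
    vessel_absorption: float = 0.7

    def __post_init__(self) -> None:
        if self.kind not in ("rainbow_letter", "usaf", "eye"):
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        if self.rows < 1 or self.cols < 1:
            raise DimensionError("phantom grid must be at least 1x1")
        if self.n_bands < 1:
            raise ValueError("phantom needs at least one band")
        if self.lambda_min_nm >= self.lambda_max_nm:
            raise ValueError("wavelength range is empty")
        if self.vessel_count < 0:
            raise ValueError("vessel count must be >= 0")


def uniform_bands(config: PhantomConfig) -> tuple[np.ndarray, np.ndarray]:
    """Uniform band centers and edges over the configured wavelength range."""
    edges = np.linspace(config.lambda_min_nm, config.lambda_max_nm, config.n_bands + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, edges


def _bands_or_uniform(config, band_centers_nm, band_edges_nm):
    if band_centers_nm is None or band_edges_nm is None:
        return uniform_bands(config)
    return np.asarray(band_centers_nm, float), np.asarray(band_edges_nm, float)


def _render_glyph(letter: str, rows: int, cols: int) -> np.ndarray:
    if letter not in GLYPHS:
        raise ValueError(f"no glyph for letter {letter!r}; available: {sorted(GLYPHS)}")
    bitmap = np.array([[int(c) for c in row] for row in GLYPHS[letter]], dtype=float)
    gh, gw = bitmap.shape
    scale = min(rows // gh, cols // gw)
    if scale < 1:
        raise DimensionError(f"glyph {letter!r} needs at least a {gh}x{gw} grid")
    big = np.kron(bitmap, np.ones((scale, scale)))
    out = np.zeros((rows, cols))
    r0 = (rows - big.shape[0]) // 2
    c0 = (cols - big.shape[1]) // 2
    out[r0 : r0 + big.shape[0], c0 : c0 + big.shape[1]] = big
    return out


def _gaussian_band_weights(
    center_nm: float, fwhm_nm: float, edges_nm: np.ndarray
) -> np.ndarray:
    """Exact integrals of a unit-mass Gaussian line over each band interval,
    renormalized to the mass falling inside the full range so every column's
    spectrum sums to one."""
    sigma = fwhm_nm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    z = (edges_nm - center_nm) / (sigma * math.sqrt(2.0))
    cdf = 0.5 * (1.0 + special.erf(z))
    mass = np.diff(cdf)
    total = mass.sum()
    if total <= 0:
        return np.zeros_like(mass)
    return mass / total


def rainbow_letter(
    config: PhantomConfig, band_centers_nm=None, band_edges_nm=None
) -> SpectralDataCube:
    """Letter silhouette under LVF rainbow illumination.

    Column x carries a Gaussian passband of FWHM ``lvf_fwhm_nm`` whose center
    sweeps linearly from ``lambda_min_nm`` (left edge) to ``lambda_max_nm``
    (right edge); each glyph pixel's spectrum integrates to ``intensity``.
    """
    centers, edges = _bands_or_uniform(config, band_centers_nm, band_edges_nm)
    glyph = _render_glyph(config.letter, config.rows, config.cols)
    sweep = np.linspace(
        config.lambda_min_nm, config.lambda_max_nm, config.cols
    )
    values = np.zeros((len(centers), config.rows, config.cols))
    for x, line_center in enumerate(sweep):
        col_mask = glyph[:, x]
        if not col_mask.any():
            continue
        w = config.intensity * _gaussian_band_weights(line_center, config.lvf_fwhm_nm, edges)
        values[:, :, x] = np.outer(w, col_mask)
    return SpectralDataCube(values, centers, edges).require_nonnegative()


def _three_bars(width_px: int, horizontal: bool) -> np.ndarray:
    """A USAF three-bar element: bars of the given width, length 5x width,
    separated by one bar width."""
    w = width_px
    length = 5 * w
    block = np.zeros((5 * w, length))
    for i in range(3):
        block[2 * i * w : (2 * i + 1) * w, :] = 1.0
    return block if horizontal else block.T


def usaf_cube(
    config: PhantomConfig, band_centers_nm=None, band_edges_nm=None
) -> SpectralDataCube:
    """USAF-1951 chart elements, identical in every band (broadband flat).

    For each requested ``(group, element)`` pair a horizontal and a vertical
    three-bar pattern is placed on the grid; the rendered bar width in pixels
    is ``period / 2 / um_per_pixel`` rounded to the nearest pixel and must be
    at least 1.
    """
    centers, edges = _bands_or_uniform(config, band_centers_nm, band_edges_nm)
    plane = np.zeros((config.rows, config.cols))
    x, y, row_h = 1, 1, 0
    for group, element in config.elements:
        period_um = frequency_to_period(usaf_frequency(USAFSpec(group, element)))
        width_px_exact = period_um / 2.0 / config.um_per_pixel
        width_px = int(round(width_px_exact))
        if width_px_exact < 1.0:
            raise ResolutionError(
                f"group {group} element {element}: bar width {width_px_exact:.2f} px "
                f"below one pixel at {config.um_per_pixel} um/px"
            )
        for horizontal in (True, False):
            block = _three_bars(width_px, horizontal)
            bh, bw = block.shape
            if x + bw + 1 > config.cols:  # wrap to the next row of elements
                x = 1
                y += row_h + 2
                row_h = 0
            if y + bh + 1 > config.rows or x + bw + 1 > config.cols:
                raise DimensionError(
                    f"elements do not fit the {config.rows}x{config.cols} grid"
                )
            plane[y : y + bh, x : x + bw] = block
            x += bw + 2
            row_h = max(row_h, bh)
    values = np.broadcast_to(
        config.intensity * plane, (len(centers), config.rows, config.cols)
    ).copy()
    return SpectralDataCube(values, centers, edges).require_nonnegative()


def _vessel_map(config: PhantomConfig) -> np.ndarray:
    """Binary occupancy of seeded random branching curves with tapering width."""
    rng = np.random.default_rng(config.seed)
    occ = np.zeros((config.rows, config.cols))
    yy, xx = np.mgrid[0 : config.rows, 0 : config.cols]

    def walk(y, x, theta, width, n_steps, depth):
        for step in range(n_steps):
            r = width * (1.0 - 0.6 * step / max(n_steps - 1, 1))  # taper
            occ[(yy - y) ** 2 + (xx - x) ** 2 <= r * r] = 1.0
            theta += rng.normal(0.0, 0.25)
            y += math.sin(theta)
            x += math.cos(theta)
            if not (0 <= y < config.rows and 0 <= x < config.cols):
                return
            if depth < 1 and step == n_steps // 2 and rng.random() < 0.7:
                walk(y, x, theta + rng.choice((-1.0, 1.0)) * 0.8,
                     0.7 * width, n_steps // 2, depth + 1)

    for _ in range(config.vessel_count):
        edge = rng.integers(4)
        if edge == 0:
            y, x, theta = 0.0, rng.uniform(0, config.cols), math.pi / 2
        elif edge == 1:
            y, x, theta = config.rows - 1.0, rng.uniform(0, config.cols), -math.pi / 2
        elif edge == 2:
            y, x, theta = rng.uniform(0, config.rows), 0.0, 0.0
        else:
            y, x, theta = rng.uniform(0, config.rows), config.cols - 1.0, math.pi
        theta += rng.normal(0.0, 0.3)
        walk(y, x, theta, config.vessel_width_px / 2.0,
             int(0.8 * max(config.rows, config.cols)), 0)
    return occ


def vessel_transmission_spectrum(config: PhantomConfig, centers_nm: np.ndarray) -> np.ndarray:
    """Smooth synthetic absorber peaking mid-band (paint-like, not hemoglobin)."""
    mid = 0.5 * (config.lambda_min_nm + config.lambda_max_nm)
    span = config.lambda_max_nm - config.lambda_min_nm
    sigma = span / 5.0
    return 1.0 - config.vessel_absorption * np.exp(
        -((centers_nm - mid) ** 2) / (2.0 * sigma**2)
    )


def eye_phantom(
    config: PhantomConfig, band_centers_nm=None, band_edges_nm=None
) -> SpectralDataCube:
    """Fundus-like phantom: smooth background plus absorbing vessel curves.

    Background pixels carry a spectrally flat reflectance modulated by a
    smooth spatial envelope; vessel pixels attenuate it with the synthetic
    absorption curve of :func:`vessel_transmission_spectrum`. The vessel map
    is rendered band-limited (Gaussian blur of ``vessel_blur_px``) because the
    relay optics pass no detail below the system's two-pixel coded-feature
    resolution; an aliased binary curve would contain structure no optical
    image carries. The field average of the returned cube is the exact
    coverage-weighted mix of the two constituent spectra, which reconstruction
    tests use as ground truth.
    """
    centers, edges = _bands_or_uniform(config, band_centers_nm, band_edges_nm)
    rng = np.random.default_rng(config.seed + 1)
    rough = rng.random((config.rows, config.cols))
    envelope = ndimage.gaussian_filter(rough, sigma=max(config.rows, config.cols) / 6.0)
    envelope = 0.85 + 0.3 * (envelope - envelope.min()) / max(
        float(np.ptp(envelope)), 1e-12
    )
    background = config.intensity * config.background_reflectance * envelope
    m = _vessel_map(config)
    if config.vessel_blur_px > 0:
        m = ndimage.gaussian_filter(m, config.vessel_blur_px)
    t = vessel_transmission_spectrum(config, centers)
    # values[k] = background * [(1 - m) + m * t_k]
    values = background[None, :, :] * ((1.0 - m)[None, :, :] + m[None, :, :] * t[:, None, None])
    return SpectralDataCube(values, centers, edges).require_nonnegative()


def field_average_spectrum(cube: SpectralDataCube) -> np.ndarray:
    """Mean spectrum over the full field of view, one value per band."""
    return cube.values.mean(axis=(1, 2))


def generate(config: PhantomConfig, band_centers_nm=None, band_edges_nm=None) -> SpectralDataCube:
    """Dispatch on ``config.kind``."""
    maker = {"rainbow_letter": rainbow_letter, "usaf": usaf_cube, "eye": eye_phantom}[
        config.kind
    ]
    return maker(config, band_centers_nm, band_edges_nm)
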