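"""Core optical domain types: spectral datacubes, coded masks, prism dispersion.

The scene is a discrete spectral datacube f[k, y, x] with L wavelength bands.
A binary coded mask T[y, x] modulates it identically in every band, and a prism
shears each band laterally (along +x) by the calibrated dispersion D(lambda).
The dispersion is represented piecewise-linearly: within each calibrated
segment the prism disperses at a constant rate (nm of wavelength per detector
pixel), so the pixel shift of a wavelength is the integral of 1/rate from the
zero-shift reference wavelength.

Coordinate convention: arrays are 0-based and indexed (band k, row y, col x);
dispersion displaces strictly along +x.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DimensionError, RangeError

__all__ = [
    "SpectralDataCube",
    "CodedMask",
    "DispersionModel",
    "SensorGeometry",
    "BandDiscretization",
    "DEFAULT_DISPERSION",
    "make_random_mask",
    "dispersion_shift",
    "discretize_bands",
]


@dataclass(frozen=True)
class SpectralDataCube:
    """A discrete spectral scene: ``values[k, y, x]`` over L wavelength bands.

    Parameters
    ----------
    values
        Real-valued grid of shape ``(L, rows, cols)``, arbitrary irradiance
        units. Physical scenes are non-negative (see ``require_nonnegative``);
        intermediate solver iterates may carry negative entries.
    band_centers_nm
        Strictly increasing band-center wavelengths, length L.
    band_edges_nm
        Increasing band-edge wavelengths, length L + 1; each center lies
        strictly inside its edge pair.
    """

    values: np.ndarray
    band_centers_nm: np.ndarray
    band_edges_nm: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        centers = np.asarray(self.band_centers_nm, dtype=float)
        edges = np.asarray(self.band_edges_nm, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "band_centers_nm", centers)
        object.__setattr__(self, "band_edges_nm", edges)
        if values.ndim != 3:
            raise DimensionError(f"cube values must be 3D (L, rows, cols), got {values.shape}")
        L = values.shape[0]
        if L < 1:
            raise DimensionError("cube must have at least one band")
        if centers.shape != (L,):
            raise DimensionError(f"expected {L} band centers, got {centers.shape}")
        if edges.shape != (L + 1,):
            raise DimensionError(f"expected {L + 1} band edges, got {edges.shape}")
        if not np.all(np.diff(centers) > 0):
            raise ValueError("band centers must be strictly increasing")
        if not np.all(np.diff(edges) > 0):
            raise ValueError("band edges must be strictly increasing")
        if not (np.all(edges[:-1] < centers) and np.all(centers < edges[1:])):
            raise ValueError("each band center must lie strictly inside its edges")

    @property
    def n_bands(self) -> int:
        return self.values.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.values.shape[1], self.values.shape[2]

    def with_values(self, values: np.ndarray) -> "SpectralDataCube":
        """Same band grid, new voxel values."""
        return SpectralDataCube(values, self.band_centers_nm, self.band_edges_nm)

    def require_nonnegative(self) -> "SpectralDataCube":
        if np.any(self.values < 0):
            raise ValueError("physical scene contains negative irradiance values")
        return self


@dataclass(frozen=True)
class CodedMask:
    """Binary coded-aperture transmission pattern T[y, x] in {0, 1}.

    ``feature_px`` is the side of the smallest coded feature in camera pixels
    (the system samples each mask feature with about 2x2 pixels); generated
    masks are constant on ``feature_px`` x ``feature_px`` blocks, measured
    masks need not be. ``seed`` records the RNG seed used at generation, if
    any.
    """

    values: np.ndarray
    feature_px: int = 2
    seed: int | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 2:
            raise DimensionError(f"mask must be 2D, got shape {values.shape}")
        if not np.isin(values, (0, 1)).all():
            raise ValueError("mask entries must all be 0 or 1")
        object.__setattr__(self, "values", values.astype(np.float64))
        if self.feature_px < 1:
            raise ValueError("feature_px must be >= 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def fill_fraction(self) -> float:
        return float(self.values.mean())


@dataclass(frozen=True)
class SensorGeometry:
    """Detector pixel grid; ``pixel_pitch_um`` is informational metadata."""

    rows: int
    cols: int
    pixel_pitch_um: float = 5.8

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise DimensionError("sensor must have at least one row and column")


@dataclass(frozen=True)
class DispersionModel:
    """Piecewise-linear prism dispersion calibration.

    ``segments`` is an ordered, contiguous list of
    ``(lambda_start_nm, lambda_end_nm, nm_per_pixel)`` with positive rates.
    ``shift(lam)`` integrates 1/nm_per_pixel from ``reference_nm`` (default
    445 nm, the shortest calibrated wavelength, which carries zero shift; any
    constant offset is absorbed into detector placement) and is therefore
    continuous and strictly increasing in wavelength.
    """

    segments: tuple[tuple[float, float, float], ...]
    reference_nm: float = 445.0

    def __post_init__(self) -> None:
        segs = tuple(tuple(float(v) for v in s) for s in self.segments)
        object.__setattr__(self, "segments", segs)
        if not segs:
            raise ValueError("dispersion model needs at least one segment")
        for start, end, rate in segs:
            if end <= start:
                raise ValueError(f"segment ({start}, {end}) is empty or reversed")
            if rate <= 0:
                raise ValueError("nm_per_pixel must be positive")
        for (_, end_a, _), (start_b, _, _) in zip(segs, segs[1:]):
            if not math.isclose(end_a, start_b, abs_tol=1e-9):
                raise ValueError("segments must be contiguous and non-overlapping")
        if not (segs[0][0] - 1e-9 <= self.reference_nm <= segs[-1][1] + 1e-9):
            raise RangeError("reference wavelength outside the calibrated range")

    @property
    def lambda_min_nm(self) -> float:
        return self.segments[0][0]

    @property
    def lambda_max_nm(self) -> float:
        return self.segments[-1][1]

    def _shift_from_min(self, lam: float, *, extrapolate: bool = False) -> float:
        # signed pixel displacement of `lam` relative to the calibrated minimum
        if not extrapolate and not (self.lambda_min_nm - 1e-9 <= lam <= self.lambda_max_nm + 1e-9):
            raise RangeError(
                f"wavelength {lam} nm outside calibrated range "
                f"[{self.lambda_min_nm}, {self.lambda_max_nm}] nm"
            )
        if lam < self.lambda_min_nm:  # extrapolate with the first segment's rate
            return (lam - self.lambda_min_nm) / self.segments[0][2]
        px = 0.0
        for start, end, rate in self.segments:
            if lam <= end:
                return px + (lam - start) / rate
            px += (end - start) / rate
        # beyond the last segment: extrapolate with its rate
        return px + (lam - self.lambda_max_nm) / self.segments[-1][2]

    def shift(self, lam: float) -> float:
        """Pixel shift of wavelength ``lam`` relative to ``reference_nm``."""
        return self._shift_from_min(lam) - self._shift_from_min(self.reference_nm)

    def inverse_shift(self, px: float, *, extrapolate: bool = False) -> float:
        """Wavelength whose shift relative to ``reference_nm`` equals ``px``."""
        target = px + self._shift_from_min(self.reference_nm)
        acc = 0.0
        if target < 0:
            if not extrapolate:
                raise RangeError(f"pixel shift {px} below the calibrated range")
            return self.lambda_min_nm + target * self.segments[0][2]
        for start, end, rate in self.segments:
            seg_px = (end - start) / rate
            if target <= acc + seg_px + 1e-12:
                return start + (target - acc) * rate
            acc += seg_px
        if not extrapolate:
            raise RangeError(f"pixel shift {px} above the calibrated range")
        return self.lambda_max_nm + (target - acc) * self.segments[-1][2]


#: Calibrated wavelength-dependent dispersion of the prism, measured with
#: monochromatic illumination over four spectral bands (nm per detector pixel).
DEFAULT_DISPERSION = DispersionModel(
    segments=(
        (445.0, 480.0, 1.67),
        (480.0, 510.0, 2.00),
        (510.0, 560.0, 2.50),
        (560.0, 602.0, 3.33),
    ),
    reference_nm=445.0,
)


def make_random_mask(
    rows: int, cols: int, feature_px: int = 2, fill: float = 0.5, seed: int = 0
) -> CodedMask:
    """Generate a random binary coded mask, block-constant on feature cells.

    Each ``feature_px x feature_px`` block is independently transparent (1)
    with probability ``fill``. The same seed always yields the same mask.
    """
    if rows % feature_px or cols % feature_px:
        raise DimensionError(
            f"mask dimensions ({rows}, {cols}) must be divisible by feature_px={feature_px}"
        )
    if not 0.0 <= fill <= 1.0:
        raise ValueError(f"fill fraction must lie in [0, 1], got {fill}")
    rng = np.random.default_rng(seed)
    blocks = (rng.random((rows // feature_px, cols // feature_px)) < fill).astype(np.float64)
    values = np.kron(blocks, np.ones((feature_px, feature_px)))
    return CodedMask(values=values, feature_px=feature_px, seed=seed)


def dispersion_shift(model: DispersionModel, lam: float) -> float:
    """Cumulative pixel shift of wavelength ``lam`` (nm), zero at the reference.

    No extrapolation: wavelengths outside the calibrated range raise
    :class:`~cassikit.errors.RangeError`.
    """
    return model.shift(lam)


@dataclass(frozen=True)
class BandDiscretization:
    """Band grid produced by :func:`discretize_bands`.

    Bands are spaced so consecutive band centers land exactly ``feature_px``
    detector pixels apart under the dispersion model, making every per-band
    shift an integer multiple of the smallest coded feature.
    """

    band_centers_nm: np.ndarray
    band_edges_nm: np.ndarray
    shifts: tuple[int, ...]
    feature_px: int

    @property
    def n_bands(self) -> int:
        return len(self.shifts)


def discretize_bands(
    model: DispersionModel, lambda_min_nm: float, lambda_max_nm: float, feature_px: int = 2
) -> BandDiscretization:
    """Discretize [lambda_min, lambda_max] into bands one coded feature apart.

    Band k is centered at the wavelength dispersed exactly ``k * feature_px``
    pixels past ``lambda_min_nm``; the band count is
    ``ceil(total_dispersion_px / feature_px)``. Band edges sit half a feature
    step either side of each center, mapped back through the inverse
    dispersion (the outermost edges extrapolate the boundary segment's rate by
    half a step so every center lies strictly inside its edges).
    """
    if feature_px < 1:
        raise ValueError("feature_px must be >= 1")
    if lambda_min_nm >= lambda_max_nm:
        raise ValueError("lambda_min must be below lambda_max")
    px_min = model.shift(lambda_min_nm)
    px_max = model.shift(lambda_max_nm)
    span_px = px_max - px_min
    if span_px < feature_px:
        raise ValueError(
            f"range [{lambda_min_nm}, {lambda_max_nm}] nm spans {span_px:.2f} px, "
            f"less than one {feature_px}-px feature step"
        )
    L = math.ceil(span_px / feature_px)
    center_px = px_min + feature_px * np.arange(L)
    edge_px = px_min + feature_px * (np.arange(L + 1) - 0.5)
    centers = np.array([model.inverse_shift(p) for p in center_px])
    edges = np.array([model.inverse_shift(p, extrapolate=True) for p in edge_px])
    shifts = tuple(int(feature_px * k) for k in range(L))
    return BandDiscretization(
        band_centers_nm=centers, band_edges_nm=edges, shifts=shifts, feature_px=feature_px
    )
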