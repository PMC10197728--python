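"""The CASSI measurement model as a matrix-free linear operator.

A single snapshot Y is the superposition of all spectral bands of the
mask-coded scene, each displaced along +x by its integer dispersion shift:

    Y[m, n] = sum_k T[m, n - d_k] . f[k, m, n - d_k] + g[m, n]

(zero outside the scene footprint; g is measurement noise). In vector form
y = Phi f + g. Because the mask is binary and the per-band shifts are
distinct, the Gram matrix Phi Phi^T is diagonal — its diagonal counts, at
each detector pixel, how many shifted mask copies are transparent there —
which is what makes the reconstruction's linear solves one-shot.

The detector is ``max(shifts)`` columns wider than the scene so no sheared
band falls off the edge; pixel integration is realized as discrete box
sampling with integer-pixel shifts (no sub-pixel splatting). Scene values may
be negative inside solver iterates; only phantom constructors enforce
non-negativity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DimensionError
from .optics import CodedMask, SpectralDataCube

__all__ = [
    "SensingOperator",
    "Measurement",
    "apply_mask",
    "forward",
    "adjoint",
    "gram_diagonal",
    "add_noise",
]


@dataclass(frozen=True)
class Measurement:
    """A 2D sensor snapshot on the detector grid.

    ``noise_sigma`` is the Gaussian noise standard deviation applied (0 for a
    noiseless simulation) and ``seed`` the RNG seed used, if any.
    """

    values: np.ndarray
    noise_sigma: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise DimensionError(f"measurement must be 2D, got shape {values.shape}")
        object.__setattr__(self, "values", values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class SensingOperator:
    """Matrix-free Phi: per-band +x shifts, mask modulation, band sum.

    Parameters
    ----------
    mask
        Binary coded mask, same spatial shape as the scene.
    shifts
        L non-negative, non-decreasing integer per-band pixel shifts d_k.
    scene_shape
        (rows, cols) of the scene grid.
    band_centers_nm, band_edges_nm
        Optional wavelength metadata attached to cubes produced by the
        adjoint; defaults to band indices.
    """

    mask: CodedMask
    shifts: tuple[int, ...]
    scene_shape: tuple[int, int]
    band_centers_nm: np.ndarray | None = None
    band_edges_nm: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "shifts", tuple(int(s) for s in self.shifts))
        if len(self.shifts) < 1:
            raise DimensionError("operator needs at least one band shift")
        if any(s < 0 for s in self.shifts):
            raise ValueError("band shifts must be non-negative")
        if any(b < a for a, b in zip(self.shifts, self.shifts[1:])):
            raise ValueError("band shifts must be non-decreasing")
        if self.mask.shape != tuple(self.scene_shape):
            raise DimensionError(
                f"mask shape {self.mask.shape} must equal scene shape {self.scene_shape}"
            )

    @property
    def n_bands(self) -> int:
        return len(self.shifts)

    @property
    def detector_shape(self) -> tuple[int, int]:
        rows, cols = self.scene_shape
        return rows, cols + max(self.shifts)

    def _band_grid(self) -> tuple[np.ndarray, np.ndarray]:
        if self.band_centers_nm is not None and self.band_edges_nm is not None:
            return np.asarray(self.band_centers_nm), np.asarray(self.band_edges_nm)
        L = self.n_bands
        return np.arange(L, dtype=float), np.arange(L + 1, dtype=float) - 0.5

    def cube_from_array(self, values: np.ndarray) -> SpectralDataCube:
        """Wrap a raw (L, rows, cols) array with this operator's band grid."""
        centers, edges = self._band_grid()
        return SpectralDataCube(values, centers, edges)


def apply_mask(cube: SpectralDataCube, mask: CodedMask) -> SpectralDataCube:
    """Modulate every band of the scene by the coded-aperture pattern."""
    if mask.shape != cube.spatial_shape:
        raise DimensionError(
            f"mask shape {mask.shape} does not match cube spatial shape {cube.spatial_shape}"
        )
    return cube.with_values(cube.values * mask.values[None, :, :])


def forward_array(op: SensingOperator, values: np.ndarray) -> np.ndarray:
    """Forward model on a raw (L, rows, cols) array; returns detector array."""
    values = np.asarray(values, dtype=float)
    L = op.n_bands
    rows, cols = op.scene_shape
    if values.shape != (L, rows, cols):
        raise DimensionError(
            f"expected cube of shape {(L, rows, cols)}, got {values.shape}"
        )
    y = np.zeros(op.detector_shape, dtype=float)
    T = op.mask.values
    for k, d in enumerate(op.shifts):
        y[:, d : d + cols] += T * values[k]
    return y


def forward(op: SensingOperator, cube: SpectralDataCube) -> Measurement:
    """Simulate the noiseless snapshot y = Phi f (add noise separately)."""
    return Measurement(values=forward_array(op, cube.values))


def adjoint_array(op: SensingOperator, y: np.ndarray) -> np.ndarray:
    """Adjoint Phi^T on a raw detector array; returns (L, rows, cols)."""
    y = np.asarray(y, dtype=float)
    if y.shape != op.detector_shape:
        raise DimensionError(
            f"expected measurement of shape {op.detector_shape}, got {y.shape}"
        )
    rows, cols = op.scene_shape
    T = op.mask.values
    out = np.empty((op.n_bands, rows, cols), dtype=float)
    for k, d in enumerate(op.shifts):
        out[k] = T * y[:, d : d + cols]
    return out


def adjoint(op: SensingOperator, y: Measurement) -> SpectralDataCube:
    """Exact transpose of :func:`forward`: un-shift, re-mask, stack bands."""
    return op.cube_from_array(adjoint_array(op, y.values))


def gram_diagonal(op: SensingOperator) -> np.ndarray:
    """diag(Phi Phi^T) as a detector-shaped map.

    At each detector pixel this counts the bands whose shifted mask copy is
    transparent there (the mask is binary, so squaring is a no-op). Off the
    diagonal Phi Phi^T vanishes identically.
    """
    rows, cols = op.scene_shape
    R = np.zeros(op.detector_shape, dtype=float)
    T = op.mask.values
    for d in op.shifts:
        R[:, d : d + cols] += T * T
    return R


def add_noise(y: Measurement, sigma: float, seed: int | None = None) -> Measurement:
    """Add i.i.d. zero-mean Gaussian noise of standard deviation ``sigma``."""
    if sigma < 0:
        raise ValueError(f"noise sigma must be non-negative, got {sigma}")
    if sigma == 0:
        return Measurement(values=y.values, noise_sigma=0.0, seed=seed)
    rng = np.random.default_rng(seed)
    noisy = y.values + rng.normal(0.0, sigma, size=y.values.shape)
    return Measurement(values=noisy, noise_sigma=float(sigma), seed=seed)
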