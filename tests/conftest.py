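"""Shared fixtures and the independent dense-matrix oracle.

``dense_phi`` materializes the sensing matrix entry-by-entry straight from
the discrete measurement formula Y[m, n] = sum_k T[m, n - d_k] f[k, m, n - d_k]
— it never calls the package's forward/adjoint code, so it can serve as an
independent reference for the matrix-free operator and the one-shot solves.
"""

import numpy as np
import pytest

from cassikit import CodedMask, SensingOperator, make_random_mask


def dense_phi(mask_values: np.ndarray, shifts, scene_shape) -> np.ndarray:
    """Dense Phi with rows indexed (m, n) raveled, columns (k, i, j) raveled."""
    rows, cols = scene_shape
    det_cols = cols + max(shifts)
    L = len(shifts)
    Phi = np.zeros((rows * det_cols, L * rows * cols))
    for k, d in enumerate(shifts):
        for i in range(rows):
            for j in range(cols):
                col_idx = (k * rows + i) * cols + j
                row_idx = i * det_cols + (j + d)
                Phi[row_idx, col_idx] = mask_values[i, j]
    return Phi


def make_operator(rows=8, cols=8, n_bands=4, feature_px=2, fill=0.5, seed=0, step=2):
    mask = make_random_mask(rows, cols, feature_px, fill, seed)
    shifts = tuple(step * k for k in range(n_bands))
    return SensingOperator(mask=mask, shifts=shifts, scene_shape=(rows, cols))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_op():
    """8x8 scene, 4 bands, 2-px shifts, 50% mask."""
    return make_operator()


@pytest.fixture
def tiny_op():
    """3x3 scene (padded 4x4 mask blocks are not needed at feature_px=1), L=2."""
    mask = CodedMask(np.array([[1, 0, 1], [0, 1, 1], [1, 1, 0]], dtype=float), feature_px=1)
    return SensingOperator(mask=mask, shifts=(0, 2), scene_shape=(3, 3))
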