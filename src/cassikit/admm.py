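"""Augmented-Lagrangian / ADMM reconstruction with a one-shot projection.

The datacube f is recovered from a single snapshot y = Phi f + g by
minimizing  Psi(f) + (gamma1/2)||y - Phi f - lam1/gamma1||^2  with variable
splitting f = v. Each ADMM iteration alternates

  1. a denoising step   v = prox_{Psi/gamma2}( f - lam2/gamma2 ),
  2. a data-consistency projection, the exact solve of
         f = (gamma2 I + gamma1 Phi^T Phi)^{-1}
             ( lam2 + gamma2 v + Phi^T (gamma1 y - lam1) ),
  3. multiplier updates  lam1 -= gamma1 (y - Phi f),  lam2 -= gamma2 (f - v).

Because Phi Phi^T is diagonal for a binary-mask CASSI operator, the
projection inverts the cube-sized system through the matrix-inversion lemma
with a single elementwise division on the detector grid — no iterative or
dense linear solver ever runs.

The denoiser is pluggable: the default is an anisotropic total-variation
proximal operator (channel-independent spatial TV, solved by projected
gradient on the dual); ``identity`` disables the prior, and ``external``
dispatches to any user-supplied callable honoring the prox contract, which
may consume the assembled guidance features (penalty map, shifted-mask stack,
Gram diagonal) that a learned denoiser would be conditioned on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .errors import ConfigurationError, DimensionError, NumericError
from .sensing import (
    Measurement,
    SensingOperator,
    adjoint_array,
    forward_array,
    gram_diagonal,
)
from .optics import SpectralDataCube

__all__ = [
    "ALState",
    "DenoiserSpec",
    "GuidanceFeatures",
    "IterationDiagnostics",
    "initialize_f0",
    "projection_step",
    "denoise_step",
    "guidance_features",
    "update_multipliers",
    "admm_reconstruct",
    "tv_prox",
    "total_variation",
    "psnr",
]


@dataclass(frozen=True)
class ALState:
    """One augmented-Lagrangian iterate.

    ``f`` and ``v`` are cube-shaped primal/auxiliary estimates; ``lam1``
    (detector-shaped) and ``lam2`` (cube-shaped) are the multipliers on the
    data term and the splitting; ``gamma1``/``gamma2`` the positive penalties.
    """

    f: np.ndarray
    v: np.ndarray
    lam1: np.ndarray
    lam2: np.ndarray
    gamma1: float
    gamma2: float
    iter: int = 0

    def __post_init__(self) -> None:
        if self.gamma1 <= 0 or self.gamma2 <= 0:
            raise ValueError("penalty parameters must be positive")
        if self.f.shape != self.v.shape or self.f.shape != self.lam2.shape:
            raise DimensionError("f, v and lam2 must share the cube shape")


@dataclass(frozen=True)
class DenoiserSpec:
    """Configuration of the prior's proximal operator.

    kind
        ``"tv"`` (anisotropic total variation, the default), ``"identity"``
        (no prior), or ``"external"`` (user callable in ``fn``).
    strength
        Prior weight; the effective prox parameter at penalty gamma2 is
        ``strength / gamma2``. Zero disables smoothing.
    max_inner_iters
        Dual projected-gradient iterations for the TV prox.
    spectral
        Also penalize gradients along the band axis (off by default).
    guidance_enabled
        Pass assembled :class:`GuidanceFeatures` to an external denoiser.
    """

    kind: str = "tv"
    strength: float = 0.2
    max_inner_iters: int = 40
    spectral: bool = False
    guidance_enabled: bool = False
    fn: Callable[..., np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("tv", "identity", "external"):
            raise ConfigurationError(f"unknown denoiser kind {self.kind!r}")
        if self.strength < 0:
            raise ValueError("denoiser strength must be non-negative")
        if self.kind == "tv" and self.max_inner_iters < 1:
            raise ValueError("tv denoiser needs max_inner_iters >= 1")
        if self.kind == "external" and self.fn is None:
            raise ConfigurationError("external denoiser requires a callable fn")


@dataclass(frozen=True)
class GuidanceFeatures:
    """System features a conditioned denoiser can be guided by.

    ``gamma_channel`` is the constant penalty map, ``shift_mask_stack`` the L
    shifted copies of the mask on the detector grid (a dense view of Phi's
    block structure), and ``gram_trace_map`` the per-pixel diagonal of
    Phi Phi^T.
    """

    gamma_channel: np.ndarray
    shift_mask_stack: np.ndarray
    gram_trace_map: np.ndarray


@dataclass
class IterationDiagnostics:
    """Per-iteration residual history of a reconstruction run."""

    data_residual: list[float] = field(default_factory=list)
    split_residual: list[float] = field(default_factory=list)

    def rows(self) -> list[dict[str, float]]:
        return [
            {"iter": i + 1, "data_residual": d, "split_residual": s}
            for i, (d, s) in enumerate(zip(self.data_residual, self.split_residual))
        ]


def _ratio_solve(
    op: SensingOperator, b: np.ndarray, gamma1: float, gamma2: float
) -> np.ndarray:
    """Solve (gamma2 I + gamma1 Phi^T Phi) x = b exactly in one shot.

    Matrix-inversion lemma with the diagonal Gram:
    x = (b - Phi^T [ Phi b / (gamma2/gamma1 + R) ]) / gamma2,  R = diag(PhiPhi^T).
    """
    if gamma1 <= 0 or gamma2 <= 0:
        raise ValueError("penalty parameters must be positive")
    R = gram_diagonal(op)
    z = forward_array(op, b) / (gamma2 / gamma1 + R)
    return (b - adjoint_array(op, z)) / gamma2


def initialize_f0(
    y: Measurement, op: SensingOperator, gamma1: float, gamma2: float
) -> np.ndarray:
    """Initial estimate f0 = (gamma2 I + gamma1 Phi^T Phi)^{-1} Phi^T y."""
    return _ratio_solve(op, adjoint_array(op, y.values), gamma1, gamma2)


def projection_step(state: ALState, y: Measurement, op: SensingOperator) -> np.ndarray:
    """Closed-form data-consistency projection (the f-update)."""
    b = state.lam2 + state.gamma2 * state.v + adjoint_array(
        op, state.gamma1 * y.values - state.lam1
    )
    return _ratio_solve(op, b, state.gamma1, state.gamma2)


def _gradients(u: np.ndarray, spectral: bool) -> list[np.ndarray]:
    g = [np.diff(u, axis=1, append=u[:, -1:, :]), np.diff(u, axis=2, append=u[:, :, -1:])]
    if spectral:
        g.append(np.diff(u, axis=0, append=u[-1:, :, :]))
    return g


def _grad_adjoint(p: list[np.ndarray], spectral: bool) -> np.ndarray:
    # transpose of the forward-difference gradient used in _gradients
    out = np.zeros_like(p[0])
    for pk, ax in zip(p, (1, 2, 0)):
        q = pk.copy()
        last = [slice(None)] * 3
        last[ax] = slice(-1, None)
        q[tuple(last)] = 0.0  # the padded last difference is always zero
        out -= np.diff(q, axis=ax, prepend=0.0)
    return out


def total_variation(u: np.ndarray, spectral: bool = False) -> float:
    """Anisotropic total variation: the l1 norm of forward differences."""
    return float(sum(np.abs(g).sum() for g in _gradients(u, spectral)))


def tv_prox(
    u: np.ndarray, tau: float, n_iters: int = 40, spectral: bool = False
) -> np.ndarray:
    """prox of tau * anisotropic TV: argmin_v tau*TV(v) + ||v - u||^2 / 2.

    Projected gradient on the dual (v = u - tau * D^T p with each dual
    component p clipped to [-1, 1]); the step 1/(4 * n_dirs * tau) respects
    the spectral-norm bound ||D D^T|| <= 4 * n_dirs of the forward-difference
    gradient, so the dual objective decreases monotonically.
    """
    if tau < 0:
        raise ValueError("tv prox weight must be non-negative")
    if tau == 0:
        return u.copy()
    n_dirs = 3 if spectral else 2
    p = [np.zeros_like(u) for _ in range(n_dirs)]
    coef = 1.0 / (4.0 * n_dirs * tau)
    v = u.copy()
    for _ in range(n_iters):
        g = _gradients(v, spectral)
        p = [np.clip(pk + coef * gk, -1.0, 1.0) for pk, gk in zip(p, g)]
        v = u - tau * _grad_adjoint(p, spectral)
    return v


def denoise_step(
    u: np.ndarray, spec: DenoiserSpec, guidance: GuidanceFeatures | None = None
) -> np.ndarray:
    """Solve the denoising subproblem v = prox_{Psi/gamma2}(u).

    ``u`` is the shifted iterate f - lam2/gamma2; the caller folds gamma2 into
    ``spec.strength`` (see :func:`admm_reconstruct`).
    """
    if spec.kind == "identity":
        return u.copy()
    if spec.kind == "tv":
        return tv_prox(u, spec.strength, spec.max_inner_iters, spec.spectral)
    if spec.kind == "external":
        if spec.guidance_enabled:
            return np.asarray(spec.fn(u, guidance))
        return np.asarray(spec.fn(u))
    raise ConfigurationError(f"unknown denoiser kind {spec.kind!r}")


def guidance_features(gamma2: float, op: SensingOperator) -> GuidanceFeatures:
    """Assemble the penalty map, shifted-mask stack, and Gram diagonal."""
    det = op.detector_shape
    rows, cols = op.scene_shape
    stack = np.zeros((op.n_bands,) + det, dtype=float)
    for k, d in enumerate(op.shifts):
        stack[k, :, d : d + cols] = op.mask.values
    return GuidanceFeatures(
        gamma_channel=np.full(det, float(gamma2)),
        shift_mask_stack=stack,
        gram_trace_map=gram_diagonal(op),
    )


def update_multipliers(state: ALState, y: Measurement, op: SensingOperator) -> ALState:
    """lam1 -= gamma1 (y - Phi f); lam2 -= gamma2 (f - v); bump the counter."""
    if y.values.shape != op.detector_shape:
        raise DimensionError("measurement shape does not match the operator")
    lam1 = state.lam1 - state.gamma1 * (y.values - forward_array(op, state.f))
    lam2 = state.lam2 - state.gamma2 * (state.f - state.v)
    return replace(state, lam1=lam1, lam2=lam2, iter=state.iter + 1)


def admm_reconstruct(
    y: Measurement,
    op: SensingOperator,
    spec: DenoiserSpec | None = None,
    n_iters: int = 50,
    gamma1: float = 1.0,
    gamma2: float = 1.0,
    schedule: float | None = None,
    clamp_nonneg: bool = False,
) -> tuple[SpectralDataCube, IterationDiagnostics]:
    """Run the full augmented-Lagrangian reconstruction.

    Parameters
    ----------
    spec
        Denoiser configuration (TV by default).
    n_iters
        Fixed iteration count; there is no tolerance-based early exit.
    gamma1, gamma2
        Initial penalties on the data term and the splitting.
    schedule
        Optional geometric penalty multiplier applied each iteration
        (``gamma_i = gamma * schedule**i``); ``None`` keeps them constant.
    clamp_nonneg
        Clip the final estimate at zero (after the last iteration only, so
        the projection algebra stays exact in between).

    Returns
    -------
    (cube, diagnostics)
        The reconstructed datacube and the per-iteration residual history
        ``||y - Phi f||_2`` and ``||f - v||_2``.
    """
    if n_iters < 1:
        raise ValueError("n_iters must be >= 1")
    if spec is None:
        spec = DenoiserSpec()
    guidance = (
        guidance_features(gamma2, op)
        if spec.kind == "external" and spec.guidance_enabled
        else None
    )
    f = initialize_f0(y, op, gamma1, gamma2)
    state = ALState(
        f=f,
        v=f.copy(),
        lam1=np.zeros(op.detector_shape),
        lam2=np.zeros_like(f),
        gamma1=gamma1,
        gamma2=gamma2,
    )
    diags = IterationDiagnostics()
    for i in range(n_iters):
        if schedule is not None:
            state = replace(
                state,
                gamma1=gamma1 * schedule**i,
                gamma2=gamma2 * schedule**i,
            )
        u = state.f - state.lam2 / state.gamma2
        inner_spec = (
            replace(spec, strength=spec.strength / state.gamma2)
            if spec.kind == "tv"
            else spec
        )
        v = denoise_step(u, inner_spec, guidance)
        state = replace(state, v=v)
        f = projection_step(state, y, op)
        state = replace(state, f=f)
        state = update_multipliers(state, y, op)
        if not np.all(np.isfinite(state.f)):
            raise NumericError(f"reconstruction diverged at iteration {i + 1}")
        diags.data_residual.append(
            float(np.linalg.norm(y.values - forward_array(op, state.f)))
        )
        diags.split_residual.append(float(np.linalg.norm(state.f - state.v)))
    out = state.f
    if clamp_nonneg:
        out = np.clip(out, 0.0, None)
    return op.cube_from_array(out), diags


def psnr(estimate: np.ndarray, truth: np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB, peak taken from the ground truth."""
    truth = np.asarray(truth, dtype=float)
    estimate = np.asarray(estimate, dtype=float)
    mse = float(np.mean((estimate - truth) ** 2))
    if mse == 0:
        return float("inf")
    peak = float(truth.max())
    return 10.0 * np.log10(peak**2 / mse)
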