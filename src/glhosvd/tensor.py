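"""Tensor-algebra primitives: mode-n unfolding, mode products, HOSVD.

The higher-order singular value decomposition (HOSVD, also known as the
Tucker decomposition with orthogonal factors) writes an order-N tensor as a
core tensor multiplied along each mode by an orthonormal factor matrix whose
columns are the left singular vectors of the corresponding mode-n unfolding.
Both denoising stages of the GL-HOSVD pipeline are built from these
primitives: decompose, hard-threshold the core, and invert.

Conventions
-----------
* Modes are 0-based, matching numpy axis numbering.
* ``unfold(T, n)`` moves mode ``n`` to the front and flattens the remaining
  modes in their original order using C (row-major) ordering.  ``fold`` is
  its exact inverse.  Any consistent column ordering yields the same
  denoising output; this one is fixed and used throughout.
* The full (non-truncated) HOSVD is always computed: every factor matrix is
  square.  Denoising comes solely from thresholding core coefficients, never
  from rank truncation.
* The sign of each singular vector is whatever the underlying LAPACK routine
  returns; callers must compare reconstructions or magnitudes, not raw
  factor entries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike, NDArray

__all__ = [
    "DWIStack",
    "HOSVDFactors",
    "unfold",
    "fold",
    "mode_product",
    "hosvd",
    "inverse_hosvd",
    "hard_threshold",
]


@dataclass
class DWIStack:
    """A stack of 2-D diffusion-weighted slices across Q encoding directions.

    The pixel data form an H x W x Q third-order tensor: one H x W magnitude
    image per diffusion-encoding direction (plus any b=0 volumes).
    Intensities are normalized so the noise-free peak is 1.0.

    Parameters
    ----------
    intensities
        Nonnegative float array of shape (H, W, Q).
    bvals
        Diffusion sensitization per volume, s/mm^2, length Q.
    bvecs
        Unit gradient direction per volume, shape (Q, 3); the zero vector
        for b=0 volumes.
    """

    intensities: NDArray[np.float64]
    bvals: NDArray[np.float64]
    bvecs: NDArray[np.float64]

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        self.bvals = np.atleast_1d(np.asarray(self.bvals, dtype=np.float64))
        self.bvecs = np.asarray(self.bvecs, dtype=np.float64)
        if self.intensities.ndim != 3:
            raise ValueError(
                f"intensities must be H x W x Q, got shape {self.intensities.shape}"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities contain non-finite values")
        if np.any(self.intensities < 0):
            raise ValueError("magnitude intensities must be nonnegative")
        q = self.intensities.shape[2]
        if self.bvals.shape != (q,):
            raise ValueError(
                f"bvals length {self.bvals.shape[0]} != number of volumes {q}"
            )
        if self.bvecs.shape != (q, 3):
            raise ValueError(
                f"bvecs must have shape ({q}, 3), got {self.bvecs.shape}"
            )
        norms = np.linalg.norm(self.bvecs, axis=1)
        nonzero = norms > 0
        if np.any(np.abs(norms[nonzero] - 1.0) > 1e-6):
            raise ValueError("nonzero gradient directions must be unit vectors")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape  # type: ignore[return-value]

    @property
    def n_directions(self) -> int:
        return self.intensities.shape[2]

    def with_intensities(self, intensities: ArrayLike) -> "DWIStack":
        """A copy of this stack carrying new pixel data, same gradient table."""
        return DWIStack(np.asarray(intensities), self.bvals.copy(), self.bvecs.copy())

    @property
    def b0_indices(self) -> NDArray[np.intp]:
        return np.flatnonzero(self.bvals == 0)


@dataclass
class HOSVDFactors:
    """Core tensor plus one square orthonormal factor matrix per mode."""

    core: NDArray[np.float64]
    factors: tuple[NDArray[np.float64], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(self.factors) != self.core.ndim:
            raise ValueError(
                f"{len(self.factors)} factors for an order-{self.core.ndim} core"
            )
        for n, f in enumerate(self.factors):
            if f.ndim != 2 or f.shape[0] != f.shape[1]:
                raise ValueError(f"factor {n} is not square: shape {f.shape}")
            if f.shape[0] != self.core.shape[n]:
                raise ValueError(
                    f"factor {n} size {f.shape[0]} != core dimension {self.core.shape[n]}"
                )

    @property
    def order(self) -> int:
        return self.core.ndim


def unfold(tensor: ArrayLike, mode: int) -> NDArray[np.float64]:
    """Mode-n matricization of a tensor.

    Rows are indexed by ``mode``; columns enumerate the remaining modes in
    their original order, row-major.
    """
    t = np.asarray(tensor, dtype=np.float64)
    if t.size == 0:
        raise ValueError("cannot unfold an empty tensor")
    if not 0 <= mode < t.ndim:
        raise ValueError(f"mode {mode} invalid for an order-{t.ndim} tensor")
    return np.moveaxis(t, mode, 0).reshape(t.shape[mode], -1)


def fold(matrix: ArrayLike, mode: int, shape: tuple[int, ...]) -> NDArray[np.float64]:
    """Inverse of :func:`unfold`: rebuild the tensor of the given shape."""
    m = np.asarray(matrix, dtype=np.float64)
    if not 0 <= mode < len(shape):
        raise ValueError(f"mode {mode} invalid for shape {shape}")
    moved = (shape[mode],) + tuple(s for i, s in enumerate(shape) if i != mode)
    return np.moveaxis(m.reshape(moved), 0, mode)


def mode_product(tensor: ArrayLike, matrix: ArrayLike, mode: int) -> NDArray[np.float64]:
    """n-mode product: multiply ``tensor`` by ``matrix`` along ``mode``.

    The output shape replaces the size of ``mode`` with the matrix row count.
    """
    t = np.asarray(tensor, dtype=np.float64)
    m = np.asarray(matrix, dtype=np.float64)
    if m.ndim != 2:
        raise ValueError("mode_product expects a 2-D matrix")
    if m.shape[1] != t.shape[mode]:
        raise ValueError(
            f"matrix has {m.shape[1]} columns but tensor mode {mode} has size "
            f"{t.shape[mode]}"
        )
    out_shape = list(t.shape)
    out_shape[mode] = m.shape[0]
    return fold(m @ unfold(t, mode), mode, tuple(out_shape))


def hosvd(tensor: ArrayLike) -> HOSVDFactors:
    """Full higher-order SVD of a real tensor.

    ``factors[n]`` holds all left singular vectors of the mode-n unfolding;
    the core is the tensor multiplied along every mode by the corresponding
    factor transpose.  The reconstruction ``core x_0 U0 x_1 U1 ...`` equals
    the input to machine precision.
    """
    t = np.asarray(tensor, dtype=np.float64)
    if not np.all(np.isfinite(t)):
        raise ValueError("tensor contains non-finite entries")
    factors = []
    for n in range(t.ndim):
        m = unfold(t, n)
        # Only the left singular vectors are needed; a fat unfolding already
        # yields a square U without forming the (huge) right basis.
        u = np.linalg.svd(m, full_matrices=m.shape[0] > m.shape[1])[0]
        factors.append(u)
    core = t
    for n, u in enumerate(factors):
        core = mode_product(core, u.T, n)
    return HOSVDFactors(core=core, factors=tuple(factors))


def inverse_hosvd(f: HOSVDFactors) -> NDArray[np.float64]:
    """Reconstruct a tensor from its (possibly thresholded) HOSVD factors."""
    out = f.core
    for n, u in enumerate(f.factors):
        out = mode_product(out, u, n)
    return out


def hard_threshold(core: ArrayLike, tau: float) -> NDArray[np.float64]:
    """Zero every core coefficient with magnitude strictly below ``tau``.

    Coefficients with ``|s| == tau`` are kept (the boundary belongs to the
    signal side).  ``tau = 0`` returns the input unchanged.
    """
    if tau < 0:
        raise ValueError(f"threshold must be nonnegative, got {tau}")
    c = np.asarray(core, dtype=np.float64)
    return np.where(np.abs(c) >= tau, c, 0.0)
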