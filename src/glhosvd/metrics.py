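"""Denoising quality metrics and diffusion parameter maps.

PSNR is computed in the peak-1 convention: for images normalized so the
noise-free peak is 1, PSNR = 10 log10(M / SSE) = -10 log10(MSE) over the M
pixels (a different peak may be supplied).  FA-RMSE is the root mean
squared difference between fractional-anisotropy maps derived from the
reference and estimated stacks.

The diffusion tensor is fit per pixel by ordinary least squares on the
log-signal,

    ln S(g, b) = ln S0 - b (Dxx gx^2 + Dyy gy^2 + Dzz gz^2
                            + 2 Dxy gx gy + 2 Dxz gx gz + 2 Dyz gy gz),

which is exact on noise-free mono-exponential data.  The apparent diffusion
coefficient is the standard two-point estimate between a low and a high
b-value, ADC = ln(S_low / S_high) / (b_high - b_low).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray

from .tensor import DWIStack

__all__ = [
    "QualityReport",
    "DiffusionTensorField",
    "ADCMap",
    "psnr",
    "fit_dti",
    "fa_rmse",
    "adc_map",
    "quality_report",
]


@dataclass(frozen=True)
class QualityReport:
    """PSNR and FA-RMSE of an estimated stack against a reference."""

    psnr_db: float
    fa_rmse: float
    m_pixels: int
    m_fa_pixels: int


@dataclass
class DiffusionTensorField:
    """Per-pixel diffusion tensor fit (units 1e-3 mm^2/s).

    ``eigenvalues`` are sorted descending and clamped at zero before the FA
    computation; ``mask`` is False where the fit was impossible (nonpositive
    signal at some volume).
    """

    tensor: NDArray[np.float64]  # (H, W, 3, 3)
    eigenvalues: NDArray[np.float64]  # (H, W, 3), lam1 >= lam2 >= lam3 >= 0
    fa: NDArray[np.float64]  # (H, W) in [0, 1]
    md: NDArray[np.float64]  # (H, W) mean diffusivity
    mask: NDArray[np.bool_]  # (H, W)


@dataclass
class ADCMap:
    """Two-point apparent diffusion coefficient map (1e-3 mm^2/s)."""

    adc: NDArray[np.float64]
    mask: NDArray[np.bool_]
    b_low: float
    b_high: float


def _as_array(x: DWIStack | NDArray[np.float64]) -> NDArray[np.float64]:
    return x.intensities if isinstance(x, DWIStack) else np.asarray(x, dtype=np.float64)


def psnr(
    reference: DWIStack | NDArray[np.float64],
    estimate: DWIStack | NDArray[np.float64],
    peak: float = 1.0,
) -> float:
    """Peak signal-to-noise ratio in dB.

    ``10 log10(peak^2 * M / ||estimate - reference||_2^2)`` over all M
    pixels.  Identical images give +inf.
    """
    ref = _as_array(reference)
    est = _as_array(estimate)
    if ref.shape != est.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {est.shape}")
    sse = float(np.sum((est - ref) ** 2))
    if sse == 0.0:
        return math.inf
    return 10.0 * math.log10(peak**2 * ref.size / sse)


def _design_matrix(bvals: NDArray[np.float64], bvecs: NDArray[np.float64]) -> NDArray[np.float64]:
    gx, gy, gz = bvecs[:, 0], bvecs[:, 1], bvecs[:, 2]
    b = bvals * 1e-3  # tensor expressed in 1e-3 mm^2/s
    return np.column_stack(
        [
            np.ones_like(b),
            -b * gx**2,
            -b * gy**2,
            -b * gz**2,
            -2 * b * gx * gy,
            -2 * b * gx * gz,
            -2 * b * gy * gz,
        ]
    )


def _fa_from_eigenvalues(lam: NDArray[np.float64]) -> NDArray[np.float64]:
    """FA = sqrt(3/2) ||lam - mean(lam)|| / ||lam||, 0 for the zero tensor."""
    norm = np.linalg.norm(lam, axis=-1)
    dev = np.linalg.norm(lam - lam.mean(axis=-1, keepdims=True), axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * dev / norm
    return np.where(norm > 0, fa, 0.0)


def fit_dti(stack: DWIStack) -> DiffusionTensorField:
    """Pixel-wise unweighted log-linear least-squares diffusion tensor fit.

    Requires at least 7 volumes including one b=0.  Pixels with any
    nonpositive signal are masked out (tensor zero, FA zero).
    """
    h, w, q = stack.shape
    if q < 7 or stack.b0_indices.size == 0:
        raise ValueError("DTI fit needs >= 7 volumes including a b=0 volume")
    a = _design_matrix(stack.bvals, stack.bvecs)
    signals = stack.intensities.reshape(-1, q)
    mask = np.all(signals > 0, axis=1)

    coeffs = np.zeros((signals.shape[0], 7))
    if mask.any():
        logs = np.log(signals[mask])
        coeffs[mask] = np.linalg.lstsq(a, logs.T, rcond=None)[0].T
    d = np.zeros((signals.shape[0], 3, 3))
    dxx, dyy, dzz, dxy, dxz, dyz = coeffs[:, 1], coeffs[:, 2], coeffs[:, 3], coeffs[:, 4], coeffs[:, 5], coeffs[:, 6]
    d[:, 0, 0], d[:, 1, 1], d[:, 2, 2] = dxx, dyy, dzz
    d[:, 0, 1] = d[:, 1, 0] = dxy
    d[:, 0, 2] = d[:, 2, 0] = dxz
    d[:, 1, 2] = d[:, 2, 1] = dyz

    lam = np.linalg.eigvalsh(d)[:, ::-1]  # descending
    lam = np.clip(lam, 0.0, None)
    fa = _fa_from_eigenvalues(lam)
    md = lam.mean(axis=-1)
    return DiffusionTensorField(
        tensor=d.reshape(h, w, 3, 3),
        eigenvalues=lam.reshape(h, w, 3),
        fa=fa.reshape(h, w),
        md=md.reshape(h, w),
        mask=mask.reshape(h, w),
    )


def fa_rmse(
    ref_fa: NDArray[np.float64],
    est_fa: NDArray[np.float64],
    root: bool = True,
) -> float:
    """Root mean squared difference between two FA maps.

    With ``root=False`` the plain mean squared difference is returned
    instead.
    """
    ref = np.asarray(ref_fa, dtype=np.float64)
    est = np.asarray(est_fa, dtype=np.float64)
    if ref.shape != est.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {est.shape}")
    mse = float(np.mean((est - ref) ** 2))
    return math.sqrt(mse) if root else mse


def adc_map(
    stack: DWIStack,
    b_low_index: int | None = None,
    b_high_index: int | None = None,
) -> ADCMap:
    """Two-point mono-exponential ADC map, in 1e-3 mm^2/s.

    ``ADC = ln(S_low / S_high) / (b_high - b_low)``, positive when the
    signal decays with b.  Volume indices default to the lowest and highest
    b-values in the stack.  Pixels with a nonpositive signal in either
    volume are masked (ADC set to NaN there).
    """
    if b_low_index is None:
        b_low_index = int(np.argmin(stack.bvals))
    if b_high_index is None:
        b_high_index = int(np.argmax(stack.bvals))
    b1 = float(stack.bvals[b_low_index])
    bn = float(stack.bvals[b_high_index])
    if bn == b1:
        raise ValueError("ADC needs two distinct b-values")
    if bn < b1:
        raise ValueError("b_high_index must point at the larger b-value")
    s1 = stack.intensities[..., b_low_index]
    sn = stack.intensities[..., b_high_index]
    mask = (s1 > 0) & (sn > 0)
    adc = np.full(s1.shape, np.nan)
    adc[mask] = np.log(s1[mask] / sn[mask]) / (bn - b1) * 1e3
    return ADCMap(adc=adc, mask=mask, b_low=b1, b_high=bn)


def quality_report(
    reference: DWIStack,
    estimate: DWIStack,
    ref_fa: NDArray[np.float64] | None = None,
) -> QualityReport:
    """PSNR plus FA-RMSE of an estimate against a noise-free reference.

    The reference FA map defaults to a DTI fit of the reference stack; pass
    the analytic ground truth when it is known.
    """
    p = psnr(reference, estimate)
    if ref_fa is None:
        ref_fa = fit_dti(reference).fa
    est_fa = fit_dti(estimate).fa
    return QualityReport(
        psnr_db=p,
        fa_rmse=fa_rmse(ref_fa, est_fa),
        m_pixels=reference.intensities.size,
        m_fa_pixels=int(np.asarray(ref_fa).size),
    )
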