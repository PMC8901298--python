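"""Two-stage GL-HOSVD denoising for multi-direction DWI slice stacks.

Stage 1 (global): the whole H x W x Q stack is treated as one third-order
tensor.  Its HOSVD core is hard-thresholded at the universal threshold
``q_global * sigma * sqrt(2 ln(H*W*Q))`` and the tensor is re-synthesized,
giving a prefiltered stack.

Stage 2 (local): for each reference patch position, spatially similar
m x m x Q blocks are collected by block matching *on the prefiltered image*
(so that grouping is not driven by noise) into a fourth-order m x m x Q x L
group.  The HOSVD basis of the prefiltered group is used to transform the
corresponding noisy group; the transform coefficients are hard-thresholded
at ``q_local * sigma * sqrt(2 ln(m*m*Q*L))`` and the group is re-synthesized.
Each pixel receives many estimates (it appears in many blocks of many
groups); they are averaged with per-group weights ``theta = 1/(1 + ||S||_0)``
where ``||S||_0`` counts the surviving core coefficients, so sparser (more
aggressively denoised) groups count more.

sigma is the noise standard deviation on the normalized intensity scale
(noise-free peak = 1) and is assumed known; :func:`estimate_sigma` is a
convenience estimator provided as an extension.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from numpy.typing import NDArray

from .tensor import DWIStack, HOSVDFactors, hard_threshold, hosvd, inverse_hosvd, mode_product

__all__ = [
    "DenoiseConfig",
    "BlockGroup",
    "universal_threshold",
    "global_stage",
    "block_distance",
    "find_similar_blocks",
    "denoise_group",
    "local_stage",
    "gl_hosvd",
    "estimate_sigma",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DenoiseConfig:
    """Tuning parameters for both denoising stages.

    Parameters
    ----------
    sigma
        Noise standard deviation on the normalized intensity scale.
    q_global, q_local
        Smoothness scalars multiplying the universal threshold in the
        global / local stage.  Larger values remove more coefficients.
    m
        Spatial block edge in pixels (blocks are m x m x Q).
    search_radius
        Half-width of the square search window around each reference
        position during block matching.
    tau_d
        Block-distance threshold (mean squared intensity difference per
        pixel).  ``None`` resolves to ``4 * sigma**2``.
    L_max
        Maximum number of similar blocks per group.
    n_step
        Sliding step between reference positions; the final row/column of
        positions is always included so every pixel is covered.
    """

    sigma: float
    q_global: float = 1.0
    q_local: float = 2.2
    m: int = 4
    search_radius: int = 8
    tau_d: float | None = None
    L_max: int = 16
    n_step: int = 2

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        if self.q_global <= 0 or self.q_local <= 0:
            raise ValueError("q_global and q_local must be positive")
        if self.m < 2:
            raise ValueError("block edge m must be at least 2")
        if not 1 <= self.n_step <= self.m:
            raise ValueError("n_step must satisfy 1 <= n_step <= m")
        if self.L_max < 1:
            raise ValueError("L_max must be at least 1")
        if self.tau_d is not None and self.tau_d < 0:
            raise ValueError("tau_d must be nonnegative")
        if self.search_radius < 1:
            raise ValueError("search_radius must be at least 1")

    @property
    def resolved_tau_d(self) -> float:
        """The distance threshold actually used (default 4*sigma^2)."""
        return 4.0 * self.sigma**2 if self.tau_d is None else self.tau_d


@dataclass
class BlockGroup:
    """A group of similar m x m x Q blocks, as a fourth-order tensor.

    ``noisy_group`` is drawn from the noisy image, ``guide_group`` from the
    prefiltered image; both have shape (m, m, Q, L).  ``coords`` are the
    top-left spatial corners of the member blocks (0-based), reference
    first.
    """

    noisy_group: NDArray[np.float64]
    guide_group: NDArray[np.float64]
    coords: NDArray[np.intp]
    ref_coord: tuple[int, int]

    def __post_init__(self) -> None:
        if self.noisy_group.shape != self.guide_group.shape:
            raise ValueError("noisy and guide groups must share a shape")
        if self.noisy_group.ndim != 4 or self.noisy_group.shape[3] < 1:
            raise ValueError("groups must be m x m x Q x L with L >= 1")
        if len(self.coords) != self.noisy_group.shape[3]:
            raise ValueError("coords length must equal group size L")
        if tuple(self.coords[0]) != tuple(self.ref_coord):
            raise ValueError("reference block must come first in coords")

    @property
    def L(self) -> int:
        return self.noisy_group.shape[3]


def universal_threshold(sigma: float, n_coeff: int, q: float) -> float:
    """Universal hard threshold ``q * sigma * sqrt(2 ln n_coeff)``.

    ``n_coeff`` is the number of transform coefficients (H*W*Q for the
    global stage, m*m*Q*L for a block group).  The logarithm is natural.
    """
    if n_coeff < 1:
        raise ValueError("n_coeff must be a positive integer")
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    if q <= 0:
        raise ValueError("q must be positive")
    return q * sigma * math.sqrt(2.0 * math.log(n_coeff))


def global_stage(noisy: DWIStack, cfg: DenoiseConfig) -> DWIStack:
    """Global HOSVD prefilter: decompose, threshold the core, re-synthesize.

    With ``sigma == 0`` the threshold is 0 and the output equals the input
    to machine precision.  Negative intensities after the inverse transform
    are clamped to 0 (magnitude data contract).
    """
    h, w, q = noisy.shape
    tau = universal_threshold(cfg.sigma, h * w * q, cfg.q_global)
    log.debug("global stage: tau_global=%.6g on %dx%dx%d stack", tau, h, w, q)
    f = hosvd(noisy.intensities)
    filtered = inverse_hosvd(HOSVDFactors(hard_threshold(f.core, tau), f.factors))
    return noisy.with_intensities(np.clip(filtered, 0.0, None))


def block_distance(a: NDArray[np.float64], b: NDArray[np.float64]) -> float:
    """Squared Euclidean distance between two blocks per pixel.

    ``||a - b||_2^2 / (m^2 Q)`` — the mean squared intensity difference over
    the m x m x Q block.  Symmetric; zero iff the blocks are identical.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"block shapes differ: {a.shape} vs {b.shape}")
    return float(np.mean((a - b) ** 2))


def _block_views(image: NDArray[np.float64], m: int) -> NDArray[np.float64]:
    """All m x m x Q blocks as a view of shape (H-m+1, W-m+1, Q, m, m)."""
    return sliding_window_view(image, (m, m), axis=(0, 1))


def find_similar_blocks(
    guide: DWIStack | NDArray[np.float64],
    ref_coord: tuple[int, int],
    cfg: DenoiseConfig,
    _views: NDArray[np.float64] | None = None,
) -> NDArray[np.intp]:
    """Coordinates of blocks similar to the reference, matched on the guide.

    Candidate blocks are those whose top-left corner lies in the square
    search window of half-width ``cfg.search_radius`` centered at
    ``ref_coord``, clipped to positions where the block fits inside the
    image.  Blocks at mean-squared distance <= tau_d are kept, sorted by
    ascending distance with ties broken by raster (row-major) order,
    truncated to ``cfg.L_max``; the reference block is always first.

    Returns an (L, 2) integer array of top-left corners.
    """
    image = guide.intensities if isinstance(guide, DWIStack) else np.asarray(guide)
    m = cfg.m
    h, w = image.shape[:2]
    i, j = ref_coord
    if not (0 <= i <= h - m and 0 <= j <= w - m):
        raise ValueError(f"reference block at {ref_coord} does not fit in {h}x{w}")
    views = _block_views(image, m) if _views is None else _views
    r0, r1 = max(0, i - cfg.search_radius), min(h - m, i + cfg.search_radius)
    c0, c1 = max(0, j - cfg.search_radius), min(w - m, j + cfg.search_radius)
    ref = views[i, j]
    window = views[r0 : r1 + 1, c0 : c1 + 1]
    dist = np.mean((window - ref) ** 2, axis=tuple(range(2, window.ndim)))
    flat = dist.ravel()  # raster order within the window
    kept = np.flatnonzero(flat <= cfg.resolved_tau_d)
    order = kept[np.argsort(flat[kept], kind="stable")]
    rows = r0 + order // dist.shape[1]
    cols = c0 + order % dist.shape[1]
    coords = np.column_stack([rows, cols])
    is_ref = (coords[:, 0] == i) & (coords[:, 1] == j)
    ref_pos = int(np.flatnonzero(is_ref)[0])  # distance 0, always kept
    coords = np.vstack([coords[ref_pos : ref_pos + 1], coords[~is_ref]])
    return coords[: cfg.L_max]


def extract_group(
    noisy: NDArray[np.float64],
    guide: NDArray[np.float64],
    coords: NDArray[np.intp],
    m: int,
) -> BlockGroup:
    """Assemble the (m, m, Q, L) noisy and guide group tensors at coords."""
    def gather(img: NDArray[np.float64]) -> NDArray[np.float64]:
        blocks = [img[a : a + m, b : b + m, :] for a, b in coords]
        return np.stack(blocks, axis=-1)

    return BlockGroup(
        noisy_group=gather(noisy),
        guide_group=gather(guide),
        coords=np.asarray(coords),
        ref_coord=tuple(coords[0]),
    )


def denoise_group(
    g: BlockGroup, cfg: DenoiseConfig
) -> tuple[NDArray[np.float64], int]:
    """Collaboratively filter one block group.

    The order-4 HOSVD basis is computed from the guide group; the noisy
    group is projected onto that basis, the coefficients are
    hard-thresholded at the local universal threshold, and the group is
    re-synthesized.  Returns the denoised group and the l0 count of
    surviving coefficients (used for the aggregation weight).
    """
    basis = hosvd(g.guide_group).factors
    coeffs = g.noisy_group
    for n, u in enumerate(basis):
        coeffs = mode_product(coeffs, u.T, n)
    tau = universal_threshold(cfg.sigma, coeffs.size, cfg.q_local)
    kept = hard_threshold(coeffs, tau)
    l0 = int(np.count_nonzero(kept))
    out = kept
    for n, u in enumerate(basis):
        out = mode_product(out, u, n)
    return out, l0


def _positions(extent: int, m: int, step: int) -> list[int]:
    """Top-left positions covering [0, extent-m], last position forced in."""
    pos = list(range(0, extent - m + 1, step))
    if pos[-1] != extent - m:
        pos.append(extent - m)
    return pos


def local_stage(noisy: DWIStack, guide: DWIStack, cfg: DenoiseConfig) -> DWIStack:
    """Guided local block-wise HOSVD denoising with weighted aggregation.

    Reference blocks slide over the image with step ``n_step``; each group
    of similar blocks is filtered by :func:`denoise_group`, and every pixel
    estimate is accumulated with the group weight
    ``theta = 1 / (1 + ||thresholded core||_0)``.  The output is the
    weighted mean per pixel; every pixel is covered by construction.
    """
    if noisy.shape != guide.shape:
        raise ValueError("noisy and guide stacks must share a shape")
    h, w, q = noisy.shape
    m = cfg.m
    if h < m or w < m:
        raise ValueError(f"image {h}x{w} is smaller than the {m}x{m} block")
    noisy_img = noisy.intensities
    guide_img = guide.intensities
    guide_views = _block_views(guide_img, m)

    numerator = np.zeros((h, w, q))
    weight_sum = np.zeros((h, w, q))
    for i in _positions(h, m, cfg.n_step):
        for j in _positions(w, m, cfg.n_step):
            coords = find_similar_blocks(guide, (i, j), cfg, _views=guide_views)
            group = extract_group(noisy_img, guide_img, coords, m)
            denoised, l0 = denoise_group(group, cfg)
            theta = 1.0 / (1.0 + l0)
            for k, (a, b) in enumerate(coords):
                numerator[a : a + m, b : b + m, :] += theta * denoised[..., k]
                weight_sum[a : a + m, b : b + m, :] += theta
    if np.any(weight_sum == 0):
        raise RuntimeError("aggregation left uncovered pixels")  # unreachable
    return noisy.with_intensities(np.clip(numerator / weight_sum, 0.0, None))


def gl_hosvd(noisy: DWIStack, cfg: DenoiseConfig) -> DWIStack:
    """Full two-stage pipeline: global prefilter, then guided local stage."""
    guide = global_stage(noisy, cfg)
    return local_stage(noisy, guide, cfg)


def estimate_sigma(stack: DWIStack) -> float:
    """Rough noise-level estimate from horizontal first differences.

    Extension beyond the core pipeline (which assumes sigma known): the
    median absolute deviation of horizontal pixel differences on the b=0
    volume (or the first volume if none), scaled to a Gaussian sigma.
    Edges inflate the estimate slightly; treat it as a starting point.
    """
    b0 = stack.b0_indices
    vol = stack.intensities[..., b0[0] if b0.size else 0]
    d = np.diff(vol, axis=1).ravel()
    mad = np.median(np.abs(d - np.median(d)))
    return float(1.4826 * mad / math.sqrt(2.0))
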