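"""Synthetic multi-direction DWI phantoms, Rician noise, and cohorts.

The phantom emulates what the denoising study measures: a 2-D slice whose
pixels carry region-wise diffusion tensors, imaged along Q quasi-uniform
gradient directions at a single shell (b = 1000 s/mm^2 by default) plus one
b=0 volume, with the single-tensor signal model

    S(g) = S0 * exp(-b * g^T D g).

Diffusion tensors are expressed in units of 1e-3 mm^2/s, so an isotropic
tensor with mean diffusivity 0.8 gives S/S0 = exp(-0.8) at b = 1000.
Magnitude noise is Rician: each pixel v becomes sqrt((v+n1)^2 + n2^2) with
n1, n2 Gaussian of standard deviation noise_level * peak.  Noise levels are
relative to the image peak (images are normalized to peak 1), in the range
0 to 0.1.

Also provided: a stroke phantom (concentric infarct core / penumbra /
normal-tissue ADC regions) and a simulated diagnostic cohort (binary
ground truth + imperfect modality calls) for exercising the
diagnostic-concordance statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.typing import NDArray

from .tensor import DWIStack

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "default_phantom_spec",
    "hemisphere_directions",
    "simulate_dwi",
    "add_rician_noise",
    "make_stroke_phantom",
    "simulate_adc_stack",
    "simulate_cohort",
]

# Region tensors of the default phantom, 1e-3 mm^2/s: isotropic background,
# a prolate ring (high FA), and an oblate core, giving both ADC and FA
# contrast across region boundaries.
_DEFAULT_TENSORS = {
    0: np.diag([0.8, 0.8, 0.8]),
    1: np.diag([1.7, 0.2, 0.2]),
    2: np.diag([1.2, 1.2, 0.3]),
}


@dataclass
class PhantomSpec:
    """Ground truth for a single-slice multi-direction DWI phantom.

    ``region_map`` labels each pixel; ``region_tensors`` maps each label to
    a symmetric positive-semidefinite 3x3 diffusion tensor (1e-3 mm^2/s).
    """

    region_map: NDArray[np.intp]
    region_tensors: dict[int, NDArray[np.float64]]
    s0: float = 1.0
    bval: float = 1000.0
    n_directions: int = 12
    noise_level: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.region_map = np.asarray(self.region_map, dtype=np.intp)
        if self.region_map.ndim != 2:
            raise ValueError("region_map must be 2-D")
        if not 0.0 <= self.noise_level <= 0.1:
            raise ValueError("noise_level must lie in [0, 0.1]")
        if self.n_directions < 6:
            raise ValueError("need Q >= 6 directions for a DTI-fittable phantom")
        labels = set(np.unique(self.region_map).tolist())
        missing = labels - set(self.region_tensors)
        if missing:
            raise ValueError(f"region_map labels without tensors: {sorted(missing)}")
        for label, d in self.region_tensors.items():
            d = np.asarray(d, dtype=np.float64)
            if d.shape != (3, 3) or not np.allclose(d, d.T, atol=1e-12):
                raise ValueError(f"tensor for region {label} is not symmetric 3x3")
            if np.linalg.eigvalsh(d).min() < -1e-12:
                raise ValueError(f"tensor for region {label} is not PSD")
            self.region_tensors[label] = d

    @property
    def shape(self) -> tuple[int, int]:
        return self.region_map.shape  # type: ignore[return-value]


def default_phantom_spec(
    shape: tuple[int, int] = (64, 64),
    n_directions: int = 12,
    bval: float = 1000.0,
    noise_level: float = 0.0,
    seed: int = 0,
) -> PhantomSpec:
    """Concentric-disk phantom: oblate core, prolate ring, isotropic background."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    r = np.hypot(yy - (h - 1) / 2.0, xx - (w - 1) / 2.0)
    region_map = np.zeros(shape, dtype=np.intp)
    region_map[r <= 0.35 * min(h, w)] = 1
    region_map[r <= 0.15 * min(h, w)] = 2
    return PhantomSpec(
        region_map=region_map,
        region_tensors={k: v.copy() for k, v in _DEFAULT_TENSORS.items()},
        bval=bval,
        n_directions=n_directions,
        noise_level=noise_level,
        seed=seed,
    )


def hemisphere_directions(q: int) -> NDArray[np.float64]:
    """Deterministic quasi-uniform unit vectors on the upper hemisphere.

    Golden-angle spiral: z is stratified over (0, 1], azimuth advances by
    the golden angle.  Antipodal symmetry of the DWI signal makes the
    hemisphere sufficient.
    """
    k = np.arange(q)
    z = (k + 0.5) / q
    phi = k * math.pi * (3.0 - math.sqrt(5.0))
    s = np.sqrt(1.0 - z**2)
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def _tensor_fa(d: NDArray[np.float64]) -> float:
    lam = np.clip(np.linalg.eigvalsh(d), 0.0, None)
    norm = np.linalg.norm(lam)
    if norm == 0:
        return 0.0
    return float(math.sqrt(1.5) * np.linalg.norm(lam - lam.mean()) / norm)


def simulate_dwi(
    spec: PhantomSpec,
) -> tuple[DWIStack, NDArray[np.float64], NDArray[np.float64]]:
    """Noise-free DWI stack plus analytic ground-truth FA and ADC images.

    The stack holds one b=0 volume followed by ``n_directions`` volumes at
    ``spec.bval``; the ground-truth ADC image is the mean diffusivity
    (trace/3) of each region tensor, in 1e-3 mm^2/s.
    """
    dirs = hemisphere_directions(spec.n_directions)
    bvals = np.concatenate([[0.0], np.full(spec.n_directions, spec.bval)])
    bvecs = np.vstack([np.zeros(3), dirs])

    h, w = spec.shape
    q = spec.n_directions + 1
    signal = np.empty((h, w, q))
    fa_truth = np.empty((h, w))
    adc_truth = np.empty((h, w))
    for label, d in spec.region_tensors.items():
        mask = spec.region_map == label
        if not mask.any():
            continue
        # b and D in reciprocal units: (s/mm^2) * (1e-3 mm^2/s) * 1e-3 is
        # dimensionless only after the 1e-3 tensor scale is applied.
        decay = np.exp(-spec.bval * 1e-3 * np.einsum("qi,ij,qj->q", dirs, d, dirs))
        signal[mask] = spec.s0 * np.concatenate([[1.0], decay])
        fa_truth[mask] = _tensor_fa(d)
        adc_truth[mask] = np.trace(d) / 3.0
    return DWIStack(signal, bvals, bvecs), fa_truth, adc_truth


def add_rician_noise(
    stack: DWIStack, noise_level: float, seed: int, peak: float | None = None
) -> DWIStack:
    """Corrupt a magnitude stack with Rician noise at a relative level.

    Each pixel v becomes sqrt((v + n1)^2 + n2^2) with n1, n2 i.i.d. Gaussian
    of standard deviation ``noise_level * peak``, where ``peak`` defaults to
    the stack maximum (1.0 for normalized phantoms).  noise_level = 0
    returns an identical copy.
    """
    if noise_level < 0:
        raise ValueError("noise_level must be nonnegative")
    if noise_level == 0:
        return stack.with_intensities(stack.intensities.copy())
    rng = np.random.default_rng(seed)
    sd = noise_level * (float(stack.intensities.max()) if peak is None else peak)
    n1 = rng.normal(0.0, sd, stack.shape)
    n2 = rng.normal(0.0, sd, stack.shape)
    noisy = np.hypot(stack.intensities + n1, n2)
    return stack.with_intensities(noisy)


def make_stroke_phantom(
    core_adc: float = 0.342,
    penumbra_adc: float = 0.803,
    normal_adc: float = 1.0,
    shape: tuple[int, int] = (64, 64),
    core_radius: float = 6.0,
    penumbra_radius: float = 14.0,
    seed: int = 0,
) -> tuple[NDArray[np.float64], dict[str, NDArray[np.bool_]]]:
    """Ground-truth ADC image of a stroke lesion with core/penumbra contrast.

    Concentric geometry: an infarct-core disk (strongly restricted
    diffusion) inside a penumbra annulus (moderately reduced ADC) inside
    normal tissue.  ADC values are in 1e-3 mm^2/s; the defaults are typical
    region means for acute infarct core and penumbra.  Returns the ADC
    image and disjoint boolean masks covering the image.
    """
    if not 0 < core_adc < penumbra_adc < normal_adc:
        raise ValueError("require 0 < core_adc < penumbra_adc < normal_adc")
    if core_radius > penumbra_radius:
        raise ValueError("core_radius must not exceed penumbra_radius")
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    r = np.hypot(yy - (h - 1) / 2.0, xx - (w - 1) / 2.0)
    core = r <= core_radius
    penumbra = (r <= penumbra_radius) & ~core
    normal = ~(core | penumbra)
    adc = np.full(shape, normal_adc)
    adc[penumbra] = penumbra_adc
    adc[core] = core_adc
    return adc, {"core": core, "penumbra": penumbra, "normal": normal}


def simulate_adc_stack(
    adc: NDArray[np.float64],
    b_low: float = 0.0,
    b_high: float = 1000.0,
    s0: float = 1.0,
) -> DWIStack:
    """Two-volume mono-exponential stack realizing a given ADC image.

    ``S(b) = s0 * exp(-b * ADC * 1e-3)`` with ADC in 1e-3 mm^2/s; used to
    turn a stroke-phantom ADC map into signal data an ADC fit can invert.
    """
    if b_high <= b_low:
        raise ValueError("b_high must exceed b_low")
    adc = np.asarray(adc, dtype=np.float64)
    low = s0 * np.exp(-b_low * 1e-3 * adc)
    high = s0 * np.exp(-b_high * 1e-3 * adc)
    bvecs = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
    if b_low == 0:
        bvecs[0] = 0.0
    return DWIStack(np.stack([low, high], axis=-1), [b_low, b_high], bvecs)


@dataclass
class CohortSpec:
    """Parameters of a simulated diagnostic cohort.

    Each patient truly has the target condition with probability
    ``prevalence``; the modality calls it with probability ``sens`` if
    present and rules it out with probability ``spec`` if absent.
    """

    n_patients: int
    prevalence: float
    sens_modality: float
    spec_modality: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be at least 1")
        for name in ("prevalence", "sens_modality", "spec_modality"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Per-patient ground truth and modality calls as a tidy table.

    Columns: ``patient_id``, ``truth`` (1 = condition present), ``call``
    (1 = modality flags it).  Deterministic given the seed.
    """
    rng = np.random.default_rng(spec.seed)
    truth = rng.random(spec.n_patients) < spec.prevalence
    call_if_pos = rng.random(spec.n_patients) < spec.sens_modality
    call_if_neg = rng.random(spec.n_patients) >= spec.spec_modality
    call = np.where(truth, call_if_pos, call_if_neg)
    return pd.DataFrame(
        {
            "patient_id": np.arange(spec.n_patients),
            "truth": truth.astype(int),
            "call": call.astype(int),
        }
    )
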