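# Methods

## The denoising model

Diffusion-weighted MR magnitude images are noisy, especially at high
b-values, and the noise propagates into every quantity derived from them
(ADC maps, tensor fits, FA maps).  A multi-direction acquisition is highly
redundant: the Q per-direction images of one slice share anatomy and differ
smoothly with gradient direction.  GL-HOSVD exploits that redundancy with a
transform-domain sparsity model in two stages.

**Global stage.**  The H×W×Q slice stack is treated as a single third-order
tensor Y and decomposed with the full (non-truncated) higher-order SVD,

    Y = S ×₁ O⁽¹⁾ ×₂ O⁽²⁾ ×₃ O⁽³⁾,

where O⁽ⁿ⁾ holds the left singular vectors of the mode-n unfolding and S is
the core.  Core coefficients are hard-thresholded at the universal
threshold

    τ_global = q_global · σ · √(2 ln(H·W·Q)),

the natural-log form of the classic "σ√(2 ln N)" cutoff under which the
maximum of N independent Gaussian coefficients falls below τ with high
probability.  The inverse transform yields the prefiltered stack X̄.
Denoising comes solely from thresholding; ranks are never truncated.

**Local stage.**  For each reference position on a sliding grid with step
`n_step` (final row/column forced in, so every pixel is covered), m×m×Q
blocks whose top-left corner lies in a square search window of half-width
`search_radius` are compared to the reference block by mean squared
intensity difference, **on the prefiltered image** — so that grouping is
driven by anatomy, not by noise.  Blocks at distance ≤ τ_d are kept,
sorted by distance (ties in raster order), truncated to L_max, reference
first.  The matched coordinates define two fourth-order m×m×Q×L groups:
G_p from the prefiltered image and G_n from the original noisy image.  The
HOSVD basis of G_p transforms G_n; the coefficients are thresholded at
τ_local = q_local·σ·√(2 ln(m·m·Q·L)); the group is re-synthesized.  Every
pixel estimate is aggregated with the per-group weight

    θ = 1 / (1 + ‖S̄‖₀),

the reciprocal of one plus the number of surviving coefficients, so groups
that compressed well (sparser, hence more reliably denoised) count more.
The output is the weighted mean, clamped at zero (magnitude data).

**Assumptions.**  σ is known, spatially uniform, and expressed on the
normalized intensity scale (noise-free peak = 1).  The thresholds are
Gaussian-derived but applied to Rician magnitude data without bias
correction; at the signal levels of the phantom (S/S0 ≥ exp(−1.7) ≈ 0.18
above an air-free background) the Rician bias is small compared to the
noise levels considered (≤ 0.1).  4-D volumes are denoised slice by slice:
the tensor model is per-slice by construction.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `sigma` | required | noise sd, peak-1 scale |
| `q_global` | 1.0 | global-stage threshold scale |
| `q_local` | 2.2 | local-stage threshold scale |
| `m` | 4 px | spatial block edge |
| `search_radius` | 8 px | half-width of the matching window |
| `tau_d` | 4σ² | block-distance cutoff (mean squared difference) |
| `L_max` | 16 | blocks per group |
| `n_step` | 2 px | reference-grid step |

The local stage re-estimates from the *noisy* data, so it tolerates a more
aggressive threshold scale than the global prefilter; hence
q_local > q_global.  τ_d = 4σ² admits blocks whose per-pixel squared
difference is a few noise variances — identical anatomy under noise — while
rejecting structurally different patches.  Smaller `n_step` improves
quality at linear cost in time; `n_step = 2` with `m = 4` gives 4-fold
block overlap in each axis.  A convenience σ estimator (scaled median
absolute deviation of horizontal first differences on the b=0 volume) is
provided as an extension; the pipeline itself treats σ as an input.

## The synthetic phantom

The default phantom is a 64×64 slice with three concentric regions, each
carrying one diffusion tensor (units 10⁻³ mm²/s): isotropic background
diag(0.8, 0.8, 0.8), a prolate ring diag(1.7, 0.2, 0.2) (FA ≈ 0.87), and an
oblate core diag(1.2, 1.2, 0.3) (FA ≈ 0.52).  Signals follow the
single-tensor model S = S0·exp(−b gᵀDg) at b = 1000 s/mm² along 12
golden-angle hemisphere directions plus one b=0 volume, S0 = 1.  Rician
noise is applied as √((v+n₁)² + n₂²) with n₁, n₂ Gaussian of sd equal to
noise_level × peak; noise levels span 0–0.1 of the peak.  Ground-truth FA
and mean-diffusivity maps are computed analytically from the region
tensors.

The stroke phantom is an ADC image with a concentric infarct-core disk
(0.342 ×10⁻³ mm²/s), penumbra annulus (0.803), and normal background (1.0)
— core and penumbra defaults are typical acute-infarct region means —
realized as a two-volume mono-exponential stack (b = 0 and 1000) when
signal data are needed.  The cohort simulator draws per-patient Bernoulli
ground truth at a given prevalence and imperfect modality calls at a given
sensitivity/specificity.

**What the phantom does not emulate:** partial-volume and CSF
contamination, spatially varying or correlated noise, EPI distortion,
motion, multi-compartment or crossing-fiber signal, and realistic cortical
geometry.  Passing tests therefore demonstrate correctness of the
algorithm and its expected qualitative behavior (two-stage > global-only >
noisy in PSNR; FA-RMSE reduction), not clinical performance on scanner
data.

## Metrics and maps

* **PSNR** = 10 log₁₀(peak²·M / SSE) with peak = 1 for normalized images;
  identical images report +inf.
* **FA-RMSE** = √(Σ(Ī_FA − I_FA)²/M_FA); the squared variant is available
  behind a flag (`root=False`).
* **DTI fit**: unweighted ordinary least squares on log-signals against the
  six tensor components plus ln S0 — exact on noise-free mono-exponential
  data; eigenvalues clamped at 0 before FA; pixels with nonpositive signal
  masked.  A weighted fit was considered and rejected: at the phantom's
  SNR the unweighted fit recovers truth to machine precision, and the
  simplest defensible estimator is preferred.
* **ADC** (two-point): ln(S_low/S_high)/(b_high − b_low), reported in
  10⁻³ mm²/s; standard ADC units (mm²/s) are used throughout even where
  source tables print mm³/s, an evident typo.

## Diagnostic concordance

Sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy (TP+TN)/N, and
Cohen's unweighted kappa (p_o − p_e)/(1 − p_e) with margin-product expected
agreement.  Interpretation bands: κ ≥ 0.75 quite satisfactory, 0.4–0.75
relatively satisfactory, < 0.4 not ideal.  Percentages are rounded to two
decimals where published tables are reproduced; raw proportions are
retained.

The bundled denoised-DWI reference table is internally inconsistent: its
cells sum to 87 gold-positives and 103 patients, while its printed
marginals say 89 and 105.  The published sensitivity (88.76% = 79/89) and
accuracy (87.62% = 92/105) follow the printed marginals; the cells give
90.80% and 89.32%.  `ConfusionTable` keeps the cells as ground truth,
exposes both readings (`use_printed_marginal` / `use_printed_total`), and
reports the discrepancies via `marginal_report()` instead of resolving
them.  The agreement values published alongside these tables (0.35 and
0.52) do not recompute from either reading under Cohen's formula (the
cells give ≈ 0.06 and ≈ 0.64); the kappa implementation is therefore
validated by its defining properties (1 on perfect agreement, 0 on
independence, direct-formula oracle on random tables) rather than against
those figures.

The penumbra-calling rule (`call_penumbra`) is a deliberately simple
ADC-band heuristic — lesion flagged when it contains a sub-threshold core
plus at least a minimum count of pixels in an intermediate ADC band — used
to close the loop from image to binary call in simulations; it is not a
validated clinical criterion.

## Numerical choices

* Unfolding uses row-major column ordering with the mode moved first; any
  consistent convention gives identical denoising output, and one is fixed
  package-wide.
* Singular-vector signs are unconstrained (LAPACK's choice); all
  comparisons are on reconstructions or magnitudes.
* Hard threshold keeps coefficients with |s| **≥** τ (boundary kept).
* Block-distance ties during matching are broken by raster order; the
  reference block is always first in its group.
* Reference-block positions are clipped to keep blocks inside the image;
  the final row/column of positions is always included, guaranteeing every
  pixel at least one estimate.
* Negative intensities after inverse transforms are clamped to 0.
* Degenerate inputs: an all-zero tensor decomposes to a zero core with an
  arbitrary orthonormal basis (reconstruction is still exact); σ = 0 makes
  both thresholds 0 and the whole pipeline an identity to ~1e-12.

## Problem sizes

The packaged benchmark uses a 64×64 slice with 12 directions + b=0
(one denoising run ≈ 2–3 s), three noise levels {0.02, 0.05, 0.1}, and a
100 000-patient simulated cohort — sizes at which every qualitative claim
the tests check is stable across seeds while the whole suite stays fast.

## Known limitations

* σ must be supplied (or estimated externally); no spatially varying noise
  model.
* No Rician bias correction inside the denoiser; at very low SNR (signal
  ≈ σ) the magnitude floor biases both the denoised image and ADC/FA
  estimates.
* Slice-wise processing ignores through-plane redundancy.
* The DTI fit is single-tensor; crossing fibers alias into lower FA.
* Runtime grows linearly in reference positions (quadratically in image
  edge at fixed step); no parallelization is attempted.
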