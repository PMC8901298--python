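# glhosvd

Two-stage **global/local HOSVD denoising** for multi-direction
diffusion-weighted MRI (DWI), with the evaluation stack that goes with it:
synthetic DWI phantoms with Rician noise, PSNR and FA-RMSE quality
metrics, DTI and ADC parameter maps, and diagnostic-concordance statistics
(sensitivity, specificity, accuracy, Cohen's κ) for penumbra detection
against a gold standard.

It is written for researchers working on diffusion MRI preprocessing —
e.g. sharpening DWI/ADC reads of the ischemic penumbra in early cerebral
infarction — who need a reproducible, testable implementation of the
algorithm and its benchmark machinery.

## The algorithm

A slice acquired along Q diffusion directions is the third-order tensor
Y ∈ ℝ^{H×W×Q}.  **Stage 1 (global prefilter)** computes the full HOSVD

    Y = S ×₁ O⁽¹⁾ ×₂ O⁽²⁾ ×₃ O⁽³⁾,

hard-thresholds the core at the universal threshold
τ = q_global·σ·√(2 ln(H·W·Q)), and inverts the transform.  **Stage 2
(guided local filtering)** matches m×m×Q blocks *on the prefiltered image*
into fourth-order m×m×Q×L groups of similar blocks, projects the
corresponding noisy groups onto the HOSVD basis of the prefiltered groups,
thresholds at τ = q_local·σ·√(2 ln(m·m·Q·L)), re-synthesizes, and averages
the many per-pixel estimates with weights θ = 1/(1+‖S̄‖₀).  Grouping on the
prefiltered image keeps block matching from chasing noise; the weights
favor groups whose transform compressed well.

See `docs/methods.md` for assumptions, parameter rationale, and what the
phantom does and does not emulate.

## Worked example

```python
from glhosvd import (DenoiseConfig, add_rician_noise, default_phantom_spec,
                     simulate_dwi, gl_hosvd, global_stage, psnr, fit_dti, fa_rmse)

spec = default_phantom_spec(shape=(64, 64), n_directions=12, seed=7)
clean, fa_truth, _ = simulate_dwi(spec)                    # 12 dirs + b=0, b=1000
noisy = add_rician_noise(clean, noise_level=0.05, seed=21)  # 5% Rician noise

cfg = DenoiseConfig(sigma=0.05)
denoised = gl_hosvd(noisy, cfg)

print(f"PSNR noisy    : {psnr(clean, noisy):.2f} dB")
print(f"PSNR global   : {psnr(clean, global_stage(noisy, cfg)):.2f} dB")
print(f"PSNR GL-HOSVD : {psnr(clean, denoised):.2f} dB")
print(f"FA-RMSE noisy   : {fa_rmse(fa_truth, fit_dti(noisy).fa):.4f}")
print(f"FA-RMSE denoised: {fa_rmse(fa_truth, fit_dti(denoised).fa):.4f}")
```

Output:

```
PSNR noisy    : 26.05 dB
PSNR global   : 35.90 dB
PSNR GL-HOSVD : 39.40 dB
FA-RMSE noisy   : 0.1414
FA-RMSE denoised: 0.0284
```

The global prefilter alone gains ~10 dB over the noisy input; the guided
local stage adds another ~3.5 dB, and the FA error of the tensor fit drops
five-fold — the expected ordering at every noise level in 0.02–0.1.

The same pipeline is available from the shell (`glhosvd phantom`,
`glhosvd denoise`, `glhosvd metrics`, `glhosvd adc`), and the
concordance statistics directly:

```
$ glhosvd diagnose --table 52,7,38,8
{
  "tp": 52, "fp": 7, "fn": 38, "tn": 8,
  "sensitivity_pct": 57.78,
  "specificity_pct": 53.33,
  "accuracy_pct": 57.14,
  "kappa": 0.0597,
  "kappa_interpretation": "not ideal"
}
```

Here sensitivity = TP/(TP+FN) = 52/90, specificity = TN/(TN+FP) = 8/15,
accuracy = 60/105, and κ is Cohen's chance-corrected agreement between the
modality and the gold standard.

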