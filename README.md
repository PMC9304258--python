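# eedn — edge-enhancement denoising for low-dose X-ray fluoroscopy

Low-dose X-ray fluoroscopy keeps radiation exposure down during cardiac
catheterisation procedures, at the price of strong quantum (Poisson) noise
that can obscure catheters, guidewires and anatomical borders.  This
package implements an edge-enhancement densenet (EEDN) denoising framework
for single fluoroscopy frames, together with everything needed to train
and evaluate it without clinical data: a physics-light fluoroscopy phantom
generator, the Poisson degradation model, and the full quantitative
evaluation stack.

It is aimed at medical-imaging researchers who want a self-contained,
CPU-only reference implementation of the method and its evaluation
protocol.

## The model

Quantum noise is simulated on a clean frame `I'` as

```
I_input(u, v) = I'(u, v) + Poisson(λ),     λ = μ·α / 100
```

where `μ` is the percentage noise level and `α` the mean intensity of the
clean frame; training corpora draw `μ` from a Gaussian over level bins
(centre 60%, σ = 20%), matching the dose gap between fluoroscopy and
acquisition exposures.

The denoiser is two-stage.  An initial dense-block network (a stack of
ultra-dense blocks, UDBs) produces an intermediate result `I_inter`; its
Laplacian edge map `I_edge` is enhanced by an attention-gated sub-network
(stride-2 encoder → UDBs gated by a six-layer attention block → transposed
convolution decoder) into `I_edge+`; and the final frame replaces the
over-smoothed edges:

```
I_output = I_inter + I_edge+ − I_edge
```

Training minimises the Charbonnier penalty `ρ(x) = √(x² + ε²)` (ε = 1e-3)
between `I_output` and the clean frame, with Adam under a halving learning
rate schedule (1e-3, halved every 2000 steps, floor 1e-6).  The plain UDB
stack without the edge branch (UDDN) is included as the baseline.

Evaluation covers reference-based metrics (MSE, PSNR, SSIM), the
reference-free local SNR (mean of per-16×16-tile `μ/σ`), the relative dose
implied by `SNR ∝ √dose`, radially averaged frequency spectra `S(r)`
rescaled to cycles/mm via the geometry-corrected Nyquist frequency, the
frequency-transfer ratio between processed and input frames, and a hard
annular bandpass filter for locating the band of clinically useful
content.

The networks run on a small numpy-based autodiff engine included in
`eedn.nn`; no GPU or deep-learning framework is required.

## Worked example

```python
import dataclasses
from eedn import (ModelConfig, TrainConfig, NoiseSpec, build_model, train,
                  denoise, build_training_set, add_poisson_noise,
                  default_template, generate_dataset, psnr, local_snr,
                  relative_dose)

# 1. synthetic fluoroscopy frames and a paired training set
#    (zero-mean noise variant: clinical "original" frames carry no
#    brightness offset, so sigma-based comparisons use mean_subtract)
frames = generate_dataset(default_template(size=(192, 192)), 12, seed=101)
dataset = build_training_set(frames, 2000, 32, NoiseSpec(seed=7, mean_subtract=True))

# 2. desk-scale network (1+1 UDBs, growth 8), 500 training steps
model = build_model(ModelConfig.desk())
model, history = train(model, dataset, TrainConfig.desk(seed=7))

# 3. held-out evaluation at the clinical 60% noise level
clean = generate_dataset(default_template(size=(128, 128)), 1, seed=202)[0]
noisy = add_poisson_noise(clean, NoiseSpec(mu_percent=60, seed=300, mean_subtract=True))
out = clean.with_pixels(denoise(model, noisy).i_output)
print(f"PSNR  {psnr(noisy, clean):.2f} -> {psnr(out, clean):.2f} dB")
print(f"local SNR  {local_snr(noisy).mean_snr:.1f} -> {local_snr(out).mean_snr:.1f}")
print(f"implied relative dose {relative_dose(local_snr(out).mean_snr, local_snr(noisy).mean_snr):.2f}")
```

prints (exact numbers vary slightly with BLAS builds):

```
PSNR  29.18 -> 36.88 dB
local SNR  13.1 -> 45.3
implied relative dose 11.92
```

A mean local SNR rising from 13.1 to 45.3 means the denoised phantom frame
has the statistics of one acquired at a much higher dose — on real
clinical frames, whose texture is far richer than a phantom's, the
analogous gain is around 2.2× in SNR (≈ 4.7× in dose).

A command-line interface mirrors the library (`eedn phantom`, `degrade`,
`build-dataset`, `train`, `denoise`, `evaluate`, `spectrum`, `transfer`,
`bandpass`); every command writes a manifest with its parameters and seed.

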