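# Methods

This note records the model, the choices made where the design was open,
and what the synthetic evaluation does and does not establish.

## Noise model

Quantum-limited fluoroscopy noise is simulated per pixel as
`I_input = I' + Poisson(λ)` with `λ = μ·α/100`, where `α` is the mean
intensity of the whole clean frame.  Two consequences are worth stating
plainly:

* **The degradation has a positive mean.**  Adding a Poisson draw shifts
  the frame brightness up by `λ`.  The default implements the model
  literally; `NoiseSpec(mean_subtract=True)` subtracts `λ` afterwards for
  a zero-mean variant, and the choice is logged.  Monotonicity of the mean
  local SNR in `μ` holds only for the zero-mean variant: with the bias,
  tile means grow with `λ` and `(μ_tile + λ)/√(σ² + λ)` turns increasing
  once `λ` exceeds roughly the tile mean, which is reached near μ = 100%
  on the default phantom.
* **`α` is a frame-level constant.**  Patches cut from a frame inherit the
  whole-frame `λ`, so a dark patch from a bright frame is degraded at the
  frame's photon scale, not its own.

Training corpora draw levels from a Gaussian over bins (centre 60%,
σ = 20%, bin width δ = 10%, bins 10–100%).  Probability mass outside the
bin range is renormalised into the covered bins so counts sum to the
requested total; per-bin counts use largest-remainder rounding, which
keeps every count within one of the plain rounded value.  Whether frames
should be clipped after degradation is left to write time: the processing
pipeline is floating point and never clips.

## Networks

The EEDN variant wires: input → initial denoiser → `I_inter` → Laplacian →
edge-enhancement branch → `I_edge+` → `I_output = I_inter + (I_edge+ −
I_edge)`.  The grouping of that sum is part of the contract: identical
edge maps return `I_inter` bit-exactly, and the composition identity holds
exactly in float32 for every forward pass.

Open design points and how they were resolved:

* **UDB internals.**  Each ultra-dense block is a dense stack of
  `udb_layers` 3×3 convolutions with PReLU, every layer consuming the
  concatenation of the block input and all previous layer outputs
  (`growth_channels` each), fused by a 1×1 convolution and closed by a
  residual connection to the block input.  The 1×1 fusion over the full
  concatenation realises the multiple interacting paths; widths are
  configurable.
* **Edge-branch width.**  The encoder maps the edge map to a
  low-resolution domain at `edge_channels = base_channels/2`.  This keeps
  the 3+3-UDB edge-enhanced network within a few percent of the 6-UDB
  baseline's parameter count (0.82M vs 0.85M at the defaults), i.e. the
  edge boost does not increase total model cost.
* **Attention block.**  Six 3×3 convolutions with PReLU followed by a
  sigmoid, sharing the encoder output with the UDB branch; the gate is
  applied by elementwise multiplication and merged with a 1×1 convolution.
* **Residual edge enhancement.**  The decoder's final convolution predicts
  a *correction to* the edge map (`I_edge+ = I_edge + correction`) and is
  zero-initialised, so an untrained network reproduces its initial
  denoiser exactly.  This is algebraically the same composition rule, but
  it prevents a partially trained branch from flooding the output with
  broadband texture: in ablations without it, the intermediate result
  reached a mean local SNR of ~47 while the composed output fell to ~16
  because the branch injected noise the Charbonnier loss barely penalises.
* **Residuals.**  The initial denoiser carries a global residual from the
  (normalised) noisy input, conventional for this family of denoisers.
* **Intensity domain.**  Networks consume frames normalised to [0, 1] by
  `2^n − 1`; the composition is applied in the normalised domain and
  re-applied after rescaling so the identity survives denormalisation.
* **Laplacian borders.**  Replicate padding, inside and outside the
  network; the in-network operator is the same 4-neighbour stencil and is
  differentiable.
* **Inputs not divisible by 4** (the encoder's downsampling) are
  edge-padded and cropped back.

The compute engine is a small reverse-mode autodiff over numpy arrays
(float32) with im2col/GEMM convolutions; transposed convolution is the
exact adjoint of the strided convolution, and the input gradient of
stride-1 convolutions is evaluated as a flipped-kernel convolution.  All
gradients are checked against central differences in the test suite.
Initialisation is He-normal from a seeded generator, so builds are
bit-reproducible.

## Training

Charbonnier loss `ρ(x) = √(x² + ε²)`, ε = 1e-3.  The public
`charbonnier_loss` sums over all elements (so `ρ(0) = ε` per element);
the training loop uses the `batchmean` reduction — the sum over the batch
of per-pixel means — so learning-rate settings transfer across patch
sizes.  The optimiser is Adam with default moments (the optimiser is not
prescribed by the method; Adam is the field convention), with its learning
rate overridden each step by `max(1e-6, 1e-3 · 0.5^⌊step/2000⌋)`.  Batches
hold 16 patches; 96×96 at full scale.  Training is reproducible: the loss
trace is a pure function of (model seed, data, schedule seed).

**Desk scale.**  The shipped desk profile trains a 1+1-UDB network
(growth 8, base width 16) for 500 steps on 2000 patches of 32×32 cut from
twelve 192×192 phantoms, and evaluates on twenty held-out 128×128 phantoms
degraded at μ = 60%.  The study uses the zero-mean noise variant for both
the corpus and the held-out degradation: the clinical mean-local-SNR
comparison is made against *original* frames, which carry no `+λ`
brightness offset, and under the literal biased model the inflated noisy
baseline turns the SNR comparison into a coin flip that measures the bias
rather than the denoiser.  The sizes were chosen so the whole study runs
in well under a minute on one CPU core; across eight audit seeds it gives
20/20 held-out frames improved in both PSNR and mean local SNR, mean PSNR
gains of 5–9 dB, SNR ratios of 2.4–3.2, and transfer ratios of 0.13–0.25
near Nyquist.

## Metrics

* PSNR from the plain mean squared error over all pixels and the
  `(2^n − 1)²` peak; identical images report `inf`.
* SSIM defaults to the *global-statistics* form — one mean, variance and
  covariance per image with `c1 = (0.01·(2^n−1))²`, `c2 = (0.03·(2^n−1))²`
  — because that is the form the evaluation protocol states; the standard
  sliding-window mean SSIM is available behind `windowed=True` and is
  clearly an extension.  Population (not sample) statistics throughout.
* Local SNR tiles the frame into non-overlapping 16×16 patches, drops
  partial border tiles, excludes zero-variance tiles (counted), and
  averages `μ/σ`.  A constant frame therefore has an undefined (NaN) mean
  local SNR rather than an infinite one.
* Relative dose is `(SNR_a/SNR_b)²`, valid under the quantum-limited
  assumption `SNR ∝ √dose`.

## Spectrum analysis

`S(r)` averages DFT *magnitudes* (not squared magnitudes — `power=True`
switches) over integer annuli in DC-centred index coordinates; no
apodization window by default (`window=True` adds Hann).  The profile
keeps every annulus out to the array corner so that
`Σ n(r)·S(r) = Σ|F|` holds exactly, but annuli beyond the per-axis
Nyquist sample only diagonal directions; `SpectrumProfile.up_to_nyquist()`
masks the physically meaningful range and all transfer-ratio analysis is
restricted to it.  Non-square frames are binned in per-axis-normalised
coordinates so both axes reach Nyquist at the same annulus.

Frequencies convert to cycles/mm through the entrance-plane pixel spacing
`detector_spacing · sed/sid` — the standard geometric magnification
correction, with the source-to-entrance distance read from DICOM tag
(0040,0306) `DistanceSourceToEntrance`, falling back to (0018,1111)
`DistanceSourceToPatient`.  Frames without geometry stay in cycles/pixel
and refuse cycles/mm operations.

The bandpass filter is a hard annular mask (no transition band), matching
an interactive band-selection tool.  One edge case is deliberate: a band
reaching the Nyquist frequency disables the upper cut, because the
diagonal DFT bins above the per-axis Nyquist would otherwise be zeroed
and the full band `[0, f_N]` must act as the identity.  Transfer curves
over image sets are computed ratio-first (one curve per image, then mean
and SD per annulus), which is what per-annulus error bars describe.

## Phantoms

Phantoms emulate the *statistical structure* of fluoroscopy content, not
its physics: a base level at 45% of the intensity range with broad
Gaussian blobs and a gentle linear gradient (anatomy; spectral mass below
0.1 cycles/mm at 0.5 mm spacing), spline-rendered curvilinear dips with a
Gaussian cross profile (catheters/wires), and straight step edges
(rib/heart borders); device and edge content populates roughly the
0.1–0.39 cycles/mm band where clinically useful detail concentrates.
Rendering is a pure function of the spec; dataset variants are derived
from a template with seeded randomisation of placements.

Passing the desk-scale study on phantoms shows that the implementation
learns, that edge composition is lossless, and that the trained model
suppresses high frequencies while improving reference and reference-free
quality metrics.  It does not establish clinical image quality: phantoms
lack scatter, detector blur, electronic noise, temporal correlation and
true anatomical texture, and the desk-scale model is far smaller than the
full configuration (6 UDBs, growth 32, 96×96 patches, tens of thousands
of steps) that full-scale replication would use.

## Known limitations

* Single-frame processing only; no temporal filtering.
* The CPU engine is adequate for desk-scale studies and inference on
  512×512 frames, but full-scale training is impractical on it.
* DICOM support covers reading (single- and multi-frame, slope/intercept
  rescaling); there is no DICOM writing.
* SSIM's global form saturates on large images with slowly varying
  luminance; use the windowed variant when comparing against conventional
  reports.
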