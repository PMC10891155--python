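# Methods

`registain` implements a virtual-staining training framework in which three
convolutional networks are optimized jointly: a generator **G** that
translates two-channel autofluorescence (AF) images of unlabeled tissue into
RGB H&E-equivalent brightfield images, a discriminator **D** that scores RGB
images as real histochemistry or not, and a registration network **R** that
predicts the displacement vector field (DVF) aligning the coarsely
registered histochemical target to the generator's output. Warping the raw
target by the predicted DVF yields a pixel-accurate training target without
any offline elastic registration. The package also implements the
surrounding workflow: coarse slide registration and tiling, training-pair
screening, stain-quality metrics, nuclei quantification, and FOV-level
artifact screening — all exercisable end-to-end on synthetic phantoms with
known ground truth.

## Model and losses

With `I_VS = G(I_AF)`, the registered target
`I_HS,reg = warp(I_HS,raw, DVF)` and `D(·) ∈ [0,1]`:

- **Generator**: `L_G = BerHu(I_VS, I_HS,reg; δ) + α·TV(I_VS) + β·(1 − D(I_VS))²`
  with `α = 0.02`, `β = 50`, and the reverse-Huber threshold
  `δ = 0.2·SD(I_HS,reg)` computed per target image. BerHu is `|d|` for
  `|d| ≤ δ` and `(d² + δ²)/(2δ)` beyond — L1-like for small residuals,
  quadratic for outliers, continuous and C¹ at the boundary.
- **Discriminator**: `L_D = D(I_VS)² + (1 − D(I_HS,raw))²`. The *raw* target
  serves as the real example so D learns the stain appearance distribution
  independent of alignment.
- **Registration**: `L_R = 1 − NCC(I_VS, I_HS,reg) + TV(DVF)`, where NCC is
  the mean windowed Pearson correlation over all k×k windows (k = 20,
  stride 1, ε = 1e−6 stabilizing the denominator; constant windows
  contribute 0). In the trainer the TV term is normalized per field element
  (`reg_tv_reduction="mean"`): a TV summed over a pixel-unit DVF has a
  per-pixel subgradient of order 1 against a registration signal of order
  1e−4 per pixel, which pins the field at a constant; the mean form balances
  the two terms at the scale of realistic smooth fields. The summed form of
  the public `registration_loss` is retained as an option.

DVF post-processing, in this fixed order: (1) 3×3 Gaussian smoothing
(separable [1,2,1]/4 weights, replicate borders), (2) per-plane clipping to
mean ± 3 SD (statistics computed on the smoothed plane and treated as
constants for differentiation), (3) absolute clipping to [−30, 30] px.
The warp itself is bilinear sampling at `p + dvf(p)` with border
replication, differentiable in both the image and the field (clamped border
samples receive zero field gradient). The raw target is always warped
directly — never a previously warped copy — so resampling blur cannot
accumulate.

## Training schedule

Per cycle: `max(3, ⌊12 − t_D/4000⌋)` generator steps (R and D frozen; the
target is realigned by the current R per step), one discriminator step, one
registration step (G frozen; gradients flow through the warp into R), with
`t_D` the discriminator iteration count. Adam throughout
(β₁ = 0.9, β₂ = 0.999); learning rates default to 1e−4 for G and R and
1e−5 for D; batch size 4; 256-px training patches in production.
AF patches are standardized per channel to zero mean/unit variance
(ε = 1e−8; constant patches map to zero); RGB targets stay on [0, 1] so the
loss and metric intensity semantics remain interpretable. Augmentation
applies identical left-right/up-down flips (p = 0.5 each) and a uniform
90°-multiple rotation to input and target. 10% of the data is held out and
the checkpoint minimizing validation `L_G` (BerHu + TV by default; the
adversarial term is configurable) is selected. Disabling the registration
network (`use_registration_net=False`) substitutes the raw target and skips
R updates — the ablation variant.

The three networks: G is an attention-gated U-Net (2→3 channels, sigmoid
output), R a plain U-Net (6→2 channels, linear output with a
zero-initialized head so the predicted field starts at zero displacement),
D a strided CNN ending in one sigmoid probability per image (the losses
treat `D(·)` as a single probability, so D pools to a scalar rather than a
patch map). Widths/depths are configurable; production defaults are depth 4
with 32 base filters, tests and benchmarks use depth 2 with 8. The networks
run on a compact numpy reverse-mode autodiff engine (`registain.nn`) with
numba-jitted convolution kernels; analytic gradients of every primitive,
including the bilinear warp, are finite-difference checked in the suite.

## Data preparation and QC algorithms

- **Rigid slide registration**: grid search over candidate rotation angles;
  for each, the integer shift maximizing the FFT cross-correlation of
  mean-subtracted luminance (channel mean) images; ties break toward the
  smallest |shift|, then |angle|. Coordinates are 0-based (row, col),
  top-left origin; shifts are reported as (dx, dy) = (col, row) displacement
  of the moving image, and `apply()` undoes them.
- **Patch-level affine refinement**: SimpleITK multi-modal registration
  (Mattes mutual information by default, correlation as an option),
  multi-resolution, with a guard that never returns a transform whose
  metric is worse than the initialization. Tiles of 3248² px are refined,
  then center-cropped to 2048² (600-px margins) to drop edge artifacts;
  tiles with < 5% tissue are discarded.
- **Pair screening**: candidate pairs are kept iff PSNR ≥ 15 dB and
  SSIM ≥ 0.6 (boundary kept), computed with the package's own metric
  definitions.
- **SSIM** is the single-window whole-image statistic
  `(2μ_Aμ_B + c₁)(2σ_AB + c₂) / ((μ_A² + μ_B² + c₁)(σ_A² + σ_B² + c₂))`
  with `c₁ = 1e−4`, `c₂ = 9e−4`, averaged over channels on the [0, 1]
  scale — not the conventional 11×11 locally windowed variant (available
  behind a flag, unused by defaults). Its range is (−1, 1]; it is 1 only
  for identical images. **PSNR** uses the squared *maximum of the
  reference* over the channel-averaged MSE; identical images report +∞.
- **Stain unmixing**: Beer–Lambert optical densities
  `OD = −log(clip(rgb, 1, 255)/255)` — the exact inverse of the phantom's
  renderer `RGB = round(255·exp(−(c_h v_h + c_e v_e)))` — least-squares
  projected onto the hematoxylin/eosin unit color vectors
  (0.650, 0.704, 0.286) and (0.072, 0.990, 0.105), normalized; negative
  concentrations clip to zero. With 8-bit quantization the roundtrip error
  is quantization-limited: ~0.009 OD on average over concentrations in
  [0, 2]², up to ~0.055 at the darkest corner.
- **Nuclei quantification**: Otsu's threshold on the hematoxylin
  concentration with a 0.15-OD floor (nuclei are hematoxylin-dense; the
  floor keeps quantization noise in stain-free images from being
  segmented), binary opening with a radius-1 disk, then 8-connected
  component count and mean component area.
- **FOV artifact screening**: each WSI is split into square FOVs (8000 px
  production default). Tissue is everything with mean RGB below 235/255.
  Metric 1 is the nuclei area fraction of tissue; metric 2 the mean eosin
  concentration over tissue, mapped to [0, 1] against a reference OD of 1.0
  (a fixed scale, so a uniformly faded slide scores near zero). A FOV is
  well-stained iff metric 1 > 0.01 AND metric 2 > 0.07, both strictly;
  zero-tissue FOVs are skipped with a reason. Paired nuclei statistics are
  compared with a two-tailed paired t-test (significance at P < 0.05).

## The phantom generator

Phantoms emulate exactly the three properties the framework must cope with:

1. **A learnable cross-modality mapping.** Nuclei are rejection-sampled
   ellipses (radius range configurable, 200 retries, 2-px minimum
   separation when overlap is disallowed — also preventing the optical blur
   from bridging adjacent nuclei) carrying hematoxylin OD ≈ 0.9 with ±15%
   per-nucleus jitter; cytoplasm is a smooth eosin OD texture (0.5–1.0 of
   the nominal OD, floor chosen to keep all tissue clearly below the QC
   background threshold) plus faint nonspecific hematoxylin; background is
   void. OD maps get a σ = 0.6 Gaussian blur (optical soft edges), are
   rendered to 8-bit RGB via Beer–Lambert, and the AF channels are fixed
   saturating functions of the OD maps (DAPI-role: `1 − exp(−2·OD_h)`;
   TxRed-role: `1 − exp(−1.5·OD_e)`) plus Gaussian sensor noise
   (SD 0.01) — invertible, nontrivial, and documented.
2. **Coarse misalignment.** Either a constant translation or a smooth
   elastic field (Gaussian-filtered white noise rescaled so the maximum
   displacement norm equals the amplitude). `true_dvf` is stored in the
   convention that aligns the raw target back to the AF frame.
3. **Under-staining artifacts.** Hematoxylin/eosin OD scaled by (1 − fade)
   inside a region mask and re-rendered.

All randomness flows from the spec's single seed through one named
generator; identical specs produce bit-identical samples.

What the phantom does *not* model: realistic cell morphology or specific
cell types, stain variability between slides, out-of-focus blur, tissue
folds/holes, scanner color profiles. Passing tests therefore demonstrate
the correctness and the qualitative behavior of the algorithms, not
performance on real autopsy tissue.

## Benchmark study conditions (toy scale)

The end-to-end benchmarks (`registain.benchmarks`, driven by
`scripts/acceptance.py` and the acceptance tests) run 64×64 phantoms,
depth-2/base-8 networks, batch 4, 12 training + 4 held-out test phantoms;
100 training cycles for the ablation runs, 120 for mapping recovery, 150
for translation recovery — lengths chosen so the full benchmark suite runs
in well under half an hour on one CPU while each behavioral outcome is
stable. Several deliberate scaled-down study conditions, chosen once from
the optimization analysis and not revisited:

- **Registration learning rate 3e−3** (production default 1e−4): at full
  scale R receives tens of thousands of updates; at ~10² toy updates Adam's
  per-step displacement bound makes the production rate unable to traverse
  a multi-pixel output change. The toy rate preserves the optimization
  trajectory length (lr × steps roughly constant).
- **One shared misalignment field per run** for the registration ablation
  (amplitude 5 px, smoothness scale 96 px — a slowly varying, near-uniform
  elastic field): a full-scale R learns sample-specific correspondence from
  >10⁶ patches; a toy R demonstrably cannot (its tracking error equals the
  field magnitude), but the slowly varying deformation of a single slide
  region — which neighboring tiles share — is learnable and probes the same
  mechanism: R absorbs the deformation so G trains on aligned targets,
  while the ablated variant bakes the deformation into G and is penalized
  against aligned held-out targets.
- **No flip/rotation augmentation in the benchmark runs** (the
  `TrainConfig.augment` flag; production default on): dihedral augmentation
  randomizes the direction of the shared field, which symmetrizes the
  misalignment into isotropic blur (its L1-median target is the aligned
  image) and removes the very effect the ablation measures.
- **Staged translation recovery**: joint toy training has a degenerate
  equilibrium in which the generator — updated 12× as often as R — absorbs
  a constant shift into its own mapping before the registration network can
  move, after which zero displacement is optimal for R. Full-scale training
  does not have this equilibrium because its deformations vary per sample
  and cannot be absorbed by a convolutional mapping. The benchmark
  therefore trains R on constant (4, 0) px misalignment against the
  *frozen* generator taken from the aligned mapping-recovery run
  (`TrainConfig.freeze_generator`) and compares R's mean post-processed DVF
  to the truth.

The mapping-recovery benchmark trains without misalignment and measures the
held-out mean absolute error of the inferred stain against the ideal
rendering.

## Numerical choices and edge cases

- Losses accept numpy arrays (returning floats; used by oracles and
  evaluation) or autodiff tensors (returning scalar graphs) through one
  arithmetic path. The tensor path of NCC floors the variance product at
  1e−12 to keep the sqrt gradient finite on constant windows.
- `normalize_patch` guards the SD with ε = 1e−8; constant patches map to
  zeros. PSNR of identical images is the +∞ sentinel. Empty nuclei masks
  report count 0 and NaN mean area. All-zero hematoxylin channels segment
  to an empty mask.
- Training aborts with a diagnostic (cycle, t_D, loss values) on
  non-finite losses.
- Checkpoints are single-file npz archives holding the generator
  configuration, parameters and training counters.
- Tiled inference standardizes the AF image once per channel, pads each
  tile to the next multiple of 2^depth with edge values, and blends
  overlapping tiles with a separable linear ramp; a single-tile image is a
  direct forward pass.

## Known limitations

- The phantom's texture-to-color mapping is far simpler than tissue
  autofluorescence; generator quality on phantoms is an upper bound in
  realism terms.
- The toy registration regime only demonstrates recovery of slowly varying
  deformations; sample-specific elastic correspondence requires data and
  iteration counts outside desk scale.
- The whole-image SSIM definition used throughout differs from the
  windowed SSIM common elsewhere; values are not comparable across
  definitions.
- The numpy/numba engine is single-threaded and CPU-bound; production-scale
  training (gigapixel WSIs, 256-px patches, ~10⁶ iterations) is out of its
  intended scope.
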