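# Methods

This note records the modelling choices behind `lightdermo`, the defaults
and why they were chosen, and what the bundled synthetic data can and cannot
show.

## Numerical substrate

The package runs on a small reverse-mode automatic-differentiation engine
(`lightdermo._tensor`): float32 tensors, a topological backward pass, and
hand-derived adjoints for grouped 2-D convolution (im2col with
`sliding_window_view` + einsum), 2×2 max pooling, batch normalization
(composed from differentiable mean/power primitives), GELU (exact
`x·Φ(x)` via `scipy.special.erf`), sigmoid, channel indexing and
concatenation, and a fused softmax/cross-entropy loss.  Every adjoint is
verified against central finite differences in the test suite.  The engine
is written for clarity and desk-scale problems, not for throughput; a
forward/backward pass over a batch of 32 images at 64×64 with the
reduced-width configuration takes on the order of a second on one CPU core.

## Architecture

- **Shuffle unit.** Even two-way channel split (the split ratio is a design
  choice; the even split is the conventional one for this unit family).
  Transform branch: 1×1 conv + BN + ReLU, 3×3 depthwise conv + BN, 1×1 conv
  + BN + GELU; identity branch untouched; concatenation restores the width
  and a group-2 channel shuffle interleaves the halves.  Stride is always 1
  inside units — all downsampling is done by the 2×2 max pools that close
  each stage.
- **SE block.** Bottleneck width `max(1, C // r)` with `r = 16` in the
  canonical model.  The excitation stack is FC → GELU → FC → sigmoid: GELU
  regulates the factor between the two FC layers and the sigmoid maps the
  final gate into (0, 1).  The FC layers carry biases.
- **Normalization.** Batch normalization with learnable scale and shift
  (2 parameters per channel), counted in every parameter total.
  Convolutions followed by BN are biasless, since BN's shift subsumes the
  bias; this convention is load-bearing for the parameter budget.
- **Stage-to-stage width growth** is a 1×1 conv + BN + GELU expansion; the
  stem uses the same expansion from 24 stem channels to the first stage
  width.
- **Head.** Global average pooling → FC(512→128) → GELU → FC(128→7).
  Softmax is the inference head; training uses the mathematically identical
  cross-entropy-over-logits formulation for numerical stability.

### Parameter budget

The published budget for this architecture is 1.9 M parameters, but not the
per-stage configuration.  Stage repeats (3, 7, 10, 9) with head width 128
were fixed as the canonical configuration because they land the exact count
at 1,920,027 (1.9 M to one decimal).  `calibrate_budget` is the documented
repair rule for edited configurations: a deterministic search over stage-4
repeat offsets (0, −1, +1, −2, +2, … ±4), each tried with the original head
width and then 64/128/256, accepting the first exact count inside
[1.85 M, 1.95 M].  The widening offsets (rather than ±1 only) let the rule
repair configurations more than one repeat away from the band.

FLOPs are reported by `count_parameters(..., count_macs=True)` using the
multiply-accumulate convention over convolutions and linear layers at the
configured input size.  MAC counts depend strongly on convention and input
size, so they are informational only and not pinned by any test.

## Data pipeline

- **Preprocessing** resizes bilinearly to 256×256 (configurable) and
  rescales uint8 input by 1/255; float input is assumed already in [0, 1].
- **ROI cropping** locates the lesion as the intensity-weighted centroid of
  (1 − grayscale) — lesions are darker than the surrounding skin — and cuts
  the largest centred square that fits the image, never smaller than half
  the short side (shifted inward at borders).  A uniform image falls back
  to the geometric centre.  The published procedure names only "centroid";
  this intensity-centroid rule is this package's concrete reading.
- **Augmentation sampling.** Single-number ranges are read symmetrically:
  rotation U(−30°, +30°), zoom U(0.9, 1.1), shear U(−0.1, +0.1); brightness
  U(0.9, 1.1); fair-coin horizontal/vertical flips; out-of-frame pixels are
  filled with black.  The noise parameter 0.45 is read as the upper bound of
  a per-image uniform draw of the Gaussian σ on [0, 1]-scaled pixels; no
  units are published for it, and the top of that range is visually
  destructive — a documented open reading, kept because it is the printed
  value.  Each sampled transform stores its full parameter set (including
  the noise seed), so augmented images replay bit-identically.
- **Balancing** brings every class to exactly the target (default 4000):
  deficit classes keep all originals and append augmented copies
  round-robin over the originals; the surplus class is subsampled without
  replacement (seeded), with dropped records retained but marked
  `downsampled-out`.  The operation is manifest-level and idempotent;
  pixels are materialized lazily on access or via `write_image_tree`.

## Training

Defaults: SGD with momentum 0.9 and weight decay 5e-4 (read as the
conventional value; the alternative literal reading 5×10⁴ would destroy
training), batch 64, 40 epochs, base learning rate 0.001 with step decay
gamma 0.5.  The decay period is not published; the default is 10 epochs
(four decays in 40), configurable.  Adam, RMSprop, Adamax, Adadelta and
Nadam are available as menu options; SGD is the default.  Cross-validation
is stratified k-fold (default 10), deterministic given the seed, and
balancing/augmentation is applied strictly **after** splitting so that no
augmented sibling of a test image can appear in its training fold — the
publication order is unstated, and the leakage-safe order is adopted.
Training is fully seeded (initialization, batch order, augmentation) and
CPU-deterministic; the best-validation-accuracy weights are restored at the
end of a run.

### Desk-scale problem sizes

Tests and the learnability check use a reduced-width configuration — stem 8,
stage widths (8, 16, 32, 64), one unit per stage, SE reduction 4, head 32,
64×64 input — trained for 15 epochs with SGD (lr 0.05, momentum 0.9, batch
32) on 100 synthetic images per class.  These sizes were chosen so that a
full training run completes in minutes on one CPU core while exercising
every architectural component; the reduced run reaches ≥ 90 % training
accuracy and transfers to held-out synthetic images.

## Synthetic data

The generator emulates what matters for testing this pipeline: seven
classes that are *separably* distributed (distinct lesion colour, ellipse
eccentricity, border irregularity, texture frequency, globule dots on a
common skin-toned background), ground-truth lesion masks, a darker-than-skin
margin sufficient for the centroid ROI rule, and the archive class imbalance
500/2000/2000/200/6000/3000/300 (total 14,000) as a named preset.  A
nearest-centroid classifier on mean lesion RGB — an oracle built from the
generator's own colour parameters — achieves ≈ 98 % accuracy, so the
classes are learnable by construction.

It does **not** emulate dermoscopy artifacts (hairs, rulers, gel bubbles),
intra-class morphology spectra, inter-patient skin-tone variation, or any
photometric realism.  Consequently, passing tests demonstrate that the
architecture, pipeline and training loop are correct and that the model can
learn colour/shape-separable classes — they say nothing about diagnostic
accuracy on real lesions, which requires the real archives and GPU-scale
training.

## GradCAM

The tap defaults to the stage-4 SE output, the last spatial map before
pooling (the published account does not name its tap layer).  Channel
weights are the spatial mean of the target logit's gradient at the tap; the
map is the ReLU of the weighted channel sum, bilinearly upsampled and
min-max normalized (all-zero maps stay zero).  Using the logit rather than
the softmax probability makes the map invariant to constant logit shifts.
Localization is validated against the generator's ground-truth masks: the
heatmap mass centroid must fall inside the lesion bounding box for at least
80 % of held-out images after the reduced training run.

## Degenerate inputs and conventions

- Channel shuffle rejects channel counts not divisible by the group count,
  naming both.
- Zero-denominator metric ratios report 0 with a warning, keeping macro
  averages defined when a class is absent from a fold.
- Uniform images fall back to centre crops; empty classes abort balancing
  with the class named; non-finite training loss aborts with a diagnostic.
- Checkpoints are npz weight archives with a JSON sidecar of the model
  configuration.

## Known limitations

- The numpy engine is single-threaded BLAS-bound; the full 256×256
  canonical model is buildable and countable in milliseconds but slow to
  train — reproducing the published real-data accuracy tables is out of
  scope.
- Published FLOPs/model-size figures for this architecture are mutually
  inconsistent with a 1.9 M float32 parameter count and are not
  reconstructible without the original counting convention; they are left
  unpinned.
- Hybrid pretrained-backbone variants are not implemented; `load_checkpoint`
  is the hook for externally produced weights.
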