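# Methods

## The model

`treefuse` implements a lightweight multimodal multi-task network for urban
tree monitoring.  One forward pass consumes a background-suppressed RGB
image of a tree and a standardized vector of environmental / biometric
sensor readings, and produces three outputs: a probability vector over four
ordinal health classes (0 = very poor … 3 = good/healthy), and scalar
estimates of daily O₂ production and CO₂ absorption.

**Image encoder.**  The visual pathway follows the EfficientNet-B0 layout:
a strided 3×3 stem (32 channels), sixteen mobile inverted bottleneck
(MBConv) blocks in seven stages with stage parameters
(expansion, kernel, stride, out-channels, repeats) =
(1,3,1,16,1), (6,3,2,24,2), (6,5,2,40,2), (6,3,2,80,3), (6,5,1,112,3),
(6,5,2,192,4), (6,3,1,320,1), a 1×1 head convolution to 1280 channels, and
global average pooling.  Each MBConv block is

    expand (1×1 conv → BN → SiLU, skipped when the factor is 1)
    → depthwise k×k conv (BN → SiLU)
    → squeeze-and-excitation gate
    → linear 1×1 projection (BN, no activation)
    → + input   (only when stride = 1 and channel counts match)

The squeeze-and-excitation (SE) stage pools each channel to a descriptor,
passes it through a two-layer bottleneck (squeeze width = ¼ of the block's
input channels, SiLU between, sigmoid output) and multiplies the resulting
per-channel gate back onto the feature map.  Gates lie strictly in (0, 1);
with zero gating weights every gate is exactly 0.5.  The residual is an
**addition**; concatenation would change the output dimensionality and
contradict the stated block output shapes.  Convolutions are bias-free
(batch norm supplies the affine terms, ε = 1e-3, running-stat momentum
0.1); SE bottleneck layers carry biases.  There is no stochastic depth.

**Sensor encoder.**  The encoded sensor vector (14 continuous channels +
one-hot species and urban zone, 30 features in the reference schema) passes
through a small MLP, d → 64 → 32, with SiLU between the two affine layers.

**Fusion and heads.**  The 32-wide sensor embedding is concatenated
(sensor block first) with the 1280-wide image embedding into a 1312-wide
fusion vector.  Three architecturally decoupled heads — no shared layers
beyond the fusion vector itself — branch from it, each FC(1312→h) → ReLU →
FC(h→out): a 4-way softmax classifier and two linear-output regressors on
the z-scored target scale.  The shared hidden width h = 344 was sized so
the full model lands on the published 5.4-million-parameter budget
(4,007,548 backbone + 4,064 MLP + 1,357,086 heads = 5,368,698 ≈ 5.4 M);
`fit_head_hidden` re-derives it and would adjust minimally if the schema
width changed.  Static multiply–accumulate count of the reference model at
224 px is 0.386 G (conv: K²·C_in/groups·C_out·H_out·W_out; FC: in·out; SE
gating FCs included, elementwise work excluded).

**Objective.**  Training minimises

    L_T = 0.4·L_cls + 0.3·L_O2 + 0.3·L_CO2

with cross-entropy (computed from logits via log-sum-exp; the softmax is
materialised only for reporting and agrees with the explicit formulation to
1e-6) and mean-absolute-error terms on z-scored gas targets.  Standardizing
the targets keeps the regression gradients on the same scale as the
classifier's.  Weights are static; dynamic balancing is deliberately out of
scope.  Health classes are treated as plain categorical: the softmax head
ignores their ordinality.

## Training recipe

Adam (β = 0.9/0.999), initial learning rate 1e-3 annealed to 0 by a cosine
over the full epoch budget, weight decay 1e-5 added to the gradient, global
gradient-norm clipping at 5.0, batch size 32, up to 120 epochs with early
stopping after 12 epochs without validation improvement.  Because the data
contract specifies only an 80/20 stratified train/test split, a stratified
10 % slice of the training split is carved out as the validation set that
drives early stopping and checkpoint selection (lowest validation L_T).
Augmentation (training only): random area crop U[0.8, 1.0] resized back,
horizontal flip p = 0.5, brightness and contrast factors U[0.8, 1.2].
Images are scaled to [0, 1] and channel-standardized with statistics
estimated from the training images.  Images arrive background-suppressed;
when a sidecar binary mask (`<name>.mask.png`) accompanies a photograph,
`load_image` sets background pixels to a constant fill before any resizing.
Training a segmentation model is explicitly out of scope.

Preprocessing: missing continuous values are imputed with the training-split
column mean, categoricals with the mode; categoricals are one-hot encoded
(strict out-of-vocabulary error by default, an all-zeros block under an
explicit flag); continuous features and gas targets are z-scored with
training-split statistics using the population (divide-by-n) convention, so
the fit set has exactly unit variance.  Zero-variance columns are a hard
error unless explicitly dropped.  Contextual metadata (coordinates,
planting year, road proximity) is not part of the model feature set.

## The tensor engine

No deep-learning framework is used: the package ships a compact
reverse-mode autodiff engine on NumPy (`treefuse.nn`) implementing exactly
the primitives the model needs — dense and depthwise convolution (kernel-
offset accumulation, which is faster than materialising sliding-window
copies at these sizes), batch normalisation with the standard hand-derived
backward, SiLU/ReLU/sigmoid, pooling, concatenation, and the two losses.
Every primitive is validated against central finite differences in the test
suite; inference is bit-deterministic.  Initialisation: truncated-normal
(fan-out) for convolutions, uniform (fan-in) for fully connected layers,
seeded through the model config.

## Profiles and problem sizes

Two configurations share every structural invariant:

* **full** — the reference deployment model: 224 px, canonical widths,
  h = 344 (5.4 M parameters, 0.39 G MACs).  Used for the static budget
  checks; training it is out of scope on CPU.
* **tiny** — width multiplier 0.25 (stem 8; stage widths 4/6/10/20/28/48/80;
  head 320), one block per stage, 96 px, h = 64 (0.18 M parameters).  All
  training experiments use this profile: recovery runs train on 800
  synthetic trees (640/160 split, ≤ 30 epochs, ~6 s/epoch on one CPU) and
  the ablation grid (full / no-SE / image-only / sensor-only × 3 seeds)
  runs 15 epochs per variant.  These sizes are the package's chosen desk-
  scale study conditions.

## The synthetic data generator

The study's real dataset (arborist labels, an unspecified physiological
model for gas targets, segmented photographs) is private; the generator is
an explicit stand-in that reproduces its statistical skeleton, not its
values.

* **Species mix**: 12 species; Platanus orientalis 27 %, Acer negundo 18 %,
  Fraxinus pennsylvanica 14 %, Morus alba 12 %, and eight rare species at
  (1 − 0.71)/8 = 3.625 % each.  A fixed per-species size factor drives
  height and canopy width scale.
* **Latent health**: class c is drawn from a configurable prior (default
  0.15/0.25/0.30/0.30), then the latent score u is drawn from a Beta(1.2,
  1.2) stretched into that class's band; bands are the even quartile
  thresholds (0.25, 0.50, 0.75), so `class = discretize(u)` holds by
  construction for every record.
* **Modality split**: u is decomposed as u = w·a + (1−w)·b with w = 0.35.
  The visual component a is expressed in the rendered image (canopy hue
  from healthy green to brown, i.e. the leaf-colour deviation) and only
  coarsely in the table (a noisy 0–5 leaf-colour score); the sensor
  component b drives the environmental channels and biometrics and is only
  coarsely visible in the image (canopy fill fraction).  Neither modality
  alone determines u, so a rule-inverting oracle using both modalities
  recovers the class strictly better (~0.96) than the sensor table alone
  (~0.90) or the image alone (~0.4 — the fill-fraction read-out of b is
  deliberately weak).  Noise-free-limit tests require the biometric and
  channel links to be exact functions of the latent record (species factor,
  a, b) when the noise scales are zero.
* **Sensor channels** (linear links in b, Gaussian noise): soil moisture
  12+28b (±1.5), temperature 24−4b (±2), humidity 35+25b (±2.5), CO₂
  480−90b ppm (±10), PM2.5 45−30b (±3), NO₂ 38−22b (±3), O₃ 55−25b (±4);
  AQI is a weighted composite of the pollutant channels plus reporting
  noise.  Healthier trees sit in moister soil and cleaner air.
* **Gas targets**: O₂ = 0.25 · cw² · cd · (0.5 + 0.5u) + ε with
  ε ~ N(0, 0.6) in arbitrary daily-rate units (cw = canopy width, cd =
  crown density), and CO₂ = 1.375 · O₂ · (1 + δ), δ ~ U(−0.05, 0.05).  The
  1.375 factor is the 44/32 CO₂:O₂ molar-mass ratio, giving the targets
  stoichiometric coupling (sample correlation ≥ 0.95).  The noise level
  (~15 % of the mean rate) is what we consider realistic for bulk
  physiological estimates; the functional form is a stand-in chosen for
  recoverable monotone structure, not ecology.
* **Renderer**: deterministic procedural drawing on a constant dark
  background (emulating background-removed photographs): a trunk rectangle
  whose width tracks height, dark bark-damage patches (count = rounded
  damage score), and an elliptical canopy of random coloured blobs whose
  count tracks crown density and whose hue interpolates green→brown with
  1−a.  No text or metadata leaks the label into pixels except through
  these documented channels.

What the generator does **not** emulate: photorealistic texture, real
backgrounds, illumination and seasonal variation, occlusions, intra-canopy
structure, or any real physiological model.  Passing the recovery and
ablation tests therefore shows that the pipeline can extract and fuse
cross-modal signal with the documented statistical structure — it says
nothing about accuracy on real urban-tree imagery.

## Numerical choices and degenerate inputs

* Population (divide-by-n) standard deviations; zero-variance feature or
  target columns are hard errors (features optionally droppable).
* Class prediction ties resolve to the lowest class index (argmax).
* Cross-entropy uses the max-shifted log-sum-exp; MAE uses the zero
  subgradient at exactly zero error.
* Cosine schedule period equals the configured epoch budget with floor 0.
* Duplicate tree IDs, unmatched modalities, wrong input resolution,
  missing-modality fusion, out-of-range labels, and empty evaluation sets
  all raise immediately rather than degrade silently.
* Checkpoints are single `.npz` files holding every parameter, batch-norm
  running statistics, the full model configuration and the fitted
  preprocessing statistics, so inference is reproducible from the file
  alone.

## Known limitations

* The ~0.4 image-only oracle shows the fill-fraction channel is a weak
  read-out of the sensor component; trained image-only models do better
  (~0.6) but the image pathway's ceiling is structural, by design.
* At the tiny profile and desk-scale budgets the squeeze-excitation effect
  on accuracy is within seed-to-seed noise (one to two test samples); the
  SE ablation clause should be read with that resolution in mind.
* Latency numbers are informational only; a NumPy engine on one CPU says
  nothing about the published edge-device latencies.
* The full-resolution model is never trained here; only its static budgets
  are checked.
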