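# Methods

## Problem and model

`finpose` tracks the pose of a single embryonic or larval zebrafish per
region of interest in grayscale behavioral recordings, then reduces the
resulting trajectories to standard kinematic readouts.  Pose is represented
by up to 10 ordered keypoints along the rostral–caudal axis (7 for
touch-evoked escape assays; a single between-the-eyes point for multiwell
visuomotor assays).  Rather than regressing coordinates directly, the network
predicts one 2-D Gaussian heatmap per keypoint at half the input resolution;
training minimizes mean squared error against encoded target Gaussians, and
inference decodes each channel's peak to subpixel precision.

### Heatmap codec

With the fixed 2× downscale, an input coordinate x maps to heatmap
coordinate x/2 − 0.25 (pixel-center convention, 0-based, x right / y down),
and back via 2·h + 0.5; this alignment keeps the round trip unbiased.
Targets are exp(−d²/2σ²) with peak value exactly 1; σ defaults to 2 heatmap
pixels.  Optional label "wiggle" adds isotropic Gaussian jitter (SD
`wiggle_sd` input px) to the target center only.

Decoding takes each channel's global argmax (row-major lowest index on ties)
and refines it per axis by log-parabolic interpolation over the immediate
neighbors.  For Gaussian-shaped peaks this refinement is exact; an
intensity-weighted 3×3 centroid was rejected because it shrinks the offset
toward the window center (≈0.4 heatmap px error at σ=2 for a half-pixel
offset), which would violate the ≤0.5 input-px round-trip contract.  Where a
neighbor is non-positive the centroid fallback applies; border peaks are not
refined along the clipped axis.  All-zero channels are reported as
undetected (confidence 0).

Accuracy is summarized as PCK — the fraction of keypoints with Euclidean
error strictly below a radius (3 px for escape-assay recordings, 1.5 px for
multiwell recordings, in input pixels) — and, for data-ablation experiments,
as *relative accuracy*: the correct-keypoint count of an ablated-data model
divided by the full-data model's count from the same seed.

## Network architectures

Both macro-architectures map (I=1, H, W) to (O=K, H/2, W/2) heatmaps and are
assembled from MobileNetV3-style inverted-bottleneck residual blocks
(expansion ratio E=2; depthwise kernel 3, configurable to 5 or 7;
squeeze-and-excitation with 4× reduction, ReLU then hard sigmoid; hard-swish
activations).

**Isotropic (default).**  An 8×8 pixel-unshuffle patchifies the input
(64·I channels at H/8), a 1×1 convolution maps to M channels, and a
normalization layer follows.  All N residual blocks run at this constant
resolution.  The outro expands 1×1 to 2M channels, applies hard swish and
spatial (channel) dropout p=0.05, maps 1×1 to (patch/2)²·O channels, and
pixel-shuffles to O×(H/2)×(W/2).  Presets: touch-evoked 512×512, M=32, N=10,
O=7; visuomotor 256×256, M=16, N=10, O=1.

**Hierarchical (comparison baseline).**  A 4×4 stride-2 convolution + norm,
then two 2×2 stride-2 stages reach H/8, where the N blocks run at M channels;
channel width halves per 2× resolution increase (M/2 at H/4, M/4 at H/2).
Two 2×2 stride-2 transposed convolutions (each + norm) return to H/2,
followed by a lightweight outro (1×1 expand 2×, hard swish, dropout, 1×1 to
O).  No encoder–decoder skip connections are used; the design is a pure
encoder–decoder.

**Block variants.**  The full block is expand-1×1 → norm → hard swish →
depthwise → norm → hard swish → squeeze-excitation → project-1×1 → norm.
The slimmed variant (default) keeps exactly one normalization and one
activation; which ones are kept is configurable (all six combinations), with
the default keeping the normalization after the depthwise convolution and
the hard swish after the expansion.  Normalization is instance norm by
default; batch, layer, and group (8 groups) are selectable.  All
normalizations use ε=1e-3 and per-channel affine parameters; batch norm
keeps running statistics with decay 0.9.

**Initialization.**  Xavier-uniform convolution weights with gain √2 when a
nonlinearity (directly or after a normalization) follows and 1 otherwise;
each block's projection convolution is further scaled by 1/√N so the
residual stream's variance stays bounded with depth; the network's final
convolution and every bias start at exactly zero.  Consequently a fresh
network outputs identically zero heatmaps and the initial MSE loss equals
the mean squared target — a property the tests assert.

## Training

MSE heatmap regression with AdamW: β₁=0.9, β₂=0.95, ε=1e-6; decoupled weight
decay 1e-5 applied to convolution weights only; batch size 16; learning rate
5e-4 (touch preset) or 1e-4 (visuomotor preset); 6000 parameter updates; no
learning-rate schedule.  Batches are drawn uniformly with replacement per
update (update-centric bookkeeping).  Datasets are split 75/25
train/validation by a seeded shuffle (train size = round(0.75·n));
standardization uses the mean and SD pooled over training-split pixels only.
Validation passes use evaluation mode (no augmentation, no dropout).

Gradient accumulation reaches any effective batch that is a multiple of the
micro-batch; because instance/layer/group normalization never couple
samples, accumulated micro-batch gradients equal full-batch gradients up to
float32 summation order (asserted to 1e-5 relative norm), whereas batch
normalization breaks the equivalence (asserted both ways).  Single-threaded
runs are bit-reproducible given (seed, config); every RNG stream (batch
sampling, augmentation, wiggle, dropout, init) derives from the root seed
with a distinct spawn key.

### Augmentation

Training-split images are augmented on the fly in a fixed order: photometric
(gamma, brightness) → one composed affine (resize, flips, rotation,
translation) applied once to the image (bilinear, median fill) and exactly
to the keypoints → standardization → additive Gaussian noise.  Defaults:
gamma exponent log-uniform [0.75, 1.33]; brightness ±0.1; resize ±10%;
rotation uniform over the full circle (orientation in a well is
unconstrained); translation ±5% of side; flip probability 0.5 per axis;
noise SD 0.05 post-standardization.  A transform that pushes every keypoint
outside the frame is resampled (bounded retries).  The magnitudes are this
package's choices; composing all geometric operations into a single affine
avoids compounded interpolation loss and makes the keypoint transform exact
(validated by a marker-pixel oracle over 500 random draws).

## Theoretical minimum memory footprint

The footprint accounting models a minimal training implementation: all
buffers allocated up front and never repurposed; implicit padding for
depthwise convolutions; index rearrangements (pixel shuffle/unshuffle)
recomputed in place rather than materialized; gradient accumulation used to
the fullest extent that leaves results unchanged — micro-batches of one
sample unless batch normalization is present, in which case the configured
batch must be held together.  Categories (4-byte floats): parameters;
gradients; AdamW moments (2 per parameter); one micro-batch of every
materialized forward activation plus layer-private caches (normalized
activations, dropout masks, squeeze-excitation gates); input/target buffers;
and two ping-pong workspace buffers of the largest intermediate tensor.
Under this accounting the isotropic touch preset needs ~88 MB versus ~121 MB
for its hierarchical counterpart while carrying more parameters (82,416 vs
76,631) — the expected trade-off, since the hierarchical network stores
high-resolution early activations.

## Synthetic data

The generator emulates the geometry and photometry of real recordings: a
dark larva (chain of soft-edged filled disks along a constant-curvature arc,
linear head-to-tail taper with a default profile approximating a 2–7 dpf
larva) on a bright background, with optional well-edge rings, probe-like bar
occluders aimed near the fish, corner-to-corner illumination gradients,
defocus blur, and Gaussian sensor noise, followed by clipping to [0, 1].
Keypoints are placed analytically on the midline at arc-length fractions
i/(K−1) (K≥2) or at 10% of body length for the single-keypoint case, so
labels are exact by construction.  Dataset defaults randomize body length
(25–45% of the frame side), curvature (±200°), heading, position, contrast,
and all scene nuisances; the probe may overlap the fish without invalidating
labels.  Per-frame RNG streams derive from the root seed via spawn keys, so
datasets are bit-reproducible.

Scripted movies translate the fish along its heading with a raised-cosine
speed bump per scheduled bout (trapezoid-integrated to per-frame positions)
and bend it with raised-cosine rostral–caudal angle bumps; the scripted
angle is the chord-sum angle, so the underlying arc curvature is scaled by
(K−1)/(K−2).  The scripted path is anchored to the most rostral keypoint —
the kinematics module's default speed reference — so bends swing the body
about that point and the measured reference-keypoint speed reproduces the
scripted profile exactly even while bends and bouts overlap.  The returned
ground truth contains the exact per-frame keypoints, letting bout counts,
peak speeds, and high-amplitude bend counts be validated against the
script.

**What the generator does not emulate:** real body-shape variation
(yolk-sac asymmetry, fin silhouettes, pigmentation), water-surface optics,
shadows, multi-animal interactions, or camera vignetting beyond a linear
gradient.  Tests passing on synthetic data therefore validate the pipeline's
correctness and trainability, not field performance on any particular rig.

## Kinematics

Speed: per-frame displacement of the reference keypoint (most rostral by
default) × mm_per_px × framerate, first frame 0; mm_per_px must be supplied
explicitly.  The rostral–caudal angle is the sum of signed turning angles
between consecutive midline chords (counterclockwise positive in image
coordinates): 0 for a straight body, invariant to rotation/translation,
negated by reflection; 7 points on a semicircle give exactly 150°.  Body
bends are one event per maximal same-sign run of the angle series (zeros
separate runs), peaking at the maximum |angle| (earliest frame on ties);
bends with |peak| ≥ 110° count as high-amplitude.  Swim bouts are maximal
runs of frames with speed strictly above 2 mm/s; single-frame bouts are
allowed and a run open at the end of the series closes at the last frame.
Stimulus summaries use the raw (unsmoothed) speed over [mark, mark + 5 s);
presentation traces use a centered mean filter whose window spans 1 s
(shrinking at the edges).  Both detectors are verified against brute-force
oracles on 1000 random series.

## Scaled-down reproducible experiments

Full-size training is out of desk-scale CPU budgets, so the package's
reproducible study (in `finpose.experiments`, exercised by the test suite
and the acceptance script) uses 128 synthetic 64×64 single-keypoint frames
and a tiny isotropic network: M=8, N=4, patch 4.  The patch is scaled with
the input so the internal grid stays at 16×16 — with 8×8 patches the 8×8
internal grid caps even training-set localization around PCK 0.84 at 2 px,
a representation ceiling rather than underfitting.  Matching the smaller
heatmap, the target σ is 1.25; the learning rate is 6e-3 (a smaller network
and a 600-update budget support a higher rate than the full-size recipes);
augmentation uses the task's orientation symmetries only (full rotation,
flips) since the generator already randomizes photometric conditions across
frames, and wiggle is off because labels are exact.  Under these frozen
settings three replicate runs reach mean validation PCK@2px ≈ 0.95 on the
study dataset (0.81–0.97 across the dataset seeds examined), and the 25%
data-ablation runs show the expected degradation (higher mean final
validation loss, relative accuracy ≤ 1).

## Numerical choices and edge cases

* float32 computation throughout training and inference (float64 only in
  loss reduction and gradient checks); footprint accounting assumes 4-byte
  scalars.
* Biased (1/N) variances in all normalizations; ε inside the square root's
  argument as var + ε.
* Decoder tie-breaks: lowest row-major index; bend/bout peak ties: earliest
  frame.
* Letterboxing for ROI → network input preserves aspect ratio, pads with the
  ROI median, and uses an exactly invertible pixel-center coordinate map, so
  the plate → ROI → network → heatmap → plate chain contributes ≤0.5 px
  beyond model error.
* Degenerate inputs raise rather than guess: constant training images (SD
  0), coincident consecutive keypoints, poses that do not fit the frame,
  stimulus marks outside the recording, zero full-data correct counts in
  relative accuracy.

## Known limitations

* CPU-only and single-threaded by design; no GPU kernels, mixed precision,
  batch-norm folding, quantization, or distributed training.
* One animal per ROI; no identity tracking across ROIs, no multi-peak
  decoding.
* The hierarchical baseline omits encoder–decoder skip connections; its
  block placement at the smallest resolution follows the design notes rather
  than a published reference implementation.
* The exact slim-block keep-combination believed optimal upstream is not
  published; the default here is one documented choice and all six
  combinations remain constructible for re-running that ablation.
* Wall-clock speed comparisons are hardware-dependent and deliberately out
  of scope; the `bench` CLI command measures them locally and labels them as
  such.
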