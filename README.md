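# finpose

Heatmap-based pose tracking and kinematic analysis for embryonic and larval
zebrafish behavioral recordings — small enough to train and run on a single
CPU core.

Zebrafish touch-evoked escape and visuomotor assays produce grayscale movies
of dark larvae in bright wells (single wells at 1000 Hz, 24-well plates at
100 Hz).  Classical threshold-and-skeletonize trackers struggle with probes
entering the field of view, uneven lighting, and early developmental stages;
`finpose` instead tracks up to 10 user-defined body keypoints with a compact
convolutional network and turns the trajectories into the field's standard
readouts: speeds, rostral–caudal body-bend angles, high-amplitude bends
(|peak| ≥ 110°), swim bouts (speed > 2 mm/s), and stimulus-response
summaries.  It is aimed at researchers who want a transparent, hackable,
desk-scale alternative to GPU-bound pose-estimation stacks — everything,
including network training, runs on numpy.

## The model

For K keypoints the network maps a standardized grayscale image
x ∈ ℝ^(1×H×W) to heatmaps ŷ ∈ ℝ^(K×H/2×W/2) and is trained by MSE against
target Gaussians

    y_k(p) = exp(−‖p − c_k‖² / 2σ²),

one per keypoint k with peak 1 at the (optionally jittered) label c_k.
Decoding refines each channel's argmax by log-parabolic interpolation (exact
for Gaussian peaks) and reports the peak value as confidence.

The default architecture is *isotropic*: an 8×8 pixel-unshuffle patchifies
the image, a 1×1 convolution sets M middle channels, N slimmed MobileNetV3
inverted-bottleneck residual blocks (expansion ratio 2, depthwise 3×3,
squeeze-and-excitation, instance normalization, hard swish) run at the
single internal resolution H/8×W/8, and an outro (1×1 expand 2×, hard swish,
spatial dropout 0.05, 1×1 to 16K channels, 4×4 pixel shuffle) emits the
heatmaps.  A conventional hierarchical encoder–decoder is included as the
comparison baseline: it holds fewer parameters but needs ~40% more training
memory under the package's theoretical-minimum footprint accounting, because
it must store high-resolution activations.

Training follows a fixed recipe: AdamW (β₁ = 0.9, β₂ = 0.95, ε = 1e-6),
weight decay 1e-5 on convolution weights only, batch size 16 (any effective
batch via gradient accumulation, which is exact for batch-size-independent
normalizations), learning rate 5e-4 (escape-assay preset) or 1e-4
(visuomotor preset), 6000 updates, on-the-fly label-consistent augmentation,
Xavier initialization with a zeroed final layer so the initial output is
identically zero.  Runs are bit-reproducible from a single seed.

Because no public labeled dataset exists for these assays, the package ships
a seeded synthetic generator (curved, tapered dark larvae; well edges; probe
occluders; illumination gradients; blur; noise) with exact midline keypoints
and scripted swim/bend movies, used by the test suite to validate every
stage against ground truth.

## Worked example

`examples/04_train_tiny_network.py` trains the scaled-down study network
(64×64 synthetic frames, one keypoint, M=8, N=4) for 600 updates, ~20 s on
one core:

```
split: 96 training / 32 validation frames
validation loss: first recorded 9.7335e-04, final 4.7777e-04
validation PCK within 2.0 px: 0.938 (30/32 keypoints)
```

The falling validation loss shows the heatmap regression converging; PCK is
the fraction of validation keypoints decoded within 2 input pixels of ground
truth — here 30 of 32, i.e. the head keypoint of most unseen fish is
localized to about a pixel.  `examples/03_network_architecture.py` prints
the full-size resource trade-off:

```
isotropic forward: input (512, 512), output 7 x 256 x 256
freshly initialized output is identically zero: True
   isotropic:   82416 parameters,    87.8 MB minimum training footprint
hierarchical:   76631 parameters,   120.8 MB minimum training footprint
```

and `examples/05_kinematic_analysis.py` recovers scripted behavior exactly
(bout and high-amplitude bend counts; peak speeds to within one-frame
discretization).  The other examples cover data generation, the heatmap
codec, and multiwell ROI tracking; each is a short, commented script.

A thin CLI wraps the same library calls:

```bash
finpose synth --out ds --frames 128 --keypoints 1 --size 64 --seed 1
finpose train --dataset ds --out model.npz --preset visuomotor
finpose track --movie frames/ --checkpoint model.npz --rows 4 --cols 6 \
              --framerate 100 --mm-per-px 0.094 --out run/
```

## Layout

- `src/finpose/synthetic.py` — seeded synthetic fish frames, datasets, movies
- `src/finpose/codec.py` — keypoints ↔ Gaussian heatmaps, PCK, relative accuracy
- `src/finpose/augment.py` — splits, standardization, label-consistent augmentation
- `src/finpose/nn/` — layers with hand-derived gradients, both architectures,
  parameter counting, footprint accounting, checkpoints
- `src/finpose/training.py` — AdamW loop, initialization, evaluation, ablation driver
- `src/finpose/kinematics.py` — speeds, angles, bends, bouts, summaries, tidy tables
- `src/finpose/{io,roi,tracking,export}.py`, `cli.py` — recordings, ROI grids,
  tracking, per-animal outputs, command line
- `src/finpose/experiments.py` — the frozen scaled-down study
- `docs/methods.md` — model, assumptions, defaults, and limitations in detail
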