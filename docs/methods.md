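# Methods

## Problem and workflow

Coronary artery calcifications (CAC) appear in 2D coronary angiography
(2DCA) as small, faint, persistent densities that are hard to spot in
non-contrast frames. Clinicians locate them by flipping between a
non-contrast frame and a contrast-enhanced frame showing the same cardiac
phase. `cacaflow` reproduces that workflow in three stages:

1. **Cardiac-phase synchronization.** For each frame `f_k` the normalized
   dissimilarity to the first frame,
   `S_k = ||f_0 − f_k||_F / (||f_0||_F + ||f_k||_F)`,
   oscillates with the heartbeat (the triangle inequality bounds it to
   [0, 1], and it is invariant under global intensity scaling). The
   cardiac period is the reciprocal of the dominant FFT frequency of the
   mean-subtracted signal, restricted to a 0.5–3.0 Hz (30–180 bpm) band
   converted to cycles/frame via the frame rate. Each annotated
   non-contrast frame `k` is paired with the smallest contrast-frame index
   `k′ ≥ onset` with `(k′ − k) mod period = 0`.
2. **Classification and ROI proposal.** Each synchronized 512×512 frame
   pair is cut into five overlapping 256×256 windows (four corners plus
   the center — the only symmetric five-window cover). A double-head
   residual encoder processes the pair: per head, a 7×7 conv/BN/ReLU
   (stride 2) and one residual double-conv block; the heads' features are
   concatenated, reduced by a 1×1 convolution, and passed through four
   residual stages of two basic blocks each (the standard 18-layer
   residual layout, widths 64/128/256/512), ending in global average
   pooling and a sigmoid classifier for patch-level CAC presence. A
   U-Net-style decoder (bilinear 2× upsampling, skip concatenation,
   double conv per stage) mirrors the encoder and emits a per-pixel ROI
   score map. The classifier gates the map: a patch predicted CAC-free
   contributes an empty mask; ties at the threshold count as positive.
3. **Post-processing.** Patch masks are fused to the frame by pixel-wise
   OR (recall-favoring, appropriate for assistive proposals), 8-connected
   components with area < 1000 px are removed (area = 1000 survives),
   and the mask is Gaussian-smoothed (σ = 3 px) and re-binarized at 0.5.
   Islands are removed *before* smoothing; the reverse order would let
   large blurred islands survive the size filter.

## Training

Ground truth: three annotators' CAC masks are fused by strict pixel-wise
majority (ties with an even annotator count resolve to background). The
decoder target `ROI_GT` is the fused mask dilated four times with a
5-pixel elliptical (by default circular) structuring element built from
the exact ellipse equation, so `k` iterations never reach beyond
`5k` pixels; disconnected components dilate jointly and may merge.

Stage 1 trains encoder + classifier with binary cross-entropy (Adam,
lr 1e-4, batch 32, 100 epochs in the reference configuration). Stage 2
freezes all encoder/classifier weights — enforced by optimizing only
decoder parameters, running the encoder in eval mode so batch-norm
statistics cannot drift, and asserting bit-identity afterwards — and
trains the decoder with the boundary loss: `mean(s · φ)` where `s` is the
sigmoid score map and `φ` the signed Euclidean distance map of `ROI_GT`
(negative inside, positive outside, zero on the inner boundary ring,
computed as `edt(¬G) − (edt(G) − 1)·G`). The loss is linear in the
scores, so the maps are precomputed once per patch. For an empty target
the map is a uniform positive constant (the image diagonal), keeping the
loss defined and minimized by the empty prediction. The boundary loss is
used alone in stage 2; no regional warm-up term is added. Cross-validation
is leave-one-acquisition-out, with the same folds reused by both stages
and validation splits taken at acquisition level (frames within an
acquisition are near-duplicates).

## Numerical engine

No GPU framework is used: the network, Adam, both losses and Grad-CAM run
on a small reverse-mode autograd engine written on numpy float32
(`cacaflow._nn`) — im2col convolutions, exact batch-norm backward,
matrix-form bilinear upsampling. Training and inference are deterministic
for a fixed seed, data order and thread count, which the reproducibility
contracts test. The engine implements only what the architecture needs.

## Synthetic phantom

The phantom emulates the target acquisition protocol: ~200 frames at
15 fps, 512×512 px (tests use 96–256 px), isotropic spacing 0.20–0.39 mm
(default 0.30), first half non-contrast, second half contrast-enhanced.
Vessels are 2–4 smooth random-walk polylines rendered as Gaussian-blurred
tubes; motion is a global sinusoidal translation with small per-branch
phase offsets, exactly periodic in the configured period (the internal
motion trace is exposed for verification). CACs are faint soft-edged
ellipses rigidly attached to a vessel vertex, equally present in both
halves (calcifications do not enhance); their exact pixel masks are
returned per frame. Noise is additive Gaussian (σ = 0.01 by default),
clipped to [0, 1]; frames are quantized to the 16-bit grid so container
round-trips are lossless. Simulated annotators perturb the true mask by
random disk dilation/erosion with radius ≤ `jitter_px`.

The phantom does **not** model X-ray projection physics, breathing,
table panning, anatomical variability, or realistic CAC size/intensity
distributions (the last are free parameters, not clinical estimates).
Passing tests therefore demonstrate algorithmic correctness and
end-to-end plumbing, not clinical performance; the published clinical
figures for this kind of workflow come from private patient data and are
out of scope here.

## Evaluation

Patch classification is scored with precision/recall/F1 (zero
denominators yield a flagged 0). ROI identification uses
intersection-over-minimum, `|A∩B| / min(|A|,|B|)` — 1 whenever one mask
contains the other, which is the right question for "does the proposal
cover the small target"; an empty mask gives a flagged 0 so gated-empty
predictions still enter aggregation. The Hausdorff distance is the
symmetric max-min Euclidean distance between the two masks' boundary
pixel sets (4-neighbor boundary, image border counts), multiplied by the
pixel spacing to give millimeters; it is an error (reported as missing)
for empty masks. HD is computed against the CAC mask, not `ROI_GT`.
Aggregates are median and quartiles with the linear-interpolation
quantile rule. Grad-CAM maps come from the last encoder stage: channel
weights are the spatially averaged gradients of the CAC probability,
the weighted activation sum is rectified, bilinearly upsampled and
min-max normalized to [0, 1] (all-zero gradients give a flagged zero
map).

## Problem sizes and defaults

The reference configuration (512-px frames, 256-px patches, widths
64–512, two blocks per stage, 100 epochs per stage) matches the clinical
protocol. The test suite and `scripts/acceptance.py` run the same code
at phantom scale: 256-px frames, 128-px patches, widths 8–64, one block
per stage, batch 8, with training stopped early once training F1 reaches
1.0 (stage 1) or training IoM reaches 0.9 (stage 2), capped at 100-200
epochs — an overfit study on a handful of patches, chosen so a complete
two-stage run plus evaluation finishes in a few CPU-minutes. Post-
processing parameters at that scale keep the defaults except where a
test explicitly exercises the `min_size` semantics.

## Design choices on genuinely open points

- *Five-window offsets*: corners + center, the symmetric cover; fusion at
  inference is OR (union) rather than logit averaging.
- *Patch positivity*: a patch is positive with ≥ 1 CAC pixel — the
  smallest unbiased threshold; configurable.
- *Heads*: independent weights (no sharing); the concatenated width is
  absorbed by a 1×1 convolution so the tail keeps the standard widths.
- *Skips*: one per resolution — the per-head block-2 outputs summed, plus
  stages 3–5.
- *Period rounding*: nearest integer, half-integers round down; only the
  non-contrast half feeds the FFT by default (contrast inflow distorts
  the signal); both choices are switchable.
- *Ellipse parameters*: "5 pixels per iteration" is read as the
  semi-axis of an isotropic ellipse (a circle); eccentricity is exposed
  as configuration.
- *ROI binarization* at 0.5 before post-processing; classifier threshold
  0.5 with ties positive.
- *Sidecar metadata* (YAML: spacing_mm, fps, contrast_onset) for TIFF/PNG
  containers, which carry no native tags for those fields.

## Known limitations

- The numpy engine is single-threaded and unsuited to clinical-scale
  training; the reference configuration is provided for completeness,
  not speed.
- The phantom's periodicity is exact; real sequences have beat-to-beat
  variability that the FFT peak averages over, so period errors of ±1
  frame are expected and tolerated downstream by design.
- The dissimilarity signal uses frame 0 as its reference; an atypical
  first frame (e.g., panning) would distort the signal. No correction is
  attempted.
- DICOM support covers plain multi-frame grayscale objects with
  PixelSpacing/CineRate; structure sets and scene files are out of scope.
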