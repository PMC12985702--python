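# Methods

This note documents the models, conventions and numerical choices
behind `endobleed`, and what the synthetic validation does and does not
establish.

## Weak labels

A frame is converted to HSV with hue on the half-degree scale
[0, 180), 8-bit saturation and value — the convention under which the
red thresholds (hue 0–8 and 172–180, S 90–255, V 50–255, all bounds
inclusive, hue 180 identified with 0) are coherent. Saturation of an
achromatic pixel (max channel 0) is defined as 0. The field-of-view
mask uses strict inequalities (S > 60 and V > 70), so boundary values
are excluded. The weak label is the conjunction of the red mask and
the FOV mask; its red-area ratio is taken over FOV pixels, not the
full frame, and the 1% dataset filter is read strictly
(ratio > 0.01; an `inclusive` flag flips this). A frame with an empty
FOV (all black) is a degenerate-frame error, not a zero. Mask files
are 8-bit PNGs holding only 0 and 255; on read, impure values raise
unless a tolerant mode binarizes at >127.

## Segmentation model

The segmentation model is a compact convolutional pixel classifier
written in numpy/scipy. A fixed feature bank computes, per pixel:
the channel-standardized RGB values (scaled to [0,1], then
standardized with means (0.485, 0.456, 0.406) and SDs (0.229, 0.224,
0.225)); S and V; a chromatic *red score* (hue proximity to red × S ×
V); Gaussian-smoothed red context at σ = 2, 4, 8 px; local red
standard deviation at σ = 2, 4 px; and structure-tensor coherence of
the red score. A trainable MLP head (16–16–1, ReLU, He init, seeded)
maps each pixel's descriptor to one logit; the output is a logit map
at input resolution. Binary cross-entropy is evaluated in the
numerically stable logit form and optimized with Adam at a learning
rate of 1e-4 and a batch size of 4 images.

The smoothed-context channels make diffuse plumes legible (high red
context at σ = 8), the local-variance channels expose speckled
cancellous bone, and coherence exposes thin curvilinear vessels —
these are exactly the cues that let fine-tuning separate bleeding from
distractors that color alone cannot.

Two implementation details matter for trainability at this fixed
learning rate:

* **Feature standardization.** Per-channel mean/scale are fitted once
  on the base-training pixel sample and stored in the checkpoint. The
  texture channels are an order of magnitude smaller than the color
  channels; without equalization the optimizer effectively cannot
  reach them within the early-stopping window.
* **Decision-region pixel sampling.** Each training image contributes
  a seeded subsample of pixels (default 4000; 2000 in the test
  profile): up to half positives, and the negative half drawn with a
  third of its budget from *red* negatives (red score > 0.2). Red
  negatives — vessels and bone under a zero mask — are the hard
  examples fine-tuning exists for; uniform sampling would dilute their
  gradient to near nothing. The loss itself is unweighted.

## Training stages

**Base training** fits the model to HSV weak labels. Early stopping
tracks validation loss with patience 20: an epoch "improves" when it
beats the best loss by more than `improvement_epsilon` (1e-4,
absolute); after `patience` consecutive non-improving epochs (one, if
patience is 0) training stops and the best-epoch checkpoint is
returned, along with a per-epoch loss log. A non-finite loss aborts
with a divergence error.

**Fine-tuning** resumes from the base checkpoint on curated samples —
red masks of definite bleeding and all-negative zero masks — and
monitors the mean Dice over a held-out monitoring set after every
epoch (IoU is logged alongside; the mean Dice is the single early-stop
scalar, patience 10). Curated and monitoring sources must be disjoint;
shared source ids are refused. The monitoring set deliberately mixes
bleeding-plus-distractor frames (reference masks cover bleeding only)
with a few distractor-only frames carrying empty masks: against an
empty reference, per-image Dice is a 0/1 step function (both-empty
pairs score 1.0), so mixed frames are what give the monitored scalar a
continuous gradient as false positives shrink.

Prediction binarizes `sigmoid(logit)` at strictly greater than 0.5
(the boundary is measure-zero but must be fixed for determinism).
8-bit input to `predict_mask` is auto-normalized with a warning.
Checkpoints store exact float64 weights plus the feature scaler;
save → load → predict is bit-identical.

## Evaluation protocol

* Dice = 2|A∩B|/(|A|+|B|), IoU = |A∩B|/|A∪B|; the identity
  D = 2J/(1+J) holds exactly per record. Two empty masks score
  (1.0, 1.0) for bookkeeping but are excluded from area-based
  summaries, which use GT-positive records only (reference area > 0
  inside the FOV).
* Image-wise positivity is ≥1 positive pixel inside a circular FOV
  (a minimum-area override exists, default 0). The circular field is
  derived per image as the largest inscribed circle of the thresholded
  FOV mask (center and radius from the Euclidean distance transform);
  a fixed-geometry override is available.
* Detection metrics (accuracy, sensitivity, specificity, PPV, NPV)
  come with two-sided 95% binomial CIs. **Wilson is the default**;
  Clopper–Pearson is available by flag. Printed reference intervals
  for these metrics match the Wilson method at two decimals (e.g. a
  25/42 specificity gives 0.44–0.73 under Wilson but 0.43–0.74 under
  the exact method), so Wilson is what the package reports by default
  even though exact intervals are sometimes the stated convention;
  both are first-class.
* The annotator panel is chosen by exhaustive search over all C(n, k)
  subsets, maximizing mean within-subset pairwise Dice; ties break to
  the lexicographically first subset of rater ids. Per-image GT
  agreement is the mean of the panel's pairwise Dice values.
  Per-rater diagnostic tables against the panel consensus use
  leave-one-out juries by default (a member never judges themself);
  a fixed-panel variant is available.
* Agreement strata are cumulative (≥0.70 ⊇ ≥0.80 ⊇ ≥0.90; thresholds
  configurable). The area stratification splits GT-positive records at
  20%, with the boundary value assigned to the low group. Summaries
  report median [IQR] and mean ± SD (sample SD, ddof 1); reported
  tables round half-up to two decimals.
* Spearman correlation uses average ranks for ties and a two-tailed
  t-approximation p-value; a constant input yields a flagged undefined
  result rather than an exception. The Shapiro–Wilk gate (3 ≤ n ≤
  5000) decides between parametric and rank methods at p < 0.05.
* Pixel-level precision–recall pools all FOV pixels across images;
  average precision is the step-interpolated sum over recall
  increments.

## Video quantification

Frames are scored one by one; the bleeding-area ratio uses the full
frame as denominator by default (with an FOV-denominator mode, both
written to the timeline CSV). In FOV mode an all-black frame is an
error; in full-frame mode its FOV ratio is recorded as NaN. Unreadable
frames are skipped with a logged gap. The composite rendering keeps
the original footage panel untouched, alters only mask-support pixels
in the overlay panel (alpha fill plus contour), and draws the ratio
series up to the current frame. Throughput measurement excludes
warmup frames and reports mean FPS and per-frame latency (their
product is 1000 by construction). Videos are numbered-frame
directories with a JSON fps sidecar.

## Synthetic study

The generator renders what the pipeline assumes about endoscopic
frames: a bright circular field (radius fraction 0.92 of the
half-width) on a near-black margin (all values < 50, hence outside
both the red and FOV bands); tan tissue with saturation clipped to
62–78 — chromatic enough to pass the FOV bands but far below the red
saturation bound; and three red component classes drawn strictly
inside the red bands *and* the FOV bands, with 1–2 quantization-margin
units to survive the HSV→RGB→HSV round trip. Plumes are sums of
anisotropic Gaussian blobs cut at the exact k-th order statistic of
the field inside the FOV, so the rendered bleeding fraction hits its
target to the pixel; vessels are 2–4 px rasterized Bézier tracks; bone
is a speckled ellipse (density 0.45). Components are kept disjoint
with priority bleeding > vessel > bone. All randomness flows through
one seeded generator per call; identical parameters give byte-identical
scenes. Videos fix the layout (field, distractors, plume potential)
and re-threshold the plume field per frame along a growth schedule,
returning exact pixel-count truth ratios.

Simulated annotators apply, in order: signed dilation/erosion, a
smooth random boundary warp (Gaussian displacement field, σ = 6 px
smoothing, scaled to the requested jitter SD), and random deletion of
components smaller than `miss_area_px` (default 256 px). All-zero
noise reproduces the truth exactly; mean Dice against truth decreases
with jitter.

**Study conditions** (the defaults of `generate_study`): 50 weak-label
training scenes with plume fractions uniform on 0.05–0.40 and both
distractor classes present; a curated set of 120 red-mask images
(plume-only scenes, fractions 0.08–0.35) and 230 zero-mask images
(distractor-only) — the published curated-set composition, kept at
full count so that a fine-tune epoch spans the same ~87 optimization
steps as at full scale, which the 10-epoch patience implicitly
assumes; 12 mixed + 3 distractor-only monitoring frames annotated by
low-noise raters (jitter SD 1 px); an evaluation set of 30 images
(one quarter GT-negative, positives spanning ratios 0.015–0.50
evenly, standing in for a "balanced ratio distribution") annotated by
five raters — three low-noise and two high-noise (one systematic
over-segmenter with occasional misses, one under-segmenter) so panel
selection has a correct answer; and 20 + 20 held-out distractor-only
and bleeding-only scenes for the before/after comparison. The test
profile runs everything at 128 px; the paper profile pins 512 px and
the published constants.

Curated red-mask scenes are plume-only by design: with distractors
present in the red-mask frames, the early fine-tune epochs exhibit a
long non-monotone transient in the monitored Dice (suppression drags
all red down before the texture channels differentiate), which the
10-epoch patience mistakes for convergence. Even so, fine-tuning
remains stochastic at desk scale — an occasional seed still stops on
the plateau with little suppression — so two-stage behavior is always
assessed over three seeded replicates (majority in tests, median in
the acceptance script).

## What the synthetic results do and do not show

Passing tests establish that the machinery is correct: thresholds and
masks match per-pixel enumeration; panel selection equals exhaustive
search; the metric identities and stratification semantics hold; the
oracle video timeline equals brute-force pixel counts; and the
two-stage training exhibits the qualitative phenomenon of interest —
near-complete recovery of weak labels by the base model, then ≥50%
distractor false-positive suppression at ≤0.05 bleeding-Dice cost
after zero-mask fine-tuning.

They do not establish clinical performance. The synthetic scenes are
hard-edged and noiseless where real irrigated footage has motion blur,
specular reflections, bubbles, instruments, mixed dilution gradients
and compression artifacts; the annotator model is a geometric
perturbation, not a model of clinical judgment; and the numpy pixel
classifier is far smaller than a full encoder–decoder segmentation
network. Published full-scale figures (e.g. Dice ≈ 0.79 on
GT-positive images, AP ≈ 0.94) are therefore not reproduction targets
at desk scale, and the throughput utility measures whatever hardware
it runs on.

## Known limitations

* MP4 I/O is not provided; videos are frame directories.
* The learning rate, batch size and patience values are treated as
  fixed pipeline constants; no hyperparameter search is implemented.
* The rater noise model cannot produce false-positive annotations on
  truly empty regions (an empty truth mask stays empty).
* Fine-tune augmentation (flip/brightness/saturation in `dataset_io`)
  is available as a preprocessing op but the desk-scale training loop
  trains on cached unaugmented pixel samples.
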