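# Methods

## Problem and scope

Intrapartum cardiotocography (CTG) pairs a fetal heart rate (FHR) trace in
beats per minute with a uterine contraction (UC) pressure trace in mmHg.
Clinically the 20-minute recording is triaged visually into *Reassuring*
(FIGO Category I) versus *Non-Reassuring* (Categories II Suspicious and III
Abnormal merged), a reading with substantial inter-observer variability.
This package implements an objective pipeline for that triage decision when
the recording is only available as a printed, gridded report page:

1. **Digitization** — recover physical-unit FHR/UC series from the raster
   page;
2. **Classification** — a CBAM-augmented EfficientNet-B0 over a
   re-rendered, standardized image of the reconstructed signals;
3. **Evaluation** — confusion-matrix and ranking metrics under stratified
   cross-validation, plus cohort-comparison statistics.

A synthetic chart generator with exact ground truth makes every stage
testable end to end without clinical data.

## Chart model and digitization

A report page carries four panels in reading order: FHR then UC for the
first ten minutes, FHR then UC for the second ten. The FHR axis spans
60–210 bpm and the UC axis 0–100 mmHg. In grayscale, grid lines and shadow
bands print darker than the trace, so a global threshold at gray level 65
separates them: pixels ≥ 65 are kept as curve foreground, pixels < 65 are
discarded as background. The synthetic renderer enforces this contract
exactly (trace gray 255, grid 40, shadow 55, background 12, all
configurable), which makes the binarization stage's behavior checkable
pixel-for-pixel against the renderer's own trace mask.

**Pixel-to-value mapping.** Within a panel of height *h* pixel rows, a row
*y* maps linearly to a value

&nbsp;&nbsp;&nbsp;&nbsp;v = vmin + y′/(h−1) · (vmax − vmin),

where y′ is the row offset measured upward from the panel's bottom row
(image rows grow downward while values grow upward). The discrete-grid
denominator h−1 makes the bottom row map exactly to vmin and the top row
exactly to vmax; the vertical quantization step is (vmax−vmin)/(h−1), about
0.6 bpm for the default 256-row FHR panels. The renderer uses the exact
inverse (nearest-row placement, no anti-aliasing), so render→digitize error
is bounded by half a quantization step for constant traces.

**Trace extraction.** Columns are sampled at fixed horizontal intervals set
by the panel width and the 10-minute panel duration (default output rate
4 Hz, the convention of public CTG signal databases). Per sampled column
the trace row is the **median** foreground row, which is robust to the
2-pixel trace thickness, vertical connecting segments on steep slopes, and
isolated speckle. Columns with no foreground are marked invalid and filled
by linear interpolation between the nearest valid columns (edge gaps held
constant); the validity mask is preserved so consumers can exclude filled
samples. The two 10-minute segments per channel are then concatenated
chronologically.

**Model input.** The reconstructed pair is re-rendered onto a blank square
canvas — FHR in the upper half, UC in the lower, same linear axes — then
replicated to 3 channels and Z-score normalized per image (ε-guard returns
an all-zero tensor for a zero-variance canvas). Whether the published
approach re-renders the reconstruction or resizes the cleaned photograph is
ambiguous; re-rendering is adopted because it makes the input a pure
function of the recovered signals. Default size 224×224; the smoke
experiments render at 56×56 (see *Problem sizes* below).

**Region localization** is configuration-driven (`ChartLayout`); a
best-effort auto-detector from horizontal projection profiles is provided
as a convenience but is not part of the tested contract, since real-world
layouts vary by monitor vendor.

## Synthetic recordings

The generator emulates class-conditional CTG morphology with standard
pattern definitions:

* **Reassuring**: baseline 125–155 bpm; variability band 6–15 bpm
  (band-limited Gaussian noise, smoothed to the 0.1–0.5 Hz short-term
  variability band, peak-to-peak ≈ the stated amplitude); 2–4 accelerations
  of ≥ 15 bpm for ≥ 15 s.
* **Non-reassuring**: reduced variability ≤ 3 bpm and late decelerations —
  20–40 bpm dips whose centers lag the uterine contraction peaks by
  20–60 s.
* Both classes share a contraction train (peaks 40–80 mmHg, durations
  60–90 s, every 2.5–4.5 min over resting tone 5–15 mmHg).

Events are Gaussian bumps with σ = duration/4; FHR is clipped to
[60, 210] bpm and UC to [0, 100] mmHg (the chart axis spans). Recordings
are 20 min at 4 Hz, fully determined by a seed.

What this does *not* emulate: sensor dropout and artifact, page skew or
warp, printing noise, baseline drift and wandering, sinusoidal or saltatory
patterns, vendor-specific layouts. Passing tests therefore demonstrate the
pipeline's correctness on clean, geometrically ideal charts — they say
nothing about robustness to degraded real-world scans, which would need
real annotated data.

## Network

The classifier is the canonical EfficientNet-B0 backbone with a
convolutional block attention module (CBAM) on its final feature map:

* **Stem**: 3×3 stride-2 convolution (3→32 channels) + BatchNorm + SiLU;
  224×224 input → 32×112×112.
* **Stages**: seven MBConv stages, widths 16/24/40/80/112/192/320, repeats
  1/2/2/3/3/4/1, kernels 3/3/5/3/5/5/3, strides 1/2/2/2/1/2/1, ending at
  320×7×7. Stage 1 is MBConv1 (expansion 1); the rest are MBConv6
  (expansion 6). Each block: 1×1 expansion (skipped at expansion 1) →
  depthwise k×k (SE gate with hidden width C_in/4 on the expanded tensor) →
  1×1 projection, with the inverted residual Y = X + F(X) iff stride 1 and
  C_in = C_out.
* **Attention head**: CBAM refines the 320×7×7 feature serially — channel
  map Mc = σ(MLP(AvgPool F) + MLP(MaxPool F)) with a shared
  reduction-16 MLP, then spatial map Ms = σ(conv7×7([AvgPool; MaxPool]
  over channels)): F″ = Ms ⊗ (Mc ⊗ F). Both maps are sigmoid outputs, so
  refinement never increases an activation's magnitude.
* **Classifier**: global average pool → dropout 0.2 → FC(320→2). The
  canonical 320→1280 1×1 head convolution is available behind
  ``include_top_conv`` but off by default, matching the single-placement
  reading of the architecture diagram (CBAM directly on the 320-channel
  projection). No parameter count is asserted for either variant.

Compound scaling d = α^φ, w = β^φ, r = γ^φ is exposed as a standalone
utility and as ``width_mult``/``depth_mult``/``input_size`` knobs; widths
round to multiples of 8 (never dropping more than 10%), repeats to
⌈r·d⌉.

The network and its training loop run on a small reverse-mode autograd core
written in numpy inside the package (`ctgvision.model.autograd`). Every
operator — dense and depthwise convolution, batch normalization,
reductions, activations, fused softmax cross-entropy — is validated in the
test suite against finite-difference gradients and naive-loop oracles.
Computation is float64 throughout; convolutions use im2col with
scatter-add backward.

## Training

Defaults mirror the reported regimen for the full-size model: Adam,
learning rate 1e-4, batch size 64, weight decay 1e-5 (classic L2 added to
the gradient), cross-entropy over the two logits, early stopping with
patience 5 on the validation loss with best-epoch weight restoration.
Initialization is seeded Kaiming-normal; no pretrained weights are used, so
the tests need no downloads.

**Precise-BN re-estimation.** With few optimizer steps the exponentially
averaged BatchNorm running statistics (momentum 0.1) lag the batch
statistics badly, and the mismatch compounds across the network's ~20
normalization layers, corrupting eval-mode outputs. Before every
validation pass the trainer therefore replaces the running statistics with
exact cumulative averages over the training set (one extra forward pass per
epoch). This is a standard remedy in short-schedule training and is a
no-op asymptotically.

## Problem sizes and the smoke configuration

The package's experiments run on one CPU, so the end-to-end smoke
configuration (`RunConfig` defaults) uses the compound-scaling machinery to
instantiate a reduced variant: width ×0.25, depth ×0.5, 56×56 inputs
(~174k parameters), trained from scratch with learning rate 3e-3 and batch
size 16 for at most 10 epochs. The larger learning rate and smaller batch
are deliberate: from-scratch training of a freshly initialized network on a
few hundred samples needs on the order of a hundred parameter updates,
which the full-size regimen (1e-4, batch 64) cannot deliver in 10 epochs.
The default smoke experiment synthesizes 400 recordings at a balanced class
ratio, digitizes every page, and either evaluates one stratified 80/20
holdout (`run_holdout`) or a full stratified 5-fold cross-validation
(`run_experiment`). On clean synthetic charts the holdout reaches
validation accuracy ≥ 0.95 and AUC ≈ 1.0 within 10 epochs.

## Evaluation

Non-Reassuring is the positive class. Threshold metrics (accuracy,
sensitivity/recall, specificity, precision, F1) derive from the 2×2
confusion matrix; zero-denominator ratios return NaN with a warning. F1 is
reported both for the positive class and macro-averaged (the mean of the
two per-class F1 scores). AUC uses the midrank Mann–Whitney formulation;
average precision uses step-wise (non-interpolated) precision, whose
random-ranking baseline equals the positive-class prevalence. Stratified
k-fold assignment delegates to scikit-learn behind the package's own
surface; fold aggregation reports mean ± sample SD (n−1) per metric plus
the element-wise summed confusion matrix. Layer-wise t-SNE embeddings are
tapped at the raw input, stage-3 output, stage-6 output and post-CBAM
pooled feature (perplexity 30 capped at (n−1)/3, fixed seed).

Cohort comparison uses Welch's t-test computed from summary statistics
(n, mean, SD per group) for continuous rows and the continuity-corrected
chi-square for categorical 2×2 rows. The corrected form is chosen because
it reproduces the reference cohort table's printed p-values
(0.543 / 0.992 / 0.155) to three decimals, which the uncorrected Pearson
statistic does not (0.509 / 0.952 / 0.114).

## External records

A minimal MIT-format (WFDB) reader covers the package's needs: text header
with a pH comment, format-16 16-bit signal file, gain/baseline scaling.
FHR dropout samples (raw 0) are marked invalid and interpolated, matching
the digitization gap policy; records longer than 20 minutes are cropped to
their final 20 minutes — the stretch closest to delivery and hence to the
umbilical-artery pH outcome. The pH label rule is: ≥ 7.05 reassuring,
< 7.05 non-reassuring, with the boundary value itself reassuring.

## Numerical conventions and edge cases

* Binarization keeps gray exactly 65 as foreground ("below the threshold"
  is background).
* Median of an even foreground run is a fractional row; the linear mapping
  accepts fractional rows.
* `splice_segments` with an empty second segment is the identity.
* Degenerate (zero-variance) standardization inputs produce an all-zero
  tensor rather than dividing by zero.
* Tied maxima in the autograd `max` share the gradient equally.
* All randomness flows from explicit integer seeds; fixed seeds give
  bit-identical datasets, weights and embeddings.

## Known limitations

* The digitizer assumes axis-aligned, unwarped panels with known boxes; no
  dewarping or OCR of printed annotations.
* One y per column: the column-median extractor cannot represent
  multi-valued columns (pen lift-offs, overlapping twin traces).
* The numpy training core is CPU-bound and meant for the package's
  reduced-scale experiments, not for full-size 224×224 training runs.
* Synthetic morphology is template-based; no claim of physiological
  fidelity beyond the standard pattern definitions listed above.
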