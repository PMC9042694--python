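# Methods

## Model and assumptions

`cytomil` implements weakly supervised slide classification under the
standard multiple-instance assumption: a slide (bag) is malignant iff at
least one of its patches (instances) is malignant, and a benign slide
contains no malignant patch at all. The slide label is cast onto every
patch during stage-1 training, which makes the patch labels noisy in
exactly one direction: patches from benign slides are always correctly
labelled, while most patches from malignant slides are false positives
(background labelled 1). The two-stage procedure exploits this asymmetry —
the stage-1 scorer only needs to *rank* truly malignant patches above
background within each slide for the top-k selection to assemble a much
cleaner stage-2 training set.

Design choices in the trainer that were genuinely open, and how they were
resolved:

- **Both classes contribute top-k.** Ranking and top-k selection are
  applied to benign slides too (their top-k patches are hard negatives),
  in addition to the `n_neg_random` random patches per benign slide.
- **Stage 2 fine-tunes** the stage-1 weights rather than retraining from
  scratch; the stage-1 representation is the whole point of the ranking.
- **One selection round** by default (`iterate_rounds=1`); repeated
  re-rank/re-train cycles are available but not the default behaviour.
- **Tie-breaking** in the ranking is lexicographic by (row, col). Any
  deterministic rule works; determinism is the requirement, and it makes
  the top-k selection exactly reproducible and oracle-testable.
- **Loss** is binary cross-entropy on a sigmoid output; optimizer is SGD
  with momentum 0.9. Neither is dictated by the problem; both are the
  plainest defaults for binary patch classification and are fully exposed
  in `MILConfig`.

## Aggregation

A patch is malignant when its probability is strictly greater than
`patch_threshold` (0.50); a slide is malignant when strictly more than
`slide_threshold` (10) of its patches are malignant. Both inequalities are
deliberately strict and both thresholds sit in `AggregationRule`. The
slide-level continuous score used for ROC analysis is the *fraction of
malignant patches* — the natural monotone extension of the counting rule —
with the mean of the top-`slide_threshold` probabilities available as an
alternative (`score_mode="topk_mean"`). Increasing any patch probability
can only raise the malignant-patch count, so slide calls are monotone in
the patch scores (property-tested).

## The backbone

`small_cnn` is a three-block convolutional network written directly in
NumPy: 3x3 convolution (padding 1) -> ReLU -> 2x2 average pooling, with
widths 8/16/32, global average pooling and a single sigmoid unit. Inputs
are bilinearly resized to `input_px` (default 32) and scaled to [-1, 1].
Backpropagation is implemented via im2col, verified against numerical
differentiation; He initialisation comes from a seeded generator, and
training touches no global random state, so runs are bit-reproducible.
The design goal is a scorer that trains on a single CPU in seconds while
exercising the identical MIL machinery a large backbone would; it is not
intended to be competitive on real cytomorphology, and no pretrained
initialisation is bundled (`init="imagenet_pretrained"` raises).

## Tiling and augmentation

Tiling crops non-overlapping `patch_px` squares on a 0-based, row-major,
half-open grid; remainder strips that cannot fit a full patch are discarded
by default (`keep_partial_edges` retains them), and background filtering by
mean intensity is off by default since blank-region exclusion is
situational. Downscaling to `model_px` uses bilinear interpolation —
standard for photographic content — and is recorded in the config.

Augmentation is a deterministic enumeration of exactly four variants per
patch: original, horizontal flip, vertical flip, and one colour-jittered
copy. The fixed 4x factor is what makes dataset bookkeeping exact
(`augment_manifest` expands record tables without touching pixels, so
multi-million-patch counts are pure arithmetic through the same code path).
Jitter amplitudes default to 0.1 per property (brightness, contrast,
saturation, each a factor drawn from U[1-a, 1+a]) — mild enough not to
destroy the label, and all in `AugmentConfig`. Jitter is not applied on top
of the flipped variants; the expansion factor is exactly 4, not 8.

## Synthetic data: what it does and does not emulate

The generator emulates the *data regime* of weakly labelled cytology: bags
of patches, slide-level labels, a minority of truly positive instances in
positive bags, zero positives in negative bags. A benign patch is a bright
textured field (base colour plus low-frequency blotch plus Gaussian noise,
`noise_sd` default 8 intensity units); a malignant patch additionally
carries 3–6 dark elliptical clusters whose depth scales with
`motif_contrast` (default 0.6), giving a separability knob that is
monotone in the measured intensity margin (asserted in tests). It does
*not* emulate real cytomorphology: no staining variation, no mesothelial
look-alikes, no focus artefacts, no class imbalance across scanners.
Passing the end-to-end tests therefore demonstrates that the MIL mechanics
recover plantable instances and classify slides correctly when a separable
instance signal exists — not that the bundled backbone would reach clinical
accuracy on real slides.

Default study conditions (the bundled `configs/demo.yaml`): 36 slides
(18 malignant / 18 benign) on 8x8 grids of 64 px patches, split
20 train / 6 validation / 10 test, `pos_patch_fraction=0.2` (13 motif
patches per malignant slide, comfortably above the >10 aggregation rule),
model input 32 px. These sizes were chosen as a desk-scale regime that a
single CPU traverses in well under a minute; patch-level positivity rates
of real malignant slides are unknown, so `pos_patch_fraction` is an
exploration parameter, not an estimate.

## Splitting

Slides are allocated to train/validation/test by stratified random
assignment. Within each class, split sizes follow largest-remainder
rounding of the requested fractions — deterministic, sums exactly, and
keeps each split's class proportion within one slide of the overall
proportion. By default an error is raised if a non-empty split would
receive zero slides of either class.

## Evaluation

- **Confusion metrics** are exact integer counts; accuracy, sensitivity and
  specificity are displayed as percentages rounded half-up to two decimals
  (full precision retained internally).
- **AUC** is the trapezoidal area under the empirical ROC (equivalently the
  Mann–Whitney pairwise statistic, with ties counting half; the equivalence
  is tested against an O(n²) oracle). The 95% CI is a percentile bootstrap
  over slides (default 2000 seeded replicates); resamples that lose one
  class entirely are skipped, the usual convention for small test sets.
- **Rater agreement** uses Kendall tau-b. Binary reads are massively tied,
  and only the tie-corrected variant can reach 1.0 for a rater identical to
  the gold standard. A constant rater has undefined tau, recorded as
  missing (NaN), never as 0.

## Randomness and reproducibility

One root seed drives everything. Each stage draws from a named substream
(`synth`, `split`, `jitter`, `negatives`, `weights`, `training_stage*`,
`bootstrap`) derived via `SeedSequence`, so changing one stage's consumption
never perturbs another. Two runs with the same config produce byte-identical
predictions (tested).

## Known limitations

- The `resnet18` backbone named in `PatchClassifier`'s interface is not
  provided; `small_cnn` is the only built-in scorer.
- The NumPy trainer is single-threaded and unsuitable for datasets beyond
  ~10⁴ patches; the module boundaries (scorer behind `PatchClassifier`)
  are where a GPU backbone would plug in.
- The continuous slide score is a modelling choice (malignant-patch
  fraction); other monotone statistics would yield different ROC curves on
  real data.
- Offline 4x augmentation quadruples storage; the in-memory path
  (`augment_dataset`) is the alternative for constrained runs.
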