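# Methods

## Problem and model

`retiqa` grades the quality of colour fundus (CF) and fluorescein
angiography (FA) retinal images along modality-specific categories —
contrast, focus, illumination and shadow & reflection for CF; contrast,
focus and noise for FA — plus an overall grade. Each category is treated
as an independent binary property (good / poor quality, derived from an
ordinal Likert grade 1–5 by the 1–2 good / 3–5 poor convention), and a
single convolutional network with one sigmoid head per category predicts
the probability of *poor* quality: a score of 1 means worst possible
quality.

The network is an 18-layer residual CNN (7×7 stem, four stages of two
basic blocks, global average pooling, linear head) with a channel-dropout
layer inside every residual branch, placed after the second convolution's
normalisation. Dropout serves two purposes:

* **regularisation** during training, and
* **Monte-Carlo-Dropout uncertainty** at inference: prediction runs
  T = 16 stochastic forward passes with dropout kept active; the mean of
  the per-pass probabilities is the reported probability p̂ and their
  variance u is the uncertainty score. u quantifies how much p̂ can be
  trusted; it is *not* the probability of poor quality. We use the
  population variance (divide by T), so the T = 1 edge case is defined
  (u = 0) and a dropout rate of 0 gives exactly u = 0. Dropout masks are
  resampled independently on every pass and are seeded, so fixed weights
  plus a seed reproduce predictions bit-for-bit.

Training minimises a **masked multi-label binary cross-entropy**: the mean
BCE over all (image, category) pairs that carry a label. Images without an
overall-quality label (synthetic datasets reproduce the partially
annotated archives this models: 81 % labelled for CF, 74 % for FA) simply
contribute nothing — no loss and no gradient — for that head, while the
remaining heads train normally. Masked targets hold a sentinel value that
is provably never read; a test perturbs it and asserts bit-identical
losses and gradients.

The network and its backward passes are implemented directly in numpy
(im2col convolutions, batch normalisation, channel dropout, Adam), which
keeps the package dependency-light and makes every computation — including
the dropout sampling — explicitly seedable. Gradients are verified against
central finite differences layer by layer in the test suite.

## Tunable parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `dropout_rate` | 0.2 | per-block channel-dropout probability; a standard value for MC-Dropout that leaves the mean prediction stable while giving a usable variance signal |
| `width_scale` | 0.25 | multiplies all stage widths (64/128/256/512 → 16/32/64/128); the full topology is recovered at 1.0, the default trains in ~2 min/10 epochs on one CPU |
| `input_side_px` | 64 | model input side; images are rescaled with an aspect-preserving zero pad so artefact geometry is never distorted. 64 px retains the phantom degradations while keeping desk-scale runtimes |
| `T` | 16 | stochastic passes per prediction |
| `tau` | 0.5 | per-image decision threshold: poor iff p̂ ≥ τ. `select_threshold` optionally tunes τ to maximise F1 for the poor class on held-out scores (candidates: midpoints of adjacent sorted unique probabilities plus 0.5; ties broken toward 0.5) |
| visit threshold | 0.5 | a visit's score is the mean of its images' binary overall decisions; the visit is poor iff score ≥ 0.5. The tie goes to *poor*, conservative toward re-acquisition |
| optimiser | Adam, lr 1e-3, batch 16 | plain unweighted BCE, no augmentation; all exposed in `TrainConfig`/YAML |
| epochs | 10 | with per-epoch model selection: the checkpoint with the best mean per-category validation AUC-ROC (dropout disabled, deterministic passes) is returned |

## Synthetic data: what it emulates, and what not

Clinical quality-grading datasets are private, so the `synthesis` module
generates labelled phantoms: a circular field of view (black outside), a
curvature-biased branching vessel tree leaving an offset optic disc, a
darker macula, and low-frequency texture. CF renders in fundus colours
(dark-red vessels); FA renders single-channel with bright vessels on a
dark background scaled by the dye phase `fa_phase` (0 = pre-dye early
frame, naturally dark and low-contrast; 1 = peak fluorescence).

Degradations are standard image-degradation operators applied in a fixed
order (contrast → focus → illumination → shadow & reflection → noise; real
artefacts have no canonical order, the fixed order buys reproducibility):

* **contrast**: affine compression toward the in-FOV mean (severity 1
  leaves 15 % of the original deviation);
* **focus**: Gaussian blur, σ = 2.5 · severity · side/64 px;
* **illumination**: multiplicative radial vignette plus global gain
  reduction;
* **shadow & reflection**: one soft-edged elliptical patch blended toward
  black (shadow) or white (reflection), polarity and placement drawn from
  the degradation seed;
* **noise** (FA): additive Gaussian plus multiplicative speckle.

Severity s ∈ [0, 1] maps to Likert grades through the step edges
0.15/0.35/0.55/0.75 — an even coverage with a slightly wider grade-1 bin
so mild artefacts stay "good"; severity 0 is an exact no-op by
construction. The overall grade of a synthetic image is the **worst
category grade**. In real gradings "overall quality" is an independent
human judgment, so this rule is a modelling choice, not a property of
clinical data.

Label/image consistency is enforced by per-category proxy statistics that
must be monotone in severity across seed-matched ladders: in-FOV intensity
std (contrast), mean Sobel gradient (focus), in-FOV mean (illumination),
max of the smoothed residual against the clean phantom (shadow &
reflection — the phantom's own bright optic disc dominates a plain
local-mean-deviation statistic at low severity, so the residual form is
used), and high-pass variance (noise).

Datasets follow a patient → visit → image hierarchy with 3–16 images per
visit, patient-level train/validation/test splits (validation:test ≈ 1:2
by patient count) and a configurable overall-label fraction applied to
the training split only. The default severity distribution is a
two-component mixture: each category independently poor with probability
0.3 (severity ~ U(0.7, 1.0)) and otherwise nearly clean
(U(0, 0.1)). The 0.3 weight keeps the derived overall label
non-degenerate (P(all categories good) ≈ 0.7⁴ ≈ 0.24 for CF) and mirrors
the imbalance flavour of real archives. FA phantoms draw
`fa_phase ~ U(0.5, 1.0)`: deep early-phase frames would look identical to
severe contrast degradation and make the synthetic contrast label
ill-posed.

**What passing tests do not show:** the phantoms are not photorealistic,
contain no disease lesions (which are known to confuse quality grading),
no device-specific noise floors, and their degradations are cleanly
parameterised single-cause artefacts. Recovery results on this benchmark
demonstrate that the method's machinery (masked training, MC-Dropout,
aggregation, evaluation) works end-to-end — they are not evidence of
clinical-grade performance.

## Evaluation conventions

* **Positive class = poor quality** for precision/recall/F1.
* AUC-ROC via the rank/Mann–Whitney equivalence (verified against a
  brute-force O(n²) pairwise oracle with ties counted ½); AUC-PRC as the
  step-wise average-precision integral, never interpolated.
* Metrics undefined on the data at hand (no positive examples, single
  class) are reported as NaN ("not available"), never as 0.
* **Uncertainty vs error**: all labelled (image, category) pairs are
  pooled, partitioned by correctness, and summarised by mean/median
  uncertainty.
* **Exclusion (selective-prediction) curve**: the scalar per-image
  uncertainty is the mean of the per-category variances; for each fraction
  q ∈ {0.1, 0.2, 0.3} the ⌈q·n⌉ most-uncertain images are removed (ties
  resolved stably by manifest order) and the pooled accuracy over all
  labelled pairs of the remainder is recomputed.
* **Uncertainty–probability correlation**: u is correlated with the
  extremity |p̂ − 0.5|, which linearises the expected ∩-shaped relation;
  a well-calibrated uncertainty yields a clearly negative Pearson r.
* **McNemar's test** (α = 0.05) on the discordant counts b, c: χ² =
  (b − c)²/(b + c) without continuity correction for b + c ≥ 25, exact
  two-sided binomial p = min(1, 2·P[Bin(b+c, ½) ≤ min(b, c)]) otherwise;
  b + c = 0 is degenerate with p = 1.

## Numerical choices and degenerate inputs

* Decision ties go to poor at both image (p̂ = τ) and visit (score =
  threshold) level.
* Probabilities are clipped to [1e-12, 1−1e-12] inside the loss; training
  aborts with a diagnostic on a non-finite loss.
* A batch whose labels are all masked contributes zero loss, warns, and
  performs no optimiser step.
* Batch-norm uses batch statistics during training and running statistics
  for both deterministic and MC inference, so the only stochasticity at
  prediction time is the dropout mask.
* Images are stored as 8-bit PNG; the ≤ 1/255 quantisation is part of the
  synthetic benchmark.
* All randomness flows from explicit seeds through `numpy.random`
  generators (`SeedSequence` spawning for datasets); regenerating a
  dataset or rerunning a pipeline with the same configuration is
  byte-identical.

## Study conditions used by the acceptance script

`scripts/acceptance.py` runs, per modality, the full pipeline at the
package's reference conditions: 600/100/200 train/validation/test images
at 128 px, the separable severity mixture above, width 0.25 / input 64 px,
10 epochs, T = 16. These sizes keep one modality under ~4 minutes on a
single CPU while leaving a comfortable margin on every recovered quantity.
Visit-level accuracy compares predicted visit decisions against the same
mean-of-binary-labels aggregation applied to the true overall labels.

## Known limitations

* The worst-category rule for the synthetic overall label ties the
  overall head to the category heads more tightly than a human overall
  judgment would.
* The numpy implementation is CPU-bound; `width_scale=1.0` with
  ImageNet-size inputs is supported but slow, and the `pretrained` hook
  only loads externally supplied weight files.
* Uncertainty is a heuristic ranking signal; no calibration into a
  "needs human review" flag is attempted.
* Visit aggregation uses the overall-quality head only and weighs all
  images of a visit equally, regardless of retinal field or FA phase.
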