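# Methods

This note documents the models, conventions and numerical choices behind
`featuregain`, what the synthetic cohort does and does not emulate, and the
known limitations of the analysis it validates.

## Stimuli and degradation

Stimuli are square grayscale images with luminance in [0, 1]. Degradation is
a square moving-average ("box") filter whose side is a stated fraction of
the image side; the standard levels are 25%, 12%, 6% and 0% (the untouched
original), presented within a sequence from strongest blur to original so
that earlier trials carry no pixel-level information about later ones.

Two details of the filter are underdetermined by a percentage alone and are
fixed here explicitly:

* **Boundary handling** — symmetric (mirror) padding with a same-size
  output. This preserves constant images exactly and introduces no dark
  frame; the implementation (a summed-area table over the padded image) is
  tested against a direct O(k²) sliding-window oracle.
* **Kernel rounding** — k = max(1, round(fraction × side)) with half-up
  rounding; even kernels anchor on the top-left of the absent center. For a
  500-pixel image the three levels give 125-, 60- and 30-pixel kernels.

The synthetic image generator places a category motif — a few overlapping
oriented Gaussian ridges with per-image jitter, five motifs standing in for
the five prior-condition object categories — on a smoothed-noise background,
plus fine i.i.d. texture (SD 0.05). The texture matters: it gives images
genuine high-spatial-frequency content so that blurring destroys local
detail while the global arrangement survives, which is the regime the
analysis is about.

## Feature model

Features come from a fixed hierarchical feedforward network: convolutions
and fully connected maps with rectifiers between layers (softmax nominally
on the last layer). Stored features are always the **pre-activation** values
z_n = c_n(w_n, x_n) + b_n. No pretrained weights are used: weights are drawn
once from a seeded standard normal scaled by 1/√fan-in. Random hierarchical
weights preserve the local-to-global receptive-field gradient across layers,
which is all the analysis logic needs; nothing here depends on the features
being semantically meaningful.

Two packaged specs:

* the **8-layer reference architecture** (5 conv + 3 fc, 227-pixel input,
  with the max-pool stages between convolutions) exists for the
  dimension calculator — it reproduces the per-layer pre-activation unit
  counts 290400, 186624, 64896, 64896, 43264, 4096, 4096, 1000 — and for
  users who plug in real weights. Note the published layer types do not
  include pooling; the pool stages are required to reproduce those printed
  dimensions and are therefore part of the spec (unit counts remain
  pre-pool).
* the **desk-scale surrogate** (32-pixel input; 5-layer: 1000/1600/500/256/
  100 units; 3-layer: 1000/400/120) used by all synthetic studies. Feature
  extraction takes well under a millisecond per image.

## Synthetic cohort

The generator mirrors the experimental design: per subject, training runs
of non-blurred images (default 1000 images in 20 runs of 50) and, per
condition (no-prior / category-prior), test runs of blurred-to-original
4-trial sequences (default 80 sequences over two runs of 40). Training and
test images are disjoint by construction.

**Voxel model.** Each voxel is assigned one network layer (sampled from its
region's depth-weighted mixing distribution) and reads a sparse random
linear combination (Bernoulli mask, default density 0.05, at least one
nonzero weight, 1/√nnz scaling) of that layer's **standardized** features
(per-unit z-scores over the training set). Regions follow the visual
hierarchy nomenclature (V1…PPA atomic; LVC/HVC/VC as voxel-set unions), with
shallow-weighted readouts for early areas and deep-weighted for higher ones.

**Sharpening.** The represented features of a test trial are
z\* = (1 − α_l)·z(stimulus) + α_l·z(original) per layer l, with α possibly
condition-dependent. This convex interpolation is the minimal generative
model under which "decoded features veer toward the original" is literally
true and recoverable; it is ground truth for recovery tests, not a claim
about mechanism. The default profile ramps α from 0.1 (shallow) to 0.5
(deep) and adds 0.15 under the category prior — a qualitative imitation of
a hierarchy-and-prior-dependent effect, exposed in configuration.

**Acquisition artifacts.** Each 8-s stimulus block is four volumes of
signal plus i.i.d. Gaussian voxel noise (default SD 1.0 on the standardized
signal scale, i.e. single-volume SNR ≈ 1, which yields decoded-vs-true
correlations around 0.6–0.7 at 0% blur after block averaging — in the upper
range of published feature-decoding accuracies). Runs add a per-voxel
baseline and a shared linear drift; the hemodynamic delay is represented as
one leading rest volume that the preprocessing shift re-absorbs. There is no
HRF convolution, no spatial autocorrelation, no motion — detrending and
z-scoring therefore invert the injected artifacts essentially exactly, which
is verified by round-trip tests.

**Behavior.** Recognition and certainty reports are Bernoulli draws coupled
to a trial fidelity computed from the generative state (blur level, partially
restored by mean α): P(correct) = chance + (1 − chance)·logistic(slope·(fidelity − mid)),
with chance 1/5 under the category prior and ≈0 without. Missing button
responses copy the previous response in the sequence, except the first
trial (forced uncertain) and the last (forced certain). Behavior only needs
the right statistical coupling for grouping analyses; it is not computed
from image content.

All randomness flows from one master seed through SHA-256-named substreams,
so regeneration is bit-exact and adding a new stream never perturbs others.

## Decoding

Preprocessing per run: volume shift (1 volume), per-voxel least-squares
linear detrend, per-voxel z-scoring within run, then averaging the four
volumes of each trial into one pattern. Note that detrending also removes
the stimulus signal's own chance linear component — exact for the injected
drift, slightly lossy for the signal, negligible for runs of ≥ 40 trials.

Decoder protocol, exactly in the train-only normalization convention:
training patterns and features are z-scored with recorded means/SDs
(zero-variance voxels dropped, zero-variance units skipped); test patterns
are normalized with the *recorded training* statistics; predictions are
denormalized by multiplying with the training feature SD only — the mean is
never added back, so predictions live in train-mean-centered space and all
"true" feature vectors used for correlation are train-mean-centered to
match.

Feature units are selected per layer by cross-validated decodability
(2 interleaved folds, one-shot ridge over all units via SVD, λ = 100),
averaged across subjects, top-k by score with ties broken by ascending
index; a layer with at most k units keeps all of them. Voxel selection per
unit takes the k voxels with the highest |Pearson correlation| with the
unit over training (absolute value because negatively correlated voxels are
equally informative for a linear decoder; a `signed_selection` switch
restores positive-only ranking).

The per-unit decoder is automatic-relevance-determination linear
regression: per-weight precision hyperparameters with evidence-approximation
updates (γ_j = 1 − α_j Σ_jj; α_j ← γ_j/m_j²; β ← (n − Σγ)/RSS), pruning a
weight to exact zero once its precision exceeds 1e8. Convergence is declared
when the maximum absolute weight change and the relative noise-precision
change both fall below `tol` — a weight-space criterion, because the
precisions of irrelevant weights grow without bound until they hit the
pruning cap and never "converge" themselves. Defaults are tol 1e-6 and 500
iterations; the replicate studies use tol 1e-4 and 150 iterations, which
changes gains by far less than their Monte-Carlo spread. Non-convergence
returns the last iterate with a warning flag. A ridge fallback is
selectable. The implementation is verified against OLS on full-rank
noise-free data, against planted sparse models, and against an independent
ARD implementation (scikit-learn's) on noisy data.

## Metrics

r_s and r_o are Pearson pattern correlations over the selected units of one
layer; for 0%-blur trials the two targets are identical and r_s = r_o
exactly. The noise-matched baseline solves, per 0%-blur stimulus i with
decoded-vs-true correlation ρ_i and true-vector SD s_i,
σ_i = s_i·√(1/ρ_i² − 1) (closed form of E[corr(f, f+ε)] = s/√(s²+σ²)), and
uses the mean σ_i across images per subject × ROI × layer; stimuli with
ρ_i ≤ 0.05 are excluded (the method is silent on failed 0% decoding; this
floor is ours). A `pooled_rho` switch instead solves one σ at the pooled
mean correlation — a documented alternative since per-image-then-average
and pool-then-solve differ at second order. Δr_noise is Monte-Carlo
averaged over 100 seeded noise draws per trial. Per-stimulus gains
(Δr_decode − Δr_noise) are computed per trial and averaged afterwards;
0%-blur rows never enter gain summaries.

Because ρ_i is estimated from a finite number of units, σ(ρ) is convex and
the per-image-mean σ is biased upward by estimation noise; with ~100 units
per layer the end-to-end matching error stays within 0.02 (audited on every
run), with ~10 units it can reach 0.1. Cells should therefore use ≥ 100
selected units when the matching tolerance matters.

Content specificity compares, over blurred trials, the correlation of
decoded features with their own original (same-image), with the other
originals in the test set (different-image; n−1 comparisons per stimulus,
39 for a 40-image set), and the true-feature baseline (stimulus features
against noncorresponding originals).

## Statistics

Gains are averaged over stimuli within subject per grouping cell, then
tested across subjects: two-sided one-sample t against zero with the
Bonferroni family supplied by the analysis recipe (24 for the 8-layer ×
3-blur grid, 8 for per-layer condition contrasts, 16 for condition ×
recognition grids), flagging p < α/m; 95% CIs as mean ± t₀.₉₇₅,ₙ₋₁·SD/√n.
Zero-variance cells raise instead of reporting p = 0, which would silently
corrupt a Bonferroni family. Factorial ANOVA is a fixed-effects linear
model with sum-to-zero contrasts and Type II sums of squares (chosen
because cells are unbalanced after behavioral grouping; the ANOVA type is
otherwise a free choice), with empty cells raising an aliasing error naming
the cells. Subjects are averaged before the ANOVA; treating subject as a
factor is a documented alternative, not implemented.

## Validation studies and their sizes

The packaged studies (`featuregain.studies`) run at reduced sizes chosen so
a replicate finishes in seconds to tens of seconds on one CPU:

* **Null calibration** — 5 subjects, 200 training images, 40 test sequences
  (20 per condition), 3-layer network, two 300-voxel regions, 100 selected
  units and 100 selected voxels per decoder, 10 replicate cohorts.
* **α recovery / depth localization** — 3 subjects, 120 training images,
  24 sequences, one 200-voxel region, 60 units, 80 voxels. The α sweep uses
  common random numbers across {0, 0.3, 0.6, 0.9} and reuses the decoders
  (training data are α-independent), isolating the sharpening effect.

## Known limitations

* **The feature-gain null is positively biased at desk scale.** With α ≡ 0
  the generator is a pure feedforward observation model, yet the measured
  mean gain is systematically positive (order +0.01 to +0.05 per cell under
  the null-calibration conditions). The mechanism, isolated by decoding
  noise-free test signals: a regularized linear decoder reconstructs
  features through the training-feature covariance and attenuates the
  blur-specific feature component more than the component the blurred and
  original images share, so decoded features genuinely veer toward the
  original even without generative sharpening — while the noise-matched
  baseline models all decoding error as isotropic noise and therefore
  under-corrects. The bias shrinks with decoding fidelity but does not
  vanish with lower noise or more training data at these cohort sizes.
  Consequence: near-zero empirical gains should not be read as evidence of
  sharpening without a matched null simulation, and the null-calibration
  acceptance check fails its CI-coverage target under these study
  conditions — deliberately left failing rather than masked by added
  between-subject variance or retuned generator settings. Differences and
  trends in gain (between α levels, conditions, layers) are recovered
  reliably; the absolute zero point is not.
* The cohort omits HRF dynamics, spatial noise correlation, motion,
  session effects and genuine between-subject heterogeneity; passing tests
  show the analysis logic is correct under the stated observation model,
  not that it is robust to real fMRI artifacts.
* Pattern correlations over ~100 selected units are noisy (SE ≈ 0.1 per
  trial); all study conclusions are about means over trials and subjects.
* The behavioral model couples reports to ground-truth fidelity, not image
  content; it supports grouping analyses, not psychophysics.
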