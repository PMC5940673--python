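# featuregain

**Does the visual system sharpen its representation of a blurred image toward
the original?** One way to ask this quantitatively is to decode brain activity
into the feature space of a hierarchical feedforward network and measure
whether the decoded features of a blurred stimulus resemble the *non-blurred
original* more than a pure feedforward account predicts. `featuregain`
implements that analysis as a tested Python pipeline, replacing the fMRI
recordings with a synthetic voxel-encoding cohort whose ground-truth
"sharpening" is an explicit, recoverable parameter.

It is aimed at computational neuroscientists who want to study the behavior
of decoder-based sharpening analyses — calibration, power, biases — under a
fully known generative model, and at anyone who needs the building blocks:
box-blur stimulus degradation, a seeded feedforward feature extractor,
sparse (ARD) linear feature decoders with the exact train-only
normalization conventions, the noise-matched feedforward baseline, and the
feature-gain statistic with its inferential machinery.

## The statistic

For each stimulus, decoders predict a per-layer feature vector from the
voxel pattern. With Pearson pattern correlations against the true features
of the blurred stimulus image (*r<sub>s</sub>*) and of the original image
(*r<sub>o</sub>*):

&nbsp;&nbsp;&nbsp;&nbsp;Δr<sub>decode</sub> = r<sub>o</sub> − r<sub>s</sub>

A feedforward system with decoding noise also produces a (negative)
Δr, so the baseline is computed from *noise-matched features* — true
stimulus features plus Gaussian noise whose level σ is calibrated in closed
form (σ = s·√(1/ρ² − 1)) so that the noisy-vs-true correlation equals the
decoded-vs-true correlation for the non-blurred stimuli, averaged across
images per subject × ROI × layer:

&nbsp;&nbsp;&nbsp;&nbsp;Δr<sub>noise</sub> = r<sub>o</sub><sup>noise</sup> − r<sub>s</sub><sup>noise</sup>

&nbsp;&nbsp;&nbsp;&nbsp;**feature gain = Δr<sub>decode</sub> − Δr<sub>noise</sub>**

Positive gain means the decoded representation is biased toward the original
image beyond what feedforward processing plus decoding error explains.

The synthetic cohort makes "sharpening" generative: each voxel reads a
sparse random linear combination of standardized layer features, and the
represented features of a test trial are the convex interpolation
z\* = (1 − α)·z(stimulus) + α·z(original), with α per layer and condition.
α = 0 is the pure feedforward null; recovering injected α profiles is the
package's core validation.

## A worked example

`examples/03_decode_and_gain.py` generates a 2-subject cohort with a
depth-ramped sharpening profile (α from 0.15 shallow to 0.45 deep, +0.15
under the category prior), trains decoders on 100 non-blurred training
images, decodes 10 blurred-to-original test sequences per condition, and
prints:

```
decoded-vs-true correlation at 0% blur (decoding quality):
roi  layer
HVC  DNN1     0.653
     DNN2     0.619
     DNN3     0.704
...

mean feature gain (blur levels pooled, 0% excluded):
roi  layer
HVC  DNN1     0.1025
     DNN2     0.1202
     DNN3     0.1141
LVC  DNN1     0.0683
     DNN2     0.0886
     DNN3     0.0649

mean feature gain by condition (category prior adds sharpening):
condition       layer
category-prior  DNN1     0.0987
...
```

Decoding works (ρ ≈ 0.6–0.7 at 0% blur), the injected sharpening expresses
as clearly positive feature gain, and the category-prior condition — whose
generative α is 0.15 higher — shows larger gain than the no-prior
condition. `examples/04_alpha_recovery.py` sweeps α over {0, 0.3, 0.6, 0.9}
with common random numbers and prints the monotonically increasing
cohort-mean gain, plus a deep-only profile whose gain localizes to the
deepest layer.

## The pipeline

The same analysis runs as a resumable stage graph from the shell:

```bash
featuregain all --config my_config.yaml --seed 7 --outdir out/
featuregain report --config my_config.yaml --outdir out/ --resume
```

Stages `generate → features → train → decode → analyze → report` write
HDF5/CSV outputs plus JSON manifests (config hash, seed, input hashes, wall
time); a stage re-run under a changed configuration raises a conflict
instead of silently mixing results. Without `--config` a small built-in
demo configuration is used.

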