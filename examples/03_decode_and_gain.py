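"""End-to-end feature-gain analysis on a small synthetic cohort.

Generates a 2-subject cohort whose voxels encode features with moderate
generative sharpening (alpha ramping from 0.15 shallow to 0.45 deep, plus a
0.15 category-prior boost), trains sparse decoders on the non-blurred
training runs, decodes the blurred test trials, and prints the mean feature
gain per ROI x layer.  Positive gain means decoded features of blurred
stimuli resemble the original image more than the noise-matched
pure-feedforward baseline predicts; with sharpening injected, gains are
clearly positive and grow toward the deeper layer.
"""

import logging

from featuregain.cohort import CohortConfig, ROISpec, SharpeningProfile
from featuregain.network import default_spec
from featuregain.pipeline import PipelineConfig, run_in_memory

logging.disable(logging.WARNING)

config = PipelineConfig(
    cohort=CohortConfig(
        n_subjects=2,
        n_train_images=100,
        train_run_size=50,
        n_test_sequences=10,
        test_runs_per_condition=1,
        network=default_spec(n_layers=3),
        rois=(
            ROISpec("LVC", 150, (0.6, 0.3, 0.1)),
            ROISpec("HVC", 150, (0.1, 0.3, 0.6)),
        ),
        sharpening=SharpeningProfile.depth_ramp(0.15, 0.45, 3, prior_boost=0.15),
    ),
    master_seed=7,
    k_voxels=75,
    k_features=40,
    slr_tol=1e-4,
    slr_max_iter=150,
    n_draws=60,
)

result = run_in_memory(config)

print("decoded-vs-true correlation at 0% blur (decoding quality):")
print(result["audit"].groupby(["roi", "layer"])["mean_rho_decoded"]
      .mean().round(3).to_string())

print("\nmean feature gain (blur levels pooled, 0% excluded):")
print(result["gain_table"].groupby(["roi", "layer"])["gain"]
      .mean().round(4).to_string())

print("\nmean feature gain by condition (category prior adds sharpening):")
print(result["gain_table"].groupby(["condition", "layer"])["gain"]
      .mean().round(4).to_string())
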