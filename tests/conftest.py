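"""Shared fixtures: a tiny but complete synthetic cohort with trained decoders.

The tiny cohort is deliberately small (2 subjects, 80 training images, 6 test
sequences per condition, 80 voxels per region) so the full
generate-train-decode-analyze path runs in seconds; tests that need specific
study conditions build their own configurations.
"""

from __future__ import annotations

import logging

import numpy as np
import pytest

from featuregain.cohort import CohortConfig, ROISpec, SharpeningProfile, generate_cohort
from featuregain.network import default_spec
from featuregain.pipeline import PipelineConfig, run_in_memory

logging.getLogger("featuregain").setLevel(logging.ERROR)


def tiny_cohort_config(alpha: float = 0.0, prior_boost: float = 0.0,
                       n_subjects: int = 2) -> CohortConfig:
    return CohortConfig(
        n_subjects=n_subjects,
        n_train_images=80,
        train_run_size=40,
        n_test_sequences=6,
        test_runs_per_condition=1,
        network=default_spec(n_layers=3),
        rois=(
            ROISpec("LVC", 80, (0.6, 0.3, 0.1)),
            ROISpec("HVC", 80, (0.1, 0.3, 0.6)),
        ),
        sharpening=SharpeningProfile.uniform(alpha, 3, prior_boost=prior_boost),
    )


def tiny_pipeline_config(tmp_outdir="featuregain_out", **overrides) -> PipelineConfig:
    cfg = PipelineConfig(
        cohort=tiny_cohort_config(**{k: overrides.pop(k) for k in
                                     ("alpha", "prior_boost", "n_subjects")
                                     if k in overrides}),
        master_seed=2024,
        outdir=str(tmp_outdir),
        k_voxels=40,
        k_features=12,
        slr_tol=1e-4,
        slr_max_iter=120,
        n_draws=40,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


@pytest.fixture(scope="session")
def tiny_cohort():
    return generate_cohort(tiny_cohort_config(), master_seed=2024)


@pytest.fixture(scope="session")
def tiny_analysis(tiny_cohort):
    """Full in-memory pipeline result on the tiny alpha=0 cohort."""
    cfg = tiny_pipeline_config()
    return run_in_memory(cfg, cohort=tiny_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
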