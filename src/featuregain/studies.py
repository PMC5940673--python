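"""Packaged validation studies: null calibration, parameter recovery, layer
localization.

These functions define the package's standard simulation studies at desk
scale and are used by the examples and the acceptance checks:

* **Null calibration** - cohorts generated with sharpening ``alpha = 0`` are
  pure feedforward observation models; the analysis should attribute no
  (or minimal) feature gain to them.  The study reports per-cell subject
  means, 95% CIs and the noise-matching audit over replicate cohorts.
* **Parameter recovery** - cohort-mean feature gain should increase with the
  generative sharpening strength.  The alpha sweep holds the master seed
  fixed within a replicate (training data and noise draws are identical
  across alphas; only the represented test features move), a matched
  comparison that isolates the effect of the sharpening parameter.
* **Layer localization** - sharpening injected only into the deepest layer
  should express as larger gain for that layer's decoded features than for
  the shallowest layer's.

Study sizes are reduced relative to the full experimental design so a
replicate finishes in seconds to tens of seconds on one CPU; the methods
note documents the sizes.
"""

from __future__ import annotations

import pandas as pd

from .cohort import CohortConfig, ROISpec, SharpeningProfile, generate_cohort
from .network import default_spec
from .pipeline import PipelineConfig, run_in_memory
from .stats import ci95_across_subjects

__all__ = [
    "null_calibration_config",
    "recovery_config",
    "run_null_calibration",
    "run_alpha_sweep",
    "run_depth_study",
]


def null_calibration_config(master_seed: int, alpha: float = 0.0) -> PipelineConfig:
    """Reduced-size study conditions for the null-calibration cohort.

    5 subjects, 200 training images (4 runs of 50), 40 test sequences
    (20 per condition), a 3-layer network, and two 300-voxel regions with
    shallow- and deep-weighted readouts.
    """
    cohort = CohortConfig(
        n_subjects=5,
        n_train_images=200,
        train_run_size=50,
        n_test_sequences=20,
        test_runs_per_condition=1,
        network=default_spec(n_layers=3),
        rois=(
            ROISpec("LVC", 300, (0.6, 0.3, 0.1)),
            ROISpec("HVC", 300, (0.1, 0.3, 0.6)),
        ),
        sharpening=SharpeningProfile.uniform(alpha, 3),
    )
    return PipelineConfig(
        cohort=cohort,
        master_seed=master_seed,
        k_voxels=100,
        k_features=100,
        slr_tol=1e-4,
        slr_max_iter=150,
        n_draws=100,
    )


def recovery_config(master_seed: int,
                    profile: SharpeningProfile | None = None) -> PipelineConfig:
    """Smaller cohort for the alpha-sweep and layer-localization studies."""
    cohort = CohortConfig(
        n_subjects=3,
        n_train_images=120,
        train_run_size=40,
        n_test_sequences=12,
        test_runs_per_condition=1,
        network=default_spec(n_layers=3),
        rois=(ROISpec("VC", 200, (1 / 3, 1 / 3, 1 / 3)),),
        sharpening=profile or SharpeningProfile.uniform(0.0, 3),
    )
    return PipelineConfig(
        cohort=cohort,
        master_seed=master_seed,
        k_voxels=80,
        k_features=60,
        slr_tol=1e-4,
        slr_max_iter=150,
        n_draws=60,
    )


def run_null_calibration(n_replicates: int = 10, base_seed: int = 0) -> dict:
    """Replicate alpha=0 cohorts; collect per-cell CIs and the matching audit.

    Returns ``cells`` (one row per replicate x ROI x layer with the subject
    mean gain, 95% CI and coverage flag), ``audit`` (noise-matching check per
    subject x ROI x layer x replicate) and ``content`` (content-specificity
    summary of the first replicate).
    """
    cell_rows = []
    audit_frames = []
    content = None
    for rep in range(n_replicates):
        cfg = null_calibration_config(master_seed=base_seed + rep)
        res = run_in_memory(cfg)
        per_subject = (
            res["gain_table"].groupby(["subject", "roi", "layer"], as_index=False)["gain"].mean()
        )
        for (roi, layer), sub in per_subject.groupby(["roi", "layer"]):
            values = sub["gain"].to_numpy()
            lo, hi = ci95_across_subjects(values)
            cell_rows.append(
                {
                    "replicate": rep, "roi": roi, "layer": layer,
                    "mean_gain": float(values.mean()),
                    "ci_lower": lo, "ci_upper": hi,
                    "covers_zero": bool(lo <= 0.0 <= hi),
                }
            )
        audit = res["audit"].copy()
        audit["replicate"] = rep
        audit_frames.append(audit)
        if rep == 0:
            content = res["content"]
    return {
        "cells": pd.DataFrame(cell_rows),
        "audit": pd.concat(audit_frames, ignore_index=True),
        "content": content,
    }


def run_alpha_sweep(alphas=(0.0, 0.3, 0.6, 0.9), master_seed: int = 0) -> pd.DataFrame:
    """Cohort-mean feature gain per alpha, with common random numbers.

    Decoders are trained once (training runs are identical across alphas)
    and reused, so differences between alphas reflect only the sharpening
    parameter.  Returns one row per alpha with the cohort-mean gain.
    """
    base_cfg = recovery_config(master_seed, SharpeningProfile.uniform(alphas[0], 3))
    first = run_in_memory(base_cfg)
    decoder_sets = first["decoder_sets"]
    rows = [{"alpha": float(alphas[0]),
             "mean_gain": float(first["gain_table"]["gain"].mean())}]
    for alpha in alphas[1:]:
        cfg = recovery_config(master_seed, SharpeningProfile.uniform(float(alpha), 3))
        cohort = generate_cohort(cfg.cohort, cfg.master_seed)
        from .decoding import stimulus_patterns

        test_patterns = {
            cohort.subjects[s].spec.subject_id: stimulus_patterns(cohort, s)[1]
            for s in range(len(cohort.subjects))
        }
        res = run_in_memory(cfg, cohort=cohort, decoder_sets=decoder_sets,
                            test_patterns=test_patterns)
        rows.append({"alpha": float(alpha),
                     "mean_gain": float(res["gain_table"]["gain"].mean())})
    return pd.DataFrame(rows)


def run_depth_study(master_seed: int = 0, deep_alpha: float = 0.6) -> pd.DataFrame:
    """Deep-only sharpening: per-layer cohort-mean gain.

    The profile sharpens only the deepest layer; the decoded gain should be
    localized there relative to the shallowest layer.
    """
    n_layers = 3
    alphas = [0.0] * n_layers
    alphas[-1] = deep_alpha
    profile = SharpeningProfile(no_prior=tuple(alphas), category_prior=tuple(alphas))
    cfg = recovery_config(master_seed, profile)
    res = run_in_memory(cfg)
    out = (
        res["gain_table"].groupby("layer", as_index=False)["gain"].mean()
        .rename(columns={"gain": "mean_gain"})
    )
    out["deep_alpha"] = deep_alpha
    return out
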