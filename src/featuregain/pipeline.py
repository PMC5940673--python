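"""Resumable analysis pipeline: generate -> features -> train -> decode ->
analyze -> report.

Each stage reads the previous stage's files from the output directory,
writes its own outputs plus a ``<stage>_manifest.json`` recording the
configuration hash, seed, input hashes, package version and wall time, and
is idempotent given the same configuration and seed.  All randomness flows
from the master seed through named substreams, so adding a stage never
perturbs another stage's draws.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._seeds import subseed
from .cohort import CohortConfig, generate_cohort
from .decoding import (
    crossval_unit_scores,
    predict_features,
    stimulus_patterns,
    train_decoders,
)
from .errors import ConfigError, ConflictError, DependencyError
from .metrics import analyze_cohort
from .network import select_feature_units
from .stats import factorial_anova, gain_report
from .storage import (
    config_from_dict,
    config_to_dict,
    load_cohort,
    load_decoders,
    load_predictions,
    save_cohort,
    save_decoders,
    save_features,
    save_predictions,
)

__all__ = ["PipelineConfig", "STAGES", "run_stage", "run_all"]

logger = logging.getLogger(__name__)

STAGES = ("generate", "features", "train", "decode", "analyze", "report")


@dataclasses.dataclass
class PipelineConfig:
    """Everything one end-to-end run needs, serializable to YAML."""

    cohort: CohortConfig = dataclasses.field(default_factory=CohortConfig)
    master_seed: int = 0
    outdir: str = "featuregain_out"
    # decoder hyperparameters
    k_voxels: int = 500
    k_features: int = 1000
    slr_tol: float = 1e-6
    slr_max_iter: int = 500
    slr_method: str = "ard"
    signed_selection: bool = False
    # metric options
    n_draws: int = 100
    rho_floor: float = 0.05
    pooled_rho: bool = False
    content_roi: str | None = None
    # stats recipe
    bonferroni_m: int | None = None  # default: n_layers x n_nonzero_blurs

    def validate(self) -> None:
        bad = []
        if self.k_voxels < 1:
            bad.append("k_voxels")
        if self.k_features < 1:
            bad.append("k_features")
        if self.slr_method not in ("ard", "ridge"):
            bad.append("slr_method")
        if self.n_draws < 1:
            bad.append("n_draws")
        if not 0 <= self.rho_floor < 1:
            bad.append("rho_floor")
        if bad:
            raise ConfigError("invalid pipeline configuration", keys=tuple(bad))
        self.cohort.validate()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"] = config_to_dict(self.cohort)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        cohort = d.pop("cohort", None)
        cfg = cls(**{k: v for k, v in d.items() if k in {f.name for f in dataclasses.fields(cls)} - {"cohort"}})
        if cohort is not None:
            cfg.cohort = config_from_dict(cohort) if isinstance(cohort, dict) else cohort
        return cfg

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _manifest_path(outdir: Path, stage: str) -> Path:
    return outdir / f"{stage}_manifest.json"


def _write_manifest(outdir: Path, stage: str, config: PipelineConfig,
                    inputs: list[Path], outputs: list[Path], t0: float) -> None:
    manifest = {
        "stage": stage,
        "seed": config.master_seed,
        "config_hash": config.config_hash(),
        "version": __version__,
        "inputs": {p.name: _hash_file(p) for p in inputs if p.exists()},
        "outputs": [p.name for p in outputs],
        "wall_time_s": round(time.time() - t0, 3),
        "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    _manifest_path(outdir, stage).write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _check_upstream(outdir: Path, stage: str, config: PipelineConfig) -> None:
    i = STAGES.index(stage)
    if i == 0:
        return
    upstream = STAGES[i - 1]
    mpath = _manifest_path(outdir, upstream)
    if not mpath.exists():
        raise DependencyError(f"stage {stage!r} requires stage {upstream!r} to have run")
    manifest = json.loads(mpath.read_text())
    if manifest.get("config_hash") != config.config_hash():
        raise ConflictError(
            f"stage {upstream!r} outputs were produced under a different configuration"
        )


def _stage_done(outdir: Path, stage: str, config: PipelineConfig) -> bool:
    mpath = _manifest_path(outdir, stage)
    if not mpath.exists():
        return False
    manifest = json.loads(mpath.read_text())
    return manifest.get("config_hash") == config.config_hash()


# ---------------------------------------------------------------------------
# Stage bodies
# ---------------------------------------------------------------------------


def _stage_generate(config: PipelineConfig, outdir: Path) -> None:
    cohort = generate_cohort(config.cohort, config.master_seed)
    save_cohort(cohort, outdir / "cohort")
    config.to_yaml(outdir / "config.yaml")


def _stage_features(config: PipelineConfig, outdir: Path) -> None:
    # the true per-trial features already live in the cohort container; this
    # stage exports them as a standalone feature archive with the spec sidecar
    cohort = load_cohort(outdir / "cohort")
    save_features(outdir / "features_train", cohort.config.network, cohort.train_features)
    save_features(outdir / "features_test_stim", cohort.config.network,
                  cohort.test_stim_features)
    save_features(outdir / "features_test_orig", cohort.config.network,
                  cohort.test_orig_features)


def select_units_for_cohort(cohort, config: PipelineConfig,
                            patterns: list[tuple[np.ndarray, np.ndarray]]) -> dict[str, np.ndarray]:
    """Shared unit selection from subject-averaged cross-validated decodability.

    Mirrors the protocol of selecting units once per layer from the mean
    decodability across subjects, computed entirely within the training
    partition.
    """
    layers = list(cohort.layer_labels)
    score_sum: dict[str, np.ndarray | None] = {layer: None for layer in layers}
    for train, _ in patterns:
        for layer in layers:
            s = crossval_unit_scores(train, cohort.train_features[layer])
            score_sum[layer] = s if score_sum[layer] is None else score_sum[layer] + s
    scores = [score_sum[layer] / len(patterns) for layer in layers]
    return dict(zip(layers, select_feature_units(scores, config.k_features)))


def _train_all(cohort, config: PipelineConfig):
    """Preprocess, select units, and train decoders for every subject.

    Returns ``(decoder_sets, test_patterns)`` keyed by subject id.
    """
    roi_names = [r.name for r in cohort.config.rois]
    patterns = [stimulus_patterns(cohort, s) for s in range(len(cohort.subjects))]
    unit_idx = select_units_for_cohort(cohort, config, patterns)
    decoder_sets = {}
    test_patterns = {}
    for s, (train, test) in enumerate(patterns):
        sid = cohort.subjects[s].spec.subject_id
        train_by_roi = {roi: train[:, cohort.roi_voxels[roi]] for roi in roi_names}
        decoder_sets[sid] = train_decoders(
            train_by_roi,
            cohort.train_features,
            k_voxels=config.k_voxels,
            k_features=config.k_features,
            unit_indices=unit_idx,
            signed_selection=config.signed_selection,
            tol=config.slr_tol,
            max_iter=config.slr_max_iter,
            method=config.slr_method,
        )
        test_patterns[sid] = test
    return decoder_sets, test_patterns


def _decode_all(cohort, decoder_sets, test_patterns):
    """Predictions per subject from stored decoders and test patterns."""
    roi_names = [r.name for r in cohort.config.rois]
    predictions = {}
    for sid, test in test_patterns.items():
        test_by_roi = {roi: test[:, cohort.roi_voxels[roi]] for roi in roi_names}
        predictions[sid] = predict_features(decoder_sets[sid], test_by_roi)
    return predictions


def run_in_memory(config: PipelineConfig, cohort=None, decoder_sets=None,
                  test_patterns=None) -> dict:
    """Run generate -> train -> decode -> analyze without touching disk.

    ``cohort`` / ``decoder_sets`` / ``test_patterns`` may be supplied to
    reuse earlier work (e.g. sweeping the sharpening profile with fixed
    training data).  Returns the analysis dict of
    :func:`featuregain.metrics.analyze_cohort` plus the intermediate
    objects.
    """
    config.validate()
    if cohort is None:
        cohort = generate_cohort(config.cohort, config.master_seed)
    if decoder_sets is None or test_patterns is None:
        decoder_sets, test_patterns = _train_all(cohort, config)
    predictions = _decode_all(cohort, decoder_sets, test_patterns)
    order = sorted(predictions, key=lambda x: int(x[1:]))
    result = analyze_cohort(
        cohort,
        [decoder_sets[s] for s in order],
        [predictions[s] for s in order],
        n_draws=config.n_draws,
        rho_floor=config.rho_floor,
        pooled_rho=config.pooled_rho,
        seed=subseed(config.master_seed, "noise-baseline"),
        content_roi=config.content_roi,
    )
    result.update(
        cohort=cohort, decoder_sets=decoder_sets,
        test_patterns=test_patterns, predictions=predictions,
    )
    return result


def _stage_train(config: PipelineConfig, outdir: Path) -> None:
    cohort = load_cohort(outdir / "cohort")
    decoder_sets, test_patterns = _train_all(cohort, config)
    save_decoders(outdir / "decoders", decoder_sets)
    order = sorted(test_patterns, key=lambda x: int(x[1:]))
    np.save(outdir / "test_patterns.npy", np.stack([test_patterns[s] for s in order]))


def _stage_decode(config: PipelineConfig, outdir: Path) -> None:
    cohort = load_cohort(outdir / "cohort")
    decoder_sets = load_decoders(outdir / "decoders")
    test_stack = np.load(outdir / "test_patterns.npy")
    test_patterns = {
        cohort.subjects[s].spec.subject_id: test_stack[s]
        for s in range(len(cohort.subjects))
    }
    predictions = _decode_all(cohort, decoder_sets, test_patterns)
    rows = []
    for sid, preds in predictions.items():
        for (roi, layer), mat in preds.items():
            rows.append({"subject": sid, "roi": roi, "layer": layer,
                         "n_trials": mat.shape[0], "n_units": mat.shape[1]})
    save_predictions(outdir / "predictions", predictions)
    pd.DataFrame(rows).sort_values(["subject", "roi", "layer"]).to_csv(
        outdir / "predictions_summary.csv", index=False
    )


def _stage_analyze(config: PipelineConfig, outdir: Path) -> None:
    cohort = load_cohort(outdir / "cohort")
    decoder_sets = load_decoders(outdir / "decoders")
    predictions = load_predictions(outdir / "predictions")
    order = sorted(predictions, key=lambda x: int(x[1:]))
    result = analyze_cohort(
        cohort,
        [decoder_sets[s] for s in order],
        [predictions[s] for s in order],
        n_draws=config.n_draws,
        rho_floor=config.rho_floor,
        pooled_rho=config.pooled_rho,
        seed=subseed(config.master_seed, "noise-baseline"),
        content_roi=config.content_roi,
    )
    float_fmt = "%.10g"
    result["gain_table"].to_csv(outdir / "gain_table.csv", index=False, float_format=float_fmt)
    result["corr_table"].to_csv(outdir / "corr_table.csv", index=False, float_format=float_fmt)
    result["content"].to_csv(outdir / "content_specificity.csv", index=False,
                             float_format=float_fmt)
    audit = result["audit"]
    audit.to_csv(outdir / "noise_audit.csv", index=False, float_format=float_fmt)
    (outdir / "noise_sigma.json").write_text(
        json.dumps(
            {
                f"{r.subject}/{r.roi}/{r.layer}": r.sigma
                for r in audit.itertuples()
            },
            indent=2,
            sort_keys=True,
        )
    )


def _stage_report(config: PipelineConfig, outdir: Path) -> None:
    gain = pd.read_csv(outdir / "gain_table.csv")
    n_layers = len({l for l in gain["layer"]})
    n_blurs = len({b for b in gain["blur"] if b > 0})
    m = config.bonferroni_m or n_layers * n_blurs
    report = gain_report(gain, m=m)
    report.to_csv(outdir / "gain_report.csv", index=False, float_format="%.10g")

    lines = ["Feature-gain report", "===================", ""]
    for roi, sub in report.groupby("roi"):
        lines.append(f"ROI {roi}:")
        for _, row in sub.iterrows():
            flag = "*" if row["significant"] else " "
            lines.append(
                f"  {row['layer']}: mean gain {row['mean_gain']:+.4f} "
                f"[{row['ci_lower']:+.4f}, {row['ci_upper']:+.4f}] "
                f"t({row['df']:.0f})={row['t']:.2f} p={row['p']:.2g} {flag}"
            )
        lines.append("")

    try:
        means = gain.groupby(["subject", "roi", "condition"], as_index=False)["gain"].mean()
        anova = factorial_anova(means, ["roi", "condition"])
        anova.to_csv(outdir / "anova_roi_condition.csv", index=False, float_format="%.10g")
        lines.append("Two-way ANOVA (ROI x condition) on subject-mean gain:")
        for _, row in anova.iterrows():
            if row["effect"] == "Residual":
                continue
            lines.append(f"  {row['effect']}: F={row['F']:.3f} p={row['p']:.4g}")
    except Exception as exc:  # pragma: no cover - degenerate tiny configs
        lines.append(f"ANOVA skipped: {exc}")
    (outdir / "report.txt").write_text("\n".join(lines) + "\n")

    _plot_gain(report, outdir / "gain_by_layer.png")


def _plot_gain(report: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rois = sorted(report["roi"].unique())
    fig, axes = plt.subplots(1, len(rois), figsize=(4 * len(rois), 3.2), squeeze=False)
    for ax, roi in zip(axes[0], rois):
        sub = report[report["roi"] == roi].sort_values("layer")
        x = np.arange(len(sub))
        err = np.vstack([
            sub["mean_gain"] - sub["ci_lower"],
            sub["ci_upper"] - sub["mean_gain"],
        ])
        ax.bar(x, sub["mean_gain"], yerr=err, capsize=3, color="#4878a8")
        ax.axhline(0.0, color="k", lw=0.8)
        ax.set_xticks(x, sub["layer"], rotation=45)
        ax.set_title(roi)
        ax.set_ylabel("feature gain")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


_STAGE_BODIES = {
    "generate": _stage_generate,
    "features": _stage_features,
    "train": _stage_train,
    "decode": _stage_decode,
    "analyze": _stage_analyze,
    "report": _stage_report,
}

_STAGE_OUTPUTS = {
    "generate": ["cohort.h5", "config.yaml"],
    "features": ["features_train.h5", "features_test_stim.h5", "features_test_orig.h5"],
    "train": ["decoders.h5", "test_patterns.npy"],
    "decode": ["predictions.h5", "predictions_summary.csv"],
    "analyze": ["gain_table.csv", "corr_table.csv", "noise_audit.csv",
                "content_specificity.csv", "noise_sigma.json"],
    "report": ["gain_report.csv", "report.txt", "gain_by_layer.png"],
}


def run_stage(name: str, config: PipelineConfig, resume: bool = False) -> Path:
    """Run one pipeline stage; returns the output directory.

    With ``resume=True`` a stage whose manifest matches the current
    configuration is skipped.  A missing upstream stage raises
    :class:`DependencyError`; upstream outputs from a different
    configuration raise :class:`ConflictError`.
    """
    if name not in STAGES:
        raise ConfigError(f"unknown stage {name!r}", keys=("stage",))
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _check_upstream(outdir, name, config)
    if resume and _stage_done(outdir, name, config):
        logger.info("stage %s up to date, skipping", name)
        return outdir
    t0 = time.time()
    logger.info("running stage %s", name)
    _STAGE_BODIES[name](config, outdir)
    inputs = []
    i = STAGES.index(name)
    if i > 0:
        inputs = [outdir / f for f in _STAGE_OUTPUTS[STAGES[i - 1]]]
    _write_manifest(outdir, name, config, inputs,
                    [outdir / f for f in _STAGE_OUTPUTS[name]], t0)
    return outdir


def run_all(config: PipelineConfig, resume: bool = False) -> Path:
    """Run every stage in order."""
    for stage in STAGES:
        run_stage(stage, config, resume=resume)
    return Path(config.outdir)
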