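"""HDF5 / CSV / JSON persistence for cohorts, features, decoders, predictions.

Layout conventions: one HDF5 group per subject (``S1`` ...), ROIs and layers
as nested groups; metadata tables travel as CSV next to the HDF5 container;
specs and normalization records as JSON sidecars/attributes.  Writers sort
keys so repeated runs with the same seed produce identical files (HDF5
timestamps aside); CSV outputs are byte-stable.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .cohort import (
    BehaviorParams,
    CohortConfig,
    CohortDataset,
    ROISpec,
    RunData,
    SharpeningProfile,
    Standardizer,
    SubjectData,
    SubjectSpec,
)
from .decoding import Decoder, DecoderSet
from .network import LayerSpec, NetworkSpec

__all__ = [
    "network_to_dict",
    "network_from_dict",
    "config_to_dict",
    "config_from_dict",
    "save_cohort",
    "load_cohort",
    "save_features",
    "load_features",
    "save_decoders",
    "load_decoders",
    "save_predictions",
    "load_predictions",
]


# ---------------------------------------------------------------------------
# Spec / config serialization
# ---------------------------------------------------------------------------


def network_to_dict(spec: NetworkSpec) -> dict:
    return {
        "input_side": spec.input_side,
        "weight_seed": spec.weight_seed,
        "layers": [dataclasses.asdict(layer) for layer in spec.layers],
    }


def network_from_dict(d: dict) -> NetworkSpec:
    return NetworkSpec(
        input_side=int(d["input_side"]),
        layers=tuple(LayerSpec(**layer) for layer in d["layers"]),
        weight_seed=int(d.get("weight_seed", 0)),
    )


def config_to_dict(config: CohortConfig) -> dict:
    return {
        "n_subjects": config.n_subjects,
        "image_side": config.image_side,
        "n_train_images": config.n_train_images,
        "train_run_size": config.train_run_size,
        "n_test_sequences": config.n_test_sequences,
        "test_runs_per_condition": config.test_runs_per_condition,
        "blur_fractions": list(config.blur_fractions),
        "network": network_to_dict(config.network),
        "rois": [
            {"name": r.name, "n_voxels": r.n_voxels, "layer_weights": list(r.layer_weights)}
            for r in config.rois
        ],
        "sharpening": {
            "no_prior": list(config.sharpening.no_prior),
            "category_prior": list(config.sharpening.category_prior),
        },
        "noise_sd": config.noise_sd,
        "volumes_per_trial": config.volumes_per_trial,
        "shift_volumes": config.shift_volumes,
        "drift_slope_range": list(config.drift_slope_range),
        "baseline_sd": config.baseline_sd,
        "encoding_sparsity": config.encoding_sparsity,
        "behavior": dataclasses.asdict(config.behavior),
    }


def config_from_dict(d: dict) -> CohortConfig:
    return CohortConfig(
        n_subjects=int(d["n_subjects"]),
        image_side=int(d["image_side"]),
        n_train_images=int(d["n_train_images"]),
        train_run_size=int(d["train_run_size"]),
        n_test_sequences=int(d["n_test_sequences"]),
        test_runs_per_condition=int(d["test_runs_per_condition"]),
        blur_fractions=tuple(float(f) for f in d["blur_fractions"]),
        network=network_from_dict(d["network"]),
        rois=tuple(
            ROISpec(r["name"], int(r["n_voxels"]), tuple(r["layer_weights"]))
            for r in d["rois"]
        ),
        sharpening=SharpeningProfile(
            no_prior=tuple(d["sharpening"]["no_prior"]),
            category_prior=tuple(d["sharpening"]["category_prior"]),
        ),
        noise_sd=float(d["noise_sd"]),
        volumes_per_trial=int(d["volumes_per_trial"]),
        shift_volumes=int(d["shift_volumes"]),
        drift_slope_range=tuple(d["drift_slope_range"]),
        baseline_sd=float(d["baseline_sd"]),
        encoding_sparsity=float(d["encoding_sparsity"]),
        behavior=BehaviorParams(**d["behavior"]),
    )


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------


def save_cohort(cohort: CohortDataset, path) -> None:
    """Write a cohort to ``<path>.h5`` plus CSV metadata tables."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path.with_suffix(".h5"), "w") as f:
        f.attrs["master_seed"] = cohort.master_seed
        f.attrs["config_json"] = json.dumps(config_to_dict(cohort.config), sort_keys=True)
        for group_name, mats in (
            ("train_features", cohort.train_features),
            ("test_stim_features", cohort.test_stim_features),
            ("test_orig_features", cohort.test_orig_features),
        ):
            grp = f.create_group(group_name)
            for layer in sorted(mats):
                grp.create_dataset(layer, data=mats[layer])
        std = f.create_group("standardizer")
        for layer in sorted(cohort.standardizer.mean):
            std.create_dataset(f"{layer}/mean", data=cohort.standardizer.mean[layer])
            std.create_dataset(f"{layer}/sd", data=cohort.standardizer.sd[layer])
        for s, subject in enumerate(cohort.subjects):
            grp = f.create_group(f"subjects/{subject.spec.subject_id}")
            grp.attrs["seed"] = subject.spec.seed
            grp.attrs["noise_sd"] = subject.spec.noise_sd
            for kind, runs in (("train", subject.train_runs), ("test", subject.test_runs)):
                for r, run in enumerate(runs):
                    rg = grp.create_group(f"{kind}_runs/{r:03d}")
                    rg.create_dataset("series", data=run.series)
                    rg.create_dataset("boundaries", data=np.asarray(run.boundaries))
                    rg.attrs["shift_volumes"] = run.shift_volumes
            subject.behavior.to_csv(
                path.parent / f"{path.stem}_behavior_{subject.spec.subject_id}.csv",
                index=False,
            )
    cohort.train_meta.to_csv(path.parent / f"{path.stem}_train_meta.csv", index=False)
    cohort.test_meta.to_csv(path.parent / f"{path.stem}_test_meta.csv", index=False)


def load_cohort(path) -> CohortDataset:
    path = Path(path)
    with h5py.File(path.with_suffix(".h5"), "r") as f:
        config = config_from_dict(json.loads(f.attrs["config_json"]))
        master_seed = int(f.attrs["master_seed"])

        def load_group(name: str) -> dict[str, np.ndarray]:
            return {layer: f[name][layer][()] for layer in f[name]}

        train_features = load_group("train_features")
        test_stim = load_group("test_stim_features")
        test_orig = load_group("test_orig_features")
        standardizer = Standardizer(
            mean={layer: f["standardizer"][layer]["mean"][()] for layer in f["standardizer"]},
            sd={layer: f["standardizer"][layer]["sd"][()] for layer in f["standardizer"]},
        )
        subjects = []
        for sid in sorted(f["subjects"], key=lambda s: int(s[1:])):
            grp = f["subjects"][sid]
            spec = SubjectSpec(
                subject_id=sid,
                seed=int(grp.attrs["seed"]),
                noise_sd=float(grp.attrs["noise_sd"]),
                drift_slope_range=config.drift_slope_range,
                behavior=config.behavior,
            )

            def load_runs(kind: str) -> list[RunData]:
                runs = []
                for r in sorted(grp[f"{kind}_runs"]):
                    rg = grp[f"{kind}_runs"][r]
                    runs.append(
                        RunData(
                            series=rg["series"][()],
                            boundaries=tuple(map(tuple, rg["boundaries"][()])),
                            shift_volumes=int(rg.attrs["shift_volumes"]),
                        )
                    )
                return runs

            behavior = pd.read_csv(path.parent / f"{path.stem}_behavior_{sid}.csv")
            subjects.append(
                SubjectData(
                    spec=spec,
                    train_runs=load_runs("train"),
                    test_runs=load_runs("test"),
                    behavior=behavior,
                )
            )
    from .cohort import _roi_voxel_map  # local import to avoid cycle at module load

    return CohortDataset(
        config=config,
        master_seed=master_seed,
        roi_voxels=_roi_voxel_map(config.rois),
        train_meta=pd.read_csv(path.parent / f"{path.stem}_train_meta.csv"),
        test_meta=pd.read_csv(path.parent / f"{path.stem}_test_meta.csv"),
        subjects=subjects,
        train_features=train_features,
        test_stim_features=test_stim,
        test_orig_features=test_orig,
        standardizer=standardizer,
        profile=config.sharpening,
    )


# ---------------------------------------------------------------------------
# Features
# ---------------------------------------------------------------------------


def save_features(path, spec: NetworkSpec, matrices: dict[str, np.ndarray]) -> None:
    """One dataset per layer, with a JSON sidecar describing the network."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path.with_suffix(".h5"), "w") as f:
        for layer in sorted(matrices):
            f.create_dataset(layer, data=matrices[layer])
    path.with_suffix(".json").write_text(
        json.dumps(network_to_dict(spec), sort_keys=True, indent=2)
    )


def load_features(path) -> tuple[NetworkSpec, dict[str, np.ndarray]]:
    path = Path(path)
    spec = network_from_dict(json.loads(path.with_suffix(".json").read_text()))
    with h5py.File(path.with_suffix(".h5"), "r") as f:
        matrices = {layer: f[layer][()] for layer in f}
    return spec, matrices


# ---------------------------------------------------------------------------
# Decoders / predictions
# ---------------------------------------------------------------------------


def save_decoders(path, decoder_sets: dict[str, DecoderSet]) -> None:
    """Persist per-subject decoder sets (weights, indices, normalization)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path.with_suffix(".h5"), "w") as f:
        for subject in sorted(decoder_sets):
            ds = decoder_sets[subject]
            sg = f.create_group(subject)
            for roi in sorted(ds.roi_stats):
                kept, mean, sd = ds.roi_stats[roi]
                rg = sg.create_group(f"roi_stats/{roi}")
                rg.create_dataset("kept", data=kept)
                rg.create_dataset("mean", data=mean)
                rg.create_dataset("sd", data=sd)
            for layer in sorted(ds.feature_stats):
                idx, mean, sd = ds.feature_stats[layer]
                lg = sg.create_group(f"feature_stats/{layer}")
                lg.create_dataset("unit_idx", data=idx)
                lg.create_dataset("mean", data=mean)
                lg.create_dataset("sd", data=sd)
            for (roi, layer) in sorted(ds.models):
                fits = ds.models[(roi, layer)]
                mg = sg.create_group(f"models/{roi}/{layer}")
                mg.create_dataset("voxel_idx", data=np.vstack([d.voxel_idx for d in fits]))
                mg.create_dataset("weights", data=np.vstack([d.weights for d in fits]))
                mg.create_dataset("intercept", data=np.array([d.intercept for d in fits]))
                mg.create_dataset(
                    "converged", data=np.array([d.converged for d in fits], dtype=bool)
                )


def load_decoders(path) -> dict[str, DecoderSet]:
    path = Path(path)
    out: dict[str, DecoderSet] = {}
    with h5py.File(path.with_suffix(".h5"), "r") as f:
        for subject in f:
            sg = f[subject]
            roi_stats = {
                roi: (
                    sg["roi_stats"][roi]["kept"][()],
                    sg["roi_stats"][roi]["mean"][()],
                    sg["roi_stats"][roi]["sd"][()],
                )
                for roi in sg["roi_stats"]
            }
            feature_stats = {
                layer: (
                    sg["feature_stats"][layer]["unit_idx"][()],
                    sg["feature_stats"][layer]["mean"][()],
                    sg["feature_stats"][layer]["sd"][()],
                )
                for layer in sg["feature_stats"]
            }
            ds = DecoderSet(roi_stats=roi_stats, feature_stats=feature_stats)
            for roi in sg.get("models", {}):
                for layer in sg["models"][roi]:
                    mg = sg["models"][roi][layer]
                    vox = mg["voxel_idx"][()]
                    weights = mg["weights"][()]
                    intercepts = mg["intercept"][()]
                    conv = mg["converged"][()]
                    ds.models[(roi, layer)] = [
                        Decoder(voxel_idx=vox[u], weights=weights[u],
                                intercept=float(intercepts[u]), converged=bool(conv[u]))
                        for u in range(weights.shape[0])
                    ]
            out[subject] = ds
    return out


def save_predictions(path, predictions: dict[str, dict[tuple[str, str], np.ndarray]]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path.with_suffix(".h5"), "w") as f:
        for subject in sorted(predictions):
            for (roi, layer) in sorted(predictions[subject]):
                f.create_dataset(
                    f"{subject}/{roi}/{layer}", data=predictions[subject][(roi, layer)]
                )


def load_predictions(path) -> dict[str, dict[tuple[str, str], np.ndarray]]:
    path = Path(path)
    out: dict[str, dict[tuple[str, str], np.ndarray]] = {}
    with h5py.File(path.with_suffix(".h5"), "r") as f:
        for subject in f:
            out[subject] = {}
            for roi in f[subject]:
                for layer in f[subject][roi]:
                    out[subject][(roi, layer)] = f[subject][roi][layer][()]
    return out
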