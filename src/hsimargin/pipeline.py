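"""End-to-end orchestration: simulate -> train -> predict -> evaluate -> saliency.

A run is driven by a single :class:`RunConfig` (loadable from YAML) and a
master seed; every stage derives its own seed from the master, so a rerun
with the same config and seed reproduces the same reports. Stage outputs are
written under one run directory together with a provenance record (config
hash, package versions, seeds).
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluation import (
    EvalCase,
    aggregate_distance_report,
    distance_report,
    optimal_operating_point,
    roc_auc,
)
from .hypercube_io import TUMOR, ConfigurationError, trim_tissue_edge, write_envi
from .intra_patient_lda import (
    DEFAULT_EDGE_TRIM_PX,
    EnsembleConfig,
    predict_map,
    train_intra_patient,
)
from .margin_geometry import distance_to_margin
from .patch_cnn import (
    CNNConfig,
    PatchSpec,
    extract_patches,
    run_inter_patient_experiment,
)
from .saliency import gradcam_spectral
from .synthetic_scene import SceneSpec, SpectralModel, generate_cohort

__all__ = [
    "RunConfig",
    "run",
    "run_intra_patient_arm",
    "tvn_patient_auc",
    "margin_eval_cases",
    "STAGES",
]

STAGES = ("simulate", "intra", "inter", "evaluate", "saliency")

#: distance grid (mm) matched to the scaled-down phantom specimens
PHANTOM_D_GRID_MM = (0.0, 0.1, 0.2, 0.3, 0.4)


@dataclass(frozen=True)
class RunConfig:
    n_patients: int = 10
    modality: str = "reflectance"
    cohort: str = "conventional"
    seed: int = 0
    scene: SceneSpec = field(default_factory=SceneSpec)
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)
    cnn: CNNConfig = field(default_factory=CNNConfig)
    patch: PatchSpec = field(default_factory=PatchSpec)
    d_grid_mm: tuple = PHANTOM_D_GRID_MM
    edge_trim_px: int = DEFAULT_EDGE_TRIM_PX
    experiments: tuple = ("TvsN", "TN")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for key, value in raw.items():
            if key == "scene":
                model = SpectralModel(**value.pop("model", {}))
                if "image_size" in value:
                    value["image_size"] = tuple(value["image_size"])
                grid_spec = value.pop("grid", None)
                if grid_spec is not None:
                    from .hypercube_io import build_band_grid

                    value["grid"] = build_band_grid(**grid_spec)
                kwargs["scene"] = SceneSpec(model=model, **value)
            elif key == "ensemble":
                kwargs["ensemble"] = EnsembleConfig(**value)
            elif key == "cnn":
                if "block_widths" in value:
                    value["block_widths"] = tuple(value["block_widths"])
                kwargs["cnn"] = CNNConfig(**value)
            elif key == "patch":
                kwargs["patch"] = PatchSpec(**value)
            elif key in ("d_grid_mm", "experiments"):
                kwargs[key] = tuple(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def config_hash(self) -> str:
        blob = json.dumps(_jsonable(asdict(self)), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# Analysis arms (shared by the CLI, the pipeline, and the acceptance script)
# ---------------------------------------------------------------------------


def run_intra_patient_arm(
    scenes: dict,
    config: EnsembleConfig = EnsembleConfig(),
    *,
    edge_trim_px: int = DEFAULT_EDGE_TRIM_PX,
) -> tuple[pd.DataFrame, dict]:
    """Personalized ensemble-LDA arm over every complete patient triplet.

    For each patient holding all three specimen types, the ensemble is
    trained on T and N, the operating threshold is chosen on the pooled fold
    validation scores, and the TN margin specimen is scored. Returns a
    per-patient summary (validation AUC, threshold) and the per-patient
    artifacts needed for distance-stratified evaluation.
    """
    patients = sorted({pid for pid, _ in scenes})
    rows, artifacts = [], {}
    for i, pid in enumerate(patients):
        if not all((pid, st) in scenes for st in ("T", "N", "TN")):
            continue
        cfg = replace(config, seed=(config.seed * 10007 + i) & 0x7FFFFFFF)
        ensemble = train_intra_patient(
            scenes[(pid, "T")], scenes[(pid, "N")], cfg, edge_trim_px=edge_trim_px
        )
        val_scores, val_labels = ensemble.validation_scores
        val_auc = roc_auc(val_scores, val_labels).auc
        threshold = optimal_operating_point(roc_auc(val_scores, val_labels)).threshold
        pmap = predict_map(ensemble, scenes[(pid, "TN")])
        rows.append(
            {"patient_id": pid, "validation_auc": val_auc, "threshold": threshold}
        )
        artifacts[pid] = {
            "ensemble": ensemble,
            "predmap": pmap,
            "threshold": threshold,
        }
    return pd.DataFrame(rows), artifacts


def margin_eval_cases(
    predictions: dict,
    thresholds: dict,
    scenes: dict,
    *,
    modality: str = "reflectance",
    edge_trim_px: int = DEFAULT_EDGE_TRIM_PX,
) -> list:
    """Build distance-stratified evaluation cases for TN margin scenes.

    ``predictions``/``thresholds`` are keyed by patient id; scenes supply the
    ground truth, the trimmed tissue mask, and the distance map.
    """
    cases = []
    for pid, pmap in predictions.items():
        scene = scenes[(pid, "TN")]
        distmap = distance_to_margin(scene.gt_mask, scene.raw.resolution_um_per_px)
        tissue_eval = trim_tissue_edge(scene.tissue_mask, edge_trim_px)
        cases.append(
            EvalCase(
                patient_id=pid,
                modality=modality,
                predmap=pmap,
                gt_mask=scene.gt_mask,
                distmap=distmap,
                tissue_eval=tissue_eval,
                threshold=thresholds[pid],
            )
        )
    return cases


def tvn_patient_auc(
    predictions: dict,
    scenes: dict,
    *,
    edge_trim_px: int = DEFAULT_EDGE_TRIM_PX,
) -> pd.DataFrame:
    """Per-patient AUC pooling T and N scene pixels (tumor-vs-normal test).

    ``predictions`` is keyed by ``(patient_id, specimen_type)``.
    """
    per_patient: dict[str, list] = {}
    for (pid, stype), pmap in predictions.items():
        scene = scenes[(pid, stype)]
        mask = trim_tissue_edge(scene.tissue_mask, edge_trim_px) & pmap.valid
        mask &= np.isfinite(pmap.values)
        per_patient.setdefault(pid, []).append(
            (pmap.values[mask], (scene.gt_mask[mask] == TUMOR).astype(int))
        )
    rows = []
    for pid, parts in sorted(per_patient.items()):
        scores = np.concatenate([s for s, _ in parts])
        labels = np.concatenate([l for _, l in parts])
        auc = roc_auc(scores, labels).auc if 0 < labels.sum() < len(labels) else float("nan")
        rows.append({"patient_id": pid, "auc": auc, "n_pixels": len(labels)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


def _log(run_dir: Path, record: dict) -> None:
    with (run_dir / "run_log.jsonl").open("a") as fh:
        fh.write(json.dumps(_jsonable(record)) + "\n")


def run(
    config: RunConfig,
    out_dir: str | Path,
    stages=STAGES,
) -> dict:
    """Execute the configured stages in order; returns in-memory results.

    The run directory is self-describing: scenes, heat maps, reports, a JSONL
    stage log, and a provenance record are all written beneath it.
    """
    run_dir = Path(out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ConfigurationError(f"unknown stages: {sorted(unknown)}")
    stages = [s for s in STAGES if s in stages]

    provenance = {
        "config_hash": config.config_hash(),
        "config": _jsonable(asdict(config)),
        "package_version": __version__,
        "numpy_version": np.__version__,
        "python_version": platform.python_version(),
        "master_seed": config.seed,
    }
    (run_dir / "provenance.json").write_text(json.dumps(provenance, indent=2))

    results: dict = {}
    scenes = None

    if "simulate" in stages:
        manifest, scenes = generate_cohort(
            config.n_patients,
            config.scene,
            config.seed,
            cohort=config.cohort,
            modality=config.modality,
            out_dir=run_dir / "scenes",
        )
        results["manifest"] = manifest
        _log(run_dir, {"stage": "simulate", "n_scenes": len(manifest)})
    else:
        from .hypercube_io import read_scene

        manifest_path = run_dir / "scenes" / "manifest.csv"
        if not manifest_path.exists():
            raise ConfigurationError(
                "simulate stage skipped but no scenes found under the run directory"
            )
        manifest = pd.read_csv(manifest_path)
        scenes = {
            (r.patient_id, r.specimen_type): read_scene(r.path)
            for r in manifest.itertuples()
        }
        results["manifest"] = manifest

    if "intra" in stages:
        ens_cfg = replace(config.ensemble, seed=config.seed)
        intra_summary, artifacts = run_intra_patient_arm(
            scenes, ens_cfg, edge_trim_px=config.edge_trim_px
        )
        cases = margin_eval_cases(
            {pid: a["predmap"] for pid, a in artifacts.items()},
            {pid: a["threshold"] for pid, a in artifacts.items()},
            scenes,
            modality=config.modality,
            edge_trim_px=config.edge_trim_px,
        )
        report = distance_report(cases, config.d_grid_mm)
        intra_summary.to_csv(run_dir / "intra_patient_summary.csv", index=False)
        report.to_csv(run_dir / "intra_patient_distance_report.csv", index=False)
        aggregate_distance_report(report).to_csv(
            run_dir / "intra_patient_distance_aggregate.csv", index=False
        )
        results["intra_summary"] = intra_summary
        results["intra_report"] = report
        results["intra_artifacts"] = artifacts
        _log(run_dir, {"stage": "intra", "n_patients": len(intra_summary)})

    if "inter" in stages:
        inter_results = {}
        # one training pass serves both tests when both experiments are wanted
        wanted = set(config.experiments)
        experiments = ("both",) if {"TvsN", "TN"} <= wanted else config.experiments
        for experiment in experiments:
            res = run_inter_patient_experiment(
                scenes,
                experiment,
                replace(config.cnn, seed=config.seed),
                config.patch,
                seed=config.seed,
            )
            inter_results[experiment] = res
            heat_dir = run_dir / f"heatmaps_{experiment.lower()}"
            heat_dir.mkdir(exist_ok=True)
            for (pid, stype), pmap in res.predictions.items():
                write_envi(
                    heat_dir / f"{pid}_{stype}.hdr",
                    pmap.values.astype(np.float32),
                )
            _log(
                run_dir,
                {
                    "stage": "inter",
                    "experiment": experiment,
                    "val_auc_per_fold": res.val_auc_of_fold,
                    "thresholds": res.thresholds,
                },
            )
        results["inter"] = inter_results

    if "evaluate" in stages and "inter" in stages:
        inter_results = results["inter"]

        def _result_for(stype):
            for exp, res in inter_results.items():
                if any(st == stype for _, st in res.predictions):
                    return res
            return None

        res = _result_for("T")
        if res is not None and "TvsN" in config.experiments:
            preds_tn_only = {
                key: p for key, p in res.predictions.items() if key[1] in ("T", "N")
            }
            tvn = tvn_patient_auc(
                preds_tn_only, scenes, edge_trim_px=config.edge_trim_px
            )
            tvn.to_csv(run_dir / "inter_tvn_patient_auc.csv", index=False)
            results["tvn_auc"] = tvn
        res = _result_for("TN")
        if res is not None and "TN" in config.experiments:
            preds = {
                pid: p for (pid, stype), p in res.predictions.items() if stype == "TN"
            }
            thr = {
                pid: res.thresholds[res.fold_of_scene[(pid, "TN")]] for pid in preds
            }
            cases = margin_eval_cases(
                preds, thr, scenes,
                modality=config.modality, edge_trim_px=config.edge_trim_px,
            )
            report = distance_report(cases, config.d_grid_mm)
            report.to_csv(run_dir / "inter_tn_distance_report.csv", index=False)
            aggregate_distance_report(report).to_csv(
                run_dir / "inter_tn_distance_aggregate.csv", index=False
            )
            results["tn_report"] = report
        _log(run_dir, {"stage": "evaluate"})

    if "saliency" in stages and "inter" in stages and results.get("inter"):
        from .patch_cnn import concatenate_patchsets
        from .saliency import aggregate_profiles

        res = next(iter(results["inter"].values()))
        grid = next(iter(scenes.values())).raw.grid
        per_class: dict[str, list] = {"scc": [], "normal": []}
        for fold, model in res.models.items():
            test_pids = res.folds.patients_in_fold(fold)
            sets = [
                extract_patches(scenes[(pid, st)], config.patch, "training")
                for pid in test_pids
                for st in ("T", "N")
                if (pid, st) in scenes
            ]
            if not sets:
                continue
            pset = concatenate_patchsets(sets)
            for cls in ("scc", "normal"):
                try:
                    per_class[cls].append(
                        gradcam_spectral(model.net, pset.patches, pset.labels, cls, grid)
                    )
                except ConfigurationError:
                    continue  # fold lacks correctly classified patches of cls
        profiles = {
            cls: aggregate_profiles(plist)
            for cls, plist in per_class.items()
            if plist
        }
        for cls, prof in profiles.items():
            pd.DataFrame(
                {"wavelength_nm": prof.wavelengths, "saliency": prof.saliency}
            ).to_csv(run_dir / f"saliency_{cls}.csv", index=False)
        results["saliency"] = profiles
        _log(run_dir, {"stage": "saliency",
                       "n_models": len(per_class["scc"])})

    return results
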