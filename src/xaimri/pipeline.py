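"""End-to-end pipeline orchestration over a run directory.

Stages run in dependency order: ``synth`` → ``preprocess`` → ``train``
(one U-Net per modality scenario) → ``ensemble`` (feature fusion of the
two designated dual-modality models) → ``evaluate`` (per-scenario
metric reports on the held-out test subjects) → ``gradcam`` (relevance
volume + overlay for one test subject).

Every stage writes its artifacts plus a completion marker holding a
hash of the config sections it consumed; re-running with an identical
config skips completed stages unless forced.  A resolved copy of the
full config lands in the run directory, so any run is reproducible
from its own directory alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np

from .config import RunConfig
from .ensemble import (
    EnsembleConfig,
    build_ensemble,
    load_ensemble_checkpoint,
    save_ensemble_checkpoint,
)
from .errors import OrchestrationError
from .gradcam import GradCamConfig, compute_gradcam, overlay
from .io import discover_subjects, load_subject_arrays, split_dataset
from .phantom import MODALITIES, PhantomSpec, generate_cohort, write_brats_layout
from .preprocess import PreprocessConfig, preprocess_subject
from .study import ALL_SCENARIOS, ENSEMBLE_BASE_A, ENSEMBLE_BASE_B, scenario_name
from .train import TrainConfig, evaluate, train
from .unet import UNetConfig, build_unet, load_checkpoint, stack_modalities

__all__ = ["STAGES", "run_pipeline"]

STAGES = ("synth", "preprocess", "train", "ensemble", "evaluate", "gradcam")
_DEPS = {
    "synth": (),
    "preprocess": ("synth",),
    "train": ("preprocess",),
    "ensemble": ("train",),
    "evaluate": ("ensemble",),
    "gradcam": ("ensemble",),
}
_SECTIONS_USED = {
    "synth": ("seed", "phantom"),
    "preprocess": ("seed", "phantom", "preprocess"),
    "train": ("seed", "phantom", "preprocess", "model", "training"),
    "ensemble": ("seed", "phantom", "preprocess", "model", "training", "ensemble"),
    "evaluate": ("seed", "phantom", "preprocess", "model", "training", "ensemble"),
    "gradcam": ("seed", "phantom", "preprocess", "model", "training", "ensemble", "gradcam"),
}

log = logging.getLogger("xaimri.pipeline")


def _config_hash(config: RunConfig, stage: str) -> str:
    payload = {k: config.to_dict().get(k, getattr(config, k, None)) for k in _SECTIONS_USED[stage]}
    return hashlib.sha1(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _marker(run_dir: Path, stage: str) -> Path:
    return run_dir / ".stages" / f"{stage}.json"


def _stage_done(run_dir: Path, stage: str, config: RunConfig) -> bool:
    m = _marker(run_dir, stage)
    if not m.exists():
        return False
    return json.loads(m.read_text()).get("config_hash") == _config_hash(config, stage)


def _mark_done(run_dir: Path, stage: str, config: RunConfig, **extra) -> None:
    m = _marker(run_dir, stage)
    m.parent.mkdir(parents=True, exist_ok=True)
    m.write_text(json.dumps({"config_hash": _config_hash(config, stage), **extra}, indent=2))


# ---------------------------------------------------------------- stages
def _stage_synth(run_dir: Path, config: RunConfig) -> None:
    spec = PhantomSpec(
        grid_shape=config.phantom.grid_shape,
        n_tumors=config.phantom.n_tumors,
        noise_sigma=config.phantom.noise_sigma,
        seed=config.stage_seed("synth"),
    )
    for subject in generate_cohort(spec, config.phantom.n_subjects):
        write_brats_layout(subject, run_dir / "phantoms")


def _stage_preprocess(run_dir: Path, config: RunConfig) -> None:
    records = discover_subjects(run_dir / "phantoms")
    if not records:
        raise OrchestrationError(f"no subjects found under {run_dir / 'phantoms'}")
    pre_cfg = PreprocessConfig.scaled(config.phantom.grid_shape, config.preprocess.cube)
    out = run_dir / "preprocessed"
    out.mkdir(parents=True, exist_ok=True)
    for rec in records:
        volumes, labels = load_subject_arrays(rec)
        pre = preprocess_subject((volumes, labels), pre_cfg, subject_id=rec.subject_id)
        np.savez(out / f"{rec.subject_id}.npz", mask=pre.mask,
                 **{m: pre.volumes[m] for m in MODALITIES})
        (out / f"{rec.subject_id}.json").write_text(json.dumps({
            "subject_id": rec.subject_id,
            "roi_box": pre.roi_box.to_dict(),
            "config": {"reference_modality": pre_cfg.reference_modality,
                       "reference_slice": pre_cfg.reference_slice,
                       "depth_range": list(pre_cfg.depth_range),
                       "target_inplane": pre_cfg.target_inplane},
        }, indent=2))


def _load_preprocessed(run_dir: Path) -> dict[str, dict]:
    out = {}
    for npz_path in sorted((run_dir / "preprocessed").glob("*.npz")):
        with np.load(npz_path) as z:
            out[npz_path.stem] = {
                "volumes": {m: z[m] for m in MODALITIES},
                "mask": z["mask"],
            }
    if not out:
        raise OrchestrationError(f"no preprocessed subjects under {run_dir / 'preprocessed'}")
    return out


def _split_sets(run_dir: Path, config: RunConfig):
    data = _load_preprocessed(run_dir)
    split = split_dataset(sorted(data), seed=config.stage_seed("split"))
    sets = {}
    for part, ids in (("train", split.train_ids), ("val", split.val_ids), ("test", split.test_ids)):
        sets[part] = [(sid, data[sid]) for sid in ids]
    return sets, split


def _samples(entries, modalities):
    return [
        (stack_modalities(d["volumes"], list(modalities)), d["mask"].astype(np.int64))
        for _, d in entries
    ]


def _train_cfg(config: RunConfig, scenario: str) -> TrainConfig:
    return TrainConfig(
        batch_size=config.training.batch_size, max_epochs=config.training.max_epochs,
        learning_rate=config.training.learning_rate, patience=config.training.patience,
        loss=config.training.loss, seed=config.stage_seed(f"train:{scenario}"),
    )


def _stage_train(run_dir: Path, config: RunConfig) -> None:
    sets, split = _split_sets(run_dir, config)
    split.to_json(run_dir / "split.json")
    models_dir = run_dir / "models"
    for scenario in ALL_SCENARIOS:
        if scenario == "ensemble":
            continue
        name = scenario_name(scenario)
        model_cfg = UNetConfig(
            in_channels=len(scenario), depth_levels=config.model.depth_levels,
            base_filters=config.model.base_filters, dropout_rate=config.model.dropout_rate,
        )
        model = build_unet(model_cfg, seed=config.stage_seed(f"init:{name}"))
        result = train(
            model, _samples(sets["train"], scenario), _samples(sets["val"], scenario),
            _train_cfg(config, name),
            checkpoint_path=models_dir / f"{name}.npz",
            checkpoint_meta={"modalities": list(scenario)},
        )
        (models_dir / f"{name}.history.json").write_text(json.dumps(result.history, indent=2))
        log.info("trained scenario %s: %d epochs, best %d", name,
                 len(result.history), result.best_epoch)


def _stage_ensemble(run_dir: Path, config: RunConfig) -> None:
    models_dir = run_dir / "models"
    bases = []
    for pair in (ENSEMBLE_BASE_A, ENSEMBLE_BASE_B):
        ckpt = models_dir / f"{scenario_name(pair)}.npz"
        if not ckpt.exists():
            raise OrchestrationError(
                f"ensemble requires the trained base checkpoint {ckpt}; run the train stage first"
            )
        model, _ = load_checkpoint(ckpt)
        bases.append((model, pair))
    ens = build_ensemble(
        bases[0], bases[1],
        EnsembleConfig(fusion_filters=config.ensemble.fusion_filters,
                       freeze_base=config.ensemble.freeze_base,
                       seed=config.stage_seed("ensemble")),
    )
    sets, _ = _split_sets(run_dir, config)
    union = ens.union_modalities
    result = train(ens, _samples(sets["train"], union), _samples(sets["val"], union),
                   _train_cfg(config, "ensemble"))
    save_ensemble_checkpoint(ens, models_dir / "ensemble.npz")
    (models_dir / "ensemble.history.json").write_text(json.dumps(result.history, indent=2))


def _stage_evaluate(run_dir: Path, config: RunConfig) -> None:
    sets, _ = _split_sets(run_dir, config)
    models_dir = run_dir / "models"
    reports_dir = run_dir / "reports"
    reports_dir.mkdir(parents=True, exist_ok=True)
    summary = {}
    for scenario in ALL_SCENARIOS:
        name = scenario_name(scenario)
        if scenario == "ensemble":
            model, sidecar = load_ensemble_checkpoint(models_dir / "ensemble.npz")
            modalities = sidecar["union_modalities"]
        else:
            ckpt = models_dir / f"{name}.npz"
            if not ckpt.exists():
                raise OrchestrationError(f"evaluate requires checkpoint {ckpt}")
            model, sidecar = load_checkpoint(ckpt)
            modalities = sidecar["modalities"]
        report = evaluate(model, _samples(sets["test"], modalities))
        report.to_json(reports_dir / f"{name}.json")
        summary[name] = {"mean_iou": report.mean_iou, "dice_coef": report.dice_coef,
                         "accuracy": report.accuracy}
    (reports_dir / "summary.json").write_text(json.dumps(summary, indent=2))


def _stage_gradcam(run_dir: Path, config: RunConfig) -> None:
    model, sidecar = load_ensemble_checkpoint(run_dir / "models" / "ensemble.npz")
    sets, _ = _split_sets(run_dir, config)
    sid, data = sets["test"][0]
    x = stack_modalities(data["volumes"], sidecar["union_modalities"])
    cam_cfg = GradCamConfig(target_class=config.gradcam.target_class,
                            colormap=config.gradcam.colormap, alpha=config.gradcam.alpha)
    heatmap = compute_gradcam(model, x, cam_cfg)
    out = run_dir / "gradcam"
    out.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(heatmap.relevance, np.eye(4)), str(out / f"{sid}_cam.nii.gz"))
    slice_index = config.gradcam.slice_index
    if slice_index is None:
        slice_index = heatmap.relevance.shape[2] // 2
    overlay(heatmap, data["volumes"]["T1ce"], slice_index,
            out_path=out / f"{sid}_overlay.png",
            panel_backgrounds={m: data["volumes"][m] for m in sidecar["union_modalities"]})


_STAGE_FNS = {
    "synth": _stage_synth,
    "preprocess": _stage_preprocess,
    "train": _stage_train,
    "ensemble": _stage_ensemble,
    "evaluate": _stage_evaluate,
    "gradcam": _stage_gradcam,
}


def run_pipeline(config: RunConfig, stages=STAGES, *, force: bool = False) -> Path:
    """Execute the requested stages in order; returns the run directory.

    Stage dependencies must be satisfied either within this call or by
    completed markers from a previous run with the same config.
    Completed stages are skipped unless ``force``.
    """
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise OrchestrationError(f"unknown stage(s) {unknown}; valid: {list(STAGES)}")
    ordered = [s for s in STAGES if s in stages]
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(run_dir / "config.yaml")
    for stage in ordered:
        for dep in _DEPS[stage]:
            if dep not in ordered[: ordered.index(stage)] and not _stage_done(run_dir, dep, config):
                raise OrchestrationError(
                    f"stage {stage!r} requires completed stage {dep!r} "
                    f"(no marker under {run_dir / '.stages'})"
                )
        if not force and _stage_done(run_dir, stage, config):
            log.info("stage %s already complete — skipping", stage)
            continue
        log.info("running stage %s", stage)
        _STAGE_FNS[stage](run_dir, config)
        _mark_done(run_dir, stage, config)
    return run_dir
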