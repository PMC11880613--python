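"""Desk-scale modality-comparison study on synthetic phantoms.

Reproduces the structure of the full experiment at a size a single CPU
handles in minutes: generate a seeded phantom cohort, preprocess it
through the ROI pipeline, train a U-Net per modality scenario —
each single modality, each dual pair, the triple — then fuse the two
designated dual-modality models into the feature-level ensemble and
evaluate every scenario on the same held-out test subjects.

The phantom contrast table is constructed so that no single modality
separates all three tumor classes from brain, which is what makes the
dual-modality and ensemble scenarios genuinely informative rather than
redundant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ensemble import EnsembleConfig, build_ensemble
from .io import split_dataset
from .metrics import MetricsReport
from .phantom import PhantomSpec, generate_cohort
from .preprocess import PreprocessConfig, preprocess_subject
from .train import TrainConfig, TrainResult, evaluate, train
from .unet import UNetConfig, build_unet, stack_modalities

__all__ = ["StudyConfig", "StudyResult", "SINGLE_SCENARIOS", "DUAL_SCENARIOS",
           "TRIPLE_SCENARIO", "ALL_SCENARIOS", "run_study"]

SINGLE_SCENARIOS = (("T1",), ("T2",), ("T1ce",), ("FLAIR",))
DUAL_SCENARIOS = (("T2", "T1ce"), ("T2", "FLAIR"), ("T1ce", "FLAIR"))
TRIPLE_SCENARIO = ("T2", "T1ce", "FLAIR")
#: the nine columns of the full experiment: four singles, three duals,
#: the triple, and the fusion ensemble of the two designated duals
ALL_SCENARIOS = SINGLE_SCENARIOS + DUAL_SCENARIOS + (TRIPLE_SCENARIO, "ensemble")

ENSEMBLE_BASE_A = ("T2", "T1ce")
ENSEMBLE_BASE_B = ("T1ce", "FLAIR")


def scenario_name(scenario) -> str:
    if scenario == "ensemble":
        return "ensemble"
    return "+".join(scenario)


@dataclass(frozen=True)
class StudyConfig:
    """Problem sizes and capacities of the desk-scale study.

    Phantoms are generated at a reduced grid and preprocessed to a
    32³ cube; models are minimal-capacity U-Nets (2 resolution levels,
    4 base filters).  Short schedules use a larger learning rate than
    the full-scale protocol, which small models tolerate and need.
    """

    n_subjects: int = 8
    grid_shape: tuple[int, int, int] = (48, 48, 40)
    n_tumors: int = 1
    noise_sigma: float = 0.05
    cube: int = 32
    depth_levels: int = 2
    base_filters: int = 4
    dropout_rate: float = 0.1
    fusion_filters: int = 16
    batch_size: int = 2
    max_epochs: int = 40
    learning_rate: float = 3e-3
    patience: int = 10
    loss: str = "weighted_cross_entropy"
    scenarios: tuple = ALL_SCENARIOS
    seed: int = 0


@dataclass
class StudyResult:
    """Per-scenario evaluation reports plus training histories."""

    reports: dict[str, MetricsReport] = field(default_factory=dict)
    train_results: dict[str, TrainResult] = field(default_factory=dict)
    split: dict = field(default_factory=dict)
    config: StudyConfig | None = None
    test_data: dict = field(default_factory=dict)
    models: dict = field(default_factory=dict)

    def mean_iou_table(self) -> dict[str, float]:
        return {name: r.mean_iou for name, r in self.reports.items()}


def _prepare_cohort(config: StudyConfig):
    spec = PhantomSpec(
        grid_shape=config.grid_shape,
        n_tumors=config.n_tumors,
        noise_sigma=config.noise_sigma,
        seed=config.seed,
    )
    cohort = generate_cohort(spec, config.n_subjects)
    pre_cfg = PreprocessConfig.scaled(config.grid_shape, config.cube)
    return [preprocess_subject(s, pre_cfg) for s in cohort]


def _samples(subjects, modalities) -> list[tuple[np.ndarray, np.ndarray]]:
    return [
        (stack_modalities(s, list(modalities)), s.mask.astype(np.int64))
        for s in subjects
    ]


def run_study(config: StudyConfig = StudyConfig(), *, keep_models: bool = False) -> StudyResult:
    """Run the requested scenarios end to end; fully seeded.

    The ensemble scenario requires (and if necessary adds) its two base
    dual-modality scenarios.  All scenarios share one subject-level
    70/15/15 split and are evaluated on the same test subjects.
    """
    config_scenarios = list(config.scenarios)
    if "ensemble" in config_scenarios:
        for pair in (ENSEMBLE_BASE_A, ENSEMBLE_BASE_B):
            if pair not in config_scenarios:
                config_scenarios.insert(config_scenarios.index("ensemble"), pair)

    subjects = _prepare_cohort(config)
    ids = [s.subject_id for s in subjects]
    split = split_dataset(ids, seed=config.seed)
    by_id = {s.subject_id: s for s in subjects}
    train_subjects = [by_id[i] for i in split.train_ids]
    val_subjects = [by_id[i] for i in split.val_ids]
    test_subjects = [by_id[i] for i in split.test_ids]

    train_cfg = TrainConfig(
        batch_size=config.batch_size, max_epochs=config.max_epochs,
        learning_rate=config.learning_rate, patience=config.patience,
        loss=config.loss, seed=config.seed,
    )
    result = StudyResult(config=config, split={
        "train_ids": list(split.train_ids), "val_ids": list(split.val_ids),
        "test_ids": list(split.test_ids),
    })

    trained = {}
    for scenario in config_scenarios:
        if scenario == "ensemble":
            continue
        name = scenario_name(scenario)
        model_cfg = UNetConfig(
            in_channels=len(scenario), depth_levels=config.depth_levels,
            base_filters=config.base_filters, dropout_rate=config.dropout_rate,
        )
        model = build_unet(model_cfg, seed=config.seed)
        tr = train(model, _samples(train_subjects, scenario),
                   _samples(val_subjects, scenario), train_cfg)
        result.train_results[name] = tr
        result.reports[name] = evaluate(model, _samples(test_subjects, scenario))
        trained[tuple(scenario)] = model

    if "ensemble" in config_scenarios:
        ens = build_ensemble(
            (trained[ENSEMBLE_BASE_A], ENSEMBLE_BASE_A),
            (trained[ENSEMBLE_BASE_B], ENSEMBLE_BASE_B),
            EnsembleConfig(fusion_filters=config.fusion_filters, seed=config.seed),
        )
        union = ens.union_modalities
        tr = train(ens, _samples(train_subjects, union),
                   _samples(val_subjects, union), train_cfg)
        result.train_results["ensemble"] = tr
        result.reports["ensemble"] = evaluate(ens, _samples(test_subjects, union))
        trained["ensemble"] = ens
        result.test_data["union_modalities"] = union

    if keep_models:
        result.models = {scenario_name(k) if k != "ensemble" else "ensemble": m
                         for k, m in trained.items()}
        result.test_data["test_subjects"] = test_subjects
    return result
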