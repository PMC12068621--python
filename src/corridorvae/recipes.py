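"""Experiment recipes: the eight model configurations and their pipelines.

The study compares one unsupervised baseline against seven variants:

========  ==============  =====================================
id        dataset         classifier heads
========  ==============  =====================================
baseline  balanced        none
E1M1      lower_left_10x  none (frequency-biased data)
E1M2      aligned_10x     none (alignment-biased data)
E2M1      balanced        linear head, task T1 (x_UC <= x_LC)
E2M2      balanced        linear head, task T2 (left/right rule)
E2M3      balanced        linear head, task T3 (alignment)
E2M4      balanced        nonlinear head (1500 units), task T4 (25 bins)
E2M5      balanced        all four heads, trained simultaneously
========  ==============  =====================================

Each recipe can be run at any capacity of the sweep Cmax in
{0.3, 1, 3, 6, 10} nats.  ``run_recipe`` materialises a run directory with a
manifest, a checkpoint, a per-epoch log and the standard analysis tables;
``compare_models`` computes the distortion matrices between two trained
models on a shared evaluation dataset.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import geometry
from .data import Dataset, DatasetSpec, TASKS, generate_dataset, n_classes
from .models import ClassifierSpec, CorridorVAE, ModelSpec
from .train import TrainConfig, TrainResult, train

EXPERIMENT_IDS = ("baseline", "E1M1", "E1M2", "E2M1", "E2M2", "E2M3", "E2M4", "E2M5")

_TASK_OF = {"E2M1": "T1", "E2M2": "T2", "E2M3": "T3", "E2M4": "T4"}


def _heads_for(experiment_id: str) -> tuple[ClassifierSpec, ...]:
    if experiment_id in _TASK_OF:
        t = _TASK_OF[experiment_id]
        kind = "nonlinear" if t == "T4" else "linear"
        return (ClassifierSpec(kind=kind, n_classes=n_classes(t)),)
    if experiment_id == "E2M5":
        return tuple(
            ClassifierSpec(kind="nonlinear" if t == "T4" else "linear",
                           n_classes=n_classes(t))
            for t in TASKS)
    return ()


def _tasks_for(experiment_id: str) -> tuple[str, ...]:
    if experiment_id in _TASK_OF:
        return (_TASK_OF[experiment_id],)
    if experiment_id == "E2M5":
        return TASKS
    return ()


def _weighting_for(experiment_id: str) -> str:
    return {"E1M1": "lower_left_10x", "E1M2": "aligned_10x"}.get(
        experiment_id, "balanced")


@dataclass(frozen=True)
class ExperimentRecipe:
    """Everything needed to reproduce one (experiment, capacity) run."""

    experiment_id: str
    c_max: float = 10.0
    n_images: int = 20_000  # desk-scale default; the full-scale study uses 200,000
    epochs: int = 300
    batch_size: int = 64
    gamma: float = 100.0
    lr: float = 5e-5
    seed: int = 0
    eval_every: int = 10
    model_spec: ModelSpec = field(default=None)  # filled in __post_init__

    def __post_init__(self) -> None:
        if self.experiment_id not in EXPERIMENT_IDS:
            raise ValueError(f"unknown experiment {self.experiment_id!r}")
        if self.model_spec is None:
            object.__setattr__(
                self, "model_spec",
                ModelSpec(classifier_heads=_heads_for(self.experiment_id)))

    @property
    def tasks(self) -> tuple[str, ...]:
        return _tasks_for(self.experiment_id)

    @property
    def dataset_spec(self) -> DatasetSpec:
        return DatasetSpec(n_images=self.n_images,
                           weighting=_weighting_for(self.experiment_id),
                           seed=self.seed)

    @property
    def train_config(self) -> TrainConfig:
        if not self.tasks:
            regime = "baseline"
        elif self.experiment_id == "E2M5":
            regime = "multitask"
        else:
            regime = "joint"
        return TrainConfig(regime=regime, tasks=self.tasks, c_max=self.c_max,
                           gamma=self.gamma, lr=self.lr,
                           batch_size=self.batch_size, epochs=self.epochs,
                           seed=self.seed, eval_every=self.eval_every)


def run_experiment(recipe: ExperimentRecipe, dataset: Dataset | None = None,
                   progress: bool = False) -> TrainResult:
    """Generate (or reuse) the recipe's dataset and train its model."""
    if dataset is None:
        dataset = generate_dataset(recipe.dataset_spec)
    return train(dataset, recipe.model_spec, recipe.train_config,
                 progress=progress)


def run_recipe(recipe: ExperimentRecipe, out_dir: str,
               dataset: Dataset | None = None, overwrite: bool = False,
               progress: bool = False) -> str:
    """Run a recipe end to end and materialise a run directory.

    The directory holds ``manifest.yaml``, ``checkpoint.npz(.yaml)``,
    ``log.csv`` (per-epoch metrics) and ``channel_kl.csv``.  Refuses to
    write into an existing run directory unless ``overwrite`` is set.
    """
    run_dir = os.path.join(out_dir,
                           f"{recipe.experiment_id}_cmax{recipe.c_max:g}")
    if os.path.exists(os.path.join(run_dir, "manifest.yaml")) and not overwrite:
        raise FileExistsError(f"run directory {run_dir!r} already exists; "
                              "pass overwrite=True to replace it")
    os.makedirs(run_dir, exist_ok=True)

    if dataset is None:
        dataset = generate_dataset(recipe.dataset_spec)
    result = run_experiment(recipe, dataset, progress=progress)

    result.model.save(os.path.join(run_dir, "checkpoint.npz"))
    result.log.to_csv(os.path.join(run_dir, "log.csv"), index=False)
    _, test = dataset.split(result.config.test_frac, result.config.split_seed)
    ckl = geometry.per_channel_kl(result.model, test)
    pd.DataFrame({"channel": np.arange(ckl.size), "kl_nats": ckl}).to_csv(
        os.path.join(run_dir, "channel_kl.csv"), index=False)

    manifest = {
        "experiment_id": recipe.experiment_id,
        "c_max": recipe.c_max, "gamma": recipe.gamma, "lr": recipe.lr,
        "n_images": recipe.n_images, "weighting": _weighting_for(recipe.experiment_id),
        "epochs": recipe.epochs, "batch_size": recipe.batch_size,
        "seed": recipe.seed, "tasks": list(recipe.tasks),
        "heads": [{"kind": h.kind, "n_classes": h.n_classes, "hidden": h.hidden}
                  for h in recipe.model_spec.classifier_heads],
        "final_metrics": {k: (float(v) if np.isscalar(v) else
                              [float(u) for u in np.ravel(v)])
                          for k, v in result.metrics.items()},
    }
    with open(os.path.join(run_dir, "manifest.yaml"), "w") as fh:
        yaml.safe_dump(manifest, fh)
    return run_dir


def compare_models(model_ref: CorridorVAE, model_cmp: CorridorVAE,
                   eval_dataset: Dataset, class_labels: np.ndarray | None = None,
                   per_label: int = 20, seed: int = 0):
    """Item- and class-level distortion matrices of ``model_cmp`` vs ``model_ref``.

    Both models embed the same (stratified subsample of the) evaluation
    dataset; ``class_labels`` (one per image of ``eval_dataset``) chooses the
    class grouping -- task classes for the task experiments, frequency
    classes for the biased-data experiments.  Returns ``(item, cls)`` where
    ``cls`` is None when no class labels are supplied.
    """
    idx = geometry.stratified_subsample(eval_dataset, per_label, seed)
    sub = eval_dataset._take(np.isin(np.arange(len(eval_dataset)), idx))
    emb_ref = geometry.embed_dataset(model_ref, sub, "ref")
    emb_cmp = geometry.embed_dataset(model_cmp, sub, "cmp")
    rho, pairs, _ = geometry.distortion_ratios(emb_ref, emb_cmp)
    item = geometry.item_distortion_matrix(rho, pairs, emb_ref.position_labels)
    cls = None
    if class_labels is not None:
        cls = geometry.class_distortion_matrix(
            rho, pairs, np.asarray(class_labels)[idx])
    return item, cls
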