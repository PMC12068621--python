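"""Training regimes, capacity annealing, and held-out evaluation.

Five regimes are supported:

* ``baseline``  -- unsupervised beta-VAE, no classifier heads.
* ``joint``     -- VAE and one or more heads trained end-to-end (hybrid models).
* ``frozen_then_classifier`` -- heads trained post hoc on a frozen VAE.
* ``transfer``  -- like the frozen regime, but the encoder comes from a model
  that was jointly specialised for a *different* task.
* ``multitask`` -- joint training with all four task heads.

The capacity C of the KL constraint ramps linearly from 0 to ``c_max`` over
the first half of the optimisation steps and stays at ``c_max`` after.  The
held-out "reconstruction loss" reported in logs is the per-pixel mean squared
error between the binary image and the decoded pixel probabilities, whose
magnitude is bounded below by the intrinsic Bernoulli pixel noise (~0.055 for
a perfect model on this dataset); the per-pixel Bernoulli cross-entropy is
reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score

from .data import Dataset, TASKS
from .models import (CorridorVAE, ModelSpec, classifier_step, kl_divergence,
                     kl_per_dimension, reconstruction_loss, training_step)
from . import nn
from .nn import Adam

REGIMES = ("baseline", "joint", "frozen_then_classifier", "transfer", "multitask")

CMAX_GRID = (0.3, 1.0, 3.0, 6.0, 10.0)  # capacity sweep, nats


@dataclass(frozen=True)
class CapacitySchedule:
    """Linear ramp of the KL capacity target: 0 -> c_max over the annealing
    steps, constant c_max thereafter."""

    c_max: float
    gamma: float = 100.0
    anneal_steps: int = 1
    total_steps: int = 1

    def capacity_at_step(self, step: int) -> float:
        if not 0 <= step <= self.total_steps:
            raise ValueError(f"step {step} outside 0..{self.total_steps}")
        if self.anneal_steps <= 0:
            return self.c_max
        return self.c_max * min(1.0, step / self.anneal_steps)


def capacity_at_step(step: int, schedule: CapacitySchedule) -> float:
    return schedule.capacity_at_step(step)


@dataclass(frozen=True)
class TrainConfig:
    regime: str = "baseline"
    tasks: tuple[str, ...] = ()  # subset of TASKS, order = head order
    c_max: float = 10.0
    gamma: float = 100.0
    lr: float = 5e-5
    batch_size: int = 64
    epochs: int = 300
    seed: int = 0
    anneal_frac: float = 0.5  # fraction of steps spent ramping C
    test_frac: float = 0.1
    split_seed: int = 7
    eval_every: int = 1  # held-out evaluation cadence, epochs

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.regime == "baseline" and self.tasks:
            raise ValueError("baseline regime takes no tasks")
        if self.regime == "multitask" and tuple(self.tasks) != TASKS:
            raise ValueError("multitask regime requires all four tasks")
        unknown = set(self.tasks) - set(TASKS)
        if unknown:
            raise ValueError(f"unknown tasks {sorted(unknown)}")


@dataclass
class TrainResult:
    model: CorridorVAE
    log: pd.DataFrame  # one row per epoch
    config: TrainConfig
    metrics: dict = field(default_factory=dict)  # final held-out metrics


def _task_columns(tasks: tuple[str, ...], dataset: Dataset) -> list[np.ndarray]:
    return [dataset.task_labels[:, TASKS.index(t)] for t in tasks]


def evaluate(model: CorridorVAE, test: Dataset,
             tasks: tuple[str, ...] = ()) -> dict:
    """Held-out metrics: reconstruction error, KL, per-task F1.

    Reconstruction is reported both as the per-pixel mean squared error
    between pixels and decoded probabilities (``recon_mse``, the headline
    reconstruction-loss metric) and as the per-pixel mean Bernoulli
    cross-entropy (``recon_bce``, nats).  Classifiers are evaluated on the
    posterior mean.  F1 is the positive-class F1 for binary tasks and the
    macro average for the 25-class task.
    """
    x = test.images.astype(float)
    params = model.encode(x)
    probs = model.decode(params.mu)
    flat_x = x.reshape(len(test), -1)
    flat_p = probs.reshape(len(test), -1)
    out = {
        "recon_mse": float(np.mean((flat_x - flat_p) ** 2)),
        "recon_bce": float(reconstruction_loss(x, probs, reduction="mean").mean()),
        "kl": float(kl_divergence(params).mean()),
        "kl_per_channel": kl_per_dimension(params).mean(axis=0),
    }
    for i, t in enumerate(tasks):
        y = test.task_labels[:, TASKS.index(t)]
        pred = model.classify(params.mu, head=i).argmax(axis=1)
        avg = "macro" if t == "T4" else "binary"
        out[f"f1_{t}"] = float(f1_score(y, pred, average=avg, zero_division=0))
    return out


def train(dataset: Dataset, model_spec: ModelSpec, config: TrainConfig,
          pretrained: CorridorVAE | None = None,
          progress: bool = False) -> TrainResult:
    """Train a model under one regime; fully reproducible given the seed.

    In the frozen and transfer regimes a ``pretrained`` model must be
    supplied; its encoder/decoder weights are copied and never updated (the
    returned model's VAE weights are bit-identical to the pretrained ones).
    """
    frozen = config.regime in ("frozen_then_classifier", "transfer")
    if frozen and pretrained is None:
        raise ValueError(f"regime {config.regime!r} requires a pretrained model")
    if config.regime == "baseline" and model_spec.classifier_heads:
        raise ValueError("baseline model must not carry classifier heads")
    if config.regime != "baseline" and \
            len(model_spec.classifier_heads) != len(config.tasks):
        raise ValueError("one classifier head per configured task is required")

    rng = np.random.default_rng(config.seed)
    train_ds, test_ds = dataset.split(config.test_frac, config.split_seed)

    model = CorridorVAE(model_spec, seed=config.seed)
    if frozen:
        for p_new, p_old in zip(model.vae_params(), pretrained.vae_params()):
            p_new.value[...] = p_old.value

    trainable = model.head_params() if frozen else model.params()
    opt = Adam(trainable, lr=config.lr)

    n = len(train_ds)
    steps_per_epoch = int(np.ceil(n / config.batch_size))
    total_steps = steps_per_epoch * config.epochs
    schedule = CapacitySchedule(config.c_max, config.gamma,
                                anneal_steps=int(config.anneal_frac * total_steps),
                                total_steps=total_steps)

    X = train_ds.images.astype(nn.DTYPE)
    ys = _task_columns(config.tasks, train_ds)

    rows = []
    step = 0
    for epoch in range(config.epochs):
        ep_loss = []
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            c = schedule.capacity_at_step(step)
            xb = X[idx]
            if frozen:
                ces = [classifier_step(model, xb, y[idx], head=i, rng=rng)
                       for i, y in enumerate(ys)]
                total = sum(ces)
            else:
                br = training_step(model, xb, [y[idx] for y in ys],
                                   config.gamma, c, rng)
                total = br.total
            if not np.isfinite(total):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, step {step}")
            opt.step()
            ep_loss.append(total)
            step += 1
        if (epoch + 1) % config.eval_every and epoch != config.epochs - 1:
            continue
        metrics = evaluate(model, test_ds, config.tasks)
        row = {"epoch": epoch, "capacity": schedule.capacity_at_step(step),
               "train_loss": float(np.mean(ep_loss)),
               "recon_mse": metrics["recon_mse"], "recon_bce": metrics["recon_bce"],
               "kl": metrics["kl"]}
        row.update({k: v for k, v in metrics.items() if k.startswith("f1_")})
        rows.append(row)
        if progress:
            print(f"  epoch {epoch:3d}  C={row['capacity']:.2f}  "
                  f"loss={row['train_loss']:.2f}  mse={row['recon_mse']:.4f}  "
                  f"kl={row['kl']:.2f}  "
                  + " ".join(f"{k}={v:.3f}" for k, v in row.items()
                             if k.startswith("f1_")))

    final = evaluate(model, test_ds, config.tasks)
    if frozen:  # freezing contract: VAE weights bit-identical
        assert all(np.array_equal(a.value, b.value) for a, b in
                   zip(model.vae_params(), pretrained.vae_params()))
    return TrainResult(model, pd.DataFrame(rows), config, final)


def run_capacity_sweep(dataset: Dataset, model_spec: ModelSpec,
                       base_config: TrainConfig,
                       c_max_list: tuple[float, ...] = CMAX_GRID,
                       pretrained: dict[float, CorridorVAE] | None = None,
                       progress: bool = False) -> dict[float, TrainResult]:
    """Train one model per capacity value with otherwise identical settings."""
    out = {}
    for c in c_max_list:
        cfg = replace(base_config, c_max=float(c))
        pre = pretrained.get(c) if pretrained else None
        out[float(c)] = train(dataset, model_spec, cfg, pretrained=pre,
                              progress=progress)
    return out
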