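"""Training loop: BCE loss, Adam with warmup/decay schedule, dynamic batching.

Optimiser defaults: Adam
(beta1 0.9, beta2 0.999, eps 1e-8), peak learning rate 1.5e-3 reached
by linear warmup over 3000 steps and then decayed by a factor 0.997
every 1000 steps (continuous exponent by default), with gradient
clipping to global norm 1.  Batches are formed dynamically by sequence
length under a token budget, so short sequences share large batches
while long ones train in small ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .model import Model

_BCE_EPS = 1e-7


class TrainError(ValueError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    """Optimiser and batching settings (defaults suit long full-scale runs)."""

    learning_rate: float = 1.5e-3
    decay_rate: float = 0.997
    decay_steps: int = 1000
    warmup_steps: int = 3000
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    gradient_clip: float = 1.0
    train_steps: int = 5000
    token_budget: int = 2000
    seed: int = 0
    decay_style: str = "continuous"  # "continuous" | "staircase"

    def __post_init__(self) -> None:
        for name in ("learning_rate", "decay_rate", "decay_steps", "warmup_steps",
                     "adam_beta1", "adam_beta2", "adam_eps", "gradient_clip",
                     "token_budget"):
            if getattr(self, name) <= 0:
                raise TrainError(f"{name} must be positive")
        if self.train_steps < 0:
            raise TrainError("train_steps must be >= 0")
        if self.train_steps and self.warmup_steps >= self.train_steps:
            # warmup never completing is almost certainly a configuration slip
            raise TrainError("warmup_steps must be < train_steps")
        if self.decay_style not in ("continuous", "staircase"):
            raise TrainError(f"unknown decay_style {self.decay_style!r}")


def desk_scale_config(seed: int = 0, train_steps: int = 5000) -> TrainConfig:
    """Training recipe for small single-device runs.

    The default :class:`TrainConfig` carries the full-scale schedule,
    tuned for half-million-step runs; at a few
    thousand steps its 3000-step warmup would occupy most of training.
    This recipe scales the schedule to short runs: warmup over 250
    steps, a higher peak rate (1e-2) appropriate for the small models
    it is used with, and a 4000-token batch budget for less noisy
    gradients.
    """
    return TrainConfig(
        learning_rate=1e-2,
        warmup_steps=250,
        token_budget=4000,
        train_steps=train_steps,
        seed=seed,
    )


def lr_at_step(cfg: TrainConfig, step: int) -> float:
    """Learning rate at an optimiser step (0-based).

    Linear warmup from 0 to the peak rate over ``warmup_steps``, then
    exponential decay ``peak * decay_rate ** ((step - warmup) / decay_steps)``.
    """
    if step < 0:
        raise TrainError("step must be >= 0")
    if step <= cfg.warmup_steps:
        return cfg.learning_rate * step / cfg.warmup_steps
    t = (step - cfg.warmup_steps) / cfg.decay_steps
    if cfg.decay_style == "staircase":
        t = math.floor(t)
    return cfg.learning_rate * cfg.decay_rate**t


def loss(probabilities: np.ndarray, targets: np.ndarray) -> float:
    """Multi-label binary cross-entropy, averaged over the vocabulary.

    ``probabilities`` and ``targets`` (0/1) are broadcastable arrays
    whose last axis is the vocabulary; probabilities are clamped to
    ``[eps, 1 - eps]``.  For batched inputs the mean is over all axes.
    """
    p = np.clip(np.asarray(probabilities, dtype=np.float64), _BCE_EPS, 1 - _BCE_EPS)
    y = np.asarray(targets, dtype=np.float64)
    if p.shape != y.shape:
        raise TrainError(f"shape mismatch {p.shape} vs {y.shape}")
    return float(np.mean(-(y * np.log(p) + (1 - y) * np.log1p(-p))))


def targets_matrix(records: Sequence, vocabulary: Sequence[str]) -> np.ndarray:
    """0/1 matrix (n_records, |vocab|) from records' closed label sets."""
    index = {lab: j for j, lab in enumerate(vocabulary)}
    y = np.zeros((len(records), len(vocabulary)), dtype=np.float32)
    for i, rec in enumerate(records):
        for lab in rec.labels:
            j = index.get(lab)
            if j is None:
                raise TrainError(
                    f"record {rec.accession!r} carries label {lab!r} "
                    "outside the model vocabulary"
                )
            y[i, j] = 1.0
    return y


def make_batches(
    records: Sequence, token_budget: int, seed: int = 0
) -> list[list]:
    """One epoch of length-bucketed batches under a padding-token budget.

    Records are shuffled (seeded), sorted by length (stable, so the
    shuffle breaks ties), and packed greedily such that every batch
    satisfies ``max_length * batch_size <= token_budget``; the batch
    order is then shuffled.  Every record appears exactly once.
    """
    too_long = [r for r in records if len(r.sequence) > token_budget]
    if too_long:
        raise TrainError(
            f"record {too_long[0].accession!r} is longer "
            f"({len(too_long[0].sequence)}) than the token budget {token_budget}"
        )
    rng = np.random.default_rng(seed)
    order = list(records)
    rng.shuffle(order)
    order.sort(key=lambda r: len(r.sequence))
    batches: list[list] = []
    current: list = []
    for r in order:
        # lengths ascend, so the candidate max length is len(r.sequence)
        if current and (len(current) + 1) * len(r.sequence) > token_budget:
            batches.append(current)
            current = []
        current.append(r)
    if current:
        batches.append(current)
    rng.shuffle(batches)
    return batches


@dataclass
class TrainLog:
    """Per-step scalars recorded during training."""

    steps: list[int] = field(default_factory=list)
    losses: list[float] = field(default_factory=list)
    lrs: list[float] = field(default_factory=list)

    def append(self, step: int, loss_value: float, lr: float) -> None:
        self.steps.append(step)
        self.losses.append(loss_value)
        self.lrs.append(lr)


def clip_by_global_norm(
    grads: dict[str, np.ndarray], clip: float
) -> tuple[dict[str, np.ndarray], float]:
    """Scale all gradients so their joint L2 norm is at most ``clip``."""
    total = math.sqrt(sum(float(np.sum(g.astype(np.float64) ** 2)) for g in grads.values()))
    if total > clip:
        scale = np.float32(clip / total)
        grads = {k: g * scale for k, g in grads.items()}
    return grads, total


def train(
    model: Model,
    records: Sequence,
    cfg: TrainConfig,
    checkpoint_dir: str | Path | None = None,
    checkpoint_every: int = 1000,
) -> TrainLog:
    """Train the model in place; returns the per-step log.

    Deterministic given ``cfg.seed`` on a single device.  Aborts with a
    diagnostic if the loss becomes non-finite.
    """
    if not records:
        raise TrainError("empty training set")
    y_index = {r.accession: i for i, r in enumerate(records)}
    y_all = targets_matrix(records, model.vocabulary)
    from .model import pad_batch  # local import to keep module load cheap

    m = {k: np.zeros_like(v) for k, v in model.params.items()}
    v = {k: np.zeros_like(vv) for k, vv in model.params.items()}
    log = TrainLog()
    step = 0
    epoch = 0
    b1, b2, eps = cfg.adam_beta1, cfg.adam_beta2, cfg.adam_eps
    while step < cfg.train_steps:
        for batch in make_batches(records, cfg.token_budget, seed=cfg.seed + epoch):
            if step >= cfg.train_steps:
                break
            x, mask = pad_batch([r.sequence for r in batch])
            y = y_all[[y_index[r.accession] for r in batch]]
            batch_loss, grads, _logits = model.forward_backward(x, mask, y)
            if not math.isfinite(batch_loss):
                raise RuntimeError(
                    f"non-finite loss {batch_loss} at step {step} "
                    f"(batch of {len(batch)}, max len "
                    f"{max(len(r.sequence) for r in batch)})"
                )
            grads, _norm = clip_by_global_norm(grads, cfg.gradient_clip)
            step += 1
            lr = lr_at_step(cfg, step)
            bc1 = 1.0 - b1**step
            bc2 = 1.0 - b2**step
            for k, g in grads.items():
                m[k] = b1 * m[k] + (1 - b1) * g
                v[k] = b2 * v[k] + (1 - b2) * (g * g)
                update = (m[k] / bc1) / (np.sqrt(v[k] / bc2) + eps)
                model.params[k] -= np.float32(lr) * update
            log.append(step, batch_loss, lr)
            if checkpoint_dir is not None and step % checkpoint_every == 0:
                Path(checkpoint_dir).mkdir(parents=True, exist_ok=True)
                model.save(Path(checkpoint_dir) / f"step{step:07d}.ckpt")
        epoch += 1
    return log
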