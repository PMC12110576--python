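"""Training loop: mirror-augmented batches, combined loss, Adam.

Each step samples a batch of original trials, constructs the mirror
batch (doubling it), runs the network on the combined batch, computes
L = L_c + w_o L_o + w_m L_m and performs one Adam update. Weight decay
(default 0.05) is applied as decoupled decay on matrix-shaped
parameters (gains and biases exempt); a coupled-L2 mode is available.

The train/test subject sets are expected to be disjoint (the
subject-independent contract); overlap is detected and warned about,
not silently accepted.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluation import fused_predict, score_predictions
from .losses import ContrastiveConfig, make_pairset, total_loss
from .model import ModelConfig, SWTModel
from .montage import EEGTrial, MirrorMap, build_mirror_map, make_mirror_batch

__all__ = ["TrainConfig", "EpochHistory", "Adam", "train_step", "fit"]


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    weight_decay: float = 0.05
    decoupled_weight_decay: bool = True
    batch_size: int = 64
    max_epochs: int = 500
    seed: int = 0
    eval_every: int = 1
    shuffle: bool = True

    def __post_init__(self):
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2 (contrastive pairs must exist)")


@dataclass
class EpochHistory:
    """Per-epoch training record."""

    train_loss: list[float] = field(default_factory=list)
    train_loss_ce: list[float] = field(default_factory=list)
    train_loss_lo: list[float] = field(default_factory=list)
    train_loss_lm: list[float] = field(default_factory=list)
    test_accuracy: list[float] = field(default_factory=list)  # mirror-fused
    test_kappa: list[float] = field(default_factory=list)
    test_accuracy_plain: list[float] = field(default_factory=list)
    test_kappa_plain: list[float] = field(default_factory=list)

    def __len__(self):
        return len(self.train_loss)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(1, len(self) + 1),
                "train_loss": self.train_loss,
                "train_loss_ce": self.train_loss_ce,
                "train_loss_lo": self.train_loss_lo,
                "train_loss_lm": self.train_loss_lm,
                "test_accuracy": self.test_accuracy,
                "test_kappa": self.test_kappa,
                "test_accuracy_plain": self.test_accuracy_plain,
                "test_kappa_plain": self.test_kappa_plain,
            }
        )


class Adam:
    """Adam with optional decoupled weight decay."""

    def __init__(self, params: dict, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0, decoupled: bool = True):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.decoupled = decoupled
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def register_new(self) -> None:
        """Pick up lazily-created parameters (the model's FC head)."""
        for k, p in self.params.items():
            if k not in self.m:
                self.m[k] = np.zeros_like(p.data)
                self.v[k] = np.zeros_like(p.data)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            decay = self.weight_decay if p.data.ndim >= 2 else 0.0
            if decay and not self.decoupled:
                g = g + decay * p.data
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            update = mhat / (np.sqrt(vhat) + self.eps)
            if decay and self.decoupled:
                update = update + decay * p.data
            p.data = p.data - self.lr * update


def train_step(
    batch: list[EEGTrial],
    model: SWTModel,
    mirror_map: MirrorMap,
    loss_cfg: ContrastiveConfig,
    optimizer: Adam,
) -> dict[str, float]:
    """One mirror-augmented training step; returns the loss components."""
    augmented, _ = make_mirror_batch(batch, mirror_map)
    signals = np.stack([t.signal for t in augmented])
    labels = np.array([t.label for t in augmented])
    n = len(batch)
    out = model.forward(signals, training=True)
    optimizer.register_new()
    pairs = make_pairset(labels[:n], labels[n:])
    L, L_c, L_o, L_m = total_loss(out.probs, labels, out.embedding, pairs, loss_cfg)
    if not np.isfinite(L.data):
        raise RuntimeError(
            f"non-finite training loss (L={float(L.data)}, ce={float(L_c.data)}, "
            f"lo={float(L_o.data)}, lm={float(L_m.data)})"
        )
    optimizer.zero_grad()
    L.backward()
    optimizer.step()
    return {
        "loss": float(L.data),
        "ce": float(L_c.data),
        "lo": float(L_o.data),
        "lm": float(L_m.data),
    }


def _check_subject_disjoint(train_set, test_set) -> None:
    tr = {t.subject_id for t in train_set}
    te = {t.subject_id for t in test_set}
    overlap = tr & te
    if overlap:
        warnings.warn(
            f"train and test sets share subjects {sorted(overlap)}; the "
            "evaluation is not subject-independent",
            stacklevel=3,
        )


def _evaluate(model, test_set, mirror_map):
    # one combined forward pass over [originals, mirrors] serves both the
    # plain and the mirror-fused metrics
    labels = np.array([t.label for t in test_set])
    perm = list(mirror_map.channel_permutation)
    sig = np.stack([t.signal for t in test_set])
    both = np.concatenate([sig, sig[:, :, perm]], axis=0)
    probs = model.predict_proba(both)
    n = len(test_set)
    plain, p_m = probs[:n], probs[n:]
    fused = (plain + p_m[:, ::-1]) / 2.0
    acc_f, kap_f, _ = score_predictions(fused.argmax(axis=1), labels)
    acc_p, kap_p, _ = score_predictions(plain.argmax(axis=1), labels)
    return acc_f, kap_f, acc_p, kap_p


def fit(
    train_set: list[EEGTrial],
    test_set: list[EEGTrial],
    model_cfg: ModelConfig | None = None,
    train_cfg: TrainConfig | None = None,
    loss_cfg: ContrastiveConfig | None = None,
    model: SWTModel | None = None,
    callback=None,
) -> tuple[dict, EpochHistory, SWTModel]:
    """Train on the original trials, evaluating on held-out subjects.

    One epoch is one full pass over the *original* training trials
    (mirrors are constructed per batch and excluded from the count).
    Batches are reshuffled each epoch from the seeded generator, so
    (seed, configs, data) fully determine the history. Returns the
    weight snapshot at the epoch of minimum training loss, the
    history, and the (final-state) model.
    """
    if not train_set or not test_set:
        raise ValueError("train and test partitions must be non-empty")
    model_cfg = model_cfg or ModelConfig()
    train_cfg = train_cfg or TrainConfig()
    loss_cfg = loss_cfg or ContrastiveConfig()
    _check_subject_disjoint(train_set, test_set)
    rng = np.random.default_rng(train_cfg.seed)
    if model is None:
        model = SWTModel(model_cfg, rng=rng)
    mirror_map = build_mirror_map(train_set[0].channel_names)
    optimizer = Adam(
        model.trainable(),
        lr=train_cfg.learning_rate,
        weight_decay=train_cfg.weight_decay,
        decoupled=train_cfg.decoupled_weight_decay,
    )
    history = EpochHistory()
    best_loss = np.inf
    best_weights = model.state_dict()
    n = len(train_set)
    for epoch in range(train_cfg.max_epochs):
        order = rng.permutation(n) if train_cfg.shuffle else np.arange(n)
        comps = []
        for start in range(0, n, train_cfg.batch_size):
            idx = order[start : start + train_cfg.batch_size]
            if len(idx) < 2:  # a single trial has no contrastive pairs
                continue
            batch = [train_set[k] for k in idx]
            comps.append(train_step(batch, model, mirror_map, loss_cfg, optimizer))
        mean = {k: float(np.mean([c[k] for c in comps])) for k in comps[0]}
        history.train_loss.append(mean["loss"])
        history.train_loss_ce.append(mean["ce"])
        history.train_loss_lo.append(mean["lo"])
        history.train_loss_lm.append(mean["lm"])
        if epoch % train_cfg.eval_every == 0 or epoch == train_cfg.max_epochs - 1:
            acc_f, kap_f, acc_p, kap_p = _evaluate(model, test_set, mirror_map)
        history.test_accuracy.append(acc_f)
        history.test_kappa.append(kap_f)
        history.test_accuracy_plain.append(acc_p)
        history.test_kappa_plain.append(kap_p)
        if mean["loss"] < best_loss:
            best_loss = mean["loss"]
            best_weights = model.state_dict()
        if callback is not None and callback(epoch, history, model):
            break
    return best_weights, history, model
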