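"""Mirror contrastive loss and the combined training objective.

The contrastive part is a margin hinge on Euclidean embedding
distances::

    loss(D, g) = max(alpha + g * (D - beta), 0),   g = +1 same class
                                                   g = -1 different class

so same-class pairs are pulled inside D < beta - alpha and
different-class pairs pushed beyond D > alpha + beta. It is applied to
two pair sets: L_o over all unordered pairs of *original* trials, and
L_m over every (mirror, original) combination — a trial and its own
mirror always carry opposite labels and therefore always form a
negative pair. The total objective is

    L = L_c + w_o * L_o + w_m * L_m

with L_c the cross-entropy over the mirror-augmented batch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor

__all__ = [
    "ContrastiveConfig",
    "PairSet",
    "make_pairset",
    "assign_pair_sign",
    "hinge_pair_loss",
    "original_set_loss",
    "mirror_set_loss",
    "cross_entropy",
    "total_loss",
]


@dataclass
class ContrastiveConfig:
    """Margin parameters and loss weights."""

    alpha: float = 0.2  # margin offset
    beta: float = 1.2  # positive/negative boundary
    w_o: float = 0.2  # weight of the original-pair loss L_o
    w_m: float = 0.3  # weight of the mirror-pair loss L_m
    aggregation: str = "mean"  # 'mean' or 'sum' over pairs
    enable_Lo: bool = True  # ablation switches
    enable_Lm: bool = True

    def __post_init__(self):
        if self.alpha < 0 or self.beta <= 0 or self.w_o < 0 or self.w_m < 0:
            raise ValueError("require alpha >= 0, beta > 0, weights >= 0")
        if self.aggregation not in ("mean", "sum"):
            raise ValueError("aggregation must be 'mean' or 'sum'")


@dataclass
class PairSet:
    """Index pairs over a mirror-augmented batch (originals first).

    ``origin`` is 'oo' for original-original pairs (unordered, unique)
    and 'mo' for mirror-original combinations.
    """

    i: np.ndarray
    j: np.ndarray
    g: np.ndarray  # +1 positive (same label), -1 negative
    origin: np.ndarray  # 'oo' | 'mo'

    def __post_init__(self):
        if np.any(self.i == self.j):
            raise ValueError("self-pairs are not allowed")


def assign_pair_sign(label_i, label_j):
    """+1 for same-class (positive) pairs, -1 otherwise. Vectorized."""
    return np.where(np.asarray(label_i) == np.asarray(label_j), 1, -1)


def make_pairset(labels_oe: np.ndarray, labels_me: np.ndarray) -> PairSet:
    """Enumerate pairs over the combined batch [originals, mirrors].

    Mirror labels must already be the swapped ones. Indices refer to
    the concatenated batch of n originals followed by m mirrors.
    """
    labels_oe = np.asarray(labels_oe)
    labels_me = np.asarray(labels_me)
    n, m = len(labels_oe), len(labels_me)
    io, jo = np.triu_indices(n, k=1)
    im, jm = np.meshgrid(np.arange(m), np.arange(n), indexing="ij")
    im, jm = im.ravel() + n, jm.ravel()
    labels_all = np.concatenate([labels_oe, labels_me])
    i = np.concatenate([io, im])
    j = np.concatenate([jo, jm])
    return PairSet(
        i=i,
        j=j,
        g=assign_pair_sign(labels_all[i], labels_all[j]),
        origin=np.array(["oo"] * len(io) + ["mo"] * len(im)),
    )


def _as_tensor_pair(x):
    return (x, True) if isinstance(x, Tensor) else (Tensor(np.asarray(x, dtype=float)), False)


def hinge_pair_loss(D, g, alpha: float = 0.2, beta: float = 1.2):
    """max(alpha + g * (D - beta), 0), elementwise over pairs."""
    Dt, is_tensor = _as_tensor_pair(D)
    out = (Dt - beta) * np.asarray(g, dtype=float) + alpha
    out = out.relu()
    if is_tensor:
        return out
    return float(out.data) if out.data.ndim == 0 else out.data


def _pair_distances(emb: Tensor, i: np.ndarray, j: np.ndarray) -> Tensor:
    diff = emb.take(i, axis=0) - emb.take(j, axis=0)
    return diff.square().sum(axis=1).sqrt()


def _aggregate(per_pair: Tensor, how: str) -> Tensor:
    return per_pair.mean() if how == "mean" else per_pair.sum()


def _contrastive(emb: Tensor, i, j, g, cfg: ContrastiveConfig) -> Tensor:
    if len(i) == 0:
        return Tensor(np.zeros((), dtype=emb.data.dtype))
    D = _pair_distances(emb, np.asarray(i), np.asarray(j))
    return _aggregate(hinge_pair_loss(D, g, cfg.alpha, cfg.beta), cfg.aggregation)


def original_set_loss(embeddings, labels, cfg: ContrastiveConfig | None = None):
    """L_o: hinge over all unordered pairs of original trials."""
    cfg = cfg or ContrastiveConfig()
    emb, is_tensor = _as_tensor_pair(embeddings)
    n = emb.shape[0]
    i, j = np.triu_indices(n, k=1)
    g = assign_pair_sign(np.asarray(labels)[i], np.asarray(labels)[j]) if n > 1 else np.array([])
    out = _contrastive(emb, i, j, g, cfg)
    return out if is_tensor else float(out.data)


def mirror_set_loss(embeddings_me, labels_me, embeddings_oe, labels_oe,
                    cfg: ContrastiveConfig | None = None):
    """L_m: hinge over every (mirror, original) combination.

    Mirror labels must already be the swapped ones; a trial paired with
    its own mirror is therefore always a negative pair.
    """
    cfg = cfg or ContrastiveConfig()
    emb_m, is_tensor = _as_tensor_pair(embeddings_me)
    emb_o, _ = _as_tensor_pair(embeddings_oe)
    from .autodiff import concat

    m, n = emb_m.shape[0], emb_o.shape[0]
    if m == 0 or n == 0:
        return Tensor(np.zeros(())) if is_tensor else 0.0
    emb = concat([emb_o, emb_m], axis=0)
    im, jo = np.meshgrid(np.arange(m) + n, np.arange(n), indexing="ij")
    labels_all = np.concatenate([np.asarray(labels_oe), np.asarray(labels_me)])
    g = assign_pair_sign(labels_all[im.ravel()], labels_all[jo.ravel()])
    out = _contrastive(emb, im.ravel(), jo.ravel(), g, cfg)
    return out if is_tensor else float(out.data)


def cross_entropy(probs, labels, floor: float = 1e-12):
    """L_c = -(1/N) sum_i ln p_i[true class] (log clamped at ``floor``)."""
    p, is_tensor = _as_tensor_pair(probs)
    labels = np.asarray(labels, dtype=int)
    onehot = np.zeros(p.shape, dtype=p.data.dtype)
    onehot[np.arange(len(labels)), labels] = 1.0
    out = -((p * onehot).sum(axis=1).log(floor=floor).mean())
    return out if is_tensor else float(out.data)


def total_loss(probs, labels, embeddings, pairset: PairSet,
               cfg: ContrastiveConfig | None = None, ce_floor: float = 1e-12):
    """Combined objective over a mirror-augmented batch.

    ``probs``/``labels``/``embeddings`` cover the full 2n batch
    (originals first, mirror labels swapped); ``pairset`` indexes into
    it. Returns (L, L_c, L_o, L_m); the ablation flags zero the
    corresponding contrastive terms.
    """
    cfg = cfg or ContrastiveConfig()
    p, is_tensor = _as_tensor_pair(probs)
    emb, _ = _as_tensor_pair(embeddings)
    L_c = cross_entropy(p, labels, floor=ce_floor)
    zero = Tensor(np.zeros((), dtype=emb.data.dtype))
    oo = pairset.origin == "oo"
    mo = pairset.origin == "mo"
    L_o = (
        _contrastive(emb, pairset.i[oo], pairset.j[oo], pairset.g[oo], cfg)
        if cfg.enable_Lo else zero
    )
    L_m = (
        _contrastive(emb, pairset.i[mo], pairset.j[mo], pairset.g[mo], cfg)
        if cfg.enable_Lm else zero
    )
    L = L_c + cfg.w_o * L_o + cfg.w_m * L_m
    if is_tensor:
        return L, L_c, L_o, L_m
    return float(L.data), float(L_c.data), float(L_o.data), float(L_m.data)
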