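"""Inference-time mirror fusion and evaluation metrics.

Mirror fusion averages a trial's predicted probabilities with the
class-swapped probabilities of its hemisphere-mirrored copy::

    p_left  = (p_left^o  + p_right^m) / 2
    p_right = (p_right^o + p_left^m) / 2

which enforces, exactly and for any weights, the symmetry
``fused(mirror(X)) = swap(fused(X))``.

Epoch-level summaries follow the three accuracy conventions used for
noisy test curves: the maximum over epochs, the mean over the final
window (default 100 epochs), and the accuracy at the epoch of minimum
training loss.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import cohen_kappa_score, confusion_matrix

from .montage import EEGTrial, MirrorMap, mirror_trial

__all__ = [
    "fused_predict",
    "score_predictions",
    "MetricSummary",
    "epoch_metric_summary",
    "paired_one_sided_ttest",
]


def fused_predict(model, trials, mirror_map: MirrorMap) -> np.ndarray:
    """Mirror-fusion probabilities for one trial or a list of trials.

    Returns an (n, 2) array of [p_left, p_right]; argmax ties break
    toward class 0 (left).
    """
    single = isinstance(trials, EEGTrial)
    if single:
        trials = [trials]
    if trials and trials[0].n_channels != mirror_map.n_channels:
        raise ValueError("montage of trials does not match the mirror map")
    mirrored = [mirror_trial(t, mirror_map) for t in trials]
    p_o = model.predict_proba(trials)
    p_m = model.predict_proba(mirrored)
    fused = (p_o + p_m[:, ::-1]) / 2.0
    return fused[0] if single else fused


@dataclass
class MetricSummary:
    max_accuracy: float
    average_accuracy: float  # mean over the final window
    accuracy_at_min_train_loss: float
    max_kappa: float
    average_kappa: float
    kappa_at_min_train_loss: float


def score_predictions(predicted, true) -> tuple[float, float, np.ndarray]:
    """Accuracy, Cohen's kappa and the 2x2 confusion matrix.

    Confusion rows are true classes, columns predicted classes.
    """
    predicted = np.asarray(predicted, dtype=int)
    true = np.asarray(true, dtype=int)
    if len(predicted) != len(true) or len(true) == 0:
        raise ValueError("predictions and labels must be equal-length and non-empty")
    cm = confusion_matrix(true, predicted, labels=[0, 1])
    accuracy = float(np.trace(cm)) / float(cm.sum())
    kappa = float(cohen_kappa_score(true, predicted, labels=[0, 1]))
    if np.isnan(kappa):  # degenerate single-class marginals
        kappa = 0.0
    return accuracy, kappa, cm


def epoch_metric_summary(history, window: int = 100) -> MetricSummary:
    """Summarize a per-epoch test curve.

    ``history`` needs ``test_accuracy``, ``test_kappa`` and
    ``train_loss`` sequences (an :class:`~mclswt.training.EpochHistory`
    works). Ties in the minimum training loss resolve to the earliest
    epoch; histories shorter than ``window`` are averaged over their
    full length with a warning.
    """
    acc = np.asarray(history.test_accuracy, dtype=float)
    kap = np.asarray(history.test_kappa, dtype=float)
    loss = np.asarray(history.train_loss, dtype=float)
    if len(acc) == 0:
        raise ValueError("empty history")
    if len(acc) < window:
        warnings.warn(
            f"history has {len(acc)} epochs < window {window}; averaging over all epochs",
            stacklevel=2,
        )
        window = len(acc)
    best = int(np.argmin(loss))
    return MetricSummary(
        max_accuracy=float(acc.max()),
        average_accuracy=float(acc[-window:].mean()),
        accuracy_at_min_train_loss=float(acc[best]),
        max_kappa=float(kap.max()),
        average_kappa=float(kap[-window:].mean()),
        kappa_at_min_train_loss=float(kap[best]),
    )


def paired_one_sided_ttest(accuracies_a, accuracies_b) -> tuple[float, float]:
    """Paired one-sided t-test of mean(a) > mean(b).

    Returns (t, p) with the upper-tail p from the t distribution with
    n-1 degrees of freedom. Zero-variance differences are handled
    explicitly: p = 0 if the mean difference is positive, 1 if
    negative, 0.5 if all differences are zero (with a warning).
    """
    a = np.asarray(accuracies_a, dtype=float)
    b = np.asarray(accuracies_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length vectors with n >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        warnings.warn("zero-variance differences in paired t-test", stacklevel=2)
        m = d.mean()
        if m > 0:
            return np.inf, 0.0
        if m < 0:
            return -np.inf, 1.0
        return 0.0, 0.5
    res = stats.ttest_rel(a, b, alternative="greater")
    return float(res.statistic), float(res.pvalue)
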