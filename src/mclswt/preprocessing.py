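"""Minimal EEG preprocessing chain for motor-imagery decoding.

The chain, applied to a continuous multichannel recording, is:

1. unit conversion to microvolts,
2. third-order zero-phase Butterworth band-pass along time
   (4–38 Hz or 0–38 Hz, the latter degenerating to a pure low-pass),
3. per-channel exponential moving standardization
   (factor_new=0.001, init_block_size=1000, eps=1e-4),
4. polyphase resampling to the target rate (250 Hz),
5. cue-locked epoching into trials of exactly
   round((epoch_end - epoch_start) * fs) samples
   (default -0.5 s .. +3.98 s around the cue: 1120 samples at 250 Hz).

Each stage is per-channel and leaves the channel order unchanged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .montage import EEGTrial

__all__ = [
    "ContinuousRecording",
    "PreprocConfig",
    "convert_to_microvolts",
    "bandpass_filter",
    "exponential_moving_standardize",
    "resample_recording",
    "extract_epochs",
    "preprocess_recording",
]

logger = logging.getLogger(__name__)


@dataclass
class ContinuousRecording:
    """A continuous EEG recording with cue annotations.

    ``cue_samples`` are 0-based sample indices of cue onsets, strictly
    increasing; ``cue_labels`` the corresponding class labels.
    """

    signal: np.ndarray  # (N, C)
    fs: float
    cue_samples: np.ndarray
    cue_labels: np.ndarray
    channel_names: list[str]
    subject_id: str = "unknown"

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        self.cue_samples = np.asarray(self.cue_samples, dtype=int)
        self.cue_labels = np.asarray(self.cue_labels, dtype=int)
        if self.signal.ndim != 2:
            raise ValueError("signal must be (samples, channels)")
        if len(self.cue_samples) != len(self.cue_labels):
            raise ValueError("cue_samples and cue_labels must have equal length")
        if np.any(np.diff(self.cue_samples) <= 0):
            raise ValueError("cue sample indices must be strictly increasing")


@dataclass
class PreprocConfig:
    """Parameters of the preprocessing chain (defaults: 250 Hz pipeline)."""

    band_low: float = 4.0  # Hz; 0 -> pure low-pass
    band_high: float = 38.0  # Hz
    filter_order: int = 3
    factor_new: float = 0.001
    init_block_size: int = 1000
    eps: float = 1e-4
    target_fs: float = 250.0
    epoch_start: float = -0.5  # s relative to cue
    epoch_end: float = 3.98  # s relative to cue
    input_unit: str = "microvolt"
    #: 'continuous' standardizes the continuous signal (default);
    #: 'epoch' applies the same recurrence per extracted epoch instead.
    standardize_stage: str = "continuous"

    def __post_init__(self):
        if not (0 <= self.band_low < self.band_high):
            raise ValueError("need 0 <= band_low < band_high")
        if self.band_high >= self.target_fs / 2:
            raise ValueError("band_high must be below the target Nyquist rate")
        n = (self.epoch_end - self.epoch_start) * self.target_fs
        if round(n) <= 0:
            raise ValueError("epoch window is empty")

    @property
    def epoch_n_samples(self) -> int:
        return int(round((self.epoch_end - self.epoch_start) * self.target_fs))


def convert_to_microvolts(signal: np.ndarray, input_unit: str) -> np.ndarray:
    """Scale a signal to microvolts (x1e6 iff given in volts)."""
    unit = input_unit.strip().lower().rstrip("s")
    if unit in ("volt", "v"):
        return np.asarray(signal, dtype=float) * 1e6
    if unit in ("microvolt", "uv", "µv"):
        return np.asarray(signal, dtype=float).copy()
    raise ValueError(f"unknown unit {input_unit!r}; expected 'volt' or 'microvolt'")


def design_bandpass(low: float, high: float, fs: float, order: int = 3) -> np.ndarray:
    """Second-order sections of the Butterworth (band|low)-pass filter."""
    nyq = fs / 2.0
    if high >= nyq:
        raise ValueError(f"band edge {high} Hz is not below Nyquist ({nyq} Hz)")
    if low <= 0:
        return sps.butter(order, high / nyq, btype="lowpass", output="sos")
    return sps.butter(order, [low / nyq, high / nyq], btype="bandpass", output="sos")


def bandpass_filter(
    signal: np.ndarray, fs: float, low: float, high: float, order: int = 3
) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth filtering along time.

    ``low=0`` degenerates to a pure low-pass at ``high``. The effective
    magnitude response is the squared single-pass response.
    """
    sos = design_bandpass(low, high, fs, order)
    return sps.sosfiltfilt(sos, np.asarray(signal, dtype=float), axis=0)


def exponential_moving_standardize(
    signal: np.ndarray,
    factor_new: float = 0.001,
    init_block_size: int = 1000,
    eps: float = 1e-4,
) -> np.ndarray:
    """Per-channel exponential moving standardization.

    Running statistics, per channel, with f = ``factor_new``::

        m_t = (1 - f) m_{t-1} + f x_t        (m init: x_0)
        v_t = (1 - f) v_{t-1} + f (x_t - m_t)^2   (v init: 0)
        y_t = (x_t - m_t) / max(sqrt(v_t), eps)

    The first ``init_block_size`` samples are instead standardized by
    that block's own mean and standard deviation (std clipped at
    ``eps``), which stabilizes the burn-in of the recurrence. The
    output is causal after the init block: appending samples never
    changes earlier outputs.
    """
    if factor_new <= 0 or eps <= 0:
        raise ValueError("factor_new and eps must be positive")
    x = np.atleast_2d(np.asarray(signal, dtype=float))
    squeeze = np.asarray(signal).ndim == 1
    if squeeze:
        x = x.T
    n, _ = x.shape
    if n < 1:
        raise ValueError("signal must contain at least one sample")
    f = factor_new
    out = np.empty_like(x)
    m = x[0].copy()
    v = np.zeros_like(m)
    for t in range(n):
        m = (1 - f) * m + f * x[t]
        d = x[t] - m
        v = (1 - f) * v + f * d * d
        out[t] = d / np.maximum(np.sqrt(v), eps)
    ib = min(init_block_size, n)
    if ib > 0:
        block = x[:ib]
        mu = block.mean(axis=0)
        sd = np.maximum(block.std(axis=0), eps)
        out[:ib] = (block - mu) / sd
    return out[:, 0] if squeeze else out


def resample_recording(rec: ContinuousRecording, target_fs: float) -> ContinuousRecording:
    """Polyphase rational resampling to ``target_fs`` (cues rescaled)."""
    if rec.fs == target_fs:
        return rec
    frac = Fraction(target_fs / rec.fs).limit_denominator(1000)
    resampled = sps.resample_poly(rec.signal, frac.numerator, frac.denominator, axis=0)
    cues = np.round(rec.cue_samples * (target_fs / rec.fs)).astype(int)
    return ContinuousRecording(
        signal=resampled,
        fs=target_fs,
        cue_samples=cues,
        cue_labels=rec.cue_labels.copy(),
        channel_names=list(rec.channel_names),
        subject_id=rec.subject_id,
    )


def extract_epochs(rec: ContinuousRecording, cfg: PreprocConfig) -> list[EEGTrial]:
    """Slice cue-locked epochs out of a (resampled) recording.

    Each epoch is the half-open sample range
    ``[cue + round(epoch_start*fs), cue + round(epoch_start*fs) + n)``
    with ``n = round((epoch_end - epoch_start) * fs)``. Cues whose
    window exceeds the recording bounds are skipped with a warning.
    """
    if rec.fs != cfg.target_fs:
        rec = resample_recording(rec, cfg.target_fs)
    fs = rec.fs
    n = cfg.epoch_n_samples
    offset = int(round(cfg.epoch_start * fs))
    trials = []
    for cue, label in zip(rec.cue_samples, rec.cue_labels):
        start = int(cue) + offset
        stop = start + n
        if start < 0 or stop > rec.signal.shape[0]:
            logger.warning(
                "skipping cue at sample %d: epoch [%d, %d) out of bounds", cue, start, stop
            )
            continue
        sig = rec.signal[start:stop].copy()
        if cfg.standardize_stage == "epoch":
            sig = exponential_moving_standardize(
                sig, cfg.factor_new, cfg.init_block_size, cfg.eps
            )
        trials.append(
            EEGTrial(
                signal=sig,
                label=int(label),
                subject_id=rec.subject_id,
                fs=fs,
                channel_names=list(rec.channel_names),
            )
        )
    return trials


def preprocess_recording(rec: ContinuousRecording, cfg: PreprocConfig) -> list[EEGTrial]:
    """Full chain: units -> bandpass -> standardize -> resample -> epoch."""
    sig = convert_to_microvolts(rec.signal, cfg.input_unit)
    sig = bandpass_filter(sig, rec.fs, cfg.band_low, cfg.band_high, cfg.filter_order)
    if cfg.standardize_stage == "continuous":
        sig = exponential_moving_standardize(
            sig, cfg.factor_new, cfg.init_block_size, cfg.eps
        )
    elif cfg.standardize_stage != "epoch":
        raise ValueError("standardize_stage must be 'continuous' or 'epoch'")
    rec2 = ContinuousRecording(
        signal=sig,
        fs=rec.fs,
        cue_samples=rec.cue_samples.copy(),
        cue_labels=rec.cue_labels.copy(),
        channel_names=list(rec.channel_names),
        subject_id=rec.subject_id,
    )
    rec2 = resample_recording(rec2, cfg.target_fs)
    return extract_epochs(rec2, cfg)
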