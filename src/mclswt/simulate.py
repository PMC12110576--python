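"""Synthetic motor-imagery EEG with contralateral ERD / ipsilateral ERS.

Each channel is the sum of a mu-band (~10 Hz) sinusoid with random
phase and 1/f^gamma Gaussian background noise. After the cue, the
channel *contralateral* to the imagined hand has its mu amplitude
multiplied by (1 - d) (event-related desynchronization) and the
ipsilateral channel by (1 + e) (event-related synchronization); the
midline channel (Cz) is unmodulated. Per-subject parameters (mu
frequency/amplitude, ERD depth, noise level) are jittered once per
subject, emulating inter-subject variability — the obstacle that
subject-independent decoding has to overcome.

Because d scales *amplitude*, band power after the cue is
(1 - d)^2 times baseline, so the expected ERD percentage has the
closed form 100 * ((1 - d)^2 - 1) — e.g. d = 0.5 gives -75%. This is
the oracle used to validate both the generator and the ERD
quantification.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .montage import LEFT, RIGHT, EEGTrial, mirror_label

__all__ = [
    "SimConfig",
    "SubjectParams",
    "ERDProfile",
    "simulate_trial",
    "simulate_dataset",
    "draw_subject_params",
    "erd_percentage",
]


@dataclass
class SimConfig:
    """Simulator parameters (defaults emulate a 3-channel, 250 Hz rig)."""

    fs: float = 250.0
    channel_names: tuple[str, ...] = ("C3", "Cz", "C4")
    trial_duration: float = 4.48  # s -> 1120 samples at 250 Hz
    cue_onset: float = 0.5  # s into the trial
    mu_freq: float = 10.0  # Hz
    mu_freq_jitter: float = 1.0  # Hz, uniform per-subject jitter
    mu_amp: float = 10.0  # microvolts (sinusoid amplitude)
    erd_depth: float = 0.5  # d: fractional contralateral amplitude drop
    ers_gain: float = 0.2  # e: fractional ipsilateral amplitude gain
    noise_exponent: float = 1.0  # gamma of the 1/f^gamma background
    noise_amp: float = 8.0  # microvolts RMS of the background noise
    subject_sigma: float = 0.1  # relative std of per-subject jitter
    ramp: bool = True  # raised-cosine onset of the modulation
    ramp_duration: float = 0.2  # s
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.erd_depth <= 1.0):
            raise ValueError("erd_depth must lie in [0, 1]")
        if self.ers_gain < 0:
            raise ValueError("ers_gain must be >= 0")
        n = self.fs * self.trial_duration
        if abs(n - round(n)) > 1e-9:
            raise ValueError("fs * trial_duration must be an integer sample count")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.trial_duration))


@dataclass
class SubjectParams:
    """Realized per-subject parameters."""

    subject_id: str
    mu_freq: float
    mu_amp: float
    erd_depth: float
    ers_gain: float
    noise_amp: float


@dataclass
class ERDProfile:
    """Mean ERD% per channel and 300 ms post-cue epoch (trial-averaged)."""

    erd: np.ndarray  # (C, n_epochs), percent; negative = desynchronization
    channel_names: list[str]
    epoch_starts: np.ndarray  # s relative to cue

    def channel(self, name: str) -> np.ndarray:
        return self.erd[self.channel_names.index(name)]


def _pink_noise(n: int, fs: float, gamma: float, rms: float, rng: np.random.Generator):
    """1/f^gamma noise by spectral shaping of white Gaussian noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    shape = np.zeros_like(f)
    shape[1:] = f[1:] ** (-gamma / 2.0)
    x = np.fft.irfft(spec * shape, n)
    sd = x.std()
    if sd > 0 and rms > 0:
        x *= rms / sd
    else:
        x[:] = 0.0
    return x


def _modulation(n: int, cue_idx: int, factor: float, ramp_n: int) -> np.ndarray:
    """Amplitude envelope: 1 before the cue, ``factor`` after (ramped)."""
    env = np.ones(n)
    if factor == 1.0 or cue_idx >= n:
        return env
    post = np.arange(n - cue_idx)
    if ramp_n > 0:
        r = np.minimum(post / ramp_n, 1.0)
        r = 0.5 * (1.0 - np.cos(np.pi * r))  # raised cosine 0 -> 1
    else:
        r = np.ones_like(post, dtype=float)
    env[cue_idx:] = 1.0 + (factor - 1.0) * r
    return env


def draw_subject_params(
    subject_id: str, cfg: SimConfig, rng: np.random.Generator
) -> SubjectParams:
    """Draw one subject's parameters (jitter scale ``cfg.subject_sigma``)."""
    s = cfg.subject_sigma

    def jitter(x):
        return float(x * max(1.0 + s * rng.standard_normal(), 0.05)) if s > 0 else float(x)

    mu_freq = cfg.mu_freq + (rng.uniform(-cfg.mu_freq_jitter, cfg.mu_freq_jitter) if s > 0 else 0.0)
    return SubjectParams(
        subject_id=subject_id,
        mu_freq=float(mu_freq),
        mu_amp=jitter(cfg.mu_amp),
        erd_depth=float(np.clip(jitter(cfg.erd_depth), 0.0, 1.0)),
        ers_gain=jitter(cfg.ers_gain),
        noise_amp=jitter(cfg.noise_amp),
    )


def simulate_trial(
    label: int,
    params: SubjectParams,
    cfg: SimConfig,
    seed: int | np.random.Generator,
) -> EEGTrial:
    """Simulate one trial; identical (seed, params, cfg) give identical data.

    For a *left*-hand label the contralateral (right-hemisphere, e.g.
    C4) channel gets the ERD and the ipsilateral (C3) channel the ERS;
    reversed for right-hand labels.
    """
    if label not in (LEFT, RIGHT):
        raise ValueError("label must be LEFT (0) or RIGHT (1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = cfg.n_samples
    cue_idx = int(round(cfg.cue_onset * cfg.fs))
    ramp_n = int(round(cfg.ramp_duration * cfg.fs)) if cfg.ramp else 0
    t = np.arange(n) / cfg.fs

    factors = {}
    for name in cfg.channel_names:
        if mirror_label(name) == name:  # midline: unmodulated
            factors[name] = 1.0
        else:
            digit = int(name[-1])
            is_left_hemisphere = digit % 2 == 1
            contralateral = (label == LEFT and not is_left_hemisphere) or (
                label == RIGHT and is_left_hemisphere
            )
            factors[name] = (
                1.0 - params.erd_depth if contralateral else 1.0 + params.ers_gain
            )

    sig = np.empty((n, len(cfg.channel_names)))
    for c, name in enumerate(cfg.channel_names):
        phase = rng.uniform(0.0, 2.0 * np.pi)
        mu = params.mu_amp * np.sin(2.0 * np.pi * params.mu_freq * t + phase)
        env = _modulation(n, cue_idx, factors[name], ramp_n)
        noise = _pink_noise(n, cfg.fs, cfg.noise_exponent, params.noise_amp, rng)
        sig[:, c] = env * mu + noise

    return EEGTrial(
        signal=sig,
        label=int(label),
        subject_id=params.subject_id,
        fs=cfg.fs,
        channel_names=list(cfg.channel_names),
    )


def simulate_dataset(
    n_subjects: int,
    trials_per_subject: int,
    cfg: SimConfig | None = None,
    seed: int | None = None,
) -> list[EEGTrial]:
    """Simulate a balanced multi-subject dataset.

    Per-subject parameters are drawn once; each subject contributes
    ``trials_per_subject`` trials with alternating left/right labels
    (balanced up to one trial when the count is odd).
    """
    cfg = cfg or SimConfig()
    if n_subjects < 1 or trials_per_subject < 1:
        raise ValueError("counts must be >= 1")
    root = np.random.default_rng(cfg.seed if seed is None else seed)
    trials: list[EEGTrial] = []
    for s in range(n_subjects):
        params = draw_subject_params(f"S{s + 1:02d}", cfg, root)
        labels = np.tile([LEFT, RIGHT], (trials_per_subject + 1) // 2)[:trials_per_subject]
        labels = root.permutation(labels)
        for lab in labels:
            trials.append(simulate_trial(int(lab), params, cfg, root))
    return trials


def _band_power(x: np.ndarray, fs: float, band: tuple[float, float]) -> float:
    """Integrated band power of a 1-D window (boxcar periodogram)."""
    f, pxx = sps.periodogram(x, fs=fs, window="boxcar", detrend=False)
    df = f[1] - f[0]
    mask = (f >= band[0]) & (f <= band[1])
    return float(pxx[mask].sum() * df)


def erd_percentage(
    trials: list[EEGTrial],
    cue_onset: float = 0.5,
    band: tuple[float, float] = (8.0, 13.0),
    baseline_window: tuple[float, float] = (-0.5, -0.1),
    post_window: tuple[float, float] = (0.0, 1.5),
    epoch_len: float = 0.3,
) -> ERDProfile:
    """Quantify ERD%: band power change relative to the pre-cue baseline.

    Baseline mu power is taken from ``baseline_window`` (seconds
    relative to the cue); the post-cue interval is split into
    non-overlapping ``epoch_len`` epochs. Per trial and channel,
    ERD% = 100 * (P_post - P_baseline) / P_baseline; the profile is the
    mean over trials. Negative values indicate desynchronization.
    """
    if not trials:
        raise ValueError("no trials given")
    fs = trials[0].fs
    n = trials[0].n_samples
    cue = int(round(cue_onset * fs))
    b0 = cue + int(round(baseline_window[0] * fs))
    b1 = cue + int(round(baseline_window[1] * fs))
    n_ep = int(round((post_window[1] - post_window[0]) / epoch_len))
    ep_n = int(round(epoch_len * fs))
    starts = [cue + int(round(post_window[0] * fs)) + k * ep_n for k in range(n_ep)]
    if b0 < 0 or b1 <= b0 or starts[-1] + ep_n > n:
        raise ValueError("analysis windows fall outside the trial")
    C = trials[0].n_channels
    acc = np.zeros((C, n_ep))
    for tr in trials:
        for c in range(C):
            p_base = _band_power(tr.signal[b0:b1, c], fs, band)
            for k, s0 in enumerate(starts):
                p_post = _band_power(tr.signal[s0 : s0 + ep_n, c], fs, band)
                acc[c, k] += 100.0 * (p_post - p_base) / p_base
    acc /= len(trials)
    return ERDProfile(
        erd=acc,
        channel_names=list(trials[0].channel_names),
        epoch_starts=np.array([post_window[0] + k * epoch_len for k in range(n_ep)]),
    )
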