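"""Left/right electrode mirroring for 10–20 montages.

Motor imagery of the left vs right hand produces event-related
desynchronization (ERD) in the *contralateral* sensorimotor cortex. A
"mirror" trial swaps the data recorded over the two hemispheres
(C3<->C4 and so on, midline channels fixed) and flips the class label,
producing a physically plausible trial of the opposite class. Mirror
trials double the training set and provide guaranteed negative pairs
for the mirror contrastive loss.

The mirror moves *data* between fixed electrode positions: the channel
name list of a mirrored trial is unchanged; only the signal columns
(and the label) are permuted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "LEFT",
    "RIGHT",
    "EEGTrial",
    "MirrorMap",
    "MontageError",
    "build_mirror_map",
    "mirror_trial",
    "make_mirror_batch",
]

#: Class encoding used throughout the package.
LEFT, RIGHT = 0, 1

_LABEL_RE = re.compile(r"^([A-Za-z]+?)(z|\d+)$", re.IGNORECASE)


class MontageError(ValueError):
    """A montage cannot be mirrored (missing partner / bad label)."""


@dataclass
class EEGTrial:
    """One epoched EEG trial.

    Attributes
    ----------
    signal : ndarray, shape (T, C)
        Samples x channels, in microvolts.
    label : int
        ``LEFT`` (0) or ``RIGHT`` (1) hand motor imagery.
    subject_id : str
        Identifier of the recorded subject.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
        Ordered 10-20 electrode labels, length C.
    is_mirror : bool
        True if this trial was produced by hemispheric mirroring.
    """

    signal: np.ndarray
    label: int
    subject_id: str
    fs: float
    channel_names: list[str] = field(default_factory=lambda: ["C3", "Cz", "C4"])
    is_mirror: bool = False

    def __post_init__(self):
        self.signal = np.asarray(self.signal)
        if self.signal.ndim != 2:
            raise ValueError("signal must be a 2-D (samples x channels) array")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite values")
        if len(self.channel_names) != self.signal.shape[1]:
            raise ValueError(
                f"channel_names has length {len(self.channel_names)} but signal "
                f"has {self.signal.shape[1]} channels"
            )
        if self.label not in (LEFT, RIGHT):
            raise ValueError(f"label must be {LEFT} (left) or {RIGHT} (right), got {self.label}")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    @property
    def n_channels(self) -> int:
        return self.signal.shape[1]


@dataclass(frozen=True)
class MirrorMap:
    """Involutive channel permutation pairing left/right electrodes.

    ``channel_permutation[i] = j`` means the mirrored trial's channel
    ``i`` carries the data of original channel ``j``. Midline
    ('z'-suffixed) channels are fixed points. The label permutation
    swaps left and right.
    """

    channel_permutation: tuple[int, ...]

    def __post_init__(self):
        perm = np.asarray(self.channel_permutation)
        if not np.array_equal(perm[perm], np.arange(len(perm))):
            raise ValueError("channel_permutation is not an involution")

    @property
    def n_channels(self) -> int:
        return len(self.channel_permutation)

    @staticmethod
    def swap_label(label: int) -> int:
        return RIGHT if label == LEFT else LEFT


def _parse_label(name: str) -> tuple[str, str]:
    m = _LABEL_RE.match(name.strip())
    if m is None:
        raise MontageError(f"channel label {name!r} is not a 10-20 label")
    return m.group(1), m.group(2)


def mirror_label(name: str) -> str:
    """Return the contralateral partner of a 10-20 label (self if midline).

    Odd digits are left hemisphere, even digits right; the partner keeps
    the letter prefix and moves the digit by one (C3<->C4, C1<->C2,
    P7<->P8). 'z'-suffixed midline labels map to themselves.
    """
    prefix, suffix = _parse_label(name)
    if suffix.lower() == "z":
        return name
    digit = int(suffix)
    partner = digit + 1 if digit % 2 == 1 else digit - 1
    return f"{prefix}{partner}"


def build_mirror_map(channel_names: list[str]) -> MirrorMap:
    """Build the left<->right channel pairing for a 10-20 montage.

    Raises
    ------
    MontageError
        If a lateral channel's contralateral partner is absent from the
        montage (naming the offending channel).
    """
    lookup = {name.strip().lower(): i for i, name in enumerate(channel_names)}
    perm = []
    for name in channel_names:
        partner = mirror_label(name)
        j = lookup.get(partner.strip().lower())
        if j is None:
            raise MontageError(
                f"channel {name!r} has no contralateral partner {partner!r} in the montage"
            )
        perm.append(j)
    return MirrorMap(tuple(perm))


def mirror_trial(trial: EEGTrial, mirror_map: MirrorMap) -> EEGTrial:
    """Construct the mirror of a trial: data columns permuted, label swapped.

    Bit-exact on the signal values; applying it twice restores the
    original trial exactly.
    """
    if trial.n_channels != mirror_map.n_channels:
        raise ValueError(
            f"trial has {trial.n_channels} channels but mirror map covers "
            f"{mirror_map.n_channels}"
        )
    perm = list(mirror_map.channel_permutation)
    return replace(
        trial,
        signal=trial.signal[:, perm].copy(),
        label=MirrorMap.swap_label(trial.label),
        channel_names=list(trial.channel_names),
        is_mirror=not trial.is_mirror,
    )


def make_mirror_batch(
    batch: list[EEGTrial], mirror_map: MirrorMap
) -> tuple[list[EEGTrial], np.ndarray]:
    """Augment a batch with its mirrors: originals first, mirrors after.

    Returns the 2n-trial batch and the pairing index array linking
    original ``i`` to its mirror at position ``pairing[i]`` (= n + i).
    """
    n = len(batch)
    if n == 0:
        return [], np.zeros(0, dtype=int)
    names = batch[0].channel_names
    for t in batch:
        if list(t.channel_names) != list(names):
            raise ValueError("all trials in a batch must share the montage")
    mirrored = [mirror_trial(t, mirror_map) for t in batch]
    pairing = np.arange(n, 2 * n)
    return list(batch) + mirrored, pairing
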