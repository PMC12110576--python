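"""Trial and recording serialization (NPZ / HDF5) and biosignal readers.

Epoched trials are stored with the keys
``signal`` (n_trials, T, C), ``label``, ``subject``, ``fs``,
``channels`` and ``is_mirror`` — the same schema whether the trials
come from the preprocessing chain or the simulator.
"""

from __future__ import annotations

import numpy as np

from .montage import EEGTrial
from .preprocessing import ContinuousRecording

__all__ = [
    "save_trials_npz",
    "load_trials_npz",
    "save_trials_hdf5",
    "load_trials_hdf5",
    "read_gdf_recording",
]


def _stack(trials: list[EEGTrial]) -> dict:
    if not trials:
        raise ValueError("cannot serialize an empty trial list")
    return dict(
        signal=np.stack([t.signal for t in trials]),
        label=np.array([t.label for t in trials], dtype=int),
        subject=np.array([str(t.subject_id) for t in trials]),
        fs=np.array([t.fs for t in trials]),
        channels=np.array([str(c) for c in trials[0].channel_names]),
        is_mirror=np.array([t.is_mirror for t in trials], dtype=bool),
    )


def _unstack(d: dict) -> list[EEGTrial]:
    channels = [str(c) for c in np.asarray(d["channels"]).tolist()]
    return [
        EEGTrial(
            signal=np.asarray(d["signal"][i], dtype=float),
            label=int(d["label"][i]),
            subject_id=str(np.asarray(d["subject"])[i]),
            fs=float(d["fs"][i]),
            channel_names=list(channels),
            is_mirror=bool(d["is_mirror"][i]),
        )
        for i in range(len(d["label"]))
    ]


def save_trials_npz(path, trials: list[EEGTrial]) -> None:
    np.savez(path, **_stack(trials))


def load_trials_npz(path) -> list[EEGTrial]:
    with np.load(path, allow_pickle=False) as d:
        return _unstack({k: d[k] for k in d.files})


def save_trials_hdf5(path, trials: list[EEGTrial]) -> None:
    import h5py

    data = _stack(trials)
    with h5py.File(path, "w") as f:
        for k, v in data.items():
            if v.dtype.kind == "U":
                v = v.astype("S")
            f.create_dataset(k, data=v)


def load_trials_hdf5(path) -> list[EEGTrial]:
    import h5py

    with h5py.File(path, "r") as f:
        d = {k: f[k][()] for k in f.keys()}
    for k in ("subject", "channels"):
        d[k] = np.array([s.decode() if isinstance(s, bytes) else str(s) for s in d[k]])
    return _unstack(d)


def read_gdf_recording(
    path,
    event_id: dict[str, int],
    channels: list[str] = ("C3", "Cz", "C4"),
    subject_id: str = "unknown",
) -> ContinuousRecording:
    """Read a GDF/EDF file into a :class:`ContinuousRecording` (requires mne).

    ``event_id`` maps annotation descriptions to class labels, e.g.
    ``{"769": 0, "770": 1}`` for the BCI Competition IV left/right cues.
    Values are returned in the file's native unit (mne loads EEG in
    volts; pass ``input_unit='volt'`` to the preprocessing config).
    """
    try:
        import mne
    except ImportError as e:  # pragma: no cover - optional dependency
        raise ImportError("reading GDF/EDF files requires the 'mne' package") from e

    reader = mne.io.read_raw_edf if str(path).lower().endswith(".edf") else mne.io.read_raw_gdf
    raw = reader(path, preload=True, verbose="error")
    picks = [raw.ch_names.index(c) for c in channels]
    sig = raw.get_data(picks=picks).T  # (N, C), volts
    events, mapping = mne.events_from_annotations(raw, verbose="error")
    wanted = {mapping[k]: v for k, v in event_id.items() if k in mapping}
    cues, labels = [], []
    for sample, _, code in events:
        if code in wanted:
            cues.append(int(sample))
            labels.append(int(wanted[code]))
    return ContinuousRecording(
        signal=sig,
        fs=float(raw.info["sfreq"]),
        cue_samples=np.asarray(cues),
        cue_labels=np.asarray(labels),
        channel_names=list(channels),
        subject_id=subject_id,
    )
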