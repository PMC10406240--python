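"""Multi-trial EEG epoch container and I/O.

Epochs are stored as a 3-D array (trials x channels x samples) together with
the sampling rate and unique channel labels.  On disk they live in a plain
``.npz`` container holding the data array plus a JSON metadata blob (``fs``,
``channel_labels``) so that files are self-describing.  EDF reading is
delegated to :mod:`mne` when it is installed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["TimeSeriesEpochs", "load_epochs", "save_epochs", "read_edf"]


@dataclass
class TimeSeriesEpochs:
    """Band-unlimited multichannel EEG epochs.

    Parameters
    ----------
    data : ndarray of shape (n_trials, n_channels, n_samples)
        Signal amplitudes, arbitrary units.
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
        Unique label per channel, same order as the channel axis.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(
                f"epoch data must be 3-D (trials, channels, samples); got shape {self.data.shape}"
            )
        n_trials, n_channels, _ = self.data.shape
        if n_trials < 1:
            raise ValueError("need at least one trial")
        if n_channels < 2:
            raise ValueError("need at least two channels")
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not self.channel_labels:
            self.channel_labels = [f"CH{i + 1:03d}" for i in range(n_channels)]
        self.channel_labels = [str(c) for c in self.channel_labels]
        if len(self.channel_labels) != n_channels:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {n_channels} channels"
            )
        if len(set(self.channel_labels)) != n_channels:
            raise ValueError("channel labels must be unique")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def trial_s(self) -> float:
        return self.n_samples / self.fs

    def subset(self, keep: list[str]) -> "TimeSeriesEpochs":
        """Restrict to the channels in ``keep``, reordered to match ``keep``."""
        idx = _label_indices(self.channel_labels, keep)
        return TimeSeriesEpochs(self.data[:, idx, :], self.fs, list(keep))

    def save(self, path) -> None:
        save_epochs(self, path)


def _label_indices(labels: list[str], keep: list[str]) -> list[int]:
    if len(keep) < 2:
        raise ValueError("must keep at least two channels")
    if len(set(keep)) != len(keep):
        raise ValueError("requested channel list contains duplicates")
    pos = {lab: i for i, lab in enumerate(labels)}
    missing = [lab for lab in keep if lab not in pos]
    if missing:
        raise KeyError(f"unknown channel label(s): {missing}")
    return [pos[lab] for lab in keep]


def save_epochs(epochs: TimeSeriesEpochs, path) -> None:
    """Write epochs to ``path`` as an ``.npz`` with a JSON metadata entry."""
    meta = json.dumps({"fs": epochs.fs, "channel_labels": epochs.channel_labels})
    np.savez(path, data=epochs.data, meta=np.array(meta))


def load_epochs(path) -> TimeSeriesEpochs:
    """Read epochs written by :func:`save_epochs`."""
    with np.load(path, allow_pickle=False) as f:
        meta = json.loads(str(f["meta"]))
        return TimeSeriesEpochs(f["data"], meta["fs"], meta["channel_labels"])


def read_edf(path, trial_s: float) -> TimeSeriesEpochs:
    """Read a continuous EDF recording and cut it into fixed-length trials.

    Requires :mod:`mne`.  The recording is split into consecutive
    non-overlapping windows of ``trial_s`` seconds; a trailing partial window
    is discarded.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - mne present in CI image
        raise ImportError("reading EDF files requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    data = raw.get_data()
    n_per = int(round(trial_s * fs))
    if n_per < 2:
        raise ValueError("trial_s too short for the recording's sampling rate")
    n_trials = data.shape[1] // n_per
    if n_trials < 1:
        raise ValueError("recording shorter than one trial")
    trials = data[:, : n_trials * n_per].reshape(data.shape[0], n_trials, n_per)
    return TimeSeriesEpochs(np.transpose(trials, (1, 0, 2)), fs, list(raw.ch_names))
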