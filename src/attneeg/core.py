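"""Core containers: multichannel recordings and fixed-length epochs.

A :class:`Recording` is a dense channels x samples array in microvolts with a
sampling rate and per-channel roles (EEG vs EOG). An :class:`Epoch` is one
3-second window cut from a recording, tagged with its provenance (task trial
or resting block) and, once behavior has been labeled, an attention level.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .channels import channel_role

#: Attention state labels: high / medium / low attention and resting state.
LEVELS = ("HA", "MA", "LA", "RS")


@dataclass
class Recording:
    """Multichannel time series in microvolts.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
    channel_roles : list of str
        ``"EEG"`` or ``"EOG"`` per channel; only EEG-role channels enter ICA
        and feature extraction.
    subject_id : str
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    channel_roles: list[str] = field(default_factory=list)
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("channel_labels length must match data rows")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not self.channel_roles:
            self.channel_roles = [channel_role(c) for c in self.channel_labels]

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def pick(self, labels: Sequence[str]) -> "Recording":
        """Sub-recording restricted to ``labels`` (order preserved)."""
        idx = [self.channel_labels.index(c) for c in labels]
        return Recording(
            data=self.data[idx].copy(),
            fs=self.fs,
            channel_labels=[self.channel_labels[i] for i in idx],
            channel_roles=[self.channel_roles[i] for i in idx],
            subject_id=self.subject_id,
        )

    def eeg(self) -> "Recording":
        labels = [c for c, r in zip(self.channel_labels, self.channel_roles) if r == "EEG"]
        return self.pick(labels)

    def eog(self) -> "Recording":
        labels = [c for c, r in zip(self.channel_labels, self.channel_roles) if r == "EOG"]
        return self.pick(labels)

    def with_data(self, data: np.ndarray) -> "Recording":
        return replace(self, data=np.asarray(data, dtype=np.float64))


@dataclass
class Epoch:
    """One fixed-length channels x samples window cut from a recording."""

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    subject_id: str
    #: ``("task", trial_idx)`` or ``("rest", block_idx)``.
    source: tuple[str, int] = ("task", 0)
    label: Optional[str] = None

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.channel_labels.index(name)]

    @property
    def is_rest(self) -> bool:
        return self.source[0] == "rest"


def save_recording(rec: Recording, path: str | Path) -> Path:
    """Persist a recording as a numeric matrix (.npz) + JSON header sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(path.with_suffix(".npz"), data=rec.data.astype(np.float32))
    header = {
        "fs": rec.fs,
        "channel_labels": rec.channel_labels,
        "channel_roles": rec.channel_roles,
        "subject_id": rec.subject_id,
        "unit": "uV",
    }
    path.with_suffix(".json").write_text(json.dumps(header, indent=1))
    return path.with_suffix(".npz")


def load_recording(path: str | Path) -> Recording:
    path = Path(path)
    header = json.loads(path.with_suffix(".json").read_text())
    data = np.load(path.with_suffix(".npz"))["data"].astype(np.float64)
    return Recording(
        data=data,
        fs=header["fs"],
        channel_labels=list(header["channel_labels"]),
        channel_roles=list(header["channel_roles"]),
        subject_id=header.get("subject_id", ""),
    )


def read_edf(path: str | Path, subject_id: str = "") -> Recording:
    """Read an EDF file into a :class:`Recording` (channel labels verbatim).

    Requires :mod:`mne`. Data are converted from Volts to microvolts.
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    labels = list(raw.ch_names)
    return Recording(
        data=raw.get_data() * 1e6,
        fs=float(raw.info["sfreq"]),
        channel_labels=labels,
        subject_id=subject_id or Path(path).stem,
    )
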