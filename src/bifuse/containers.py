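"""In-memory containers for recordings, epochs and sub-trials.

Conventions: the cue is at t = 0 s; epochs are half-open intervals
``[t_start, t_start + duration)``; sample indices are 0-based; class labels
are the strings ``"left"`` and ``"right"`` everywhere past the I/O boundary.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

LABELS = ("left", "right")

MODALITIES = ("eeg", "nirs-intensity", "nirs-chromophore")

CONTAINER_VERSION = 1


@dataclass
class RawRecording:
    """One participant's continuous multichannel signal of one modality.

    ``data`` is channels x samples.  ``events`` is a list of
    ``(onset_sample, label)`` pairs with label in {"left", "right"}.
    ``pre_cue_s`` / ``post_cue_s`` document how much context is guaranteed
    around every event onset.
    """

    participant_id: str
    modality: str
    channel_names: list[str]
    sample_rate_hz: float
    data: np.ndarray
    events: list[tuple[int, str]] = field(default_factory=list)
    pre_cue_s: float = 0.0
    post_cue_s: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.modality not in MODALITIES:
            raise ValueError(
                f"unknown modality {self.modality!r}; expected one of {MODALITIES}"
            )
        if self.data.ndim != 2:
            raise ValueError(f"data must be channels x samples, got shape {self.data.shape}")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {self.data.shape[0]} data rows"
            )
        n = self.data.shape[1]
        pre = int(round(self.pre_cue_s * self.sample_rate_hz))
        post = int(round(self.post_cue_s * self.sample_rate_hz))
        for onset, label in self.events:
            if label not in LABELS:
                raise ValueError(f"unknown event label {label!r}; expected one of {LABELS}")
            if onset - pre < 0 or onset + post > n:
                raise ValueError(
                    f"event at sample {onset} lacks {self.pre_cue_s} s pre / "
                    f"{self.post_cue_s} s post context within {n} samples"
                )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.sample_rate_hz


@dataclass
class Epoch:
    """A cue-locked windowed segment (channels x samples) with a label."""

    modality: str  # "eeg", "hbo" or "hbr"
    data: np.ndarray
    sample_rate_hz: float
    t_start_s: float
    label: str
    parent_trial_id: str
    participant_id: str = ""
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError(f"epoch data must be channels x samples, got {self.data.shape}")
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}; expected one of {LABELS}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    def replace(self, **kw) -> "Epoch":
        return dataclasses.replace(self, **kw)


@dataclass
class ChromophoreEpoch:
    """Paired HbO / HbR epochs sharing channels, timing and label."""

    hbo: Epoch
    hbr: Epoch

    def __post_init__(self) -> None:
        a, b = self.hbo, self.hbr
        if a.data.shape != b.data.shape:
            raise ValueError(f"HbO/HbR shape mismatch: {a.data.shape} vs {b.data.shape}")
        for attr in ("sample_rate_hz", "t_start_s", "label", "parent_trial_id"):
            if getattr(a, attr) != getattr(b, attr):
                raise ValueError(f"HbO/HbR disagree on {attr}")

    @property
    def label(self) -> str:
        return self.hbo.label

    @property
    def parent_trial_id(self) -> str:
        return self.hbo.parent_trial_id


@dataclass
class SubTrial:
    """A 3-s window cut identically from the EEG epoch and one fNIRS
    chromophore epoch of the same parent trial."""

    eeg: Epoch
    fnirs: Epoch
    parent_trial_id: str
    window_index: int
    window_start_s: float

    def __post_init__(self) -> None:
        if self.eeg.label != self.fnirs.label:
            raise ValueError("EEG and fNIRS sub-trial labels disagree")
        if self.eeg.data.shape != self.fnirs.data.shape:
            raise ValueError(
                f"modality shape mismatch: {self.eeg.data.shape} vs {self.fnirs.data.shape}"
            )

    @property
    def label(self) -> str:
        return self.eeg.label


def write_container(rec: RawRecording, path: str | Path) -> Path:
    """Write a recording as ``<path>.npy`` plus a JSON sidecar ``<path>.json``.

    The round trip through :func:`read_container` reproduces data, names,
    rate and events exactly.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.save(path.with_suffix(".npy"), rec.data)
    sidecar = {
        "container_version": CONTAINER_VERSION,
        "participant_id": rec.participant_id,
        "modality": rec.modality,
        "channel_names": list(rec.channel_names),
        "sample_rate_hz": rec.sample_rate_hz,
        "events": [[int(onset), label] for onset, label in rec.events],
        "pre_cue_s": rec.pre_cue_s,
        "post_cue_s": rec.post_cue_s,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path.with_suffix(".npy")


def read_container(path: str | Path) -> RawRecording:
    """Read a recording written by :func:`write_container`."""
    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    version = meta.get("container_version")
    if version != CONTAINER_VERSION:
        raise ValueError(
            f"container version mismatch: file has {version!r}, "
            f"reader supports {CONTAINER_VERSION}"
        )
    data = np.load(path.with_suffix(".npy"))
    return RawRecording(
        participant_id=meta["participant_id"],
        modality=meta["modality"],
        channel_names=meta["channel_names"],
        sample_rate_hz=meta["sample_rate_hz"],
        data=data,
        events=[(int(onset), label) for onset, label in meta["events"]],
        pre_cue_s=meta["pre_cue_s"],
        post_cue_s=meta["post_cue_s"],
    )
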