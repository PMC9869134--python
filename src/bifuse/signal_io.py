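"""Reading the open bimodal dataset and the package's own container format.

The open-dataset reader is an optional extra: the rest of the package never
depends on it, and it follows the distributed MAT-file layout documented
below.  Expected per-participant layout under ``root``::

    root/<participant_id>/eeg.mat    variables: x (samples x channels),
                                     fs, clab, mrk_pos, mrk_y
    root/<participant_id>/nirs.mat   same variables at the fNIRS rate

``mrk_y`` carries integer condition codes mapped to "left"/"right" through
``event_code_map`` (default {1: "left", 2: "right"}); event labels are
normalized to those two strings at this boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .containers import RawRecording, read_container, write_container

__all__ = [
    "DatasetManifest",
    "load_open_dataset",
    "read_container",
    "write_container",
]

DEFAULT_EVENT_CODES = {1: "left", 2: "right"}


@dataclass
class DatasetManifest:
    """Participants and file paths of one local copy of the open dataset."""

    root: Path
    participant_ids: list[str]
    eeg_filename: str = "eeg.mat"
    nirs_filename: str = "nirs.mat"
    event_code_map: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_EVENT_CODES))

    def __post_init__(self):
        self.root = Path(self.root)
        missing = []
        for pid in self.participant_ids:
            for fname in (self.eeg_filename, self.nirs_filename):
                p = self.root / pid / fname
                if not p.exists():
                    missing.append(str(p))
        if missing:
            raise FileNotFoundError(f"manifest references missing files: {missing}")


def _flat_str_list(arr) -> list[str]:
    out = []
    for item in np.ravel(arr):
        while isinstance(item, np.ndarray):
            item = item.item() if item.size == 1 else item.ravel()[0]
        out.append(str(item))
    return out


def _load_mat_recording(
    path: Path,
    participant_id: str,
    modality: str,
    event_code_map: dict[int, str],
) -> RawRecording:
    from scipy.io import loadmat

    if not path.exists():
        raise FileNotFoundError(f"dataset file not found: {path}")
    try:
        mat = loadmat(path, squeeze_me=True)
    except Exception as err:
        raise ValueError(f"could not parse MAT file {path}: {err}") from err
    try:
        x = np.atleast_2d(np.asarray(mat["x"], dtype=float))
        fs = float(np.ravel(mat["fs"])[0])
        clab = _flat_str_list(mat["clab"])
        mrk_pos = np.ravel(mat["mrk_pos"]).astype(int)
        mrk_y = np.ravel(mat["mrk_y"]).astype(int)
    except KeyError as err:
        raise ValueError(f"MAT file {path} lacks required variable {err}") from err
    unknown = sorted(int(c) for c in set(mrk_y.tolist()) - set(event_code_map))
    if unknown:
        raise ValueError(
            f"unknown event codes {unknown} in {path}; codes found: "
            f"{sorted(set(mrk_y.tolist()))}, known: {sorted(event_code_map)}"
        )
    data = x.T  # stored samples x channels
    events = [(int(p), event_code_map[int(c)]) for p, c in zip(mrk_pos, mrk_y)]
    return RawRecording(
        participant_id=participant_id,
        modality=modality,
        channel_names=clab,
        sample_rate_hz=fs,
        data=data,
        events=events,
    )


def load_open_dataset(
    root_path: str | Path,
    participant_id: str,
    eeg_filename: str = "eeg.mat",
    nirs_filename: str = "nirs.mat",
    event_code_map: dict[int, str] | None = None,
) -> tuple[RawRecording, RawRecording]:
    """Load one participant as (EEG at its native 200 Hz, fNIRS intensity at
    10 Hz); EOG channels stay present (flagged by name) for the EEG chain
    to drop."""
    codes = event_code_map or DEFAULT_EVENT_CODES
    base = Path(root_path) / participant_id
    eeg = _load_mat_recording(base / eeg_filename, participant_id, "eeg", codes)
    nirs = _load_mat_recording(base / nirs_filename, participant_id, "nirs-intensity", codes)
    return eeg, nirs
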