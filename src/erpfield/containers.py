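"""In-memory containers for epoched and trial-averaged EEG."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EpochsArray", "EvokedMap"]


@dataclass(frozen=True)
class EpochsArray:
    """Single-participant, single-condition epoched EEG.

    ``data`` is trials x channels x samples in microvolts; ``tmin_ms`` is the
    epoch start relative to the time-locking event (negative = pre-stimulus).
    ``lock`` records which event the epochs are locked to (the face/context
    paradigm has two face onsets per sequence, ``Face_1`` and ``Face_2``).
    """

    participant: str
    condition: str
    data: np.ndarray
    sfreq: float
    tmin_ms: float
    ch_names: tuple[str, ...]
    lock: str = "Face_2"

    def __post_init__(self):
        object.__setattr__(self, "data", np.asarray(self.data, dtype=float))
        object.__setattr__(self, "ch_names", tuple(self.ch_names))
        if self.data.ndim != 3:
            raise ValueError("epochs data must be trials x channels x samples")
        if self.data.shape[1] != len(self.ch_names):
            raise ValueError("channel axis does not match ch_names")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times_ms(self) -> np.ndarray:
        n = self.data.shape[2]
        return self.tmin_ms + np.arange(n) * 1000.0 / self.sfreq


@dataclass(frozen=True)
class EvokedMap:
    """Per-participant, per-condition trial average (channels x samples)."""

    participant: str
    condition: str
    data: np.ndarray
    sfreq: float
    tmin_ms: float
    ch_names: tuple[str, ...]
    lock: str = "Face_2"
    n_trials: int = 0

    def __post_init__(self):
        object.__setattr__(self, "data", np.asarray(self.data, dtype=float))
        object.__setattr__(self, "ch_names", tuple(self.ch_names))
        if self.data.ndim != 2:
            raise ValueError("evoked data must be channels x samples")
        if self.data.shape[0] != len(self.ch_names):
            raise ValueError("channel axis does not match ch_names")

    @property
    def times_ms(self) -> np.ndarray:
        n = self.data.shape[1]
        return self.tmin_ms + np.arange(n) * 1000.0 / self.sfreq
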