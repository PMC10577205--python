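"""In-memory containers shared by the simulator, the extraction chain and IO."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: acquisition sampling rate, Hz
SFREQ = 500.0
#: epoch span relative to trial onset, ms
EPOCH_START_MS = -200.0
EPOCH_STOP_MS = 1798.0
N_SAMPLES = 1000

#: 10-20 montage subset used throughout: frontal N2 pool, centroparietal P3
#: pool, the two mastoids (reference) and Fp1 (blink proxy).
FRONTAL_POOL = ("Fz", "F1", "F2", "F3", "F4")
CP_POOL = ("CPz", "CP1", "CP2", "CP3", "CP4")
MASTOIDS = ("TP9", "TP10")
MONTAGE = FRONTAL_POOL + CP_POOL + MASTOIDS + ("Fp1",)


def epoch_times() -> np.ndarray:
    """Time axis in ms: -200 … +1798 in 2-ms steps (1000 samples), 0 = trial onset."""
    return EPOCH_START_MS + 1000.0 / SFREQ * np.arange(N_SAMPLES)


@dataclass
class EpochSet:
    """Per-trial multichannel EEG segments with condition metadata.

    ``data`` is (n_epochs, n_channels, n_samples) in μV.  ``metadata`` has one
    row per epoch with at least condition / distractor / stimulator columns
    plus a ``blink_injected`` flag set by the artifact injector.
    """

    subject_id: str
    channels: list[str]
    times: np.ndarray
    data: np.ndarray
    metadata: pd.DataFrame

    def __post_init__(self):
        n_ep, n_ch, n_t = self.data.shape
        if n_ch != len(self.channels):
            raise ValueError("channel count mismatch")
        if n_t != self.times.size:
            raise ValueError("sample count mismatch")
        if len(self.metadata) != n_ep:
            raise ValueError("metadata row count mismatch")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def sfreq(self) -> float:
        return 1000.0 / float(self.times[1] - self.times[0])

    def channel_index(self, name: str) -> int:
        try:
            return self.channels.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in EpochSet") from None

    def copy(self) -> "EpochSet":
        return EpochSet(self.subject_id, list(self.channels), self.times.copy(),
                        self.data.copy(), self.metadata.copy())


@dataclass
class ERPAverage:
    """Condition-averaged, baseline-corrected waveform for one subject."""

    subject_id: str
    condition: str                 # e.g. "Go" / "NoGo" (or a full sub-key)
    channels: list[str]
    times: np.ndarray
    data: np.ndarray               # (n_channels, n_samples), μV
    n_epochs: int
    eligible: bool = True

    def channel_trace(self, name: str) -> np.ndarray:
        return self.data[self.channels.index(name)]


@dataclass(frozen=True)
class PeakMeasure:
    """A single detected component peak on one channel."""

    component: str                 # "N2" | "P3"
    channel: str
    latency_ms: float              # trial-onset frame
    amplitude_uv: float            # signed, relative to baseline


@dataclass(frozen=True)
class PooledComponent:
    """Pool-averaged N2/P3 measures and the N2-P3 interpeak latency."""

    pool: str                      # "frontal" | "centroparietal"
    n2_amplitude_uv: float
    n2_latency_ms: float
    p3_amplitude_uv: float
    p3_latency_ms: float
    n2_p3_ipl_ms: float            # mean over channels of (P3 - N2) latency
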