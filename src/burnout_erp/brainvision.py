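"""BrainVision Core format interchange for epoched data.

Epochs are written as one continuous multiplexed IEEE float32 recording
(epochs concatenated back-to-back) with one stimulus marker per trial at the
trial-onset sample.  The marker code encodes the epoch's condition cell:

    S 1..8   test epochs,     code = 1 + index into CONDITION_CELLS
    S 11..18 practice epochs, code = 10 + the same index

Reading goes through :mod:`mne` (the de-facto reader for the format) and
re-cuts the -200 ... +1798 ms epochs around each stimulus marker.  The
``blink_injected`` simulation flag is not representable in the format and is
restored as False on read.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .containers import N_SAMPLES, EpochSet, epoch_times

#: fixed ordering of (condition, distractor, stimulator) cells -> marker code
CONDITION_CELLS = [
    (c, d, s)
    for c in ("Go", "NoGo")
    for d in ("emotional", "neutral")
    for s in ("ON", "OFF")
]

_PRE_SAMPLES = 100   # samples before trial onset in each epoch


def _cell_code(condition: str, distractor: str, stimulator: str,
               is_practice: bool) -> int:
    idx = CONDITION_CELLS.index((condition, distractor, stimulator))
    return idx + 1 + (10 if is_practice else 0)


def write_brainvision(epochs: EpochSet, out_dir: str, basename: str) -> str:
    """Write an EpochSet as a .vhdr/.vmrk/.eeg triplet; returns the .vhdr path."""
    os.makedirs(out_dir, exist_ok=True)
    vhdr = os.path.join(out_dir, basename + ".vhdr")
    vmrk = os.path.join(out_dir, basename + ".vmrk")
    eeg = os.path.join(out_dir, basename + ".eeg")

    n_ep, n_ch, n_t = epochs.data.shape
    sampling_interval_us = int(round(1e6 / epochs.sfreq))

    # multiplexed: (samples, channels) interleaved
    continuous = epochs.data.transpose(0, 2, 1).reshape(n_ep * n_t, n_ch)
    continuous.astype("<f4").tofile(eeg)

    with open(vhdr, "w", encoding="utf-8") as f:
        f.write("BrainVision Data Exchange Header File Version 1.0\n\n")
        f.write("[Common Infos]\nCodepage=UTF-8\n")
        f.write(f"DataFile={basename}.eeg\nMarkerFile={basename}.vmrk\n")
        f.write("DataFormat=BINARY\nDataOrientation=MULTIPLEXED\n")
        f.write(f"NumberOfChannels={n_ch}\n")
        f.write(f"SamplingInterval={sampling_interval_us}\n\n")
        f.write("[Binary Infos]\nBinaryFormat=IEEE_FLOAT_32\n\n")
        f.write("[Channel Infos]\n")
        for i, ch in enumerate(epochs.channels, start=1):
            f.write(f"Ch{i}={ch},,1,µV\n")

    with open(vmrk, "w", encoding="utf-8") as f:
        f.write("BrainVision Data Exchange Marker File, Version 1.0\n\n")
        f.write("[Common Infos]\nCodepage=UTF-8\n")
        f.write(f"DataFile={basename}.eeg\n\n")
        f.write("[Marker Infos]\n")
        f.write("Mk1=New Segment,,1,1,0,00000000000000000000\n")
        for i, row in enumerate(epochs.metadata.itertuples(index=False)):
            code = _cell_code(row.condition, row.distractor, row.stimulator,
                              bool(getattr(row, "is_practice", False)))
            pos = i * n_t + _PRE_SAMPLES + 1    # 1-based trial-onset sample
            f.write(f"Mk{i + 2}=Stimulus,S{code:3d},{pos},1,0\n")
    return vhdr


def _validate_triplet(vhdr_path: str) -> None:
    base = os.path.splitext(vhdr_path)[0]
    for ext in (".vmrk", ".eeg"):
        if not os.path.exists(base + ext):
            raise FileNotFoundError(f"missing companion file {base + ext}")
    n_ch = None
    orientation = "MULTIPLEXED"
    with open(vhdr_path, encoding="utf-8") as f:
        for line in f:
            if line.startswith("NumberOfChannels="):
                n_ch = int(line.split("=")[1])
            if line.startswith("DataOrientation="):
                orientation = line.split("=")[1].strip()
    if orientation != "MULTIPLEXED":
        raise ValueError(f"unsupported data orientation {orientation!r}")
    if n_ch:
        size = os.path.getsize(base + ".eeg")
        if size % (4 * n_ch) != 0:
            raise ValueError(".eeg payload truncated: size not a whole number "
                             "of float32 multiplexed samples")
        n_samples = size // (4 * n_ch)
        with open(base + ".vmrk", encoding="utf-8") as f:
            for line in f:
                if line.startswith("Mk") and "Stimulus" in line:
                    pos = int(line.split(",")[2])
                    if pos - _PRE_SAMPLES - 1 < 0 or \
                            pos - _PRE_SAMPLES - 1 + N_SAMPLES > n_samples:
                        raise ValueError(
                            "marker-defined epoch extends past the recording "
                            "(.eeg payload truncated?)")


def read_brainvision(vhdr_path: str, subject_id: str = "") -> EpochSet:
    """Read a triplet written by :func:`write_brainvision` (or any BrainVision
    Core recording carrying S1..S8 / S11..S18 trial markers) into an EpochSet."""
    import mne

    _validate_triplet(vhdr_path)
    raw = mne.io.read_raw_brainvision(vhdr_path, preload=True, verbose="error")
    if abs(raw.info["sfreq"] - 500.0) > 1e-6:
        raise ValueError(f"expected 500 Hz recording, got {raw.info['sfreq']}")
    data_uv = raw.get_data() * 1e6          # mne returns Volts
    n_total = data_uv.shape[1]

    rows, slabs = [], []
    for ann in raw.annotations:
        desc = ann["description"]
        if not desc.startswith("Stimulus/S"):
            continue
        code = int(desc.split("S")[-1])
        onset_sample = int(round(ann["onset"] * raw.info["sfreq"]))
        start = onset_sample - _PRE_SAMPLES
        stop = start + N_SAMPLES
        if start < 0 or stop > n_total:
            raise ValueError("marker-defined epoch extends past the recording "
                             "(truncated .eeg payload?)")
        is_practice = code > 10
        cond, dist, stim = CONDITION_CELLS[(code - 1) % 10]
        rows.append({"condition": cond, "distractor": dist, "stimulator": stim,
                     "is_practice": is_practice, "blink_injected": False})
        slabs.append(data_uv[:, start:stop])
    if not rows:
        raise ValueError("no stimulus markers found")
    return EpochSet(subject_id=subject_id or os.path.basename(vhdr_path),
                    channels=list(raw.ch_names), times=epoch_times(),
                    data=np.stack(slabs), metadata=pd.DataFrame(rows))
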