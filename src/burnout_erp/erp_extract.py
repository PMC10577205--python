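"""ERP preprocessing and measurement chain.

Order of operations (mirroring a conventional ERP workflow): linked-mastoid
re-reference -> 0.1-40 Hz zero-phase band-pass -> 80 μV peak-to-peak epoch
rejection -> per-condition baseline-corrected averaging (minimum 50 clean
epochs per condition) -> windowed-extremum peak detection -> channel-pool
averaging and N2-P3 interpeak latency.

Peak definitions (trial-onset time frame; the Go/NoGo signal appears 300 ms
after trial onset): N2 is the most negative sample in 500-650 ms, P3 the
most positive sample in a window starting no earlier than 600 ms and
strictly after the channel's N2 peak, ending at 800 ms.  Ties break toward
the earlier sample, so detection is fully deterministic; there is no manual
peak adjustment stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .containers import (CP_POOL, FRONTAL_POOL, MASTOIDS, EpochSet, ERPAverage,
                         PeakMeasure, PooledComponent)

N2_WINDOW_MS = (500.0, 650.0)
P3_WINDOW_MS = (600.0, 800.0)
BASELINE_MS = (-200.0, 0.0)

POOLS = {"frontal": FRONTAL_POOL, "centroparietal": CP_POOL}


def rereference_linked_mastoids(epochs: EpochSet,
                                mastoids: tuple[str, str] = MASTOIDS) -> EpochSet:
    """Subtract the arithmetic mean of the two mastoid channels from every
    channel, sample-wise."""
    for m in mastoids:
        if m not in epochs.channels:
            raise ValueError(f"mastoid channel {m!r} missing")
    out = epochs.copy()
    i1, i2 = (out.channel_index(m) for m in mastoids)
    ref = 0.5 * (out.data[:, i1, :] + out.data[:, i2, :])
    out.data -= ref[:, None, :]
    return out


def bandpass(epochs: EpochSet, low_hz: float = 0.1, high_hz: float = 40.0,
             order: int = 4) -> EpochSet:
    """Zero-phase Butterworth band-pass (applied forward-backward), so peak
    latencies are not shifted."""
    nyq = epochs.sfreq / 2.0
    if not (0.0 < low_hz < high_hz < nyq):
        raise ValueError(f"invalid band edges ({low_hz}, {high_hz}) for "
                         f"Nyquist {nyq} Hz")
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass",
                        fs=epochs.sfreq, output="sos")
    out = epochs.copy()
    # maximal padding: the 0.1 Hz edge has an impulse response longer than
    # the epoch, so short default padding leaves large edge transients
    out.data = signal.sosfiltfilt(sos, out.data, axis=-1,
                                  padlen=out.data.shape[-1] - 1)
    return out


def reject_artifacts(epochs: EpochSet, threshold_uv: float = 80.0,
                     channels: list[str] | None = None) -> tuple[EpochSet, pd.DataFrame]:
    """Drop epochs whose peak-to-peak amplitude exceeds ``threshold_uv`` on
    any analysis channel; return the retained set and a per-epoch log."""
    if threshold_uv <= 0:
        raise ValueError("threshold must be positive")
    if channels is None:
        channels = epochs.channels
    idx = [epochs.channel_index(ch) for ch in channels]
    ptp = epochs.data[:, idx, :].max(axis=-1) - epochs.data[:, idx, :].min(axis=-1)
    worst = ptp.argmax(axis=1)
    rejected = ptp.max(axis=1) > threshold_uv
    log = pd.DataFrame({
        "epoch": np.arange(epochs.n_epochs),
        "rejected": rejected,
        "max_ptp_uv": ptp.max(axis=1),
        "offending_channel": [channels[w] if r else ""
                              for w, r in zip(worst, rejected)],
    })
    keep = ~rejected
    out = EpochSet(epochs.subject_id, list(epochs.channels), epochs.times.copy(),
                   epochs.data[keep].copy(),
                   epochs.metadata.loc[keep].reset_index(drop=True))
    return out, log


def baseline_correct(data: np.ndarray, times: np.ndarray,
                     window: tuple[float, float] = BASELINE_MS) -> np.ndarray:
    """Subtract the per-channel mean over the pre-onset baseline window."""
    mask = (times >= window[0]) & (times < window[1])
    return data - data[..., mask].mean(axis=-1, keepdims=True)


def average_conditions(epochs: EpochSet, min_epochs: int = 50,
                       by: tuple[str, ...] = ("condition",),
                       exclude_practice: bool = True) -> dict[str, ERPAverage]:
    """Baseline-correct and average epochs per condition.

    Sub-averages are first formed at the full condition x distractor x
    stimulator granularity, then combined by unweighted mean to the requested
    level (stimulator ON/OFF and distractor sub-averages are averaged, not
    epoch-pooled).  A condition with fewer than ``min_epochs`` contributing
    clean epochs in total is marked ineligible.
    """
    meta = epochs.metadata
    sel = np.ones(len(meta), dtype=bool)
    if exclude_practice and "is_practice" in meta.columns:
        sel &= ~meta["is_practice"].to_numpy()
    if not sel.any():
        raise ValueError(f"subject {epochs.subject_id}: no epochs to average")
    data = baseline_correct(epochs.data[sel], epochs.times)
    meta = meta.loc[sel].reset_index(drop=True)

    full_keys = ["condition", "distractor", "stimulator"]
    sub_avgs: dict[tuple, tuple[np.ndarray, int]] = {}
    for key, grp in meta.groupby(full_keys, sort=True):
        rows = grp.index.to_numpy()
        sub_avgs[key] = (data[rows].mean(axis=0), len(rows))

    out: dict[str, ERPAverage] = {}
    level = [full_keys.index(b) for b in by]
    targets = sorted({tuple(k[i] for i in level) for k in sub_avgs})
    for tgt in targets:
        parts = [(avg, n) for key, (avg, n) in sub_avgs.items()
                 if tuple(key[i] for i in level) == tgt]
        combined = np.mean([avg for avg, _ in parts], axis=0)
        n_total = sum(n for _, n in parts)
        name = "/".join(tgt)
        out[name] = ERPAverage(subject_id=epochs.subject_id, condition=name,
                               channels=list(epochs.channels),
                               times=epochs.times.copy(), data=combined,
                               n_epochs=n_total,
                               eligible=n_total >= min_epochs)
    return out


def _window_indices(times: np.ndarray, lo: float, hi: float) -> np.ndarray:
    idx = np.flatnonzero((times >= lo) & (times <= hi))
    if idx.size == 0:
        raise ValueError(f"window [{lo}, {hi}] ms outside the epoch")
    return idx


def detect_peak(avg: ERPAverage, channel: str, component: str,
                n2_window: tuple[float, float] = N2_WINDOW_MS,
                p3_window: tuple[float, float] = P3_WINDOW_MS) -> PeakMeasure:
    """Windowed-extremum peak detection on one channel.

    N2 = minimum in the N2 window; P3 = maximum in the P3 window restricted
    to samples strictly after the channel's N2 peak (subsequence constraint).
    Ties break toward the earlier sample (argmin/argmax first occurrence).
    """
    trace = avg.channel_trace(channel)
    t = avg.times
    n2_idx = _window_indices(t, *n2_window)
    i_n2 = n2_idx[int(np.argmin(trace[n2_idx]))]
    if component == "N2":
        return PeakMeasure("N2", channel, float(t[i_n2]), float(trace[i_n2]))
    if component == "P3":
        lo = max(p3_window[0], float(t[i_n2]) + 2.0)
        p3_idx = _window_indices(t, lo, p3_window[1])
        i_p3 = p3_idx[int(np.argmax(trace[p3_idx]))]
        return PeakMeasure("P3", channel, float(t[i_p3]), float(trace[i_p3]))
    raise ValueError(f"unknown component {component!r}")


def pool_component(n2_measures: list[PeakMeasure], p3_measures: list[PeakMeasure],
                   pool: str) -> PooledComponent:
    """Average per-channel N2/P3 measures over a pool and compute the N2-P3
    interpeak latency (per-channel P3 minus N2 latency, then averaged)."""
    expected = set(POOLS[pool])
    got_n2 = {m.channel for m in n2_measures}
    got_p3 = {m.channel for m in p3_measures}
    if got_n2 != expected or got_p3 != expected:
        missing = (expected - got_n2) | (expected - got_p3)
        raise ValueError(f"pool {pool!r}: missing channels {sorted(missing)}")
    n2_by = {m.channel: m for m in n2_measures}
    p3_by = {m.channel: m for m in p3_measures}
    chans = sorted(expected)
    ipl = float(np.mean([p3_by[c].latency_ms - n2_by[c].latency_ms for c in chans]))
    return PooledComponent(
        pool=pool,
        n2_amplitude_uv=float(np.mean([n2_by[c].amplitude_uv for c in chans])),
        n2_latency_ms=float(np.mean([n2_by[c].latency_ms for c in chans])),
        p3_amplitude_uv=float(np.mean([p3_by[c].amplitude_uv for c in chans])),
        p3_latency_ms=float(np.mean([p3_by[c].latency_ms for c in chans])),
        n2_p3_ipl_ms=ipl,
    )


def measure_pools(avg: ERPAverage) -> dict[str, PooledComponent]:
    """Detect N2 and P3 on every pool channel and pool them."""
    out = {}
    for pool, chans in POOLS.items():
        n2 = [detect_peak(avg, ch, "N2") for ch in chans]
        p3 = [detect_peak(avg, ch, "P3") for ch in chans]
        out[pool] = pool_component(n2, p3, pool)
    return out


def preprocess(epochs: EpochSet, low_hz: float = 0.1, high_hz: float = 40.0,
               threshold_uv: float = 80.0) -> tuple[EpochSet, pd.DataFrame]:
    """Re-reference, filter, and reject: the fixed preprocessing front-end."""
    x = rereference_linked_mastoids(epochs)
    x = bandpass(x, low_hz, high_hz)
    return reject_artifacts(x, threshold_uv)


def extract_subject(epochs: EpochSet, min_epochs: int = 50,
                    low_hz: float = 0.1, high_hz: float = 40.0,
                    threshold_uv: float = 80.0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full chain for one subject.

    Returns a tidy measurement table (one row per condition x pool) and the
    rejection log.  Ineligible conditions (fewer than ``min_epochs`` clean
    epochs) are included with ``eligible=False`` so exclusions stay visible.
    """
    clean, log = preprocess(epochs, low_hz, high_hz, threshold_uv)
    averages = average_conditions(clean, min_epochs=min_epochs)
    rows = []
    for cond, avg in averages.items():
        for pool, pc in measure_pools(avg).items():
            rows.append({
                "subject": epochs.subject_id, "condition": cond, "pool": pool,
                "n2_amplitude_uv": pc.n2_amplitude_uv,
                "n2_latency_ms": pc.n2_latency_ms,
                "p3_amplitude_uv": pc.p3_amplitude_uv,
                "p3_latency_ms": pc.p3_latency_ms,
                "n2_p3_ipl_ms": pc.n2_p3_ipl_ms,
                "n_epochs": avg.n_epochs, "eligible": avg.eligible,
            })
    return pd.DataFrame(rows), log
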