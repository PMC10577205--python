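"""Synthetic cohort generator: questionnaire profiles, behaviour, and EEG epochs.

The generator emulates a two-group occupational-burnout study: subjects carry
questionnaire scores (BBI-15 burnout inventory, BDI-21 depression inventory,
BRIEF-A executive-function T-scores), perform the Executive RT Go/NoGo test,
and yield per-trial EEG epochs containing an N2 (negative, frontal-maximal)
and a P3 (positive, centroparietal-maximal) component on top of 1/f
background noise, with optional blink artifacts.

Group-level defaults are calibrated to the study's printed ERP-subgroup
summaries (questionnaire means/SDs, group median RTs, per-type error rates,
Go-condition pooled CP P3 amplitude and N2-P3 interpeak latency).  Two modes
of ERP generation are supported:

* *group defaults* — every subject receives the group's component parameters
  exactly; used for pipeline parameter-recovery checks, where the only
  variability is measurement noise;
* *dispersed* — per-subject component parameters are drawn around the group
  defaults with between-subject SDs derived from the printed IQRs, and the
  subject's P3 amplitude is latently coupled to the BBI-15 score; used for
  cohort-level correlation and group-contrast analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import (CP_POOL, FRONTAL_POOL, MASTOIDS, MONTAGE, N_SAMPLES,
                         SFREQ, EpochSet, epoch_times)
from .task_design import LIGHT_ONSET_MS, ResponseRecord, TrialSpec

# IQR -> SD for a normal distribution
_IQR_TO_SD = 1.0 / 1.349


@dataclass(frozen=True)
class SubjectProfile:
    subject_id: str
    group: str                     # "burnout" | "non_burnout"
    bbi15: float                   # 15..90
    bdi21: float                   # 0..63
    brief_bri: float               # T-scores, 20..100
    brief_mi: float
    brief_gec: float
    age_years: float
    sex: str


@dataclass(frozen=True)
class ScaleCalib:
    mean: float
    sd: float
    lo: float
    hi: float


@dataclass
class GroupCalibration:
    """Per-group questionnaire / behaviour calibration."""

    bbi15: ScaleCalib
    bdi21: ScaleCalib
    brief_bri: ScaleCalib
    brief_mi: ScaleCalib
    brief_gec: ScaleCalib
    age: ScaleCalib
    rt_median_ms: float
    rt_subject_sigma: float        # log-scale SD of subject median RT
    rt_trial_sigma: float          # log-scale within-subject trial RT SD
    p_incorrect: float             # wrong button, per Go trial
    p_miss: float                  # no press, per Go trial
    p_commission: float            # press, per NoGo trial


@dataclass
class CohortCalibration:
    """Two-group cohort calibration plus the latent profile<->ERP coupling.

    ``bbi_p3_coupling`` is the within-group correlation between the latent
    standard-normal deviates of the BBI-15 score and of the subject's
    generative Go P3 amplitude.  Its default is a one-off Monte-Carlo
    calibration such that the *cohort-level* (both groups pooled, 18 + 17
    subjects) Spearman correlation between generative P3 amplitude and BBI-15
    equals the study's printed value of 0.45 — the between-group separation
    alone contributes roughly 0.34 of it, the within-group coupling the rest.
    """

    burnout: GroupCalibration
    non_burnout: GroupCalibration
    error_intercept_sd: float = 0.5    # per-subject random intercept, logit scale
    bbi_p3_coupling: float = 0.245

    def group(self, name: str) -> GroupCalibration:
        if name == "burnout":
            return self.burnout
        if name == "non_burnout":
            return self.non_burnout
        raise KeyError(f"unknown group {name!r}")


def _rt_sigma(median: float, iqr: float) -> float:
    # log-normal: IQR = m*(e^{z s} - e^{-z s}), z = 0.6745
    return math.asinh(iqr / (2.0 * median)) / 0.6745


def default_calibration() -> CohortCalibration:
    """Defaults calibrated to the printed ERP-subgroup summaries."""
    mk = lambda m, s, lo, hi: ScaleCalib(m, s, lo, hi)
    burnout = GroupCalibration(
        bbi15=mk(60.06, 10.34, 15, 90),
        bdi21=mk(15.89, 7.12, 0, 63),
        brief_bri=mk(58.94, 11.58, 20, 100),
        brief_mi=mk(63.17, 9.98, 20, 100),
        brief_gec=mk(62.06, 10.08, 20, 100),
        age=mk(46.44, 8.96, 18, 70),
        rt_median_ms=358.0, rt_subject_sigma=_rt_sigma(358.0, 81.0),
        rt_trial_sigma=0.25,
        p_incorrect=0.0098, p_miss=0.0021, p_commission=0.0117,
    )
    non_burnout = GroupCalibration(
        bbi15=mk(33.06, 8.47, 15, 90),
        bdi21=mk(4.12, 2.93, 0, 63),
        brief_bri=mk(46.18, 9.86, 20, 100),
        brief_mi=mk(47.47, 9.86, 20, 100),
        brief_gec=mk(46.53, 9.84, 20, 100),
        age=mk(45.76, 9.71, 18, 70),
        rt_median_ms=401.0, rt_subject_sigma=_rt_sigma(401.0, 107.0),
        rt_trial_sigma=0.25,
        p_incorrect=0.0078, p_miss=0.0020, p_commission=0.0078,
    )
    return CohortCalibration(burnout=burnout, non_burnout=non_burnout)


# ---------------------------------------------------------------------------
# ERP generation config


@dataclass(frozen=True)
class ComponentParams:
    """Group/condition component parameters (trial-onset time frame, ms / μV)."""

    n2_latency_ms: float
    n2_amplitude_uv: float         # negative
    p3_latency_ms: float
    p3_amplitude_uv: float         # positive

    def validate(self) -> None:
        if not (500.0 <= self.n2_latency_ms <= 650.0):
            raise ValueError("N2 latency outside the 500-650 ms search window")
        if not (600.0 <= self.p3_latency_ms <= 800.0):
            raise ValueError("P3 latency outside the 600-800 ms search window")
        if self.p3_latency_ms <= self.n2_latency_ms:
            raise ValueError("P3 latency must exceed N2 latency")
        if self.n2_amplitude_uv > 0:
            raise ValueError("N2 amplitude must be negative")
        if self.p3_amplitude_uv < 0:
            raise ValueError("P3 amplitude must be positive")


@dataclass(frozen=True)
class ComponentDispersion:
    """Between-subject SDs around the group defaults (dispersed mode)."""

    n2_latency_sd: float = 10.0
    n2_amplitude_sd: float = 1.5
    p3_latency_sd: float = 0.0
    p3_amplitude_sd: float = 0.0


@dataclass
class ErpGenConfig:
    """Waveform-generation configuration.

    Components are raised-cosine (Hann) bumps of compact support
    ``latency ± width/2``; the bump peak equals the configured amplitude
    exactly, which makes noiseless generative parameters recoverable by the
    extraction chain.  N2 is frontal-maximal and P3 centroparietal-maximal
    via per-channel topography weights; both components are also present on
    the other pool (scaled), since interpeak latency is reported on the
    centroparietal pool.
    """

    sampling_rate: float = SFREQ
    montage: tuple[str, ...] = MONTAGE
    n2_width_ms: float = 80.0
    p3_width_ms: float = 150.0
    #: per-channel (n2_weight, p3_weight); pool-defining channels get 1.0 so
    #: that the pooled mean amplitude equals the configured amplitude.
    topography: dict = field(default_factory=lambda: {
        **{ch: (1.0, 0.55) for ch in FRONTAL_POOL},
        **{ch: (0.45, 1.0) for ch in CP_POOL},
        **{ch: (0.0, 0.0) for ch in MASTOIDS},
        "Fp1": (0.2, 0.2),
    })
    noise_sd_uv: float = 8.0
    noise_f_lo_hz: float = 0.25    # 1/f spectrum flattens below this
    noise_f_hi_hz: float = 40.0
    blink_rate: float = 0.05
    blink_amplitude_uv: float = 120.0
    blink_width_ms: float = 250.0
    #: (group, condition) -> defaults; Go values calibrated so pooled CP P3
    #: amplitude and N2-P3 IPL reproduce the printed group medians
    #: (burnout 9.89 μV / 188.2 ms, non-burnout 6.73 μV / 135.0 ms).
    components: dict = field(default_factory=lambda: {
        ("burnout", "Go"): ComponentParams(540.0, -4.0, 728.0, 9.89),
        ("burnout", "NoGo"): ComponentParams(542.0, -6.0, 690.0, 6.44),
        ("non_burnout", "Go"): ComponentParams(544.0, -4.0, 680.0, 6.73),
        ("non_burnout", "NoGo"): ComponentParams(542.0, -6.0, 690.0, 6.14),
    })
    dispersion: dict = field(default_factory=lambda: {
        ("burnout", "Go"): ComponentDispersion(p3_latency_sd=85.4 * _IQR_TO_SD,
                                               p3_amplitude_sd=5.69 * _IQR_TO_SD),
        ("burnout", "NoGo"): ComponentDispersion(p3_latency_sd=20.0,
                                                 p3_amplitude_sd=5.57 * _IQR_TO_SD),
        ("non_burnout", "Go"): ComponentDispersion(p3_latency_sd=49.4 * _IQR_TO_SD,
                                                   p3_amplitude_sd=3.48 * _IQR_TO_SD),
        ("non_burnout", "NoGo"): ComponentDispersion(p3_latency_sd=20.0,
                                                     p3_amplitude_sd=3.58 * _IQR_TO_SD),
    })

    def validate(self) -> None:
        for params in self.components.values():
            params.validate()
        if self.blink_amplitude_uv <= 80.0:
            raise ValueError("blink amplitude must exceed the 80 μV rejection threshold")


# Go latency defaults sit on the 2-ms sample grid so noiseless recovery is
# exact; the implied interpeak latencies are 728-540 = 188 ms (burnout) and
# 680-544 = 136 ms (non-burnout), i.e. within one sample of the 188.2 / 135.0
# ms calibration medians.


# ---------------------------------------------------------------------------
# Profile sampling


def _truncnorm(rng: np.random.Generator, calib: ScaleCalib, size=None,
               z: np.ndarray | float | None = None):
    """Normal draw clamped to scale bounds (truncation shift negligible at the
    calibrated means)."""
    if z is None:
        z = rng.standard_normal(size)
    return np.clip(calib.mean + calib.sd * np.asarray(z, float), calib.lo, calib.hi)


def sample_profile(group: str, calib: CohortCalibration, rng: np.random.Generator,
                   subject_id: str = "S00", bbi_z: float | None = None) -> SubjectProfile:
    """Draw one subject's questionnaire profile for the given group.

    ``bbi_z`` optionally fixes the standard-normal deviate behind the BBI-15
    draw, which is how the latent coupling to the generative P3 amplitude is
    threaded through (see :func:`sample_subject_erp_params`).
    """
    g = calib.group(group)
    if bbi_z is None:
        bbi_z = float(rng.standard_normal())
    # correlated questionnaire deviates: burnout-construct scales share a
    # common factor with BBI (they co-vary strongly in the study cohort)
    shared = 0.6
    mk = lambda c: float(_truncnorm(rng, c,
                                    z=shared * bbi_z + math.sqrt(1 - shared ** 2)
                                    * rng.standard_normal()))
    return SubjectProfile(
        subject_id=subject_id, group=group,
        bbi15=float(_truncnorm(rng, g.bbi15, z=bbi_z)),
        bdi21=mk(g.bdi21),
        brief_bri=mk(g.brief_bri),
        brief_mi=mk(g.brief_mi),
        brief_gec=mk(g.brief_gec),
        age_years=float(_truncnorm(rng, g.age)),
        sex="F" if rng.random() < 0.9 else "M",
    )


def normative_tscore_sample(n: int, rng: np.random.Generator,
                            mean: float = 50.0, sd: float = 10.0) -> np.ndarray:
    """Draw ``n`` T-scores from the normative population (mean 50, SD 10)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return mean + sd * rng.standard_normal(n)


def sample_subject_erp_params(group: str, erp_cfg: ErpGenConfig,
                              calib: CohortCalibration, rng: np.random.Generator,
                              bbi_z: float | None = None,
                              dispersed: bool = True) -> dict:
    """Per-subject component parameters for both conditions.

    In dispersed mode the Go P3 amplitude deviate is correlated with
    ``bbi_z`` by ``calib.bbi_p3_coupling``; latencies and amplitudes are
    clamped so every subject stays compatible with the peak search windows.
    """
    out = {}
    rho = calib.bbi_p3_coupling
    for (g, cond), base in erp_cfg.components.items():
        if g != group:
            continue
        if not dispersed:
            out[cond] = base
            continue
        d = erp_cfg.dispersion[(g, cond)]
        if cond == "Go" and bbi_z is not None:
            amp_z = rho * bbi_z + math.sqrt(1 - rho ** 2) * rng.standard_normal()
        else:
            amp_z = rng.standard_normal()
        n2_lat = float(np.clip(base.n2_latency_ms + d.n2_latency_sd * rng.standard_normal(),
                               505.0, 645.0))
        n2_amp = float(min(base.n2_amplitude_uv + d.n2_amplitude_sd * rng.standard_normal(),
                           -0.5))
        p3_lat = float(np.clip(base.p3_latency_ms + d.p3_latency_sd * rng.standard_normal(),
                               max(605.0, n2_lat + 10.0), 795.0))
        p3_amp = float(max(base.p3_amplitude_uv + d.p3_amplitude_sd * amp_z, 0.5))
        out[cond] = ComponentParams(n2_lat, n2_amp, p3_lat, p3_amp)
    return out


# ---------------------------------------------------------------------------
# Behaviour


def simulate_behavior(profile: SubjectProfile, trials: list[TrialSpec],
                      calib: CohortCalibration, rng: np.random.Generator,
                      intercept_sd: float | None = None) -> list[ResponseRecord]:
    """Simulate button presses and RTs for one subject.

    RTs are log-normal around a subject-level median itself log-normal around
    the group median.  Error types are Bernoulli per applicable trial with a
    shared per-subject random intercept on the logit scale, giving the mixed
    logistic model a true random effect to recover.
    """
    g = calib.group(profile.group)
    if intercept_sd is None:
        intercept_sd = calib.error_intercept_sd
    u = intercept_sd * rng.standard_normal()
    logit = lambda p: math.log(p / (1 - p)) if 0 < p < 1 else (-math.inf if p == 0 else math.inf)
    expit = lambda x: 1 / (1 + math.exp(-x)) if x != -math.inf else 0.0
    p_inc = expit(logit(g.p_incorrect) + u)
    p_miss = expit(logit(g.p_miss) + u)
    p_comm = expit(logit(g.p_commission) + u)
    subj_median = g.rt_median_ms * math.exp(g.rt_subject_sigma * rng.standard_normal())

    def draw_rt() -> float:
        return subj_median * math.exp(g.rt_trial_sigma * rng.standard_normal())

    records = []
    for t in trials:
        if t.is_go:
            r = rng.random()
            if r < p_miss:
                rec = ResponseRecord(pressed=False)
            elif r < p_miss + p_inc:
                wrong = "down" if t.triangle == "up" else "up"
                rec = ResponseRecord(pressed=True, button=wrong, rt_ms=draw_rt())
            else:
                rec = ResponseRecord(pressed=True, button=t.triangle, rt_ms=draw_rt())
        else:
            if rng.random() < p_comm:
                rec = ResponseRecord(pressed=True, button=str(rng.choice(["up", "down"])),
                                     rt_ms=draw_rt())
            else:
                rec = ResponseRecord(pressed=False)
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# EEG epochs


def _hann_bump(times_ms: np.ndarray, latency_ms: float, width_ms: float) -> np.ndarray:
    """Unit-peak raised-cosine bump supported on latency ± width/2."""
    x = (times_ms - latency_ms) / width_ms
    out = np.zeros_like(times_ms, dtype=float)
    mask = np.abs(x) < 0.5
    out[mask] = 0.5 * (1.0 + np.cos(2.0 * np.pi * x[mask]))
    return out


def pink_noise(rng: np.random.Generator, shape: tuple, n_samples: int,
               sd: float, fs: float = SFREQ, f_lo: float = 0.25,
               f_hi: float = 40.0) -> np.ndarray:
    """Band-limited 1/f ("pink") noise, exact stationary SD ``sd`` per trace.

    Power spectrum ∝ 1/f between ``f_lo`` and ``f_hi``, flat below ``f_lo``,
    zero above ``f_hi`` (EEG background after anti-aliasing).
    """
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    amp = np.zeros_like(freqs)
    band = (freqs > 0) & (freqs <= f_hi)
    amp[band] = 1.0 / np.sqrt(np.maximum(freqs[band], f_lo))
    if n_samples % 2 == 0:
        amp[-1] = 0.0
    # scale so that Var(x_t) == sd^2 given X_k = amp_k * (a + ib), a,b ~ N(0,1)
    scale = sd * n_samples / (2.0 * np.sqrt(np.sum(amp ** 2)))
    amp = amp * scale
    z = rng.standard_normal((*shape, freqs.size)) + 1j * rng.standard_normal((*shape, freqs.size))
    return np.fft.irfft(amp * z, n=n_samples, axis=-1)


def simulate_epochs(profile: SubjectProfile, trials: list[TrialSpec],
                    erp_cfg: ErpGenConfig, rng: np.random.Generator,
                    subject_params: dict | None = None) -> EpochSet:
    """Simulate one multichannel epoch per trial.

    Each epoch is the topography-weighted sum of the N2 (negative) and P3
    (positive) bumps at the subject's (or the group-default) latencies, plus
    independent pink noise per channel.  Blink artifacts are added separately
    by :func:`inject_artifacts`.
    """
    erp_cfg.validate()
    if subject_params is None:
        subject_params = {cond: p for (g, cond), p in erp_cfg.components.items()
                          if g == profile.group}
    times = epoch_times()
    channels = list(erp_cfg.montage)
    n_ch = len(channels)
    n_ep = len(trials)
    w_n2 = np.array([erp_cfg.topography[ch][0] for ch in channels])
    w_p3 = np.array([erp_cfg.topography[ch][1] for ch in channels])

    # signal templates per condition: (n_ch, n_t)
    templates = {}
    for cond, p in subject_params.items():
        n2 = p.n2_amplitude_uv * _hann_bump(times, p.n2_latency_ms, erp_cfg.n2_width_ms)
        p3 = p.p3_amplitude_uv * _hann_bump(times, p.p3_latency_ms, erp_cfg.p3_width_ms)
        templates[cond] = np.outer(w_n2, n2) + np.outer(w_p3, p3)

    data = np.empty((n_ep, n_ch, N_SAMPLES))
    for i, t in enumerate(trials):
        data[i] = templates[t.condition]
    if erp_cfg.noise_sd_uv > 0:
        data += pink_noise(rng, (n_ep, n_ch), N_SAMPLES, erp_cfg.noise_sd_uv,
                           fs=erp_cfg.sampling_rate, f_lo=erp_cfg.noise_f_lo_hz,
                           f_hi=erp_cfg.noise_f_hi_hz)
    meta = pd.DataFrame({
        "condition": [t.condition for t in trials],
        "distractor": [t.distractor for t in trials],
        "stimulator": [t.stimulator for t in trials],
        "is_practice": [t.is_practice for t in trials],
        "blink_injected": False,
    })
    return EpochSet(subject_id=profile.subject_id, channels=channels,
                    times=times, data=data, metadata=meta)


def inject_artifacts(epochs: EpochSet, erp_cfg: ErpGenConfig,
                     rng: np.random.Generator) -> EpochSet:
    """Add frontal-dominant blink transients to a random subset of epochs.

    Every injected blink exceeds the 80 μV peak-to-peak rejection criterion
    on Fp1 by construction; injected epochs are flagged in the metadata.
    """
    if erp_cfg.blink_amplitude_uv <= 80.0:
        raise ValueError("blink amplitude must exceed 80 μV")
    out = epochs.copy()
    if erp_cfg.blink_rate <= 0:
        return out
    flags = rng.random(out.n_epochs) < erp_cfg.blink_rate
    blink_topo = np.zeros(len(out.channels))
    for i, ch in enumerate(out.channels):
        if ch == "Fp1":
            blink_topo[i] = 1.0
        elif ch in FRONTAL_POOL:
            blink_topo[i] = 0.4
        elif ch in CP_POOL:
            blink_topo[i] = 0.1
        elif ch in MASTOIDS:
            blink_topo[i] = 0.05
    for i in np.flatnonzero(flags):
        center = float(rng.uniform(0.0, 1500.0))
        bump = erp_cfg.blink_amplitude_uv * _hann_bump(out.times, center,
                                                       erp_cfg.blink_width_ms)
        out.data[i] += np.outer(blink_topo, bump)
    out.metadata = out.metadata.copy()
    out.metadata["blink_injected"] = flags
    return out
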