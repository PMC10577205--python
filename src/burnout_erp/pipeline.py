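"""End-to-end orchestration: simulate subjects, run the extraction chain,
collect cohort-level tables, and drive the parameter-recovery experiments.

Subjects are processed one at a time (a subject's epoch array is ~25 MB;
only the measurement tables are kept), and every stage draws from a child
stream of one master seed, so a full run is reproducible from (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import erp_extract, task_design
from .containers import EpochSet
from .synthetic_cohort import (CohortCalibration, ErpGenConfig, SubjectProfile,
                               default_calibration, inject_artifacts,
                               sample_profile, sample_subject_erp_params,
                               simulate_behavior, simulate_epochs)


@dataclass
class SubjectData:
    profile: SubjectProfile
    trials: list
    outcomes: list
    epochs: EpochSet
    generative_params: dict        # condition -> ComponentParams


def simulate_subject(subject_id: str, group: str, rng: np.random.Generator,
                     calib: CohortCalibration | None = None,
                     erp_cfg: ErpGenConfig | None = None,
                     dispersed: bool = True,
                     conditions: tuple[str, ...] | None = None,
                     n_test_blocks: int = 4,
                     with_artifacts: bool = True) -> SubjectData:
    """Simulate one subject: profile, task session, behaviour, and epochs.

    EEG is simulated for the test blocks only (practice blocks are excluded
    from every analysis).  ``conditions`` optionally restricts epoch
    simulation to a subset of trial conditions (e.g. ``("Go",)``) when only
    those averages are needed.
    """
    calib = calib or default_calibration()
    erp_cfg = erp_cfg or ErpGenConfig()
    bbi_z = float(rng.standard_normal())
    profile = sample_profile(group, calib, rng, subject_id=subject_id, bbi_z=bbi_z)
    params = sample_subject_erp_params(group, erp_cfg, calib, rng,
                                       bbi_z=bbi_z, dispersed=dispersed)
    trials = task_design.generate_session(rng, n_practice=0, n_test=n_test_blocks)
    responses = simulate_behavior(profile, trials, calib, rng)
    outcomes = [task_design.classify_response(t, r) for t, r in zip(trials, responses)]
    epoch_trials = trials if conditions is None else \
        [t for t in trials if t.condition in conditions]
    epochs = simulate_epochs(profile, epoch_trials, erp_cfg, rng,
                             subject_params=params)
    if with_artifacts:
        epochs = inject_artifacts(epochs, erp_cfg, rng)
    return SubjectData(profile=profile, trials=trials, outcomes=outcomes,
                       epochs=epochs, generative_params=params)


def profiles_frame(profiles: list[SubjectProfile]) -> pd.DataFrame:
    return pd.DataFrame([{
        "subject_id": p.subject_id, "group": p.group, "bbi15": p.bbi15,
        "bdi21": p.bdi21, "brief_bri": p.brief_bri, "brief_mi": p.brief_mi,
        "brief_gec": p.brief_gec, "age_years": p.age_years, "sex": p.sex,
    } for p in profiles])


def simulate_and_extract_cohort(n_burnout: int, n_non_burnout: int, seed: int,
                                calib: CohortCalibration | None = None,
                                erp_cfg: ErpGenConfig | None = None,
                                dispersed: bool = True,
                                conditions: tuple[str, ...] | None = None,
                                min_epochs: int = 50,
                                threshold_uv: float = 80.0,
                                keep_outcomes: bool = True) -> dict:
    """Simulate a two-group cohort and run the full extraction chain.

    Returns a dict of tidy tables: ``profiles``, ``measurements`` (per
    subject x condition x pool), ``behavior`` (per-subject summaries),
    ``outcomes`` (per-trial rows for the error models), ``rejections``, and
    ``generative`` (the per-subject generative component parameters, for
    recovery checks only — never consumed by the analysis itself).
    """
    calib = calib or default_calibration()
    erp_cfg = erp_cfg or ErpGenConfig()
    ss = np.random.SeedSequence(seed)
    plan = [("burnout", i) for i in range(n_burnout)] + \
           [("non_burnout", i) for i in range(n_non_burnout)]
    child_seeds = ss.spawn(len(plan))

    profiles, meas, behav, outc, rej, gen = [], [], [], [], [], []
    for (group, i), child in zip(plan, child_seeds):
        sid = f"{'B' if group == 'burnout' else 'N'}{i + 1:02d}"
        rng = np.random.default_rng(child)
        sub = simulate_subject(sid, group, rng, calib, erp_cfg,
                               dispersed=dispersed, conditions=conditions)
        profiles.append(sub.profile)
        m, log = erp_extract.extract_subject(sub.epochs, min_epochs=min_epochs,
                                             threshold_uv=threshold_uv)
        meas.append(m)
        log.insert(0, "subject", sid)
        rej.append(log)
        bs = task_design.summarize_behavior(sub.outcomes)
        behav.append({"subject_id": sid, "group": group,
                      "median_rt_ms": bs.median_rt_ms, "iqr_rt_ms": bs.iqr_rt_ms,
                      "pct_total_errors": bs.pct_total_errors,
                      "pct_incorrect": bs.pct_incorrect,
                      "pct_missing": bs.pct_missing,
                      "pct_commission": bs.pct_commission})
        if keep_outcomes:
            of = task_design.outcomes_to_frame(sub.outcomes)
            of.insert(0, "subject", sid)
            of.insert(1, "group", group)
            outc.append(of)
        for cond, p in sub.generative_params.items():
            gen.append({"subject_id": sid, "group": group, "condition": cond,
                        "gen_n2_latency_ms": p.n2_latency_ms,
                        "gen_n2_amplitude_uv": p.n2_amplitude_uv,
                        "gen_p3_latency_ms": p.p3_latency_ms,
                        "gen_p3_amplitude_uv": p.p3_amplitude_uv})

    return {
        "profiles": profiles_frame(profiles),
        "measurements": pd.concat(meas, ignore_index=True),
        "behavior": pd.DataFrame(behav),
        "outcomes": pd.concat(outc, ignore_index=True) if outc else None,
        "rejections": pd.concat(rej, ignore_index=True),
        "generative": pd.DataFrame(gen),
    }


# ---------------------------------------------------------------------------
# Parameter-recovery experiments (the headline checks of this package)


def go_cp_measures(measurements: pd.DataFrame) -> pd.DataFrame:
    """Eligible Go-condition centroparietal rows, one per subject."""
    m = measurements
    return m[(m["condition"] == "Go") & (m["pool"] == "centroparietal")
             & m["eligible"]]


def recover_group_medians(group: str, n_subjects: int, seed: int,
                          calib: CohortCalibration | None = None,
                          erp_cfg: ErpGenConfig | None = None) -> dict:
    """Pipeline parameter-recovery for one group.

    Every subject receives the group-default component parameters (no
    between-subject dispersion), so the across-subject medians of the
    extracted pooled CP Go P3 amplitude and N2-P3 IPL estimate how faithfully
    the measurement chain recovers the generative values under default noise
    and artifact rates.
    """
    n_b = n_subjects if group == "burnout" else 0
    n_n = n_subjects if group == "non_burnout" else 0
    res = simulate_and_extract_cohort(n_b, n_n, seed, calib, erp_cfg,
                                      dispersed=False, conditions=("Go",),
                                      keep_outcomes=False)
    go = go_cp_measures(res["measurements"])
    return {
        "group": group,
        "n_subjects": int(len(go)),
        "median_p3_amplitude_uv": float(go["p3_amplitude_uv"].median()),
        "median_ipl_ms": float(go["n2_p3_ipl_ms"].median()),
        "median_p3_latency_ms": float(go["p3_latency_ms"].median()),
    }


def coupling_recovery(n_replicates: int = 50, n_burnout: int = 18,
                      n_non_burnout: int = 17, seed: int = 0,
                      calib: CohortCalibration | None = None,
                      erp_cfg: ErpGenConfig | None = None) -> dict:
    """Spearman-correlation plumbing check.

    For each replicate cohort (dispersed mode, default BBI<->P3 coupling),
    correlate the pipeline-extracted pooled CP Go P3 amplitude with the
    simulated BBI-15 score; report the mean rho across replicates.
    """
    from .group_stats import spearman

    rhos = []
    rep_seeds = np.random.SeedSequence(seed).spawn(n_replicates)
    for child in rep_seeds:
        rep_seed = int(child.generate_state(1)[0] % (2 ** 31))
        res = simulate_and_extract_cohort(n_burnout, n_non_burnout, rep_seed,
                                          calib, erp_cfg, dispersed=True,
                                          conditions=("Go",),
                                          keep_outcomes=False)
        go = go_cp_measures(res["measurements"]).set_index("subject")
        prof = res["profiles"].set_index("subject_id")
        joined = go.join(prof, how="inner")
        rhos.append(spearman(joined["p3_amplitude_uv"], joined["bbi15"]).rho)
    rhos = np.asarray(rhos)
    return {"mean_rho": float(rhos.mean()), "sd_rho": float(rhos.std(ddof=1)),
            "n_replicates": n_replicates,
            "n_per_cohort": n_burnout + n_non_burnout}
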