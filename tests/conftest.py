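import numpy as np
import pandas as pd
import pytest

from burnout_erp.pipeline import simulate_subject
from burnout_erp.synthetic_cohort import ErpGenConfig, default_calibration


def simulate_glmm_trials(rng, n_subjects=50, n_trials=256, beta_group=0.0,
                         re_sd=0.5, base_logit=-3.5):
    """Direct Bernoulli simulation from the random-intercept logistic model
    (the independent oracle for the mixed-model fitter)."""
    rows = []
    for i in range(n_subjects):
        u = re_sd * rng.standard_normal()
        group = "burnout" if i < n_subjects // 2 else "non_burnout"
        g = 0.0 if group == "burnout" else beta_group
        stim = np.tile(["ON", "OFF"], n_trials // 2)
        dist = np.repeat(["emotional", "neutral"], n_trials // 2)
        p = 1 / (1 + np.exp(-(base_logit + g + u)))
        y = rng.random(n_trials) < p
        rows.append(pd.DataFrame({"subject": f"S{i}", "group": group,
                                  "stimulator": stim, "distractor": dist,
                                  "y": y.astype(int)}))
    return pd.concat(rows, ignore_index=True)


@pytest.fixture
def calib():
    return default_calibration()


@pytest.fixture
def noiseless_cfg():
    """Generator config with noise and artifacts switched off."""
    return ErpGenConfig(noise_sd_uv=0.0, blink_rate=0.0)


@pytest.fixture
def noiseless_subject(noiseless_cfg):
    """One burnout subject at the group-default component parameters,
    noise-free (one test block keeps it light)."""
    rng = np.random.default_rng(7)
    return simulate_subject("B01", "burnout", rng, erp_cfg=noiseless_cfg,
                            dispersed=False, n_test_blocks=1,
                            with_artifacts=False)
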