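# burnout-erp

A tested, fully synthetic re-implementation of a Go/NoGo event-related
potential (ERP) biomarker analysis for occupational burnout.

Burnout has no established electrophysiological marker. One candidate line
of evidence comes from the Executive RT test — a Go/NoGo reaction-time task
with emotional distractors — during which EEG shows two classic components:
a frontal-maximal negative deflection (**N2**, cognitive control /
inhibition) and a centroparietal positive deflection (**P3**, attentional
resource allocation). The analysis this package reproduces contrasts a
burnout and a non-burnout group on pooled N2/P3 peak amplitudes and
latencies and on the **N2–P3 interpeak latency** (IPL, per-channel
P3 latency − N2 latency, averaged over a channel pool), and regresses
burnout (BBI-15) and executive-function (BRIEF-A metacognition index)
questionnaire scores on the ERP measures.

The original recordings are not shareable, so everything here runs on a
calibrated synthetic cohort: the package simulates task sessions,
questionnaire profiles, behaviour, and multichannel EEG epochs whose
generative parameters match the published group summaries, then measures
how faithfully the full analysis chain recovers them.

## What is implemented

- `burnout_erp.task_design` — Executive RT trial sequences (64-trial blocks,
  32 Go / 32 NoGo fully crossed with emotional/neutral distractors, Go-rule
  colour reversal per block) and the four-way error taxonomy
  (correct / incorrect / miss / commission).
- `burnout_erp.synthetic_cohort` — subject profiles (BBI-15, BDI-21, BRIEF-A
  T-scores), log-normal RTs, per-trial Bernoulli errors with a per-subject
  random intercept, and EEG epochs: raised-cosine N2/P3 bumps with
  frontal/centroparietal topography, band-limited 1/f noise, blink
  artifacts.
- `burnout_erp.erp_extract` — linked-mastoid re-reference, 0.1–40 Hz
  zero-phase Butterworth band-pass, 80 μV peak-to-peak epoch rejection,
  baseline-corrected condition averaging (≥50 clean epochs), deterministic
  windowed-extremum N2/P3 peak detection, channel-pool averaging and IPL.
- `burnout_erp.group_stats` — Kruskal–Wallis group contrasts, mixed-effects
  logistic error models (random subject intercept, fitted by Gauss–Hermite
  approximate marginal likelihood; cross-checked against `lme4::glmer`),
  Spearman correlations, and the OLS biomarker regressions.
- `burnout_erp.brainvision` / `cli` / `reporting` — BrainVision Core
  (.vhdr/.vmrk/.eeg) interchange, a `burnout-erp` command-line interface,
  and a deterministic end-to-end runner.

The numbered scripts under `analysis/` are thin drivers over the library:
simulate + extract the default 18 + 17 cohort, run the group statistics,
and run the parameter-recovery experiments.

## Worked example

```sh
python analysis/01_simulate_and_extract.py
python analysis/02_group_analysis.py
```

prints (seed 7):

```
simulated + extracted 35 subjects in 20 s
epoch rejection: 510/8960 (5.7%)
ERP-eligible Go averages: 35 subjects
  burnout: median CP Go P3 amplitude 7.54 uV, median CP Go IPL 178.8 ms
  non_burnout: median CP Go P3 amplitude 6.29 uV, median CP Go IPL 124.0 ms
...
CP P3 Go amplitude: burnout median > non-burnout median
```

Here ~6% of epochs are rejected (blinks plus occasional noise excursions
over 80 μV), every subject retains ≥50 clean Go epochs, and the burnout
group shows the expected larger centroparietal Go P3 and longer N2–P3 IPL.
Because this is one 35-subject cohort, single-cohort statistics are noisy;
`analysis/03_parameter_recovery.py` and `analysis/04_correlation_recovery.py`
run the calibrated recovery experiments (group-default subjects, replicate
cohorts) that quantify pipeline accuracy rather than cohort luck.

A quick library-level session:

```python
import numpy as np
from burnout_erp.pipeline import simulate_subject
from burnout_erp.erp_extract import extract_subject

sub = simulate_subject("B01", "burnout", np.random.default_rng(1),
                       dispersed=False)
measures, rejection_log = extract_subject(sub.epochs)
print(measures[["condition", "pool", "p3_amplitude_uv", "n2_p3_ipl_ms"]])
```

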