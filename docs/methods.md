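# Methods

This note documents the generative model, the measurement chain, the
statistical layer, and the design choices taken where the published
description left the design open. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Task model

The Executive RT test is modelled exactly at the design level: a session is
4 practice + 4 test blocks; each block holds 64 trials — a full crossing of
condition (Go/NoGo) × distractor (emotional/neutral) with 16 trials per
cell — in a seeded random order. The block's Go-rule colour (green or red)
alternates between consecutive blocks. A trial runs triangle (150 ms) →
fixation (150 ms) → traffic light; time 0 of every epoch is *trial onset*
(triangle onset), and the Go/NoGo signal appears at +300 ms. Practice
blocks are generated but excluded from every analysis.

Two conventions the published description does not fix:

- **RT reference point.** RTs are measured from traffic-light onset — the
  earliest moment the Go/NoGo decision is possible. Trial-onset timestamps
  are retained, so the convention is switchable.
- **Error-rate denominators.** Incorrect and missing responses are % of Go
  trials, commissions % of NoGo trials, total errors % of all trials,
  matching the domains of the four outcome dichotomisations.

The stimulator ON/OFF flag is carried as metadata only (it alternates by
block half); ON and OFF epochs are averaged in every analysis, so its exact
schedule is analysis-irrelevant.

## Synthetic cohort

### Questionnaires and behaviour

Per-group questionnaire draws are normal with the published ERP-subgroup
means/SDs (e.g. BBI-15 burnout 60.06 ± 10.34, non-burnout 33.06 ± 8.47;
BRIEF-A MI 63.17 ± 9.98 vs 47.47 ± 9.86), clamped to scale bounds
(truncation shifts < 2 % of an SD at these means — ignored). Burnout-construct
scales share a latent factor (loading 0.6) with the BBI deviate so the
questionnaire block co-varies as in the study cohort. The normative
BRIEF-A model is N(50, 10) by definition of T-scores.

Reaction times are log-normal at two levels: subject median RTs are
log-normal around the group median (358 ms burnout / 401 ms non-burnout,
log-SDs derived from the printed IQRs of 81 / 107 ms), and trial RTs are
log-normal around the subject median (log-SD 0.25, a typical within-subject
RT dispersion). Errors are Bernoulli per applicable trial with per-type
base rates set to the printed per-type group medians (burnout:
incorrect 0.98 %, miss 0.21 % of Go; commission 1.17 % of NoGo) and a
per-subject random intercept (SD 0.5 on the logit scale, shared across
types) so the mixed logistic model has a true random effect to recover.
Medians are not additive, so the implied median *total*-error rate
(≈1.2 %) is necessarily below the separately printed total-error median;
the per-type rates were treated as primary.

### EEG epochs

Epochs are 1000 samples at 500 Hz spanning −200…+1798 ms. Each epoch is

    signal(channel, t) = w_N2(ch) · A_N2 · h(t − L_N2; 80 ms)
                       + w_P3(ch) · A_P3 · h(t − L_P3; 150 ms) + noise,

where `h(·; w)` is a unit-peak raised-cosine (Hann) bump of full width `w`.
The compact support and unit peak make generative parameters exactly
recoverable in the noiseless limit, which anchors the oracle tests. The
published description gives no waveform model; the Hann bump is this
package's choice.

Topography: N2 weight 1.0 on the frontal pool (Fz, F1–F4) and 0.45 on the
centroparietal pool (CPz, CP1–CP4); P3 weight 1.0 on CP and 0.55 frontal;
mastoids (TP9/TP10) carry no signal; Fp1 carries 0.2 of each. Both
components are present on both pools because the analysis reports the
N2–P3 IPL on CP channels. Pool-defining weights are exactly 1.0 so the
pooled mean amplitude equals the configured amplitude.

Group/condition component defaults (trial-onset frame):

| group, condition | N2 lat / amp | P3 lat / amp | implied IPL |
|---|---|---|---|
| burnout, Go | 540 ms / −4 μV | 728 ms / **9.89 μV** | 188 ms |
| non-burnout, Go | 544 ms / −4 μV | 680 ms / **6.73 μV** | 136 ms |
| burnout, NoGo | 542 ms / −6 μV | 690 ms / 6.44 μV | 148 ms |
| non-burnout, NoGo | 542 ms / −6 μV | 690 ms / 6.14 μV | 148 ms |

Bold values are the published Go-condition group medians; the Go latencies
were chosen so the implied IPLs match the published 188.2 / 135.0 ms while
P3 single-peak latencies differ far less between groups (matching the null
single-peak latency contrast). Latencies are constrained to the 2-ms sample
grid so noiseless recovery is exact; 545 ms (the natural choice for the
non-burnout N2) is off-grid and is snapped to 544 ms — the earlier
neighbour, consistent with the package-wide earlier-tie-break convention —
making the generative non-burnout IPL 136 ms rather than 135. NoGo N2 is
deeper than Go N2 (inhibition-related frontal negativity); NoGo amplitudes
use the published NoGo medians.

Noise is band-limited 1/f ("pink") noise — power ∝ 1/f between 0.25 and
40 Hz, flat below, zero above — with stationary SD 8 μV per channel,
independent across channels and epochs. Blink artifacts are 250-ms Hann
transients of 120 μV on Fp1 (spread 0.4 to frontal, 0.1 to CP channels) on
a random 5 % of epochs; every blink exceeds the 80 μV rejection criterion
on Fp1 by construction.

### Two generation modes

- **Group defaults** (parameter-recovery experiments): every subject gets
  the table above verbatim; across-subject variation is measurement noise
  only, so recovered medians isolate pipeline bias.
- **Dispersed** (cohort analyses): per-subject parameters are drawn around
  the defaults with between-subject SDs derived from the published IQRs
  (IQR/1.349; e.g. Go P3 amplitude SD 4.22 μV burnout, 2.58 μV
  non-burnout; Go P3 latency SD 63.3 / 36.6 ms), clamped to stay
  window-compatible. The subject's Go P3 amplitude deviate is correlated
  with the BBI-15 deviate at ρ_w = 0.245. This within-group coupling was
  calibrated once, by Monte-Carlo on generative quantities, so that the
  *cohort-level* (18 + 17 pooled) Spearman correlation between generative
  P3 amplitude and BBI-15 equals the published 0.45; the between-group
  separation alone contributes ≈ 0.34 of it.

## Measurement chain

Order: linked-mastoid re-reference → band-pass → rejection → averaging →
peak detection → pooling.

- **Re-reference:** arithmetic mean of TP9/TP10 subtracted from every
  channel.
- **Filter:** 4th-order Butterworth 0.1–40 Hz applied forward–backward
  (`sosfiltfilt`), so it is zero-phase and peak latencies are unshifted.
  The 0.1 Hz edge has an impulse response longer than a 2-s epoch;
  filtering uses maximal odd-extension padding (epoch length − 1) to keep
  edge transients out of the analysis windows. Only the band itself is
  published; the realization is this package's choice.
- **Rejection:** an epoch is dropped iff any channel's within-epoch
  max − min exceeds 80 μV; the log records the offending channel. The
  published ICA-based ocular correction step (commercial software,
  unspecified) is deliberately replaced by threshold rejection alone: the
  synthetic blink model makes the rejected set exactly identifiable, which
  the oracle tests exploit.
- **Averaging:** epochs are baseline-corrected per channel (mean over
  −200…0 ms subtracted), averaged within full condition × distractor ×
  stimulator cells, and cells are combined by *unweighted* sub-average
  means to the Go/NoGo level (ON/OFF and distractor averaging). The
  ≥50-clean-epoch eligibility rule is applied at the Go/NoGo level: a
  session provides at most 32 epochs per 8-way cell, so a stricter
  granularity would be unsatisfiable by design.
- **Peak detection:** N2 = most negative sample in 500–650 ms; P3 = most
  positive sample in [max(600, N2 + 2 ms), 800 ms] (the subsequence
  constraint guarantees P3 follows N2 on every channel). Ties break to the
  earlier sample. This replaces "semiautomatic detection with visual
  inspection" by a fully deterministic rule — a reproducibility decision;
  window endpoints are inclusive and configurable.
- **Pooling:** arithmetic means over the 5-channel pools; IPL is computed
  per channel then averaged (equivalently mean(P3) − mean(N2), by
  linearity — asserted as an invariant).

## Statistics

- **Kruskal–Wallis** (two groups, df = 1, midranks, tie correction) via
  `scipy.stats.kruskal`, kept in the Kruskal–Wallis form rather than the
  equivalent rank-sum test to mirror the original analysis; degenerate
  all-tied input returns H = 0, p = 1 with a flag.
- **Mixed logistic error models:** one model per error type on its
  dichotomisation domain; fixed effects group, stimulator, valence; random
  intercept per subject. No frequentist mixed-logistic fitter exists in the
  installed Python stack, so the marginal likelihood is maximised directly
  by 41-node Gauss–Hermite quadrature (the Laplace-class approximate
  marginal-likelihood contract) with analytic gradients; SEs come from the
  numerical observed information, ORs with Wald 95 % CIs. The test suite
  cross-checks coefficients, SEs and the random-intercept SD against
  `lme4::glmer`. Complete separation (overall or within a predictor level)
  is flagged and the affected CIs reported unbounded.
- **Spearman** via midranks with the t-approximation for p (cohort n ≈ 35);
  an exact full-enumeration permutation p is available behind a flag for
  n ≤ 10.
- **Biomarker regressions:** OLS (statsmodels) of BBI-15 and BRIEF-A MI on
  {P3 amplitude, P3 latency} and {P3 amplitude, IPL}, complete cases only,
  rank-deficient designs refused; reports F(df1, df2), p, R², adjusted R².
  No multiple-testing correction anywhere, mirroring the original analysis;
  p-values are nominal.
- Repeated-measures ANOVA is intentionally not implemented (no such result
  is reported in the analysis being reproduced).

## Problem sizes and experiment design

The recovery experiments use the study's ERP-eligible group sizes (18
burnout, 17 non-burnout). For experiments whose endpoint is the Go average
only (parameter recovery, correlation recovery), EEG is simulated for Go
trials alone — 128 epochs/subject, of which ≈ 121 survive rejection,
comfortably above the 50-epoch minimum. The correlation-recovery experiment
uses 50 replicate cohorts of 35; with a per-cohort rho SD ≈ 0.13 the Monte
Carlo SE of the mean is ≈ 0.02. One master seed fans out to per-subject and
per-replicate child streams (`numpy.random.SeedSequence`), making every
experiment reproducible end-to-end.

## What the generator does and does not emulate

It emulates the design-level structure (trial counts, balance, rule
reversal), group-calibrated questionnaire/behaviour/ERP distributions,
1/f background noise, and super-threshold blinks. It does **not** emulate
volume conduction or realistic source topographies, eye movements other
than blinks, electrode drift or impedance artifacts, practice-block
learning effects, tVNS stimulation effects, or any BBI-15 severity
sub-structure (severity bands are not numerically published; group is an
explicit label). Passing recovery tests therefore demonstrates the
correctness and calibration of the *pipeline* under this generative model,
not the clinical validity of the biomarker on real EEG.

## Known limitations

- Peak picking on noisy averages is a small-sample extreme-value statistic:
  with default noise the extracted amplitude carries a slight positive bias
  and the N2 latency a slight late bias (the N2 search window is asymmetric
  around the bump), visible as a few-ms downward IPL bias in the recovery
  experiments — well inside the stated recovery tolerances.
- The mixed-model fitter supports a single random intercept and two-level
  fixed effects only — exactly the published model family, but nothing
  beyond it.
- BrainVision IO targets the Core format profile this package writes
  (multiplexed IEEE float32, stimulus markers S1–S18); reading arbitrary
  third-party recordings relies on `mne` and the same marker convention.
- The published whole-cohort inferential statistics (χ² values, Table-level
  correlations and R² on the original 35 subjects) depend on unavailable
  raw data; they enter here as calibration constants and directional
  expectations, not as reproduction targets.
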