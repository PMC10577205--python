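"""Preprocessing chain and peak measurement: oracles and invariants."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from burnout_erp import task_design as td
from burnout_erp.containers import (CP_POOL, MONTAGE, EpochSet, ERPAverage,
                                    PeakMeasure, epoch_times)
from burnout_erp.erp_extract import (average_conditions, bandpass,
                                     baseline_correct, detect_peak,
                                     extract_subject, measure_pools,
                                     pool_component, preprocess,
                                     reject_artifacts,
                                     rereference_linked_mastoids)
from burnout_erp.synthetic_cohort import (ComponentParams, ErpGenConfig,
                                          default_calibration,
                                          inject_artifacts, sample_profile,
                                          simulate_epochs)


def _flat_epochs(n_ep=4, fill=0.0):
    times = epoch_times()
    data = np.full((n_ep, len(MONTAGE), times.size), fill, float)
    meta = pd.DataFrame({"condition": ["Go"] * n_ep,
                         "distractor": ["neutral"] * n_ep,
                         "stimulator": ["ON"] * n_ep,
                         "is_practice": False, "blink_injected": False})
    return EpochSet("S", list(MONTAGE), times, data, meta)


class TestRereference:
    def test_constant_mastoids(self):
        ep = _flat_epochs()
        ep.data[:, ep.channel_index("TP9"), :] = 5.0
        ep.data[:, ep.channel_index("TP10"), :] = 5.0
        ep.data[:, ep.channel_index("Fz"), :] = 7.0
        out = rereference_linked_mastoids(ep)
        assert np.allclose(out.data[:, out.channel_index("Fz"), :], 2.0)

    def test_asymmetric_mastoids(self):
        ep = _flat_epochs()
        ep.data[:, ep.channel_index("TP9"), :] = 4.0
        ep.data[:, ep.channel_index("TP10"), :] = 6.0
        ep.data[:, ep.channel_index("Fz"), :] = 10.0
        out = rereference_linked_mastoids(ep)
        assert np.allclose(out.data[:, out.channel_index("Fz"), :], 5.0)

    def test_mastoid_pair_mean_zero(self):
        ep = _flat_epochs()
        ep.data[:] = np.random.default_rng(0).normal(size=ep.data.shape)
        out = rereference_linked_mastoids(ep)
        pair = (out.data[:, out.channel_index("TP9"), :]
                + out.data[:, out.channel_index("TP10"), :])
        assert np.allclose(pair, 0.0, atol=1e-12)

    def test_missing_mastoid_raises(self):
        ep = _flat_epochs()
        ep.channels[ep.channel_index("TP9")] = "XX"
        with pytest.raises(ValueError):
            rereference_linked_mastoids(ep)


class TestBandpass:
    def _sine(self, freq, amp=10.0):
        ep = _flat_epochs(n_ep=2)
        t_s = (ep.times - ep.times[0]) / 1000.0
        ep.data[:] = amp * np.sin(2 * np.pi * freq * t_s)
        return ep

    def test_passband_preserved(self):
        ep = self._sine(10.0)
        out = bandpass(ep)
        mid = slice(200, 800)
        ratio = out.data[0, 0, mid].std() / ep.data[0, 0, mid].std()
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_stopband_attenuated(self):
        """100 Hz amplitude reduced by >= 90% (quadrature projection on the
        epoch interior isolates the 100 Hz component from edge transients)."""
        ep = self._sine(100.0)
        out = bandpass(ep)
        t_s = (ep.times - ep.times[0]) / 1000.0
        mid = slice(200, 800)

        def amp_at(x):
            c = np.cos(2 * np.pi * 100 * t_s[mid])
            s = np.sin(2 * np.pi * 100 * t_s[mid])
            return 2 * np.hypot(np.mean(x[mid] * c), np.mean(x[mid] * s))

        assert amp_at(out.data[0, 0]) < 0.1 * amp_at(ep.data[0, 0])

    def test_dc_removed(self):
        ep = _flat_epochs(fill=50.0)
        out = bandpass(ep)
        assert np.abs(out.data[0, 0, 100:900]).max() < 1.0

    @pytest.mark.parametrize("band", [(0.0, 40.0), (40.0, 0.1), (0.1, 300.0)])
    def test_invalid_edges(self, band):
        with pytest.raises(ValueError):
            bandpass(_flat_epochs(), *band)

    def test_zero_phase_no_latency_shift(self, noiseless_subject):
        """Filtering leaves the noiseless P3 peak latency untouched."""
        ep = noiseless_subject.epochs
        filt = bandpass(ep)
        cp = ep.channel_index("CPz")
        go = np.flatnonzero((ep.metadata["condition"] == "Go").to_numpy())[0]
        assert np.argmax(filt.data[go, cp]) == np.argmax(ep.data[go, cp])


class TestRejectArtifacts:
    def test_blink_rejected_flat_retained(self):
        ep = _flat_epochs(n_ep=3)
        fp1 = ep.channel_index("Fp1")
        ep.data[1, fp1, 400:420] = 100.0     # 100 uV transient
        kept, log = reject_artifacts(ep)
        assert kept.n_epochs == 2
        assert log.loc[1, "rejected"] and log.loc[1, "offending_channel"] == "Fp1"
        assert not log.loc[0, "rejected"]

    def test_rejection_equals_injection_oracle(self, noiseless_cfg):
        """With zero noise, the rejected set is exactly the injected-blink set."""
        cfg = dataclasses.replace(noiseless_cfg, blink_rate=0.2)
        calib = default_calibration()
        prof = sample_profile("burnout", calib, np.random.default_rng(0), "S")
        trials = td.generate_session(1, 0, 2)
        ep = simulate_epochs(prof, trials, cfg, np.random.default_rng(0))
        ep = inject_artifacts(ep, cfg, np.random.default_rng(5))
        kept, log = reject_artifacts(ep)
        assert (log["rejected"].to_numpy()
                == ep.metadata["blink_injected"].to_numpy()).all()
        assert not kept.metadata["blink_injected"].any()

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(1)
        ep = _flat_epochs(n_ep=30)
        ep.data[:] = rng.normal(scale=25.0, size=ep.data.shape)
        kept_counts = [reject_artifacts(ep, thr)[0].n_epochs
                       for thr in (200.0, 120.0, 80.0, 40.0)]
        assert kept_counts == sorted(kept_counts, reverse=True)

    def test_nonpositive_threshold(self):
        with pytest.raises(ValueError):
            reject_artifacts(_flat_epochs(), 0.0)


class TestAverageConditions:
    def test_identical_epochs_average(self, noiseless_subject):
        ep = noiseless_subject.epochs
        avgs = average_conditions(ep, min_epochs=1)
        go_rows = (ep.metadata["condition"] == "Go").to_numpy()
        expected = baseline_correct(ep.data[go_rows][0], ep.times)
        np.testing.assert_allclose(avgs["Go"].data, expected, atol=1e-10)

    def test_min_epochs_eligibility(self):
        ep = _flat_epochs(n_ep=49)
        avgs = average_conditions(ep, min_epochs=50)
        assert not avgs["Go"].eligible
        avgs = average_conditions(ep, min_epochs=49)
        assert avgs["Go"].eligible

    def test_baseline_mean_zero(self, noiseless_subject):
        avgs = average_conditions(noiseless_subject.epochs, min_epochs=1)
        t = avgs["Go"].times
        base = avgs["Go"].data[:, (t >= -200) & (t < 0)]
        assert np.abs(base.mean(axis=1)).max() < 1e-9

    def test_clt_noise_scaling(self):
        rng = np.random.default_rng(2)
        ep = _flat_epochs(n_ep=400)
        ep.data[:] = rng.normal(size=ep.data.shape)
        single_rms = np.sqrt(np.mean(ep.data[0] ** 2))
        avg = average_conditions(ep, min_epochs=1)["Go"]
        avg_rms = np.sqrt(np.mean(avg.data ** 2))
        assert avg_rms == pytest.approx(single_rms / np.sqrt(400), rel=0.25)

    def test_empty_after_exclusion_raises(self):
        ep = _flat_epochs(n_ep=4)
        ep.metadata["is_practice"] = True
        with pytest.raises(ValueError):
            average_conditions(ep)


def _avg_from_trace(trace_fn):
    times = epoch_times()
    data = np.zeros((len(MONTAGE), times.size))
    data[:] = trace_fn(times)[None, :]
    return ERPAverage("S", "Go", list(MONTAGE), times, data, n_epochs=100)


class TestDetectPeak:
    def test_noiseless_recovery(self):
        def trace(t):
            x = np.zeros_like(t)
            x[(t >= 535) & (t <= 545)] = -4.0
            x[(t >= 720) & (t <= 735)] = 6.0
            return x
        avg = _avg_from_trace(trace)
        n2 = detect_peak(avg, "Fz", "N2")
        # plateau covers grid samples 536..544; ties break to the earliest
        assert (n2.latency_ms, n2.amplitude_uv) == (536.0, -4.0)
        p3 = detect_peak(avg, "Fz", "P3")
        assert (p3.latency_ms, p3.amplitude_uv) == (720.0, 6.0)

    def test_tie_breaks_earlier(self):
        def trace(t):
            x = np.zeros_like(t)
            x[t == 700] = 5.0
            x[t == 750] = 5.0
            return x
        p3 = detect_peak(_avg_from_trace(trace), "CPz", "P3")
        assert p3.latency_ms == 700.0

    def test_p3_subsequence_constraint(self):
        """A positive maximum at/before the N2 sample is not a valid P3."""
        def trace(t):
            x = np.zeros_like(t)
            x[t == 640] = -3.0       # N2 late in its window
            x[t == 610] = 9.0        # big early positivity, before N2
            x[t == 700] = 4.0
            return x
        avg = _avg_from_trace(trace)
        assert detect_peak(avg, "CPz", "N2").latency_ms == 640.0
        assert detect_peak(avg, "CPz", "P3").latency_ms == 700.0

    def test_exhaustive_scan_oracle(self):
        """Windowed extremum equals a brute-force scan on random waveforms."""
        rng = np.random.default_rng(3)
        times = epoch_times()
        n2_win = np.flatnonzero((times >= 500) & (times <= 650))
        for _ in range(1000):
            trace = rng.normal(size=times.size)
            data = np.tile(trace, (len(MONTAGE), 1))
            avg = ERPAverage("S", "Go", list(MONTAGE), times, data, 100)
            n2 = detect_peak(avg, "Fz", "N2")
            p3 = detect_peak(avg, "Fz", "P3")
            # oracle: exhaustive scan
            i_n2 = min(n2_win, key=lambda i: (trace[i], i))
            assert times[i_n2] == n2.latency_ms
            assert trace[i_n2] == n2.amplitude_uv
            p3_lo = max(600.0, times[i_n2] + 2.0)
            p3_win = [i for i in range(times.size)
                      if p3_lo <= times[i] <= 800.0]
            i_p3 = max(p3_win, key=lambda i: (trace[i], -i))
            assert times[i_p3] == p3.latency_ms
            assert trace[i_p3] == p3.amplitude_uv
            assert p3.latency_ms > n2.latency_ms


class TestPooling:
    def _measures(self, lat_pairs):
        n2s, p3s = [], []
        for ch, (n2_lat, p3_lat) in zip(CP_POOL, lat_pairs):
            n2s.append(PeakMeasure("N2", ch, n2_lat, -3.0))
            p3s.append(PeakMeasure("P3", ch, p3_lat, 8.0))
        return n2s, p3s

    def test_uniform_latencies(self):
        n2s, p3s = self._measures([(540, 728)] * 5)
        pc = pool_component(n2s, p3s, "centroparietal")
        assert pc.n2_p3_ipl_ms == pytest.approx(188.0)
        assert pc.p3_amplitude_uv == 8.0 and pc.n2_amplitude_uv == -3.0

    def test_ipl_equals_mean_difference(self):
        pairs = [(530, 700), (540, 710), (550, 760), (535, 705), (545, 745)]
        n2s, p3s = self._measures(pairs)
        pc = pool_component(n2s, p3s, "centroparietal")
        mean_diff = np.mean([p - n for n, p in pairs])
        assert pc.n2_p3_ipl_ms == pytest.approx(mean_diff)
        assert pc.n2_p3_ipl_ms == pytest.approx(pc.p3_latency_ms - pc.n2_latency_ms)

    def test_missing_channel_raises(self):
        n2s, p3s = self._measures([(540, 728)] * 5)
        with pytest.raises(ValueError):
            pool_component(n2s[:-1], p3s, "centroparietal")


class TestPipelineInvariants:
    def test_rereference_baseline_commute(self, noiseless_subject):
        ep = noiseless_subject.epochs.copy()
        rng = np.random.default_rng(0)
        ep.data += rng.normal(scale=3.0, size=ep.data.shape)
        a = baseline_correct(rereference_linked_mastoids(ep).data, ep.times)
        ref = rereference_linked_mastoids(ep)
        ref.data = baseline_correct(ref.data, ep.times)
        b0 = ep.copy()
        b0.data = baseline_correct(b0.data, ep.times)
        b = baseline_correct(rereference_linked_mastoids(b0).data, ep.times)
        np.testing.assert_allclose(a, b, atol=1e-9)

    @pytest.mark.parametrize("group,cond,exp_amp,exp_lat_n2,exp_lat_p3", [
        ("burnout", "Go", 9.89, 540.0, 728.0),
        ("non_burnout", "Go", 6.73, 544.0, 680.0),
    ])
    def test_noiseless_end_to_end_recovery(self, noiseless_cfg, group, cond,
                                           exp_amp, exp_lat_n2, exp_lat_p3):
        """Noise off: generative amplitudes recovered exactly (without the
        band-pass) and within 2% with it; latencies within one sample."""
        from burnout_erp.pipeline import simulate_subject
        sub = simulate_subject("S", group, np.random.default_rng(0),
                               erp_cfg=noiseless_cfg, dispersed=False,
                               n_test_blocks=1, with_artifacts=False)
        # exact route: no filter
        ep = rereference_linked_mastoids(sub.epochs)
        pc = measure_pools(average_conditions(ep, min_epochs=1)[cond])["centroparietal"]
        assert pc.p3_amplitude_uv == pytest.approx(exp_amp, abs=1e-9)
        assert pc.p3_latency_ms == exp_lat_p3
        # latency within one sample (generative value may sit off-grid)
        assert abs(pc.n2_latency_ms - exp_lat_n2) <= 2.0
        # full chain with zero-phase filter: amplitude within 2%, latency +-2 ms
        m, _ = extract_subject(sub.epochs, min_epochs=1)
        row = m[(m.condition == cond) & (m.pool == "centroparietal")].iloc[0]
        assert row.p3_amplitude_uv == pytest.approx(exp_amp, rel=0.02)
        assert abs(row.p3_latency_ms - exp_lat_p3) <= 2.0
        assert abs(row.n2_p3_ipl_ms - (exp_lat_p3 - exp_lat_n2)) <= 4.0

    def test_ineligible_condition_flagged(self, noiseless_subject):
        m, _ = extract_subject(noiseless_subject.epochs, min_epochs=50)
        # one block: 32 Go epochs < 50
        assert not m["eligible"].any()
        m2, _ = extract_subject(noiseless_subject.epochs, min_epochs=30)
        assert m2["eligible"].all()
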