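import numpy as np
import pytest
from dataclasses import replace

import sahpkit as sk
from sahpkit.spikes import (
    smooth, detect_spikes, spike_threshold, spike_waveform_features,
    train_stats, sweep_spike_analysis, first_spike_cell_average,
    pre_step_baseline, SpikeFeatures,
)

from _oracles import smooth_midpoint_ols, scan_spike_features
from conftest import make_cell


def _flat_trace(proto, level=-70.0):
    t = proto.time_grid()
    return sk.VoltageTrace(time=t, voltage=np.full_like(t, level),
                           protocol=proto)


class TestSmooth:
    def test_constant_unchanged(self, proto_10k):
        tr = _flat_trace(proto_10k)
        out = smooth(tr, 1.0)
        np.testing.assert_allclose(out.voltage, tr.voltage, atol=1e-12)

    def test_exact_ramp_unchanged(self, proto_10k):
        t = proto_10k.time_grid()
        tr = sk.VoltageTrace(time=t, voltage=-70.0 + 3.0 * t,
                             protocol=proto_10k)
        np.testing.assert_allclose(smooth(tr, 1.0).voltage, tr.voltage,
                                   atol=1e-9)

    def test_equals_per_window_ols_midpoint(self, proto_10k):
        rng = np.random.default_rng(3)
        t = proto_10k.time_grid()[:600]
        proto = replace(proto_10k, record_dur=50.0, zero_current_dur=10.0,
                        hyper_onset=5.0, hyper_step_dur=10.0,
                        depol_onset=20.0, depol_step_dur=20.0)
        v = rng.standard_normal(len(t))
        tr = sk.VoltageTrace(time=t, voltage=v, protocol=proto)
        out = smooth(tr, 1.0)  # 11 samples at 10 kHz
        brute = smooth_midpoint_ols(v, 11)
        np.testing.assert_allclose(out.voltage[5:-5], brute[5:-5], atol=1e-10)

    def test_window_shorter_than_3_samples_rejected(self, proto_10k):
        tr = _flat_trace(proto_10k)
        with pytest.raises(ValueError, match="fewer than 3"):
            smooth(tr, 0.1)


class TestDetectSpikes:
    def test_flat_trace_yields_nothing(self, proto):
        assert len(detect_spikes(_flat_trace(proto))) == 0

    def test_amplitude_criterion_rejects_small_bumps(self, proto_short):
        """3 bumps of +50 mV and 1 of +30 mV: exactly 3 detections."""
        t = proto_short.time_grid()
        v = np.full_like(t, -70.0)
        times_ms = [750.0, 800.0, 850.0]
        for tm in times_ms + [900.0]:
            height = 50.0 if tm in times_ms else 30.0
            v += height * np.exp(-0.5 * ((t - tm / 1000.0) / 0.0004) ** 2)
        tr = sk.VoltageTrace(time=t, voltage=v, protocol=proto_short)
        det = detect_spikes(tr)
        assert len(det) == 3
        dt_ms = 1000.0 / proto_short.sampling_rate
        np.testing.assert_allclose(det, times_ms, atol=dt_ms + 1e-9)

    def test_counts_match_generator_across_family(self, proto_short):
        for seed in range(3):
            for step in sk.DEPOL_STEP_GRID:
                p = replace(proto_short, depol_step_amp=float(step))
                tr, gt = sk.generate_trace(
                    p, sk.TraceGenParams(noise_sd=0.3, seed=seed))
                det = detect_spikes(smooth(tr, 1.0))
                assert len(det) == gt.n_spikes
                np.testing.assert_allclose(
                    det / 1000.0, gt.spike_times, atol=5e-4)


class TestSpikeThreshold:
    def test_piecewise_linear_breakpoint_exact(self, proto_short):
        """Ramp at 10 mV/ms breaking to 25 mV/ms: threshold at the
        breakpoint sample (raw trace, no smoothing smear)."""
        fs = proto_short.sampling_rate
        t = proto_short.time_grid()
        v = np.full_like(t, -70.0)
        t_bp = 0.75  # s, inside the depolarizing step
        pre = (t >= t_bp - 0.002) & (t < t_bp)
        post = (t >= t_bp) & (t < t_bp + 0.004)
        v[pre] = -70.0 + 10.0 * (t[pre] - (t_bp - 0.002)) * 1000.0
        v_bp = -70.0 + 20.0
        v[post] = v_bp + 25.0 * (t[post] - t_bp) * 1000.0
        after = t >= t_bp + 0.004
        v[after] = v[post][-1]
        tr = sk.VoltageTrace(time=t, voltage=v, protocol=proto_short)
        peak_ms = (t_bp + 0.004) * 1000.0
        th_v, th_t = spike_threshold(tr, peak_ms, _smoothed=tr)
        assert th_t == pytest.approx(t_bp * 1000.0, abs=1000.0 / fs + 1e-9)
        assert th_v == pytest.approx(v_bp, abs=25.0 / fs * 1000.0 * 2)

    def test_matches_brute_force_scan(self, proto_short):
        tr, gt = sk.generate_trace(proto_short,
                                   sk.TraceGenParams(noise_sd=0.2, seed=5))
        sm = smooth(tr, 0.2)
        fs = sm.sampling_rate
        for tp in gt.spike_times * 1000.0:
            th_v, th_t = spike_threshold(tr, tp, _smoothed=sm)
            ref = scan_spike_features(sm.time * 1000.0, sm.voltage,
                                      int(round(tp / 1000.0 * fs)))
            assert th_v == pytest.approx(ref["threshold_v"], abs=0.5)
            assert th_t == pytest.approx(ref["threshold_t"],
                                         abs=2 * 1000.0 / fs)

    def test_recovers_generated_threshold_within_1mV(self, proto_short):
        for seed in range(5):
            tr, gt = sk.generate_trace(
                proto_short, sk.TraceGenParams(noise_sd=0.1, seed=seed))
            sm = smooth(tr, 0.2)
            for tp in gt.spike_times * 1000.0:
                th_v, _ = spike_threshold(tr, tp, _smoothed=sm)
                assert th_v == pytest.approx(
                    gt.params.spike_shape.threshold, abs=1.0)

    def test_subthreshold_slope_flagged_missing(self, proto_short):
        tr = _flat_trace(proto_short)
        th_v, th_t = spike_threshold(tr, 800.0, _smoothed=tr)
        assert np.isnan(th_v) and np.isnan(th_t)


class TestWaveformFeatures:
    def test_triangular_spike_closed_form(self, proto_short):
        """Linear rise 0→100 mV over 1 ms, fall over 2 ms, threshold 0:
        rise 600 µs, slope 100 mV/ms, half-width 1.5 ms by geometry."""
        t = proto_short.time_grid()
        v = np.zeros_like(t)
        t0, peak_s = 0.75, 0.751
        rise = (t >= t0) & (t < peak_s)
        fall = (t >= peak_s) & (t < peak_s + 0.002)
        v[rise] = 100.0 * (t[rise] - t0) * 1000.0
        v[fall] = 100.0 * (1.0 - (t[fall] - peak_s) * 1000.0 / 2.0)
        tr = sk.VoltageTrace(time=t, voltage=v, protocol=proto_short)
        f = spike_waveform_features(tr, peak_s * 1000.0, _smoothed=tr)
        dt_us = 1e6 / proto_short.sampling_rate
        assert f.threshold_v == pytest.approx(0.0, abs=0.2)
        assert f.rise_time_20_80 == pytest.approx(600.0, abs=2 * dt_us)
        assert f.rising_slope == pytest.approx(100.0, rel=0.05)
        assert f.half_width == pytest.approx(1.5, abs=0.01)

    def test_template_features_match_brute_force(self, proto_short):
        tr, gt = sk.generate_trace(proto_short,
                                   sk.TraceGenParams(noise_sd=0.1, seed=2))
        sm = smooth(tr, 0.2)
        fs = sm.sampling_rate
        dt_ms = 1000.0 / fs
        for tp in gt.spike_times * 1000.0:
            f = spike_waveform_features(tr, tp, _smoothed=sm)
            i_pk = int(round(f.t_peak / 1000.0 * fs))
            ref = scan_spike_features(sm.time * 1000.0, sm.voltage, i_pk)
            assert f.rise_time_20_80 == pytest.approx(
                ref["rise_time_20_80"], abs=dt_ms * 1000.0)
            assert f.half_width == pytest.approx(ref["half_width"],
                                                 abs=dt_ms)
            assert f.v_peak == pytest.approx(ref["v_peak"], abs=0.2)

    def test_offset_invariance(self, proto_short):
        tr, gt = sk.generate_trace(proto_short, sk.TraceGenParams(seed=3))
        shifted = replace(tr, voltage=tr.voltage + 7.5)
        tp = gt.spike_times[0] * 1000.0
        f0 = spike_waveform_features(tr, tp)
        f1 = spike_waveform_features(shifted, tp)
        assert f1.v_peak - f0.v_peak == pytest.approx(7.5, abs=1e-6)
        assert f1.threshold_v - f0.threshold_v == pytest.approx(7.5, abs=1e-6)
        for name in ("amplitude", "rise_time_20_80", "rising_slope",
                     "half_width"):
            assert getattr(f1, name) == pytest.approx(getattr(f0, name),
                                                      rel=1e-9)

    def test_realistic_template_geometry(self, proto_short):
        """Default templates land in the physiological feature ranges."""
        tr, gt = sk.generate_trace(proto_short,
                                   sk.TraceGenParams(noise_sd=0.0, seed=0))
        f = spike_waveform_features(tr, gt.spike_times[0] * 1000.0)
        assert 100 < f.rise_time_20_80 < 400
        assert 0.8 < f.half_width < 2.0
        assert 45 < f.amplitude < 75


class TestTrainStats:
    @pytest.mark.parametrize("times, accommodation", [
        ([0.0, 10.0, 20.0, 30.0], 100.0),
        ([0.0, 10.0, 25.0, 45.0], 200.0),
    ])
    def test_accommodation_arithmetic(self, times, accommodation):
        st = train_stats(np.array(times))
        assert st.accommodation_pct == pytest.approx(accommodation)
        assert st.n_spikes == len(times)
        assert len(st.isis) == len(times) - 1

    def test_two_spikes_accommodation_missing(self):
        st = train_stats(np.array([0.0, 12.0]))
        assert np.isnan(st.accommodation_pct)
        assert st.first_isi == st.last_isi == 12.0

    def test_empty_and_single(self):
        assert train_stats(np.array([])).n_spikes == 0
        st = train_stats(np.array([5.0]))
        assert st.n_spikes == 1 and len(st.isis) == 0
        assert np.isnan(st.mean_isi)

    def test_recovers_generator_adaptation(self, proto_short):
        """Measured accommodation tracks the generative ratio within 5%
        whenever the train has >= 4 spikes."""
        for step in (250, 350, 450):
            p = replace(proto_short, depol_step_amp=float(step))
            tr, gt = sk.generate_trace(
                p, sk.TraceGenParams(noise_sd=0.2, seed=1,
                                     isi_adaptation=2.0))
            if gt.n_spikes < 4:
                continue
            _, st = sweep_spike_analysis(tr)
            assert st.accommodation_pct == pytest.approx(200.0, rel=0.05)


class TestCellAverage:
    def test_arithmetic_mean_of_first_spikes(self):
        per_step = {
            150.0: [SpikeFeatures(rise_time_20_80=150.0, half_width=1.0)],
            175.0: [SpikeFeatures(rise_time_20_80=170.0, half_width=1.2)],
            200.0: [],
        }
        cell = sk.CellRecord(cell_id="c")
        avg = first_spike_cell_average(cell, per_step=per_step)
        assert avg.rise_time_20_80 == pytest.approx(160.0)
        assert avg.half_width == pytest.approx(1.1)

    def test_no_spikes_yields_all_missing(self):
        cell = sk.CellRecord(cell_id="c")
        avg = first_spike_cell_average(cell, per_step={150.0: []})
        assert all(np.isnan(getattr(avg, n)) for n in SpikeFeatures._FIELDS)

    def test_identical_spikes_average_to_single_value(self, proto_short):
        params = sk.TraceGenParams(noise_sd=0.0, seed=0)
        cell = make_cell(proto_short, params, steps=[300, 325])
        avg = first_spike_cell_average(cell)
        one = sweep_spike_analysis(cell.sweeps[300.0])[0][0]
        assert avg.threshold_v == pytest.approx(one.threshold_v, abs=0.3)
        assert avg.half_width == pytest.approx(one.half_width, abs=0.05)


def test_no_spurious_detections_in_noise(proto_short):
    """At noise_sd <= 0.5 mV detection is exhaustive and exact across the
    step family."""
    for seed in range(3):
        for step in (150, 300, 450):
            p = replace(proto_short, depol_step_amp=float(step))
            tr, gt = sk.generate_trace(
                p, sk.TraceGenParams(noise_sd=0.5, seed=seed))
            det = detect_spikes(smooth(tr, 1.0))
            assert len(det) == gt.n_spikes
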