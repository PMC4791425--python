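"""Action-potential and synaptic feature extraction."""

import numpy as np
import pytest

from patchseq.ephys import (ap_shape_features, ap_threshold,
                            build_parameter_table, detect_psc_events,
                            detect_spikes, extract_features, firing_rate,
                            input_resistance, na_current_amplitude,
                            read_parameter_table, write_parameter_table,
                            PARAM_COLUMNS)
from patchseq.simulate import simulate_sweeps
from patchseq.sweeps import SweepSet

from conftest import toy_sweepset

FS = 100000.0  # dense time base for hand-built waveforms


def _ramp_trace(t, v_points):
    """Piecewise-linear voltage through (time_s, mV) anchor points."""
    ts, vs = zip(*v_points)
    return np.interp(t, ts, vs)


class TestDetectSpikes:
    def test_flat_trace_has_no_spikes(self):
        t = np.arange(5000) / FS
        assert detect_spikes(t, np.full(t.size, -65.0), 10.0).size == 0

    def test_single_synthetic_ap_peaks_once(self):
        t = np.arange(5000) / FS
        v = _ramp_trace(t, [(0, -65), (0.02, -65), (0.021, 30),
                            (0.023, -65), (0.05, -65)])
        peaks = detect_spikes(t, v, 10.0)
        assert peaks.size == 1
        assert peaks[0] == np.argmax(v)

    def test_simulator_planted_count_recovered_exactly(self):
        ss, gt = simulate_sweeps(0.8, seed=1, cell_id="c")
        target = max(range(len(gt["spike_counts"])),
                     key=lambda i: gt["spike_counts"][i])
        peaks = detect_spikes(ss.time, ss.voltage[target], 10.0)
        assert peaks.size == gt["spike_counts"][target] > 0

    def test_nonuniform_time_base_rejected(self):
        t = np.concatenate([np.arange(100) / FS, [0.002, 0.005]])
        with pytest.raises(ValueError, match="non-uniform"):
            detect_spikes(t, np.full(t.size, -65.0), 10.0)


class TestAPThreshold:
    def test_constructed_crossing_voltage(self):
        # dV/dt steps 5 -> 20 mV/ms exactly at -40 mV
        t = np.arange(2000) / FS
        v = _ramp_trace(t, [(0, -50), (0.002, -40), (0.0055, 30),
                            (0.008, -50), (0.02, -50)])
        peak = int(np.argmax(v))
        assert ap_threshold(t, v, peak, 10.0) == pytest.approx(-40.0,
                                                               abs=0.05)

    def test_unreachable_slope_criterion_is_nd(self):
        t = np.arange(2000) / FS
        v = _ramp_trace(t, [(0, -50), (0.002, -40), (0.0055, 30),
                            (0.008, -50), (0.02, -50)])
        assert np.isnan(ap_threshold(t, v, int(np.argmax(v)), 1e5))

    def test_simulator_threshold_within_1mv(self):
        ss, gt = simulate_sweeps(0.5, seed=1, cell_id="c")
        feats = extract_features(ss)
        assert feats["threshold"] == pytest.approx(
            gt["params"]["threshold"], abs=1.0)


class TestAPShape:
    def _triangle(self):
        # linear rise -50 -> +30 at 70 mV/ms, symmetric fall; the apex sits
        # exactly on a sample so peak - threshold is exact
        t = np.arange(4000) / FS
        rise = 80.0 / 70.0 * 1e-3
        apex = 0.012  # = sample 1200 at FS
        v = _ramp_trace(t, [(0, -50), (apex - rise, -50), (apex, 30),
                            (apex + rise, -50), (0.04, -50)])
        return t, v, int(np.argmax(v))

    def test_amplitude_is_peak_minus_threshold(self):
        t, v, peak = self._triangle()
        _, amp, _ = ap_shape_features(t, v, peak, -40.0)
        assert amp == pytest.approx(70.0, abs=0.1)

    def test_symmetric_triangle_rise_and_halfwidth(self):
        t, v, peak = self._triangle()
        rise, _, hw = ap_shape_features(t, v, peak, -40.0)
        assert rise == pytest.approx(1.0, abs=0.02)
        assert hw == pytest.approx(1.0, abs=0.02)

    def test_truncated_sweep_gives_nd_halfwidth(self):
        t, v, peak = self._triangle()
        rise, amp, hw = ap_shape_features(t[:peak + 1], v[:peak + 1],
                                          peak, -40.0)
        assert rise == pytest.approx(1.0, abs=0.02)
        assert amp == pytest.approx(70.0, abs=0.1)
        assert np.isnan(hw)

    def test_threshold_must_be_below_peak(self):
        t, v, peak = self._triangle()
        with pytest.raises(ValueError):
            ap_shape_features(t, v, peak, 40.0)


class TestFiringRate:
    def test_best_sweep_count_over_pulse_duration(self):
        ss = toy_sweepset([0, 4, 10])
        assert firing_rate(ss) == pytest.approx(20.0)

    def test_spikeless_cell_rate_zero(self):
        assert firing_rate(toy_sweepset([0, 0, 0])) == 0.0

    def test_unexcitable_flag_gives_nd(self):
        ss = toy_sweepset([0, 0])
        ss.unexcitable = True
        assert np.isnan(firing_rate(ss))

    def test_simulator_rate_matches_planted_count(self):
        ss, gt = simulate_sweeps(0.95, seed=2, cell_id="c")
        assert firing_rate(ss) == pytest.approx(gt["spike_count_max"] / 0.5)


class TestInputResistance:
    def test_deflection_over_current(self):
        ss = toy_sweepset([0], stim_amps=[-20.0], rin_mohm=200.0)
        assert input_resistance(ss) == pytest.approx(200.0, rel=1e-6)

    def test_scales_with_current_level(self):
        ss = toy_sweepset([0], stim_amps=[-50.0], rin_mohm=200.0)
        assert input_resistance(ss) == pytest.approx(200.0, rel=1e-6)

    def test_zero_first_level_is_undefined(self):
        ss = toy_sweepset([0], stim_amps=[0.0], rin_mohm=200.0)
        with pytest.raises(ValueError, match="undefined Rin"):
            input_resistance(ss)

    def test_simulated_passive_cell_within_5pct(self):
        ss, gt = simulate_sweeps(1.0, seed=3, cell_id="c")  # Rin ~150 MΩ
        assert input_resistance(ss) == pytest.approx(gt["params"]["rin"],
                                                     rel=0.05)


class TestPSCDetection:
    @staticmethod
    def _vc_trace(event_times, amp=30.0, tau_decay_ms=5.0, noise=0.0,
                  seed=0, duration=10.0, fs=5000.0):
        rng = np.random.default_rng(seed)
        t = np.arange(int(duration * fs)) / fs
        i = noise * rng.standard_normal(t.size)
        w = np.arange(int(0.1 * fs)) / fs * 1e3
        tpl = np.exp(-w / tau_decay_ms) - np.exp(-w / 1.0)
        tpl /= tpl.max()
        for t0 in event_times:
            j = int(t0 * fs)
            i[j:j + tpl.size] -= amp * tpl[:t.size - j]
        return t, i

    def test_flat_trace_has_no_events(self):
        t, i = self._vc_trace([])
        times, freq, classes = detect_psc_events(t, i)
        assert freq == 0.0 and len(classes) == 0

    def test_five_events_in_ten_seconds(self):
        t, i = self._vc_trace([1.0, 3.0, 5.0, 7.0, 9.0])
        times, freq, classes = detect_psc_events(t, i)
        assert len(times) == 5
        assert freq == pytest.approx(0.5)

    def test_decay_kinetics_classification(self):
        t, i = self._vc_trace([2.0, 6.0], tau_decay_ms=5.0)
        _, _, fast = detect_psc_events(t, i)
        t, i = self._vc_trace([2.0, 6.0], tau_decay_ms=25.0)
        _, _, slow = detect_psc_events(t, i)
        assert fast == ["epsc", "epsc"]
        assert slow == ["ipsc", "ipsc"]

    def test_snr5_recovery_with_at_most_one_false_positive(self):
        ss, gt = simulate_sweeps(0.9, seed=3, cell_id="c")  # amp/noise ~ 5
        t, i = ss.vc_trace
        times, _, _ = detect_psc_events(t, i)
        planted = np.array([e["time"] for e in gt["events"]])
        matched = sum(np.any(np.abs(times - p) < 0.01) for p in planted)
        assert matched >= 0.9 * planted.size
        assert len(times) - matched <= 1

    def test_short_trace_warns_but_computes(self):
        t, i = self._vc_trace([0.2], duration=0.5)
        with pytest.warns(UserWarning, match="shorter than 1 s"):
            _, freq, _ = detect_psc_events(t, i)
        assert freq > 0


class TestNaCurrent:
    def test_single_dip_magnitude(self):
        t = np.arange(1000) / 5000.0
        i = -800.0 * np.exp(-0.5 * ((t - 0.1) / 0.0015) ** 2)
        assert na_current_amplitude(t, i) == pytest.approx(800.0, rel=0.01)

    def test_monotone_outward_trace_is_nd(self):
        t = np.arange(1000) / 5000.0
        assert np.isnan(na_current_amplitude(t, 1200.0 * t / 0.2))

    def test_missing_trace_is_nd(self):
        assert np.isnan(na_current_amplitude(None, None))

    def test_simulated_ramp_within_5pct(self):
        # planted inward peak ~1200 pA on a rising outward ramp with noise
        ss, gt = simulate_sweeps(0.55, seed=4, cell_id="c")
        na = na_current_amplitude(*ss.ramp_trace)
        assert na == pytest.approx(gt["params"]["na_current"], rel=0.05)


class TestParameterTable:
    def _rows(self, n=20):
        rng = np.random.default_rng(0)
        return [(f"c{i}", {c: float(rng.uniform(1, 10))
                           for c in PARAM_COLUMNS}) for i in range(n)]

    def test_shape_is_cells_by_nine(self):
        table = build_parameter_table(self._rows())
        assert table.shape == (20, 9)
        assert list(table.columns) == PARAM_COLUMNS

    def test_unexcitable_cell_has_nd_ap_shape_and_zero_rate(self):
        ss, _ = simulate_sweeps(0.0, seed=11, cell_id="c")  # unexcitable draw
        feats = extract_features(ss)
        table = build_parameter_table([("c", feats)])
        assert table.loc["c", "firing_rate"] == 0.0
        for col in ("threshold", "rise_time", "halfwidth", "amplitude"):
            assert np.isnan(table.loc["c", col])

    def test_duplicate_cell_id_rejected(self):
        rows = self._rows(3) + [self._rows(1)[0]]
        with pytest.raises(ValueError, match="duplicate"):
            build_parameter_table(rows)

    def test_csv_roundtrip_preserves_nd(self, tmp_path):
        rows = self._rows(5)
        rows[2][1]["halfwidth"] = float("nan")
        rows[4][1]["na_current"] = float("nan")
        table = build_parameter_table(rows)
        path = tmp_path / "params.csv"
        write_parameter_table(path, table)
        assert "ND" in path.read_text()
        back = read_parameter_table(path)
        assert back.isna().equals(table.isna())
        assert np.allclose(back.fillna(0), table.fillna(0))


class TestInvariances:
    def test_voltage_offset_shifts_threshold_only(self):
        ss, _ = simulate_sweeps(0.6, seed=5, cell_id="c")
        f0 = extract_features(ss)
        shifted = SweepSet(ss.cell_id, ss.time, ss.voltage + 7.0,
                           ss.sampling_rate, ss.stim_amplitudes,
                           ss.stim_window)
        f1 = extract_features(shifted)
        assert f1["threshold"] == pytest.approx(f0["threshold"] + 7.0,
                                                abs=1e-9)
        for col in ("rise_time", "halfwidth", "amplitude", "firing_rate"):
            assert f1[col] == pytest.approx(f0[col], abs=1e-9)

    def test_resampling_preserves_amplitude_and_rate(self):
        ss, _ = simulate_sweeps(0.6, seed=6, cell_id="c")
        t2 = np.arange(2 * ss.time.size - 1) / (2 * ss.sampling_rate)
        v2 = np.array([np.interp(t2, ss.time, v) for v in ss.voltage])
        ss2 = SweepSet(ss.cell_id, t2, v2, 2 * ss.sampling_rate,
                       ss.stim_amplitudes, ss.stim_window)
        f0, f1 = extract_features(ss), extract_features(ss2)
        assert f1["firing_rate"] == f0["firing_rate"]
        # amplitude within one original sample interval of upstroke travel
        assert f1["amplitude"] == pytest.approx(f0["amplitude"], abs=1.0)

    def test_spike_count_monotone_in_current(self):
        ss, _ = simulate_sweeps(0.7, seed=7, cell_id="c")
        counts = [detect_spikes(ss.time, v, 10.0).size for v in ss.voltage]
        order = np.argsort(ss.stim_amplitudes)
        assert (np.diff(np.asarray(counts)[order]) >= 0).all()
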