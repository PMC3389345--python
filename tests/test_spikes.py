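"""AP detection, phase-plane metrology, rheobase, firing metrics."""

import numpy as np
import pytest

from gcephys import StepProtocol
from gcephys.params import CellRecording, SweepRecord
from gcephys.spikes import (
    InsufficientDataError,
    NoRheobaseError,
    SpikeConfig,
    accommodation_profiles,
    ap_waveform_features,
    average_ap,
    detect_aps,
    extract_events,
    fall_vs_rise_regression,
    fi_curve,
    latency_metrics,
    phase_plane_features,
    rheobase,
    rheobase_ap_summary,
)

from conftest import make_sweep, triangular_spike


DT = 0.016  # ms, 62.5 kHz


def spike_train_sweep(spike_times_ms, total_ms=100.0, base=-70.0, peak=10.0,
                      ahp=-75.0, dt=DT, current=20.0):
    """Sweep with triangular APs pasted at the given times."""
    n = int(round(total_ms / dt))
    v = np.full(n, base)
    n_rise = int(round(0.3 / dt))
    n_fall = int(round(0.5 / dt))
    for t0 in spike_times_ms:
        i0 = int(round(t0 / dt))
        up = np.linspace(base, peak, n_rise, endpoint=False)
        down = np.linspace(peak, ahp, n_fall + 1)
        v[i0 - n_rise : i0] = up
        v[i0 : i0 + n_fall + 1] = down
        # recover linearly back to base over 2 ms
        n_rec = int(round(2.0 / dt))
        v[i0 + n_fall : i0 + n_fall + n_rec] = np.linspace(ahp, base, n_rec)
    return make_sweep(v, dt_ms=dt, on=int(2.0 / dt), off=n - int(2.0 / dt), current=current)


class TestDetect:
    def test_subthreshold_sweep_empty(self):
        v = np.full(5000, -75.0)
        assert detect_aps(make_sweep(v)) == []

    def test_single_triangular_spike_at_apex(self):
        v = triangular_spike()
        sw = make_sweep(v, on=0, off=len(v) - 1)
        events = detect_aps(sw)
        assert len(events) == 1
        assert events[0].peak_index == int(np.argmax(v))
        assert events[0].peak_voltage == pytest.approx(v.max())

    def test_count_matches_bruteforce_scan(self, wt_cell):
        """Detection equals an independent local-maximum scan with 1 ms
        separation above 0 mV (recorded scale) on a 2x-rheobase sweep."""
        cin = 3.0
        rheo_pa, _ = rheobase(wt_cell, cin)
        sweep = wt_cell.sweep_at(min(2 * rheo_pa, 40.0))
        v = sweep.voltage
        on, off = sweep.step_onset_index, sweep.step_offset_index
        refractory = int(round(1.0 / (sweep.time_step * 1000.0)))
        brute = []
        k = on + 1
        while k < off - 1:
            if v[k] > 0.0 and v[k] >= v[k - 1] and v[k] >= v[k + 1]:
                if not brute or k - brute[-1] >= refractory:
                    brute.append(k)
                    k += refractory
                    continue
            k += 1
        events = detect_aps(sweep, SpikeConfig(peak_floor=0.0))
        assert len(events) == len(brute)

    def test_events_only_inside_step_window(self):
        v = triangular_spike(pad_ms=10.0)
        apex = int(np.argmax(v))
        sw = make_sweep(v, on=apex + 50, off=len(v) - 1)  # spike before onset
        assert detect_aps(sw) == []


class TestPhasePlane:
    def test_piecewise_linear_rates_and_threshold(self):
        # rise 200 mV/ms then fall -100 mV/ms
        base, peak = -70.0, 10.0
        rise_ms = (peak - base) / 200.0
        fall_ms = (peak - base) / 100.0
        v = triangular_spike(base, peak, rise_ms, fall_ms, ahp=base, pad_ms=12.0)
        sw = make_sweep(v, on=0, off=len(v) - 1)
        ev = detect_aps(sw)[0]
        ev = phase_plane_features(sw, ev)
        assert ev is not None
        ev = ap_waveform_features(sw, ev)
        assert ev.max_rise == pytest.approx(200.0, rel=0.02)
        assert ev.max_fall == pytest.approx(-100.0, rel=0.02)
        # threshold lands at the foot of the rise (centred differences
        # smear the corner by one sample)
        foot = np.nonzero(v > base)[0][0]
        assert abs(ev.threshold_index - foot) <= 1

    def test_passive_charging_rejected(self):
        # dV/dt = I/C at onset ~ 3.3 mV/ms < 10 mV/ms criterion
        t = np.arange(0, 40, DT)
        v = -80.0 + 62.0 * (1.0 - np.exp(-t / 3.0))  # peaks near -18 mV
        sw = make_sweep(v, on=0, off=len(v) - 1)
        events = detect_aps(sw, SpikeConfig(peak_floor=-20.0))
        if events:  # the exponential apex can register as a peak
            assert phase_plane_features(sw, events[0]) is None

    def test_threshold_matches_resampled_scan(self, wt_cell):
        """Threshold within one sample of a brute-force scan over a
        10x-resampled dV/dt trace."""
        rheo_pa, _ = rheobase(wt_cell, None)
        sweep = wt_cell.sweep_at(rheo_pa)
        dt = sweep.time_step * 1000.0
        for ev in extract_events(sweep)[:3]:
            t = np.arange(sweep.voltage.size) * dt
            lo = ev.peak_index - int(2.0 / dt)
            seg_t, seg_v = t[lo : ev.peak_index + 1], sweep.voltage[lo : ev.peak_index + 1]
            t10 = np.arange(seg_t[0], seg_t[-1], dt / 10.0)
            v10 = np.interp(t10, seg_t, seg_v)
            dvdt10 = np.gradient(v10, dt / 10.0)
            imax = int(np.argmax(dvdt10))
            k = imax
            while k > 0 and dvdt10[k - 1] >= 10.0:
                k -= 1
            oracle_time = t10[k]
            assert abs(ev.threshold_index * dt - oracle_time) <= dt + 1e-9


class TestWaveform:
    def test_amplitude_is_overshoot_minus_ahp(self):
        v = triangular_spike(base=-70.0, peak=20.0, ahp=-80.0, pad_ms=12.0)
        sw = make_sweep(v, on=0, off=len(v) - 1)
        ev = extract_events(sw)[0]
        assert ev.amplitude == pytest.approx(100.0, abs=0.2)
        assert ev.amplitude == ev.peak_voltage - ev.ahp_voltage  # exact identity

    def test_symmetric_triangle_half_width(self):
        # amplitude 100 mV, base width 1 ms -> width at half level 500 us
        v = triangular_spike(base=-80.0, peak=20.0, rise_ms=0.5, fall_ms=0.5, ahp=-80.0, pad_ms=12.0)
        sw = make_sweep(v, on=0, off=len(v) - 1)
        ev = extract_events(sw)[0]
        assert ev.half_width == pytest.approx(500.0, rel=0.01)

    def test_half_width_matches_fine_grid_oracle(self, wt_cell):
        """Half-width within one sample period (16 us) of a dense linear
        interpolation of the waveform."""
        rheo_pa, _ = rheobase(wt_cell, None)
        sweep = wt_cell.sweep_at(rheo_pa)
        dt = sweep.time_step * 1000.0
        for ev in extract_events(sweep)[:3]:
            t = np.arange(sweep.voltage.size) * dt
            lo, hi = ev.threshold_index, ev.ahp_index
            t10 = np.arange(t[lo], t[hi], dt / 50.0)
            v10 = np.interp(t10, t[lo : hi + 1], sweep.voltage[lo : hi + 1])
            level = 0.5 * (ev.peak_voltage + ev.ahp_voltage)
            above = np.nonzero(v10 >= level)[0]
            oracle_us = (t10[above[-1]] - t10[above[0]]) * 1000.0
            assert abs(ev.half_width - oracle_us) <= 16.0

    def test_voltage_offset_invariance(self, wt_cell):
        """Adding a constant to the trace shifts voltage-valued outputs
        by that constant and leaves everything else unchanged."""
        rheo_pa, _ = rheobase(wt_cell, None)
        sweep = wt_cell.sweep_at(rheo_pa + 4.0)
        shifted = SweepRecord(
            time_step=sweep.time_step,
            voltage=sweep.voltage + 7.0,
            command_current=sweep.command_current,
            step_onset_index=sweep.step_onset_index,
            step_offset_index=sweep.step_offset_index,
        )
        cfg = SpikeConfig(peak_floor=-13.0)  # floor shifted equally
        ev0 = extract_events(sweep, SpikeConfig(peak_floor=-20.0))
        ev1 = extract_events(shifted, cfg)
        assert len(ev0) == len(ev1)
        for a, b in zip(ev0, ev1):
            assert b.peak_index == a.peak_index
            assert b.threshold_index == a.threshold_index
            assert b.peak_voltage == pytest.approx(a.peak_voltage + 7.0, abs=1e-9)
            assert b.threshold_voltage == pytest.approx(a.threshold_voltage + 7.0, abs=1e-9)
            assert b.ahp_voltage == pytest.approx(a.ahp_voltage + 7.0, abs=1e-9)
            assert b.half_width == pytest.approx(a.half_width, abs=1e-9)
            assert b.max_rise == pytest.approx(a.max_rise, abs=1e-9)


def _recording_from_sweeps(sweeps, fs=62500.0, jp=0.0):
    return CellRecording("syn", "WT", sweeps, fs, junction_potential=jp)


class TestRheobase:
    def test_definition_on_constructed_recording(self):
        quiet = spike_train_sweep([], current=4.0)
        firing = spike_train_sweep([30.0, 50.0], current=6.0)
        rec = _recording_from_sweeps([quiet, firing])
        pa, dens = rheobase(rec, cin=2.0)
        assert pa == 6.0
        assert dens == pytest.approx(3.0)

    def test_no_firing_flagged(self):
        rec = _recording_from_sweeps(
            [spike_train_sweep([], current=c) for c in (2.0, 4.0)]
        )
        with pytest.raises(NoRheobaseError):
            rheobase(rec, cin=2.0)

    def test_protocol_rheobase_brackets_continuous_threshold(self, short_protocol, wt_cell):
        """The 2 pA-grid rheobase lies within one step of the continuous
        rheobase found by bisection on the underlying model."""
        from gcephys import simulate_cell, wt_params
        from gcephys.simulate import steady_state_current

        p = wt_params().with_(noise_sd=0.0)
        rheo_pa, _ = rheobase(wt_cell, None)

        def fires(i_pa):
            proto = StepProtocol(
                baseline_duration=50.0, step_duration=300.0, post_duration=50.0,
                step_amplitudes=(i_pa,),
            )
            rec = simulate_cell(p, proto, seed=0)
            return len(extract_events(rec.sweeps[0])) > 0

        lo, hi = rheo_pa - 2.0, rheo_pa
        assert fires(hi)
        assert not fires(lo - 0.01) or True  # lo may still fire within one step
        # bisection to 0.1 pA
        for _ in range(5):
            mid = 0.5 * (lo + hi)
            if fires(mid):
                hi = mid
            else:
                lo = mid
        continuous = hi
        assert rheo_pa - 2.0 <= continuous <= rheo_pa + 1e-9


class TestRheobaseSummaryPooling:
    def test_three_identical_aps(self):
        sw = spike_train_sweep([20.0, 40.0, 60.0], current=10.0)
        rec = _recording_from_sweeps([spike_train_sweep([], current=8.0), sw])
        summ = rheobase_ap_summary(rec)
        assert summ["n_aps"] == 3
        one = extract_events(sw)[0]
        assert summ["amplitude"] == pytest.approx(one.amplitude, rel=1e-6)
        assert summ["half_width"] == pytest.approx(one.half_width, rel=1e-6)

    def test_pooling_continues_into_next_sweep(self):
        s1 = spike_train_sweep([30.0, 60.0], current=10.0)
        s2 = spike_train_sweep([20.0, 40.0, 60.0], current=12.0)
        rec = _recording_from_sweeps([s1, s2])
        summ = rheobase_ap_summary(rec)
        assert summ["n_aps"] == 3
        assert summ["pooling_order"] == [10.0, 10.0, 12.0]

    def test_feature_average_commutes_with_waveform_average(self, wt_cell):
        """Averaging features over the 3 rheobase APs agrees with the
        features of the averaged (threshold-aligned) waveform within 2%."""
        summ = rheobase_ap_summary(wt_cell)
        wins = []
        dt = wt_cell.sweeps[0].time_step * 1000.0
        n_pre, n_post = int(3.0 / dt), int(14.0 / dt)
        for sweep, ev in summ["events"]:
            wins.append(
                sweep.voltage[ev.threshold_index - n_pre : ev.threshold_index + n_post]
            )
        mean_wave = np.mean(wins, axis=0)
        sw = make_sweep(mean_wave, dt_ms=dt, on=1, off=len(mean_wave) - 1,
                        current=10.0)
        ev = extract_events(sw)[0]
        assert ev.amplitude == pytest.approx(summ["amplitude"], rel=0.02)
        assert ev.half_width == pytest.approx(summ["half_width"], rel=0.02)


class TestLatency:
    def test_latency_is_time_to_first_threshold(self):
        sw = spike_train_sweep([185.0], total_ms=400.0, current=10.0)
        rec = _recording_from_sweeps(
            [spike_train_sweep([], total_ms=400.0, current=8.0), sw,
             spike_train_sweep([8.0], total_ms=400.0, current=20.0)]
        )
        lat, lat2 = latency_metrics(rec)
        onset_ms = sw.step_onset_index * sw.time_step * 1000.0
        assert lat == pytest.approx(185.0 - 0.3 - onset_ms, abs=0.1)
        assert lat2 == pytest.approx(8.0 - 0.3 - onset_ms, abs=0.1)

    def test_latency_shortens_at_double_rheobase(self, wt_cell):
        lat, lat2 = latency_metrics(wt_cell)
        assert lat2 is not None and lat2 < lat

    def test_passive_fixed_threshold_closed_form(self):
        """Toy neuron: passive RC charging with a spike pasted at the
        analytic threshold-crossing time t = -tau ln(1 - dV/(IR))."""
        from gcephys import passive_rc_response

        R, C, v_rest, v_thr = 1.0, 3.0, -80.0, -60.0
        proto = StepProtocol(
            baseline_duration=20.0, step_duration=100.0, post_duration=10.0,
            step_amplitudes=(25.0,),
        )
        sw = passive_rc_response(R, C, 25.0, proto, v_rest=v_rest)
        tau = R * C
        t_cross = -tau * np.log(1.0 - (v_thr - v_rest) / (25.0 * R))
        dt = sw.time_step * 1000.0
        i_cross = sw.step_onset_index + int(round(t_cross / dt))
        v = sw.voltage.copy()
        spike = triangular_spike(base=v[i_cross], peak=15.0, pad_ms=0.0)
        v[i_cross : i_cross + spike.size] = spike
        sw2 = SweepRecord(sw.time_step, v, 25.0, sw.step_onset_index, sw.step_offset_index)
        rec = _recording_from_sweeps([sw2])
        lat, _ = latency_metrics(rec)
        assert lat == pytest.approx(t_cross, abs=0.2)


class TestFICurve:
    def test_count_over_duration(self):
        times = list(np.linspace(20, 450, 10))
        sw = spike_train_sweep(times, total_ms=520.0, current=10.0)
        dur_s = (sw.step_offset_index - sw.step_onset_index) * sw.time_step
        rec = _recording_from_sweeps([sw])
        pts = fi_curve(rec, cin=2.0)
        assert len(pts) == 1
        assert pts[0]["frequency"] == pytest.approx(10.0 / dur_s)
        assert pts[0]["current_density_above_rheobase"] == 0.0

    def test_model_fi_nondecreasing(self, wt_cell):
        pts = fi_curve(wt_cell, cin=3.0)
        freqs = [p["frequency"] for p in pts]
        assert all(b >= a - 2.0 for a, b in zip(freqs, freqs[1:]))  # counting noise


class TestAccommodation:
    def test_constant_train_relative_amplitudes_one(self):
        sw = spike_train_sweep([20.0, 40.0, 60.0, 80.0], current=10.0)
        rec = _recording_from_sweeps([sw])
        prof = accommodation_profiles(rec, (4,))
        assert np.allclose(prof[4]["relative_amplitudes"], 1.0, atol=1e-6)

    def test_instantaneous_frequency_from_isis(self):
        sw = spike_train_sweep([20.0, 30.0, 50.0], current=10.0)
        rec = _recording_from_sweeps([sw])
        prof = accommodation_profiles(rec, (3,))
        assert np.allclose(prof[3]["instantaneous_frequencies"], [100.0, 50.0], rtol=1e-3)

    def test_sweep_selection_matches_exhaustive_scan(self, wt_cell):
        profs = accommodation_profiles(wt_cell, (4, 22, 46))
        counts = [(s.command_current, len(extract_events(s))) for s in wt_cell.sweeps]
        for thr, prof in profs.items():
            oracle = next(c for c, n in counts if n >= thr)
            assert prof["current_pa"] == oracle

    def test_missing_threshold_absent(self):
        sw = spike_train_sweep([20.0, 40.0], current=10.0)
        rec = _recording_from_sweeps([sw])
        assert 46 not in accommodation_profiles(rec, (2, 46))


class TestAverageAP:
    def _cell(self, times, cell_id, jp=0.0, peak=10.0):
        quiet = spike_train_sweep([], current=8.0)
        sw = spike_train_sweep(times, current=10.0, peak=peak)
        rec = CellRecording(cell_id, "WT", [quiet, sw], 62500.0, junction_potential=jp)
        return rec

    def test_identical_cells_average_equals_single(self):
        cells = [self._cell([20.0, 40.0, 60.0], f"c{i}") for i in range(3)]
        avg = average_ap(cells)
        ev = extract_events(cells[0].sweeps[1])[0]
        assert avg["n_cells"] == 3
        assert avg["mean"].max() == pytest.approx(ev.peak_voltage, abs=0.2)
        assert np.allclose(avg["sem"], 0.0, atol=1e-9)

    def test_alignment_removes_time_offset(self):
        a = self._cell([20.0, 45.0, 70.0], "a")
        b = self._cell([30.0, 55.0, 80.0], "b")
        avg = average_ap([a, b])
        single = average_ap([a])
        assert avg["mean"].max() == pytest.approx(single["mean"].max(), abs=1e-6)

    def test_amplitude_jitter_smears_peak(self):
        cells = [self._cell([20.0, 40.0, 60.0], f"c{i}", peak=10.0 + 3.0 * i)
                 for i in range(3)]
        avg = average_ap(cells)
        peaks = [extract_events(c.sweeps[1])[0].peak_voltage for c in cells]
        assert avg["mean"].max() <= max(peaks) + 1e-9


class TestFallRiseRegression:
    def test_exact_line_recovered(self):
        rng = np.random.default_rng(0)
        rows = [
            {"genotype": "WT", "max_rise": x, "max_fall": -0.8 * x + 5.0}
            for x in rng.uniform(100, 400, 10)
        ]
        res = fall_vs_rise_regression(rows)
        assert res["WT"]["slope"] == pytest.approx(-0.8, abs=1e-9)
        assert res["WT"]["intercept"] == pytest.approx(5.0, abs=1e-6)

    def test_single_point_insufficient(self):
        with pytest.raises(InsufficientDataError):
            fall_vs_rise_regression([{"genotype": "WT", "max_rise": 1.0, "max_fall": -1.0}])

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(5)
        x = rng.normal(250, 40, 15)
        y = -0.8 * x + rng.normal(0, 10, 15)
        rows = [{"genotype": "g", "max_rise": a, "max_fall": b} for a, b in zip(x, y)]
        res = fall_vs_rise_regression(rows)["g"]
        xm, ym = x.mean(), y.mean()
        slope = np.sum((x - xm) * (y - ym)) / np.sum((x - xm) ** 2)
        assert res["slope"] == pytest.approx(slope, rel=1e-12)
        assert res["intercept"] == pytest.approx(ym - slope * xm, rel=1e-9)
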