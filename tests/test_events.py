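"""Calcium-event detection and waveform metrics."""

import numpy as np
import pytest

from olivescope import SimConfig
from olivescope.events import (CalciumEvent, DetectionParams, align_events,
                               complete_events, detect_events, event_metrics)
from olivescope.photometry import FluorescenceTrace
from olivescope import photometry, sim


def make_trace(values, fr=30.0, unit="fW"):
    return FluorescenceTrace(np.asarray(values, dtype=float), frame_rate=fr,
                             unit=unit)


class TestDetectEvents:
    def test_constant_trace_yields_no_events(self):
        assert detect_events(make_trace(np.full(300, 5.0))) == []

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            detect_events(make_trace(np.ones(30)))

    def test_step_on_noisy_baseline_is_one_event_at_step(self):
        rng = np.random.default_rng(7)
        values = 100.0 + rng.normal(0.0, 0.1, 600)
        values[300:] += 10.0  # step of ~100x the slope noise SD
        events = detect_events(make_trace(values))
        assert len(events) == 1
        assert abs(events[0].onset_frame - 299) <= 1

    def test_close_twin_transients_merge_keeping_larger(self, camera):
        t = np.arange(600) / 30.0
        values = 400.0 * (1.0 + sim.ideal_dff(
            SimConfig(duration=20.0, spike_times=(5.0, 5.3),
                      shoulder_widths=(10.0, 12.0)), t))
        events = detect_events(make_trace(values))
        # peaks 300 ms apart are within the 500 ms separation rule
        assert len(events) == 1

    def test_interpeak_intervals_respect_min_separation(self, camera):
        cfg = sim.random_cell_config(duration=120.0, event_rate_hz=0.15,
                                     width_range_ms=(9.0, 20.0), f0=600.0,
                                     seed=5)
        trace, _ = sim.simulate_fluorescence(cfg, camera)
        fw = photometry.counts_to_power(trace, camera)
        events = detect_events(fw)
        peaks = np.array([e.peak_frame for e in events])
        if len(peaks) > 1:
            assert np.diff(peaks).min() >= int(round(0.5 * 30.0))

    def test_noise_free_onset_within_one_frame(self, camera):
        cfg = SimConfig(duration=20.0, spike_times=(5.0,),
                        shoulder_widths=(10.0,), f0=400.0, shot_noise=False)
        trace, _ = sim.simulate_fluorescence(cfg, camera)
        fw = photometry.counts_to_power(trace, camera)
        events = detect_events(fw)
        assert len(events) == 1
        # the onset frame is the last sample before the rise; the spike
        # lands at t=5 s, whose last pre-rise frame is 149
        assert abs(events[0].onset_frame - 149) <= 1

    def test_zero_variance_returns_empty_not_nan(self):
        out = detect_events(make_trace(np.zeros(300)))
        assert out == []


class TestEventMetrics:
    def test_linear_ramp_rise_time(self):
        # ramp onset->peak spanning 10 frames at 30 fps: RT = 333 ms
        values = np.full(300, 100.0)
        values[100:110] = 100.0 + np.arange(1, 11) * 5.0
        values[110:] = 100.0 + 10 * 5.0
        ev = event_metrics(make_trace(values),
                           CalciumEvent(onset_frame=99, peak_frame=109))
        assert ev.rise_time_ms == pytest.approx(333.3, abs=35.0)

    def test_no_rise_gives_zero_dff_peak(self):
        values = np.full(300, 100.0)
        ev = event_metrics(make_trace(values),
                           CalciumEvent(onset_frame=50, peak_frame=50))
        assert ev.dff_peak == pytest.approx(0.0)
        assert ev.f_peak == ev.f0

    def test_dff_peak_arithmetic(self):
        values = np.full(300, 400.0)
        values[100] = 420.0
        ev = event_metrics(make_trace(values),
                           CalciumEvent(onset_frame=99, peak_frame=100))
        assert ev.f0 == 400.0
        assert ev.f_peak == 420.0
        assert ev.dff_peak == pytest.approx(0.05)

    def test_truncated_window_flagged(self):
        values = np.full(120, 100.0)
        values[110:] = 150.0
        ev = event_metrics(make_trace(values),
                           CalciumEvent(onset_frame=109, peak_frame=110))
        assert "truncated" in ev.flags

    def test_rise_time_recovered_from_forward_model(self, camera):
        # 10.5 ms shoulder encodes a 300 ms rise; noise-free recovery
        # must land within one frame
        cfg = SimConfig(duration=20.0, spike_times=(5.0,),
                        shoulder_widths=(10.5,), f0=400.0, shot_noise=False)
        trace, truth = sim.simulate_fluorescence(cfg, camera)
        fw = photometry.counts_to_power(trace, camera)
        events = complete_events(fw, detect_events(fw))
        assert len(events) == 1
        assert events[0].rise_time_ms == pytest.approx(
            truth.expected_rise_times[0], abs=33.4)

    def test_rise_time_monotone_in_shoulder_width(self, camera):
        # width ordering must survive the full pipeline; expression level
        # matches the bright tTA/TRE cells used for the width calibration
        rng = np.random.default_rng(0)
        widths = rng.uniform(5.0, 20.0, 50)
        measured = []
        for i, w in enumerate(widths):
            cfg = SimConfig(duration=20.0, spike_times=(5.0,),
                            shoulder_widths=(float(w),), f0=1500.0, seed=i)
            trace, _ = sim.simulate_fluorescence(cfg, camera)
            fw = photometry.counts_to_power(trace, camera)
            events = complete_events(fw, detect_events(fw))
            assert len(events) == 1
            measured.append(events[0].rise_time_ms)
        from scipy.stats import spearmanr
        rho = spearmanr(widths, measured).statistic
        assert rho > 0.9


class TestAlignEvents:
    def test_single_event_single_row(self, flat_trace):
        mat, valid = align_events(flat_trace,
                                  [CalciumEvent(onset_frame=100, peak_frame=110)])
        assert mat.shape[0] == 1 and valid[0]
        assert np.all(mat[0] == 1000.0)

    def test_identical_events_have_zero_column_variance(self, flat_trace):
        evs = [CalciumEvent(onset_frame=i, peak_frame=i + 5)
               for i in (60, 120, 180)]
        mat, valid = align_events(flat_trace, evs)
        assert valid.all()
        assert np.allclose(np.var(mat, axis=0), 0.0)

    def test_out_of_bounds_rows_padded_and_invalid(self, flat_trace):
        evs = [CalciumEvent(onset_frame=2, peak_frame=5),
               CalciumEvent(onset_frame=150, peak_frame=160)]
        mat, valid = align_events(flat_trace, evs)
        assert not valid[0] and valid[1]
        assert np.isnan(mat[0]).any() and not np.isnan(mat[1]).any()

    def test_empty_event_list(self, flat_trace):
        mat, valid = align_events(flat_trace, [])
        assert mat.size == 0 and valid.size == 0

    def test_mean_of_noisy_copies_recovers_template(self, camera):
        # Monte-Carlo: onset-aligned average converges on the template
        template_cfg = SimConfig(duration=20.0, spike_times=(5.0,),
                                 shoulder_widths=(12.0,), f0=800.0,
                                 shot_noise=False)
        clean, _ = sim.simulate_fluorescence(template_cfg, camera)
        clean_fw = photometry.counts_to_power(clean, camera)
        traces, evs = [], []
        for seed in range(100):
            cfg = SimConfig(duration=20.0, spike_times=(5.0,),
                            shoulder_widths=(12.0,), f0=800.0, seed=seed)
            tr, _ = sim.simulate_fluorescence(cfg, camera)
            traces.append(photometry.counts_to_power(tr, camera))
            evs.append(CalciumEvent(onset_frame=149, peak_frame=160))
        mat, valid = align_events(traces, evs)
        mean = mat[valid].mean(axis=0)
        sem = mat[valid].std(axis=0, ddof=1) / np.sqrt(valid.sum())
        ref, _ = align_events(clean_fw, [evs[0]])
        assert np.all(np.abs(mean - ref[0]) <= 3.0 * sem + 1e-9)
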