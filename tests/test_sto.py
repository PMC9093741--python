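"""Subthreshold-oscillation spectra and classification."""

import numpy as np
import pytest

from olivescope import SimConfig, STOParams, STOResult
from olivescope import photometry, sim, sto
from olivescope.events import CalciumEvent
from olivescope.photometry import FluorescenceTrace


def make_trace(values, fr=30.0, unit="fW"):
    return FluorescenceTrace(np.asarray(values, dtype=float), frame_rate=fr,
                             unit=unit)


def fluorescence_sto_result(sto_dff, sto_freq=6.0, f0=1500.0, seed=0,
                            camera=None):
    cfg = SimConfig(duration=10.0, sto_freq=sto_freq, sto_dff=sto_dff,
                    f0=f0, seed=seed)
    tr, _ = sim.simulate_fluorescence(cfg, camera)
    fw = photometry.counts_to_power(tr, camera)
    d = photometry.dff(fw, float(np.median(fw.values)))
    return sto.analyze_fluorescence_sto(d)


class TestExciseEvents:
    def test_no_events_is_identity(self, flat_trace):
        out = sto.excise_events(flat_trace, [])
        assert np.array_equal(out.values, flat_trace.values)

    def test_event_in_constant_trace_stays_constant(self):
        values = np.full(600, 10.0)
        values[300:320] += 5.0
        out = sto.excise_events(make_trace(values),
                                [CalciumEvent(onset_frame=300, peak_frame=310)])
        assert np.allclose(out.values, 10.0)

    def test_transient_removal_cuts_low_band_leaves_sto_peak(self, camera):
        cfg = SimConfig(duration=60.0, sto_freq=6.0, sto_dff=0.004, f0=1000.0,
                        spike_times=(10.0,), shoulder_widths=(20.0,),
                        shot_noise=False)
        tr, _ = sim.simulate_fluorescence(cfg, camera)
        fw = photometry.counts_to_power(tr, camera)
        raw = sto.welch_psd_array(fw.values - fw.values.mean(), 30.0)
        cut = sto.excise_events(fw, [CalciumEvent(onset_frame=300,
                                                  peak_frame=310)])
        exc = sto.welch_psd_array(cut.values - cut.values.mean(), 30.0)
        low = (raw.frequencies > 0) & (raw.frequencies < 3.0)
        low_mass = np.trapezoid(exc.psd[low], exc.frequencies[low])
        raw_low_mass = np.trapezoid(raw.psd[low], raw.frequencies[low])
        assert low_mass < 0.2 * raw_low_mass
        peak = np.isclose(raw.frequencies, 6.0)
        assert exc.psd[peak] == pytest.approx(raw.psd[peak], rel=0.1)

    def test_events_covering_most_of_trace_rejected(self):
        values = np.arange(300, dtype=float)
        with pytest.raises(ValueError, match="80%"):
            sto.excise_events(make_trace(values),
                              [CalciumEvent(onset_frame=5, peak_frame=10)],
                              post_s=9.5)


class TestBandpass:
    def test_constant_trace_maps_to_zero(self):
        out = sto.bandpass_array(np.full(300, 123.0), 30.0)
        assert np.max(np.abs(out)) < 1e-9 * 123.0

    def test_in_band_sinusoid_preserved(self):
        t = np.arange(600) / 30.0
        out = sto.bandpass_array(np.sin(2 * np.pi * 7.0 * t), 30.0)
        assert np.max(np.abs(out[100:-100])) >= 0.9

    def test_out_of_band_sinusoid_attenuated(self):
        t = np.arange(600) / 30.0
        out = sto.bandpass_array(np.sin(2 * np.pi * 0.5 * t), 30.0)
        assert np.max(np.abs(out[100:-100])) <= 0.1

    def test_nyquist_violation_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            sto.bandpass_array(np.zeros(300), 24.0, (3.0, 12.0))


class TestWelchPsd:
    def test_white_noise_parseval(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0.0, 1.0, 3000)
        res = sto.welch_psd_array(x, 30.0)
        total = np.trapezoid(res.psd, res.frequencies)
        assert total == pytest.approx(x.var(), rel=0.1)

    def test_sinusoid_peak_frequency_within_bin(self):
        t = np.arange(300) / 30.0
        res = sto.welch_psd_array(np.sin(2 * np.pi * 6.0 * t), 30.0)
        assert abs(res.peak_freq - 6.0) <= 0.5

    def test_dominant_component_wins(self):
        t = np.arange(300) / 30.0
        x = 2.0 * np.sin(2 * np.pi * 6.0 * t) + np.sin(2 * np.pi * 9.0 * t)
        assert sto.welch_psd_array(x, 30.0).peak_freq == pytest.approx(6.0, abs=0.5)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="segment"):
            sto.welch_psd_array(np.zeros(30), 30.0)

    def test_band_power_monotone_in_sto_amplitude(self):
        powers = []
        for amp in (1.0, 2.0, 4.0, 8.0):
            cfg = SimConfig(duration=10.0, sto_amp=amp, sto_freq=6.0,
                            vm_noise_sd=0.5, seed=7)
            vm, _ = sim.simulate_vm(cfg)
            filtered = sto.bandpass_array(vm.values, vm.sampling_rate, (3, 12))
            powers.append(sto.welch_psd_array(filtered, vm.sampling_rate).band_power)
        assert np.all(np.diff(powers) > 0)


class TestClassification:
    def test_zero_trace_not_oscillating(self):
        res = sto.welch_psd_array(np.zeros(100_000), 10_000.0)
        assert sto.classify_oscillating(res, modality="vm") is False

    def test_two_mv2_cell_is_oscillating(self):
        # sto_amp = 2 mV carries 2 mV^2 mean square, above the 1 mV^2 cut
        cfg = SimConfig(duration=10.0, sto_amp=2.0, sto_freq=6.0,
                        vm_noise_sd=0.5, seed=3)
        vm, _ = sim.simulate_vm(cfg)
        filtered = sto.bandpass_array(vm.values, vm.sampling_rate, (3, 12))
        res = sto.welch_psd_array(filtered, vm.sampling_rate)
        assert sto.classify_oscillating(res, modality="vm") is True

    def test_modalities_agree_on_strong_oscillator(self, camera):
        amp_mv = 4.0
        cfg = SimConfig(duration=10.0, sto_freq=7.0, sto_amp=amp_mv,
                        sto_dff=sim.DFF_PCT_PER_MV * amp_mv / 100.0,
                        f0=1500.0, vm_noise_sd=0.5, seed=5)
        vm, _ = sim.simulate_vm(cfg)
        tr, _ = sim.simulate_fluorescence(cfg, camera)
        fw = photometry.counts_to_power(tr, camera)
        fres = sto.analyze_fluorescence_sto(
            photometry.dff(fw, float(np.median(fw.values))))
        vfilt = sto.bandpass_array(vm.values, vm.sampling_rate, (3, 12))
        vres = sto.welch_psd_array(vfilt, vm.sampling_rate)
        assert sto.classify_oscillating(vres, modality="vm")
        assert fres.oscillating

    def test_unknown_modality_rejected(self):
        res = STOResult(np.array([1.0]), np.array([1.0]), 0.0, 6.0)
        with pytest.raises(ValueError):
            sto.classify_oscillating(res, modality="emg")


class TestFrequencyMatch:
    def test_identical_paired_simulation_gives_unity(self, camera):
        amp_mv = 4.0
        cfg = SimConfig(duration=10.0, sto_freq=7.0, sto_amp=amp_mv,
                        sto_dff=sim.DFF_PCT_PER_MV * amp_mv / 100.0,
                        f0=1500.0, vm_noise_sd=0.5, seed=6)
        vm, _ = sim.simulate_vm(cfg)
        tr, _ = sim.simulate_fluorescence(cfg, camera)
        fw = photometry.counts_to_power(tr, camera)
        fres = sto.analyze_fluorescence_sto(
            photometry.dff(fw, float(np.median(fw.values))))
        vfilt = sto.bandpass_array(vm.values, vm.sampling_rate, (3, 12))
        vres = sto.welch_psd_array(vfilt, vm.sampling_rate)
        sto.classify_oscillating(vres, modality="vm")
        ratio = sto.frequency_match(vres, fres)
        assert ratio == pytest.approx(1.0, abs=0.5 / 7.0)

    def test_non_oscillating_input_is_error(self):
        a = STOResult(np.array([6.0]), np.array([1.0]), 10.0, 6.0,
                      oscillating=True)
        b = STOResult(np.array([6.0]), np.array([1.0]), 0.0, 6.0,
                      oscillating=False)
        with pytest.raises(ValueError):
            sto.frequency_match(a, b)


class TestPeakFrequencyRecovery:
    @pytest.mark.parametrize("freq", [4.0, 6.0, 8.0, 10.0, 12.0])
    def test_fluorescence_peak_recovery_within_bin(self, camera, freq):
        res = fluorescence_sto_result(0.005, sto_freq=freq, seed=int(freq),
                                      camera=camera)
        assert abs(res.peak_freq - freq) <= 0.5
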