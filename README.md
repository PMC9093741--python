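# olivescope

Quantitative analysis of inferior-olive (IO) neuron activity from
1-photon GCaMP6s imaging and paired patch-clamp recordings.

IO neurons carry two unusual electrophysiological signatures: 3–13 Hz
subthreshold membrane oscillations (STOs) and action potentials with a
variable-duration calcium shoulder (the "spike width", ~4–22 ms).  Both
leave traces in somatic GCaMP6s fluorescence, but at 30 fps and a few
percent ΔF/F they sit near the noise floor of a 1-photon camera.  This
package provides the measurement chain to extract them:

* **photometry** — calibrated conversion of camera counts to light
  power, `P = counts·(full_well/digital_max)·1.6×10⁻¹⁹ J·f_s`, ROI
  traces, baseline F₀ (minimum of the 500 ms pre-onset window) and
  ΔF/F;
* **events** — calcium-event (eCa) detection by slope z-score (z ≥ 4,
  500 ms peak separation) and waveform metrics, including a sub-frame
  rise-time estimator;
* **sto** — Blackman-windowed Welch spectra of the 3–12 Hz band,
  event excision, and the oscillating/non-oscillating classification
  (band power > 1 mV² for voltage; sinusoid-equivalent amplitude
  > 0.12% ΔF/F for fluorescence);
* **ephys** — spike detection, calcium-shoulder width at the
  baseline +10 mV threshold, PCA + elbow k-means waveform typing,
  spikelet identification;
* **calibration** — the linear translation between eCa rise time and
  spike width, `w = 0.06·RT − 7.5 ms` (6 ms per 100 ms, anchored at
  200 ms ↦ 4.5 ms), and expected burst spikelet counts at 270 Hz,
  `1 + ⌊w·f/1000⌋`;
* **anatomy** — neuron/astrocyte classification (NeuN radial profile
  > 20% within 2 µm, or soma area > 100 µm²), reference-normalized
  expression, inside/outside structural specificity at a Z = 3
  threshold, nearest-neighbour distances, cell-type preference;
* **sim** — synthetic membrane voltage, GCaMP6s fluorescence through a
  full camera model (600 000 e⁻ full well, 130 e⁻ dark noise, shot
  noise, quantization), and two-reporter anatomy fields, all with
  ground-truth manifests;
* **pipeline / CLI** — end-to-end reproducible runs
  (`olivescope run --config cfg.yaml`).

See `docs/methods.md` for the models, estimators and their assumptions.

## Worked example

Simulate one IO cell that oscillates at 6 Hz and fires two spikes with
8 ms and 16 ms calcium shoulders, then run the analysis chain:

```python
import numpy as np
from olivescope import SimConfig, calibration, events, photometry, sim, sto

camera = photometry.CameraModel()
cfg = SimConfig(duration=30.0, spike_times=(5.0, 17.0),
                shoulder_widths=(8.0, 16.0), sto_freq=6.0, sto_amp=3.0,
                sto_dff=0.0025, f0=800.0, vm_noise_sd=0.3, seed=42)

counts, truth = sim.simulate_fluorescence(cfg, camera)
fw = photometry.counts_to_power(counts, camera)          # counts -> fW
found = events.complete_events(fw, events.detect_events(fw))

model = calibration.default_model()
for ev in found:
    print(f"onset={ev.onset_frame/30:.2f}s  rt={ev.rise_time_ms:.0f}ms  "
          f"dff={ev.dff_peak*100:.1f}%  width={model.predict(ev.rise_time_ms):.1f}ms")

quiet = sto.excise_events(fw, found)
dff = photometry.dff(quiet, float(np.median(quiet.values)))
res = sto.analyze_fluorescence_sto(dff)
print(f"STO: peak {res.peak_freq:.1f} Hz  amp {res.dff_amplitude_pct:.2f}%  "
      f"oscillating={res.oscillating}")
```

Output:

```
onset=4.97s  rt=237ms  dff=3.8%  width=6.7ms
onset=16.97s  rt=377ms  dff=6.6%  width=15.1ms
STO: peak 6.0 Hz  amp 0.20%  oscillating=True
```

Both spikes are detected at their onsets; the rise times read back
through the calibration give 6.7 and 15.1 ms against the planted 8 and
16 ms shoulders, and the 6 Hz oscillation is recovered at its planted
frequency with an amplitude above the 0.12% classification threshold.

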