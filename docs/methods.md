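# Methods

`olivescope` reimplements, as a tested pipeline, the quantitative
analysis of inferior-olive (IO) neuron activity recorded with 1-photon
GCaMP6s imaging and paired patch-clamp electrophysiology, together with
the anatomical quantification of transgene expression, and a synthetic
generator that emulates the physiology and camera statistics the
analysis assumes.

## Photometric calibration

Raw digital counts are mapped to light power assuming a linear sCMOS
sensor whose ADC ceiling (65 535 counts) corresponds to a full well of
600 000 electrons, with 130 e⁻ RMS dark noise:

    electrons = counts x full_well / digital_max
    P [W]     = electrons x 1.6e-19 [J] x frame_rate [1/s]

reported in femtowatts.  Full scale at 30 fps is exactly 2880 fW.  The
electron energy constant is kept at the rounded 1.6x10⁻¹⁹ J so that the
numeric scale matches the original calibration; CODATA would shift all
powers by 0.16%.  The counts→electrons mapping (digital max ↦ full
well) is an assumption about the camera gain, exposed as configurable.
No background subtraction is performed anywhere.

Baseline F₀ is the minimum over the 500 ms window preceding an event
onset (the available prefix near the recording start), and
DFF = (F − F₀)/F₀.

## Calcium-event detection

Events are found from the maximal instantaneous slope increase of the
fluorescence trace, z-scored against a robust (1.4826 x MAD) estimate
of the whole-trace slope scatter, with threshold z ≥ 4 and a minimal
peak-to-peak separation of 500 ms (closer peaks merge, keeping the
larger; ties keep the earlier).  Because a GCaMP6s rise spans several
frames at 30 fps, the slope is measured across a ~165 ms span of a
~100 ms boxcar-smoothed trace; a single-frame difference of the raw
trace would drown in shot noise.  Both spans are parameters.

The reported onset frame is the last sample still at the local
pre-event baseline (within one noise SD; the margin is relaxed to 2 and
3 SD when noise rides high) before the rise — operationally the last
pre-rise sample, matching the intuitive "last sample with non-positive
slope" but with bounded error under correlated smoothing noise.
Candidate events whose rise contains a second distinct slope-threshold
crossing are flagged `double` and diverted to a review table rather
than accepted, an automatic surrogate for the manual curation of
compound events.

### Rise-time estimation

Rise time (onset to transient peak) is the pipeline's key readout, but
the transient top is flat: at 30 fps and realistic expression levels,
the raw argmax of the peak jitters over several frames of shot noise
(measured 45–85 ms error).  `event_metrics` therefore reads the rise
time from a weighted least-squares fit of a canonical transient —
alpha-function rise `amp·(t/rt)·e^(1−t/rt)` joined continuously to a
single-exponential decay with the indicator's decay constant (1.5 s for
GCaMP6s, configurable) — with onset time, rise time, amplitude and
baseline free.  Weights follow the shot-noise scaling (variance
proportional to the signal); three rise-time starting points guard
against local minima, and fits pinned at their rise-time bounds fall
back to frame arithmetic.  A numeric Cramér–Rao analysis at 400 fW
expression shows per-event rise-time errors are information-limited to
roughly 25–76 ms for shoulder widths 18 down to 5 ms; the fit operates
near that bound.  This estimator assumes the transient family above; on
real data with different kinetics the frame-resolution fallback bounds
the damage but the model should be revisited.

## Subthreshold oscillations

Traces are band-passed to 3–12 Hz with a zero-phase 3rd-order
Butterworth filter (flat passband, no phase distortion of oscillation
timing), and spectra are estimated with a Blackman-windowed Welch
method, 2 s segments and 50% overlap — 0.5 Hz resolution on a 10 s
recording, matching the typical acquisition length.  Band power is the
PSD integral over 3–12 Hz (the mean square the oscillation carries, in
mV² or DFF²); a 5 mV sinusoid yields 12.5 mV².

Before spectral analysis of fluorescence, event windows (onset − 100 ms
to onset + 4 s, about three decay constants) are excised and bridged by
linear interpolation, so decaying transient flanks do not leak power
into the 0–3 Hz range and below.

Cells are classified *oscillating* when

* voltage: band power > 1 mV², or
* fluorescence: sinusoid-equivalent DFF amplitude > 0.12%.

The fluorescence amplitude is estimated from the spectral peak: the PSD
is integrated over peak ± 1 Hz after subtracting the broadband noise
floor (median in-band density, robust to a narrow peak), and converted
to the amplitude of the sinusoid carrying the excess power,
a = √(2·P).  A time-domain peak-to-peak estimate is reported alongside
but deliberately not used for classification: per-frame shot noise at
full-well exposure is ≥ 0.13% DFF, so any raw time-domain amplitude
sits above the 0.12% criterion regardless of the cell's state, and a
peak-to-peak statistic grows without bound with recording length.

The voltage/fluorescence STO coupling in the simulator (0.085% DFF per
mV) is chosen so the two classification thresholds correspond: a
1 mV² oscillation (amplitude 1.41 mV) maps onto 0.12% DFF.

## Spike waveforms

Spikes in voltage traces are depolarizations exceeding the trace median
(robust against STOs and sparse spiking) by +10 mV, with the initiation
point at the last sample before the rising phase crosses baseline
+2 mV and a 20 ms refractory merge.  Spike width is the duration of the
calcium shoulder: the contiguous time above baseline +10 mV from the
first up-crossing to the first down-crossing, sub-sample interpolated.
The threshold is relative to the pre-spike baseline, not absolute
voltage, so the measure transfers across cells; waveforms that never
reach it are spikelets (gap-junction echoes of neighbours' spikes),
reported with width 0 and a flag.

Waveform typing uses PCA on the raw, initiation-aligned waveforms
(mean-centred only — no z-scoring, so millivolt geometry is preserved)
followed by k-means on the first two component scores, k = 1…10 with
10 seeded restarts.  k is chosen at the elbow of the within-cluster
sum-of-squares curve, formalized as the point of maximal perpendicular
distance to the chord joining k = 1 and k = k_max on axis-normalized
coordinates.  Because k-means on structureless data produces a smooth
~1/k decay whose chord distance peaks spuriously at k ≈ 3, curves whose
strongest knee is no sharper than that reference (normalized distance
≤ 0.40) are declared structureless and yield k = 1.  Measured knee
strengths: ~0.29–0.33 for a single Gaussian blob, ~0.55 for three
planted clusters.

## Rise-time → spike-width calibration

The linear translation between calcium-event rise time and
electrophysiological spike width is 6 ms of width per 100 ms of rise
time, anchored so a 200 ms rise time (the shortest events) maps to
4.5 ms — the midpoint of the 4–5 ms range, a documented convention.
Hence `width = 0.06·RT − 7.5 ms`; at the mean in-vivo rise time of
351 ms this predicts 13.56 ms.  Rise times below 150 ms fall in the
short-IO-spike regime without a clear calcium shoulder; values are
still returned but flagged unreliable.  `fit_calibration` provides the
ordinary least-squares version for user data.

The expected number of axonal burst spikelets for a spike of width *w*
at burst frequency *f* (270 Hz default) is `1 + floor(w·f/1000)` — one
initial spike plus one per completed inter-spikelet interval.  This
yields 4 at 13.7 ms but 6 at 21.8 ms; no single floor/round rule maps
the whole observed width range onto a 4–5 count, so the rule (and the
frequency) are exposed as parameters rather than asserted as fact.

## Anatomical quantification

Neurons are separated from non-neuronal cells ("astrocytes") either by
the NeuN criterion — the radial intensity profile (1-pixel annuli,
normalized to its own maximum) exceeds 0.20 strictly within a 2 µm
radius — or by soma area strictly greater than 100 µm².  Boundary
values classify as non-neuron; the sources are silent on ties, so the
strict inequality is a documented convention.  Normalized expression is
the test-reporter (EGFP) mean intensity divided by the reference
reporter (tdTomato); structural specificity thresholds each channel at
its whole-image mean + 3 SD (configurable to background-region
statistics) and reports labelled-extent and supra-threshold-intensity
ratios separately inside and outside the region contour — compartments
with no labelled reference pixels report missing, not zero.  Cell-type
preference normalizes labelled neuron and astrocyte counts by a
co-injected control and reports the percent excess of the neuron ratio.
Segmentation is out of scope; the functions consume ROI tables, label
images and masks.

## Synthetic data

The voltage generator is phenomenological, not conductance-based: a
baseline (−55 mV) plus a sinusoidal STO (3.5–13 Hz range in IO cells),
spike templates (0.5 ms rise to +80 mV, 0.5 ms fall to a +20 mV plateau
lasting the shoulder width, then a −10 mV after-hyperpolarization
decaying over ~50 ms), 10 ms half-sine spikelet bumps (~2 mV), and
Gaussian noise, at 10 kHz — sufficient for millisecond-resolution width
measurements at this scale.

The fluorescence forward model computes ideal power
`P(t) = f0·(1 + sto_dff·sin + Σ transients)`, converts to expected
electrons per frame, applies Poisson shot noise and Gaussian dark
noise, and quantizes to clipped counts.  Each spike's transient peaks
at the rise time implied by the width calibration used in inverse
(`RT = 200 + (w − 4.5)·100/6` ms) with peak DFF of 0.35% per ms of
width, chosen so a 13.7 ms spike yields ~4.8% DFF — inside the 1–12%
range of in-vivo somatic events; the absolute gain is a free parameter
of the generator, not a measured quantity.  Overlapping transients add.
Expression (`f0`) must stay below 60% of the full-well-equivalent power
(1728 fW at 30 fps), mirroring the acquisition practice of keeping the
sensor below 60% of full well.

The anatomy generator renders disk somata on a jittered grid with
neuron areas strictly above 110 µm² and astrocyte areas below 95 µm²,
so their 5th/95th percentiles straddle the 100 µm² boundary by
construction and area classification is perfect — tests against it
validate the classification logic, not segmentation on real tissue.
What the generators do *not* emulate: dendritic and neuropil signal,
motion, photobleaching, indicator saturation, gap-junction network
dynamics, irregular soma shapes, or spatially varying background.
Passing tests therefore demonstrate the correctness of the measurement
chain under the stated statistical model of the data, not performance
on raw microscopy.

## Problem sizes and defaults

Simulated studies use 10 s records for spectral analysis (0.5 Hz
resolution), ~100 s multi-event records for detection statistics (10
cells x 10 events at 0.1 Hz-scale rates, matching sparse in-vitro IO
firing), 50 paired cells spanning the oscillation threshold, and
n = 50–60 waveforms for clustering — sizes chosen to give stable
statistics for each check while keeping any single study comfortably
below a minute of compute.

## Known limitations

* The rise-time fit assumes the generator's transient family; real
  GCaMP6s kinetics vary with expression and calcium load.
* The 0.12% DFF criterion is an operating point tied to the spectral
  amplitude estimator described above; a different estimator needs a
  recalibrated threshold.
* The elbow knee-strength floor (0.40) is calibrated against the 1/k
  reference decay; moderately separated clusters near that strength may
  be declared structureless.
* The mixed-unit equivalence sometimes quoted between DFF amplitude and
  PSD density (percent vs fW²/Hz) is not asserted anywhere; both
  quantities are reported separately.
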