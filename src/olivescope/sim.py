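"""Synthetic inferior-olive physiology and camera forward model.

Three generators with ground-truth manifests:

``simulate_vm``
    Membrane voltage as a phenomenological template sum: a sinusoidal
    subthreshold oscillation (STO, 3.5-13 Hz in IO cells), IO action
    potentials built from a 1 ms sodium peak (+80 mV), a calcium-shoulder
    plateau (+20 mV, 4-22 ms), and a -10 mV after-hyperpolarization
    decaying over ~50 ms, plus small gap-junction spikelet bumps and
    Gaussian noise.  No conductance-based dynamics are modelled.

``simulate_fluorescence``
    GCaMP6s fluorescence for the same cell: ideal light power
    P(t) = f0 * (1 + sto_dff*sin + sum of transients), where each spike
    produces a transient whose rise time encodes the shoulder width
    (inverse of the rise-time->width calibration) and whose peak DFF is
    proportional to the width.  Power is converted to expected electrons
    per frame, Poisson shot noise and Gaussian dark noise are applied,
    and the result is quantized to digital counts.

``simulate_anatomy``
    A two-reporter confocal field (EGFP test channel, tdTomato reference
    channel, NeuN stain) of disk-shaped somata whose area distributions
    straddle the 100 um^2 neuron/astrocyte boundary by construction.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from skimage.draw import disk as draw_disk

from .calibration import (DEFAULT_ANCHOR_RT_MS, DEFAULT_ANCHOR_WIDTH_MS,
                          DEFAULT_SLOPE)
from .ephys import VoltageTrace
from .photometry import (CameraModel, FluorescenceTrace, electrons_to_counts,
                         power_to_electrons)

__all__ = [
    "SimConfig",
    "GroundTruth",
    "expected_rise_time",
    "simulate_vm",
    "simulate_fluorescence",
    "simulate_anatomy",
    "simulate_specificity_field",
    "DFF_PER_MS_WIDTH",
    "DFF_PCT_PER_MV",
]

#: Peak DFF per ms of calcium-shoulder width.  Chosen so a 13.7 ms spike
#: yields ~4.8% DFF, inside the 1-12% range of in-vivo somatic events.
DFF_PER_MS_WIDTH = 0.0035

#: Fluorescence STO amplitude (% DFF) per mV of membrane STO amplitude.
#: Couples the two modality thresholds: a 1 mV^2 mean-square oscillation
#: (amplitude 1.414 mV) maps onto the 0.12% DFF classification threshold.
DFF_PCT_PER_MV = 0.12 / np.sqrt(2.0)

_SODIUM_RISE_MS = 0.5
_SODIUM_FALL_MS = 0.5
_SODIUM_PEAK_MV = 80.0
_SHOULDER_MV = 20.0
_AHP_MV = -10.0
_AHP_FALL_MS = 0.5
_AHP_SPAN_MS = 50.0
_AHP_TAU_MS = 12.0
_SPIKELET_MS = 10.0


def expected_rise_time(width_ms: float | np.ndarray) -> float | np.ndarray:
    """Fluorescence rise time [ms] encoding a given shoulder width [ms].

    Inverse of the default rise-time->width calibration:
    ``RT = 200 + (width - 4.5) * 100/6``.
    """
    rt = DEFAULT_ANCHOR_RT_MS + (np.asarray(width_ms, dtype=float)
                                 - DEFAULT_ANCHOR_WIDTH_MS) / DEFAULT_SLOPE
    return float(rt) if rt.ndim == 0 else rt


@dataclass
class SimConfig:
    """Parameters of one simulated IO cell.

    Times in seconds, widths in ms, voltages in mV, light power in fW.
    """

    duration: float = 10.0
    fs_vm: float = 10_000.0
    fs_img: float = 30.0
    sto_freq: float = 6.0
    sto_amp: float = 0.0
    baseline_vm: float = -55.0
    spike_times: Sequence[float] = field(default_factory=tuple)
    shoulder_widths: Sequence[float] = field(default_factory=tuple)
    spikelet_times: Sequence[float] = field(default_factory=tuple)
    spikelet_amp: float = 2.0
    f0: float = 400.0
    sto_dff: float = 0.0
    decay_tau: float = 1.5
    vm_noise_sd: float = 0.0
    shot_noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.spike_times = tuple(float(t) for t in self.spike_times)
        self.shoulder_widths = tuple(float(w) for w in self.shoulder_widths)
        self.spikelet_times = tuple(float(t) for t in self.spikelet_times)
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.fs_vm < 20 * self.fs_img:
            raise ValueError("fs_vm must be at least 20x fs_img")
        if len(self.spike_times) != len(self.shoulder_widths):
            raise ValueError("one shoulder width per spike is required")
        if any(not (0.0 <= t < self.duration) for t in self.spike_times):
            raise ValueError("spike_times must lie within [0, duration)")
        if any(not (0.0 < w <= 30.0) for w in self.shoulder_widths):
            raise ValueError("shoulder widths must lie in (0, 30] ms")
        if self.f0 < 0:
            raise ValueError("f0 must be non-negative")
        if self.sto_freq <= 0:
            raise ValueError("sto_freq must be positive")
        if self.decay_tau <= 0:
            raise ValueError("decay_tau must be positive")


@dataclass
class GroundTruth:
    """Manifest of what a generator actually planted."""

    spike_times: tuple[float, ...] = ()
    shoulder_widths: tuple[float, ...] = ()
    expected_rise_times: tuple[float, ...] = ()
    sto_freq: float = 0.0
    oscillating: bool = False
    cell_labels: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        if not (len(self.spike_times) == len(self.shoulder_widths)
                == len(self.expected_rise_times)):
            raise ValueError("per-spike ground-truth fields must have equal length")

    def to_dict(self) -> dict:
        return {
            "spike_times": list(self.spike_times),
            "shoulder_widths": list(self.shoulder_widths),
            "expected_rise_times": list(self.expected_rise_times),
            "sto_freq": self.sto_freq,
            "oscillating": self.oscillating,
            "cell_labels": None if self.cell_labels is None else list(self.cell_labels),
        }


def _ground_truth(config: SimConfig) -> GroundTruth:
    rts = tuple(float(expected_rise_time(w)) for w in config.shoulder_widths)
    # oscillating by the 1 mV^2 mean-square criterion on the planted sinusoid
    return GroundTruth(
        spike_times=tuple(config.spike_times),
        shoulder_widths=tuple(config.shoulder_widths),
        expected_rise_times=rts,
        sto_freq=config.sto_freq,
        oscillating=bool(config.sto_amp**2 / 2.0 > 1.0),
    )


def _spike_template(width_ms: float, fs: float) -> np.ndarray:
    """Voltage template of one IO spike, relative to baseline, at rate fs."""
    dt_ms = 1000.0 / fs

    def n(ms: float) -> int:
        return max(1, int(round(ms / dt_ms)))

    rise = np.linspace(0.0, _SODIUM_PEAK_MV, n(_SODIUM_RISE_MS), endpoint=False)
    fall = np.linspace(_SODIUM_PEAK_MV, _SHOULDER_MV, n(_SODIUM_FALL_MS), endpoint=False)
    plateau = np.full(n(width_ms), _SHOULDER_MV)
    drop = np.linspace(_SHOULDER_MV, _AHP_MV, n(_AHP_FALL_MS), endpoint=False)
    t_ahp = np.arange(n(_AHP_SPAN_MS)) * dt_ms
    ahp = _AHP_MV * np.exp(-t_ahp / _AHP_TAU_MS)
    return np.concatenate([rise, fall, plateau, drop, ahp])


def simulate_vm(config: SimConfig) -> tuple[VoltageTrace, GroundTruth]:
    """Simulate a membrane-voltage recording with known spike content."""
    fs = config.fs_vm
    n = int(round(config.duration * fs))
    t = np.arange(n) / fs
    v = config.baseline_vm + config.sto_amp * np.sin(2 * np.pi * config.sto_freq * t)

    # reject overlapping spikes: templates may not collide
    order = np.argsort(config.spike_times)
    spans = []
    for i in order:
        ts, w = config.spike_times[i], config.shoulder_widths[i]
        span_s = (_SODIUM_RISE_MS + _SODIUM_FALL_MS + w + _AHP_FALL_MS + _AHP_SPAN_MS) / 1000.0
        spans.append((ts, ts + span_s))
    for (_, prev_end), (nxt_start, _) in zip(spans, spans[1:]):
        if nxt_start < prev_end:
            raise ValueError("spikes overlap: spacing is shorter than their widths")

    for ts, w in zip(config.spike_times, config.shoulder_widths):
        tpl = _spike_template(w, fs)
        i0 = int(round(ts * fs))
        i1 = min(n, i0 + len(tpl))
        v[i0:i1] += tpl[: i1 - i0]

    if config.spikelet_times:
        m = max(2, int(round(_SPIKELET_MS / 1000.0 * fs)))
        bump = config.spikelet_amp * np.sin(np.pi * np.arange(m) / (m - 1))
        for ts in config.spikelet_times:
            i0 = int(round(ts * fs))
            i1 = min(n, i0 + m)
            v[i0:i1] += bump[: i1 - i0]

    if config.vm_noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        v = v + rng.normal(0.0, config.vm_noise_sd, n)

    trace = VoltageTrace(values=v, sampling_rate=fs, cell_id=f"sim-{config.seed}")
    return trace, _ground_truth(config)


def _transient(tau_s: np.ndarray, rt_s: float, amp: float, decay_tau: float) -> np.ndarray:
    """Alpha-function rise peaking at rt_s, then exponential decay.

    The rise is amp * (t/rt) * exp(1 - t/rt): indicator binding starts
    immediately after the spike (finite onset slope) and flattens into
    the peak at t = rt, where it joins the single-exponential decay
    continuously and with matching (zero) slope.
    """
    out = np.zeros_like(tau_s)
    rising = (tau_s >= 0) & (tau_s <= rt_s)
    x = tau_s[rising] / rt_s
    out[rising] = amp * x * np.exp(1.0 - x)
    decaying = tau_s > rt_s
    out[decaying] = amp * np.exp(-(tau_s[decaying] - rt_s) / decay_tau)
    return out


def ideal_dff(config: SimConfig, frame_times: np.ndarray) -> np.ndarray:
    """Noise-free DFF signal: STO sinusoid plus spike transients (additive)."""
    s = config.sto_dff * np.sin(2 * np.pi * config.sto_freq * frame_times)
    for ts, w in zip(config.spike_times, config.shoulder_widths):
        rt_s = float(expected_rise_time(w)) / 1000.0
        amp = DFF_PER_MS_WIDTH * w
        s = s + _transient(frame_times - ts, rt_s, amp, config.decay_tau)
    return s


def simulate_fluorescence(config: SimConfig,
                          camera: Optional[CameraModel] = None
                          ) -> tuple[FluorescenceTrace, GroundTruth]:
    """Forward-model the GCaMP6s fluorescence of one simulated cell.

    Returns a raw-count trace at ``fs_img`` plus the ground truth.  The
    expression level ``f0`` must stay below 60% of the full-well
    equivalent power to leave headroom for transients, and the total
    expected signal may never exceed the full well.
    """
    camera = camera or CameraModel(frame_rate=config.fs_img)
    limit = 0.6 * camera.full_well_power_fw(config.fs_img)
    if config.f0 > limit:
        raise ValueError(
            f"f0={config.f0:.0f} fW exceeds 60% of the full-well-equivalent "
            f"power ({limit:.0f} fW at {config.fs_img:g} fps)")

    nf = int(round(config.duration * config.fs_img))
    frame_times = (np.arange(nf) + 0.5) / config.fs_img
    power_fw = config.f0 * (1.0 + ideal_dff(config, frame_times))
    expected_e = power_to_electrons(power_fw, camera, config.fs_img)

    over = np.nonzero(expected_e > camera.full_well)[0]
    if over.size:
        raise ValueError(
            f"expected signal exceeds the full well in {over.size} frames "
            f"(first frames: {over[:10].tolist()})")

    if config.shot_noise:
        rng = np.random.default_rng(config.seed)
        electrons = rng.poisson(expected_e).astype(float)
        electrons += rng.normal(0.0, camera.dark_noise, nf)
    else:
        electrons = expected_e
    counts = electrons_to_counts(electrons, camera)
    trace = FluorescenceTrace(counts, frame_rate=config.fs_img,
                              roi_id=f"sim-{config.seed}", unit="counts")
    return trace, _ground_truth(config)


def random_cell_config(duration: float = 60.0,
                       event_rate_hz: float = 0.1,
                       width_range_ms: tuple[float, float] = (5.0, 20.0),
                       min_separation_s: float = 5.0,
                       f0: float = 400.0,
                       sto_freq: float = 6.0,
                       sto_amp: float = 0.0,
                       sto_dff: float = 0.0,
                       vm_noise_sd: float = 0.3,
                       seed: int = 0) -> SimConfig:
    """Draw a cell with Poisson-like spiking at realistic IO rates.

    Spike times are drawn uniformly and thinned to the requested minimal
    separation (IO neurons rarely fire above 0.2 Hz in vitro); widths
    are uniform over ``width_range_ms``.
    """
    rng = np.random.default_rng(seed)
    n_target = rng.poisson(event_rate_hz * duration)
    # leave margin at the edges so baselines and decays fit the record
    lo, hi = 2.0, duration - 5.0
    times: list[float] = []
    for t in np.sort(rng.uniform(lo, max(lo, hi), n_target)):
        if not times or t - times[-1] >= min_separation_s:
            times.append(float(t))
    widths = rng.uniform(*width_range_ms, len(times))
    return SimConfig(duration=duration, sto_freq=sto_freq, sto_amp=sto_amp,
                     spike_times=tuple(times), shoulder_widths=tuple(widths),
                     f0=f0, sto_dff=sto_dff, vm_noise_sd=vm_noise_sd,
                     seed=int(rng.integers(0, 2**31 - 1)))


# ---------------------------------------------------------------------------
# anatomy field generator
# ---------------------------------------------------------------------------

def _sample_areas(rng: np.random.Generator, n_neurons: int, n_astro: int
                  ) -> tuple[np.ndarray, np.ndarray]:
    # neurons strictly above 110 um^2, astrocytes strictly below 95 um^2,
    # so the 5th/95th percentiles straddle the 100 um^2 boundary for any draw
    neuron = 110.0 + rng.gamma(4.0, 10.0, n_neurons)
    astro = np.clip(95.0 - rng.gamma(4.0, 6.0, n_astro), 20.0, 94.0)
    return neuron, astro


def simulate_anatomy(n_neurons: int, n_astro: int, seed: int = 0,
                     pixel_size_um: float = 1.0,
                     egfp_tdtomato_ratio: float = 1.2,
                     ratio_cv: float = 0.0,
                     image_margin_um: float = 12.0,
                     ) -> tuple[dict[str, np.ndarray], pd.DataFrame, GroundTruth]:
    """Render a labelled two-reporter soma field with a NeuN channel.

    Somata are disks on a jittered grid.  Neuron soma areas are drawn
    above 110 um^2 and astrocyte areas below 95 um^2, so an area
    threshold at 100 um^2 separates the classes perfectly.  Neurons
    receive cytosolic NeuN staining; astrocytes none.  Per-cell EGFP
    intensity is ``egfp_tdtomato_ratio`` times the tdTomato intensity
    (with optional lognormal cell-to-cell scatter ``ratio_cv``).

    Returns (channels, soma table, ground truth); ``channels`` maps
    'egfp' / 'tdtomato' / 'neun' / 'labels' to images.
    """
    if n_neurons < 0 or n_astro < 0:
        raise ValueError("cell counts must be non-negative")
    rng = np.random.default_rng(seed)
    neuron_areas, astro_areas = _sample_areas(rng, n_neurons, n_astro)
    areas = np.concatenate([neuron_areas, astro_areas])
    labels = ["neuron"] * n_neurons + ["non-neuron"] * n_astro
    n_cells = len(areas)

    # jittered grid placement; spacing leaves room for the largest somata
    pitch_um = 2 * np.sqrt(areas.max() / np.pi) + 6.0 if n_cells else 30.0
    cols = max(1, int(np.ceil(np.sqrt(n_cells)))) if n_cells else 1
    rows = max(1, int(np.ceil(n_cells / cols))) if n_cells else 1
    size_y = int(np.ceil((rows * pitch_um + 2 * image_margin_um) / pixel_size_um))
    size_x = int(np.ceil((cols * pitch_um + 2 * image_margin_um) / pixel_size_um))

    egfp = np.zeros((size_y, size_x), dtype=float)
    tdtom = np.zeros_like(egfp)
    neun = np.zeros_like(egfp)
    label_img = np.zeros_like(egfp, dtype=int)

    order = rng.permutation(n_cells) if n_cells else np.array([], dtype=int)
    records = []
    for slot, idx in enumerate(order):
        r_grid, c_grid = divmod(slot, cols)
        jitter = rng.uniform(-2.0, 2.0, 2)
        cy = (image_margin_um + (r_grid + 0.5) * pitch_um + jitter[0]) / pixel_size_um
        cx = (image_margin_um + (c_grid + 0.5) * pitch_um + jitter[1]) / pixel_size_um
        radius_px = np.sqrt(areas[idx] / np.pi) / pixel_size_um
        rr, cc = draw_disk((cy, cx), radius_px, shape=egfp.shape)

        tdtom_level = rng.uniform(80.0, 120.0)
        ratio = egfp_tdtomato_ratio
        if ratio_cv > 0:
            sigma = np.sqrt(np.log(1 + ratio_cv**2))
            ratio *= rng.lognormal(-sigma**2 / 2, sigma)
        egfp_level = tdtom_level * ratio
        tdtom[rr, cc] = tdtom_level
        egfp[rr, cc] = egfp_level
        label_img[rr, cc] = idx + 1
        neun_level = rng.uniform(150.0, 250.0) if labels[idx] == "neuron" else 0.0
        if neun_level:
            neun[rr, cc] = neun_level

        records.append({
            "id": int(idx),
            "centroid_y_um": cy * pixel_size_um,
            "centroid_x_um": cx * pixel_size_um,
            "area_um2": float(areas[idx]),
            "egfp": egfp_level,
            "tdtomato": tdtom_level,
            "neun": neun_level,
            "label": labels[idx],
        })

    table = pd.DataFrame(records).sort_values("id").reset_index(drop=True) \
        if records else pd.DataFrame(
            columns=["id", "centroid_y_um", "centroid_x_um", "area_um2",
                     "egfp", "tdtomato", "neun", "label"])
    channels = {"egfp": egfp, "tdtomato": tdtom, "neun": neun, "labels": label_img}
    truth = GroundTruth(cell_labels=tuple(labels))
    return channels, table, truth


def simulate_specificity_field(shape: tuple[int, int] = (256, 256),
                               inside_fraction: float = 0.25,
                               test_over_ref_extent: float = 2.0,
                               outside_fraction: float = 0.02,
                               ref_inside_fraction: float = 0.05,
                               bright: float = 400.0,
                               background: float = 100.0,
                               background_sd: float = 5.0,
                               seed: int = 0,
                               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Paired test/reference images with planted labelling extents.

    The central disk (fraction ``inside_fraction`` of the image area) is
    the target region; inside it the test channel labels exactly
    ``test_over_ref_extent`` times as many pixels as the reference
    channel, and outside both label ``outside_fraction``.  Returns
    (test_image, ref_image, region_mask).
    """
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    r = np.sqrt(inside_fraction * shape[0] * shape[1] / np.pi)
    mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2

    test = rng.normal(background, background_sd, shape)
    ref = rng.normal(background, background_sd, shape)
    for img, frac_in in ((test, ref_inside_fraction * test_over_ref_extent),
                         (ref, ref_inside_fraction)):
        inside_idx = np.flatnonzero(mask.ravel())
        outside_idx = np.flatnonzero(~mask.ravel())
        k_in = int(round(frac_in * inside_idx.size))
        k_out = int(round(outside_fraction * outside_idx.size))
        chosen = np.concatenate([
            rng.choice(inside_idx, size=k_in, replace=False),
            rng.choice(outside_idx, size=k_out, replace=False),
        ])
        img.ravel()[chosen] = bright
    return test, ref, mask
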