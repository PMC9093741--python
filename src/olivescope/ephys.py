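"""Membrane-voltage spike measurement and waveform typing.

IO spikes are detected from current-clamp traces by a +10 mV excursion
above the trace median, with the initiation point placed at the last
sample before the rising phase crosses baseline + 2 mV.  The "spike
width" is the duration of the calcium shoulder: the contiguous time the
waveform spends above baseline + 10 mV, with sub-sample interpolation at
the crossings.  Small gap-junction spikelets never reach the threshold
and are reported with width 0 and a spikelet flag.

Waveform typing follows the field's standard recipe: PCA on the raw,
initiation-aligned waveforms (mean-centred, not rescaled), then k-means
on the first two component scores with the cluster count chosen at the
elbow of the within-cluster sum-of-squares curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

__all__ = [
    "VoltageTrace",
    "SpikeWaveform",
    "PcaResult",
    "DegenerateWaveformsError",
    "detect_spikes_vm",
    "extract_waveforms",
    "spike_width",
    "measure_spike",
    "pca_waveforms",
    "cluster_spikes",
    "sto_power_vm",
]

#: Depolarization above median baseline that qualifies as a spike [mV].
SPIKE_THRESHOLD_MV = 10.0
#: Rising-phase crossing that defines the initiation point [mV].
INITIATION_MV = 2.0
#: Merge window for multiple threshold crossings of one spike [ms].
REFRACTORY_MS = 20.0

#: Knee-strength floor for the elbow rule: within-cluster sum-of-squares
#: curves that bend no more sharply than a 1/k reference (normalized
#: chord distance <= 0.40) carry no cluster structure and yield k = 1.
KNEE_STRENGTH_MIN = 0.40


class DegenerateWaveformsError(ValueError):
    """All waveforms identical: PCA variance is zero."""


@dataclass
class VoltageTrace:
    """Membrane potential time series in mV."""

    values: np.ndarray
    sampling_rate: float
    cell_id: str | int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("voltage values must be one-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("voltage values must be finite")
        if self.sampling_rate < 1000:
            raise ValueError("sampling_rate must be at least 1 kHz")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def rate(self) -> float:
        return self.sampling_rate

    @property
    def duration(self) -> float:
        return len(self.values) / self.sampling_rate


@dataclass
class SpikeWaveform:
    """One aligned spike segment and its measurements."""

    segment: np.ndarray
    sampling_rate: float
    init_index: int = 0
    width_ms: float = np.nan
    is_spikelet: bool = False
    pc_scores: Optional[np.ndarray] = None
    cluster: Optional[int] = None


@dataclass
class PcaResult:
    components: np.ndarray
    explained_variance_ratio: np.ndarray
    scores: np.ndarray  # first two components, shape (n, 2)
    full_scores: np.ndarray = field(repr=False, default=None)


def detect_spikes_vm(trace: VoltageTrace,
                     threshold_mv: float = SPIKE_THRESHOLD_MV,
                     initiation_mv: float = INITIATION_MV,
                     refractory_ms: float = REFRACTORY_MS) -> list[int]:
    """Indices of spike initiation points.

    Baseline is the trace median (robust to STOs and sparse spikes).
    Depolarizations above baseline + ``threshold_mv`` are spikes;
    crossings closer than ``refractory_ms`` are merged.  Returns an
    empty list for a silent trace.
    """
    v = trace.values
    if len(v) < trace.sampling_rate * 0.1:
        raise ValueError("trace must be at least 100 ms long")
    baseline = float(np.median(v))
    above = v > baseline + threshold_mv
    if not above.any():
        return []
    edges = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if above[0]:
        edges = np.concatenate([[0], edges])
    gap = int(round(refractory_ms / 1000.0 * trace.sampling_rate))
    merged = [int(edges[0])]
    for e in edges[1:]:
        if e - merged[-1] > gap:
            merged.append(int(e))

    init_level = baseline + initiation_mv
    inits = []
    for e in merged:
        j = e
        while j > 0 and v[j - 1] > init_level:
            j -= 1
        inits.append(max(0, j - 1))
    return inits


def extract_waveforms(trace: VoltageTrace, inits: Sequence[int],
                      pre_ms: float = 5.0, post_ms: float = 60.0
                      ) -> tuple[np.ndarray, list[int]]:
    """Initiation-aligned waveform matrix; skips out-of-bounds spikes.

    Returns (matrix, kept initiation indices); rows start ``pre_ms``
    before the initiation point.
    """
    fs = trace.sampling_rate
    npre = int(round(pre_ms / 1000.0 * fs))
    npost = int(round(post_ms / 1000.0 * fs))
    rows, kept = [], []
    for i in inits:
        if i - npre >= 0 and i + npost <= len(trace.values):
            rows.append(trace.values[i - npre: i + npost])
            kept.append(int(i))
    mat = np.array(rows) if rows else np.empty((0, npre + npost))
    return mat, kept


def spike_width(waveform: np.ndarray, baseline: float, sampling_rate: float,
                threshold_mv: float = SPIKE_THRESHOLD_MV) -> tuple[float, bool]:
    """Calcium-shoulder duration [ms] above baseline + 10 mV.

    Measured from the first up-crossing to the first subsequent
    down-crossing, with sub-sample linear interpolation at both
    crossings.  Waveforms that never reach the threshold are spikelets:
    width 0 with the flag set.  Invariant to a common vertical offset of
    waveform and baseline.
    """
    w = np.asarray(waveform, dtype=float)
    thr = baseline + threshold_mv
    above = w >= thr
    if not above.any():
        return 0.0, True
    i = int(np.argmax(above))  # first sample at/above threshold
    if i == 0:
        t_up = 0.0
    else:
        t_up = (i - 1) + (thr - w[i - 1]) / (w[i] - w[i - 1])
    rest = np.flatnonzero(~above[i:])
    if rest.size == 0:
        t_dn = float(len(w) - 1)  # truncated at segment end
    else:
        j = i + int(rest[0])  # first sample back below threshold
        t_dn = (j - 1) + (thr - w[j - 1]) / (w[j] - w[j - 1])
    return (t_dn - t_up) * 1000.0 / sampling_rate, False


def measure_spike(segment: np.ndarray, baseline: float, sampling_rate: float
                  ) -> SpikeWaveform:
    width, spikelet = spike_width(segment, baseline, sampling_rate)
    return SpikeWaveform(segment=np.asarray(segment, dtype=float),
                         sampling_rate=sampling_rate,
                         width_ms=width, is_spikelet=spikelet)


def pca_waveforms(matrix: np.ndarray) -> PcaResult:
    """Mean-centred PCA of raw aligned waveforms (no rescaling).

    Requires at least 3 waveforms; identical waveforms (zero total
    variance) raise :class:`DegenerateWaveformsError`.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3:
        raise ValueError("need a matrix of at least 3 aligned waveforms")
    if np.allclose(x, x[0]):
        raise DegenerateWaveformsError("all waveforms identical; variance is zero")
    n_comp = min(x.shape[0] - 1, x.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    full = pca.fit_transform(x)
    evr = pca.explained_variance_ratio_
    # components with zero variance contribute nothing; keep ratios summing to 1
    evr = evr / evr.sum()
    return PcaResult(components=pca.components_,
                     explained_variance_ratio=evr,
                     scores=full[:, :2],
                     full_scores=full)


def _wss_curve(points: np.ndarray, k_max: int, seed: int) -> np.ndarray:
    return np.array([
        KMeans(n_clusters=k, n_init=10, random_state=seed).fit(points).inertia_
        for k in range(1, k_max + 1)
    ])


def _elbow(wss: np.ndarray) -> int:
    """Elbow by maximal perpendicular distance to the k=1..k_max chord.

    Both axes are normalized to [0, 1] before measuring distances.  A
    curve whose strongest knee is no sharper than a 1/k reference decay
    (distance <= KNEE_STRENGTH_MIN) is treated as structureless: k = 1.
    """
    if wss[0] <= 0 or wss[0] == wss[-1]:
        return 1
    k = np.arange(len(wss), dtype=float)
    x = k / k[-1]
    y = (wss - wss[-1]) / (wss[0] - wss[-1])
    dist = (1.0 - x - y) / np.sqrt(2.0)
    if dist.max() <= KNEE_STRENGTH_MIN:
        return 1
    return int(np.argmax(dist) + 1)


def cluster_spikes(pc_scores: np.ndarray, k_max: int = 10, seed: int = 0
                   ) -> tuple[np.ndarray, int]:
    """K-means typing of spike waveforms in PC space.

    Runs k-means for k = 1..k_max (10 restarts, seeded) and picks k at
    the elbow of the within-cluster sum-of-squares curve.  Deterministic
    under a fixed seed.  Degenerate identical points give k = 1.
    """
    pts = np.asarray(pc_scores, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    if pts.shape[0] < k_max + 1:
        raise ValueError(f"need at least k_max + 1 = {k_max + 1} points")
    if np.allclose(pts, pts[0]):
        return np.zeros(pts.shape[0], dtype=int), 1
    wss = _wss_curve(pts, k_max, seed)
    k = _elbow(wss)
    labels = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(pts)
    return labels, k


def sto_power_vm(trace: VoltageTrace, params=None, excise_spikes: bool = True) -> float:
    """Subthreshold-oscillation band power of a voltage trace [mV^2].

    Band-passes to 3-12 Hz and integrates the Blackman-windowed Welch
    PSD over the band (the mean-square voltage the oscillation carries,
    thresholded at 1 mV^2 for the oscillating/non-oscillating call).
    Spike windows are excised by linear interpolation first so spike
    energy does not leak into the band.
    """
    from . import sto  # local import to avoid a cycle

    params = params or sto.STOParams()
    v = trace.values.astype(float)
    if excise_spikes:
        inits = detect_spikes_vm(trace)
        if inits:
            fs = trace.sampling_rate
            pre = int(round(0.010 * fs))
            post = int(round(0.080 * fs))
            v = sto.excise_windows(v, [(i - pre, i + post) for i in inits])
    filtered = sto.bandpass_array(v, trace.sampling_rate, params.band)
    result = sto.welch_psd_array(filtered, trace.sampling_rate, params)
    return result.band_power
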