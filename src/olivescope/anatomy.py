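"""Transgene-expression quantification in labelled IO tissue.

Covers the anatomical arm of the analysis: separating neurons from
non-neuronal cells (astrocytes) by NeuN radial staining profile or by
the 100 um^2 soma-area threshold, reference-normalized expression
(EGFP / tdTomato), structural specificity of labelling inside versus
outside the IO contour (Z = 3 intensity thresholding), nearest-neighbor
soma distances, and cell-type preference of a construct against a
co-injected control.

Segmentation itself is out of scope: the functions consume soma tables,
label images or masks (hand-drawn ROIs in the original workflow; the
simulator provides ground-truth masks).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "RegionMask",
    "radial_profile",
    "classify_by_neun",
    "classify_by_area",
    "normalized_expression",
    "structure_specificity",
    "nn_distances",
    "cell_type_preference",
    "AREA_THRESHOLD_UM2",
    "NEUN_THRESHOLD",
    "NEUN_RADIUS_UM",
]

#: Soma-area boundary separating IO neurons from non-neurons [um^2].
AREA_THRESHOLD_UM2 = 100.0
#: Normalized NeuN intensity a neuron must exceed ...
NEUN_THRESHOLD = 0.20
#: ... within this radius of the soma centre [um].
NEUN_RADIUS_UM = 2.0


@dataclass
class RegionMask:
    """Named binary region (e.g. the IO contour) over an image grid."""

    mask: np.ndarray
    pixel_size_um: float = 1.0
    name: str = "IO"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("region mask must be 2-D")
        if not self.mask.any():
            raise ValueError("region mask is empty")


def radial_profile(image: np.ndarray, center: tuple[float, float],
                   r_max_um: float, pixel_size_um: float = 1.0
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Annulus-averaged intensity versus radius, normalized to its max.

    ``center`` is (row, col) in pixels.  Annuli are one pixel wide out
    to ``r_max_um``; the profile is divided by its maximum so the peak
    equals 1.  An all-zero neighbourhood has no normalizer and raises.
    Returns (radii_um, profile).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be 2-D")
    cy, cx = center
    if not (0 <= cy < img.shape[0] and 0 <= cx < img.shape[1]):
        raise ValueError("center must lie inside the image")
    if r_max_um <= 0:
        raise ValueError("r_max must be positive")

    yy, xx = np.indices(img.shape)
    r_px = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    r_max_px = r_max_um / pixel_size_um
    n_bins = max(1, int(np.ceil(r_max_px)))
    sel = r_px < n_bins
    bins = r_px[sel].astype(int)
    sums = np.bincount(bins, weights=img[sel], minlength=n_bins)
    counts = np.bincount(bins, minlength=n_bins)
    profile = np.divide(sums, counts, out=np.zeros(n_bins), where=counts > 0)
    peak = profile.max()
    if peak <= 0:
        raise ValueError("no signal within r_max; profile cannot be normalized")
    radii_um = (np.arange(n_bins) + 0.5) * pixel_size_um
    return radii_um, profile / peak


def classify_by_neun(radii_um: np.ndarray, profile: np.ndarray,
                     threshold: float = NEUN_THRESHOLD,
                     radius_um: float = NEUN_RADIUS_UM) -> str:
    """'neuron' iff normalized NeuN staining exceeds 20% within 2 um.

    Strictly greater than the threshold; 0.20 exactly is 'non-neuron'.
    """
    radii_um = np.asarray(radii_um, dtype=float)
    profile = np.asarray(profile, dtype=float)
    if radii_um.size == 0 or radii_um.max() < radius_um:
        raise ValueError(f"profile must cover at least {radius_um:g} um")
    inner = profile[radii_um <= radius_um]
    return "neuron" if np.any(inner > threshold) else "non-neuron"


def classify_by_area(area_um2: float,
                     threshold_um2: float = AREA_THRESHOLD_UM2) -> str:
    """'neuron' iff soma area strictly exceeds 100 um^2."""
    return "neuron" if area_um2 > threshold_um2 else "non-neuron"


def normalized_expression(test_mean: float, reference_mean: float) -> float:
    """Test-channel intensity normalized to the reference reporter."""
    if reference_mean <= 0:
        raise ValueError("reference intensity must be positive")
    return test_mean / reference_mean


def structure_specificity(test_image: np.ndarray, ref_image: np.ndarray,
                          region: RegionMask, z: float = 3.0
                          ) -> dict[str, Optional[float]]:
    """Labelled extent and intensity of test vs reference, inside/outside
    the region.

    Each channel is thresholded at its whole-image mean + z*SD; pixels
    above are "labelled".  Per compartment, the extent ratio is the
    labelled pixel count of the test channel over the reference's, and
    the intensity ratio the mean supra-threshold intensity of test over
    reference.  Compartments without supra-threshold reference pixels
    yield ``None`` (undefined, not zero).
    """
    test = np.asarray(test_image, dtype=float)
    ref = np.asarray(ref_image, dtype=float)
    if test.shape != ref.shape or test.shape != region.mask.shape:
        raise ValueError("images and region mask must share a shape")

    test_lab = test > test.mean() + z * test.std()
    ref_lab = ref > ref.mean() + z * ref.std()

    out: dict[str, Optional[float]] = {}
    for name, comp in (("inside", region.mask), ("outside", ~region.mask)):
        t_n = int(np.sum(test_lab & comp))
        r_n = int(np.sum(ref_lab & comp))
        out[f"{name}_extent_ratio"] = t_n / r_n if r_n else None
        if r_n and t_n:
            out[f"{name}_intensity_ratio"] = (
                float(test[test_lab & comp].mean())
                / float(ref[ref_lab & comp].mean()))
        else:
            out[f"{name}_intensity_ratio"] = None
    return out


def nn_distances(centroids: np.ndarray) -> np.ndarray:
    """Per-cell shortest Euclidean distance to any other centroid."""
    pts = np.asarray(centroids, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("need at least 2 centroids")
    d = cdist(pts, pts)
    np.fill_diagonal(d, np.inf)
    return d.min(axis=1)


def cell_type_preference(test_counts: Mapping[str, float],
                         ref_counts: Mapping[str, float]) -> float:
    """Neuron-over-astrocyte labelling preference of a construct [%].

    Labelled neuron and astrocyte counts are each normalized by the
    co-injected reference construct, and the preference is the percent
    excess of the neuron ratio over the astrocyte ratio: positive values
    mean neuron-preferring.
    """
    for key in ("neuron", "astro"):
        if ref_counts.get(key, 0) <= 0:
            raise ValueError(f"reference {key} count must be positive")
    neuron_ratio = test_counts["neuron"] / ref_counts["neuron"]
    astro_ratio = test_counts["astro"] / ref_counts["astro"]
    if astro_ratio == 0:
        raise ValueError("astrocyte ratio is zero; preference undefined")
    return (neuron_ratio / astro_ratio - 1.0) * 100.0
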