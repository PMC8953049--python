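"""Infarct size estimation from PET slices and TTC stain photographs.

PET route: the activity distribution inside the myocardial VOI on a short-axis
slice is split into low / medium / high perfusion classes by a two-threshold
Otsu criterion (exhaustive maximisation of between-class variance over all
bin-pair splits — exact and deterministic, no iterative refinement).  The low
class is read as infarct; medium and high are viable, and

    infarct % = 100 x low / (low + medium + high).

Stain route: a TTC-stained slice photograph is segmented in HSV/lightness
space — near-white background removed by a lightness threshold, tissue split
into viable (dark red hue, saturated) vs infarcted (tan hue, weakly
saturated) by configurable hue-saturation boxes — and the same percentage is
computed on pixel counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.color import rgb2hsv

from .errors import DegenerateInputError, ValidationError
from .image_io import VoiMask, VolumeGrid

#: Grid axis treated as the left-ventricular long axis; short-axis slices
#: are planes perpendicular to it.
SHORT_AXIS = 2


def otsu_two_thresholds(
    values, n_bins: int = 64
) -> tuple[float, float]:
    """Two thresholds maximising three-class between-class variance.

    The value range is binned into ``n_bins`` equal-width bins and every
    bin-pair split (i, j) is scored; the score depends only on class
    weights and means, so the search is exact over the binned data.
    Returns bin-edge thresholds ``(t1, t2)`` defining the classes
    ``v < t1``, ``t1 <= v < t2``, ``v >= t2``.
    """
    v = np.asarray(values, dtype=float).ravel()
    if np.unique(v).size < 3:
        raise DegenerateInputError(
            "three-class thresholding needs at least 3 distinct values"
        )
    counts, edges = np.histogram(v, bins=int(n_bins), range=(v.min(), v.max()))
    mids = 0.5 * (edges[:-1] + edges[1:])

    w = np.concatenate([[0.0], np.cumsum(counts)])          # cumulative weight
    s = np.concatenate([[0.0], np.cumsum(counts * mids)])   # cumulative sum

    def class_score(lo: int, hi: int) -> float:
        # weight * mean^2 contribution of bins [lo, hi)
        cw = w[hi] - w[lo]
        if cw == 0:
            return 0.0
        return (s[hi] - s[lo]) ** 2 / cw

    best, best_split = -np.inf, None
    nb = len(counts)
    for i in range(1, nb - 1):
        left = class_score(0, i)
        for j in range(i + 1, nb):
            score = left + class_score(i, j) + class_score(j, nb)
            if score > best + 1e-12:
                best, best_split = score, (i, j)
    i, j = best_split
    return float(edges[i]), float(edges[j])


def classify(values: np.ndarray, thresholds: tuple[float, float]) -> np.ndarray:
    """Label values 0 (low), 1 (medium), 2 (high) by the two thresholds."""
    t1, t2 = thresholds
    if not t1 < t2:
        raise ValidationError(f"thresholds must be increasing, got ({t1}, {t2})")
    v = np.asarray(values, dtype=float)
    return np.where(v < t1, 0, np.where(v < t2, 1, 2))


def stratify_slice(
    volume: VolumeGrid,
    mask: VoiMask,
    slice_index: int,
    thresholds: tuple[float, float],
) -> np.ndarray:
    """Three-class label map of one short-axis slice.

    Returns a 2D integer array: -1 outside the mask, otherwise 0/1/2 for
    low/medium/high perfusion.  Every masked voxel in the slice receives
    exactly one label.
    """
    volume.require_congruent(mask, what="volume/mask")
    sl = [slice(None)] * 3
    sl[SHORT_AXIS] = slice_index
    plane = volume.values[tuple(sl)]
    mplane = mask.values[tuple(sl)]
    if not mplane.any():
        raise ValidationError(f"slice {slice_index} does not intersect the mask")
    labels = np.full(plane.shape, -1, dtype=int)
    labels[mplane] = classify(plane[mplane], thresholds)
    return labels


@dataclass(frozen=True)
class SliceInfarctEstimate:
    """Otsu-stratified infarct estimate for one short-axis slice."""

    thresholds: tuple[float, float]
    low_count: int
    medium_count: int
    high_count: int

    @property
    def infarct_pct(self) -> float:
        total = self.low_count + self.medium_count + self.high_count
        return 100.0 * self.low_count / total


def infarct_percentage(
    volume: VolumeGrid,
    mask: VoiMask,
    slice_index: int,
    thresholds: tuple[float, float] | None = None,
    n_bins: int = 64,
) -> SliceInfarctEstimate:
    """Infarct percentage on one short-axis slice.

    Thresholds default to the two-threshold Otsu split of the masked voxel
    values on that slice; an explicit ``thresholds`` pair overrides it (the
    programmatic stand-in for manual expert adjustment of the class
    boundaries).
    """
    if thresholds is None:
        sl = [slice(None)] * 3
        sl[SHORT_AXIS] = slice_index
        vals = volume.values[tuple(sl)][mask.values[tuple(sl)]]
        if vals.size == 0:
            raise ValidationError(f"slice {slice_index} does not intersect the mask")
        thresholds = otsu_two_thresholds(vals, n_bins=n_bins)
    labels = stratify_slice(volume, mask, slice_index, thresholds)
    counts = [int(np.sum(labels == k)) for k in (0, 1, 2)]
    if sum(counts) == 0:
        raise ValidationError("no masked voxels to stratify")
    return SliceInfarctEstimate(thresholds, *counts)


def lv_infarct_percentage(
    volume: VolumeGrid,
    mask: VoiMask,
    thresholds: tuple[float, float] | None = None,
    n_bins: int = 64,
) -> SliceInfarctEstimate:
    """Whole-VOI aggregate: one Otsu split over all masked voxels.

    Equivalent to a voxel-weighted mean of per-slice percentages computed at
    shared thresholds; provided as a convenience beside the per-slice
    estimate.
    """
    mask.require_nonempty()
    vals = volume.values[mask.values]
    if thresholds is None:
        thresholds = otsu_two_thresholds(vals, n_bins=n_bins)
    labels = classify(vals, thresholds)
    counts = [int(np.sum(labels == k)) for k in (0, 1, 2)]
    return SliceInfarctEstimate(tuple(thresholds), *counts)


def _hue_in_ranges(hue_deg: np.ndarray, ranges) -> np.ndarray:
    out = np.zeros(hue_deg.shape, dtype=bool)
    for lo, hi in ranges:
        out |= (hue_deg >= lo) & (hue_deg <= hi)
    return out


@dataclass(frozen=True)
class StainColorConfig:
    """Hue/saturation boxes for TTC stain segmentation.

    Hue in degrees on the HSV wheel; saturation and lightness in [0, 1].
    Defaults: viable myocardium stains dark red (hue near 0/360, strongly
    saturated), infarct stays tan (hue 20-60 deg, weakly saturated), and the
    photo background is near-white (high lightness).  All boxes are exposed
    because stain intensity varies between preparations.
    """

    viable_hue_deg: tuple = ((330.0, 360.0), (0.0, 20.0))
    viable_sat_min: float = 0.4
    infarct_hue_deg: tuple = ((20.0, 60.0),)
    infarct_sat_range: tuple[float, float] = (0.1, 0.5)
    background_lightness_min: float = 0.9


@dataclass(frozen=True)
class StainSegmentation:
    """Pixel-level viable/infarct segmentation of a stained slice photo."""

    viable_mask: np.ndarray
    infarct_mask: np.ndarray

    @property
    def infarct_pct(self) -> float:
        n_inf = int(self.infarct_mask.sum())
        n_via = int(self.viable_mask.sum())
        return 100.0 * n_inf / (n_inf + n_via)


def stain_infarct(
    image: np.ndarray, config: StainColorConfig = StainColorConfig()
) -> StainSegmentation:
    """Segment a TTC stain photograph into viable vs infarcted tissue.

    ``image`` is an RGB array (uint8 or float in [0, 1]).  Background pixels
    are removed by an HSL-lightness threshold; remaining tissue pixels are
    classified by the hue-saturation boxes in ``config``.  Pixels matching
    neither box (shadows, slide edges) are excluded from the percentage.
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] < 3:
        raise ValidationError("expected an RGB image (H x W x 3)")
    rgb = img[..., :3].astype(float)
    if rgb.max() > 1.0:
        rgb = rgb / 255.0

    lightness = 0.5 * (rgb.max(axis=2) + rgb.min(axis=2))
    tissue = lightness <= config.background_lightness_min
    if not tissue.any():
        raise ValidationError("no tissue pixels remain after background removal")

    hsv = rgb2hsv(rgb)
    hue_deg = hsv[..., 0] * 360.0
    sat = hsv[..., 1]

    viable = (
        tissue
        & _hue_in_ranges(hue_deg, config.viable_hue_deg)
        & (sat > config.viable_sat_min)
    )
    lo, hi = config.infarct_sat_range
    infarct = (
        tissue
        & _hue_in_ranges(hue_deg, config.infarct_hue_deg)
        & (sat >= lo)
        & (sat <= hi)
        & ~viable
    )
    if not (viable.any() or infarct.any()):
        raise ValidationError("no pixels match the viable or infarct color boxes")
    return StainSegmentation(viable_mask=viable, infarct_mask=infarct)
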