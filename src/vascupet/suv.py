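"""Decay correction, SUV conversion, and VOI activity quantification.

The standardized uptake value normalises voxel activity by injected dose per
body mass:

    SUV (g/mL) = voxel (Bq/mL) x C x weight (kg) / dose (Bq) x 1000 (g/kg)

where C = 2^(delay / half-life) corrects the measured activity back to
injection time (C = 1 when the delay is zero, so correction to scan start is
obtained simply by passing ``delay_min=0``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .image_io import (
    UNIT_BQ_ML,
    UNIT_SUV,
    AcquisitionMeta,
    VoiMask,
    VolumeGrid,
)
from .errors import UnitError


def decay_factor(delay_min: float, half_life_min: float) -> float:
    """Decay-correction factor C = 2^(delay / half-life), always >= 1."""
    if delay_min < 0:
        raise ValidationError(f"delay must be >= 0 min, got {delay_min}")
    if half_life_min <= 0:
        raise ValidationError(f"half-life must be positive, got {half_life_min}")
    return float(2.0 ** (delay_min / half_life_min))


def to_suv(volume: VolumeGrid, meta: AcquisitionMeta) -> VolumeGrid:
    """Convert a Bq/mL volume to SUV (g/mL) units."""
    if volume.unit != UNIT_BQ_ML:
        raise UnitError(f"SUV conversion requires a Bq/mL volume, got {volume.unit!r}")
    c = decay_factor(meta.delay_min, meta.half_life_min)
    scale = c * meta.weight_kg / meta.dose_bq * 1000.0
    return VolumeGrid(volume.values * scale, volume.voxel_size_mm, UNIT_SUV)


@dataclass(frozen=True)
class VoiStats:
    """Summary of voxel activity inside a VOI."""

    sum: float
    mean: float
    voxel_count: int
    volume_mL: float


def voi_total(volume: VolumeGrid, mask: VoiMask) -> VoiStats:
    """Total and mean activity of the masked voxels.

    The raw voxel-value sum is what downstream vasodilation ratios use; the
    mL-normalised volume is reported alongside for reference.
    """
    volume.require_congruent(mask, what="volume/mask")
    mask.require_nonempty()
    vals = volume.values[mask.values]
    return VoiStats(
        sum=float(vals.sum()),
        mean=float(vals.mean()),
        voxel_count=int(vals.size),
        volume_mL=vals.size * volume.voxel_volume_mL,
    )


@dataclass
class ActivityHistogram:
    """Histogram of voxel activity inside a VOI; counts conserve voxel count."""

    bin_edges: np.ndarray
    counts: np.ndarray
    unit: str

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.bin_edges.ndim != 1 or np.any(np.diff(self.bin_edges) <= 0):
            raise ValidationError("bin edges must be strictly increasing")
        if len(self.counts) != len(self.bin_edges) - 1:
            raise ValidationError("need exactly one count per bin")
        if np.any(self.counts < 0):
            raise ValidationError("counts must be non-negative")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "bin_start": self.bin_edges[:-1],
                "bin_end": self.bin_edges[1:],
                "count": self.counts,
            }
        )


def histogram(
    volume: VolumeGrid,
    mask: VoiMask,
    bins: int | np.ndarray = 64,
) -> ActivityHistogram:
    """Histogram of masked voxel values.

    ``bins`` is either a bin count (equal-width bins spanning the masked
    min-max, widened trivially when all values coincide) or an explicit
    strictly-increasing edge array.
    """
    volume.require_congruent(mask, what="volume/mask")
    mask.require_nonempty()
    vals = volume.values[mask.values]
    if np.ndim(bins) == 0:
        lo, hi = float(vals.min()), float(vals.max())
        if lo == hi:  # degenerate range: single-value VOI
            hi = lo + 1.0
        counts, edges = np.histogram(vals, bins=int(bins), range=(lo, hi))
    else:
        edges = np.asarray(bins, dtype=float)
        if np.any(np.diff(edges) <= 0):
            raise ValidationError("explicit bin edges must be strictly increasing")
        counts, edges = np.histogram(vals, bins=edges)
        if counts.sum() != vals.size:
            raise ValidationError(
                "explicit bin edges do not cover all masked values; "
                f"{vals.size - counts.sum()} voxels fall outside"
            )
    return ActivityHistogram(edges, counts, volume.unit)
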