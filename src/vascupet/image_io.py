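"""Volume, mask and acquisition-metadata containers with NIfTI-1 round-trip I/O.

The pipeline operates on already-reconstructed voxel volumes.  Geometry is
deliberately rigid: every operation requires *congruent* grids (same shape,
same spacing) and no resampling is ever performed, mirroring a single-scanner
acquisition where rest/stress volumes share the reconstruction grid.

Unit bookkeeping matters because the same arrays flow through Bq/mL
quantification, SUV conversion, and signed "difference" imaging; the unit
tag is carried in memory and persisted in a small JSON sidecar next to the
NIfTI file (NIfTI-1 itself has no standard activity-unit field).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import GeometryError, UnitError, ValidationError

#: Recognised unit tags for :class:`VolumeGrid`.
UNIT_BQ_ML = "Bq_per_mL"
UNIT_SUV = "SUV_g_per_mL"
UNIT_DIFFERENCE = "difference"
VALID_UNITS = (UNIT_BQ_ML, UNIT_SUV, UNIT_DIFFERENCE)

#: Physical half-life of fluorine-18 in minutes.
F18_HALF_LIFE_MIN = 109.77


@dataclass
class VolumeGrid:
    """A 3D scalar field with voxel spacing (mm) and an activity-unit tag.

    Parameters
    ----------
    values
        3D array of voxel values. Must be finite; must be non-negative
        unless ``unit`` is ``"difference"``.
    voxel_size_mm
        Positive spacing triple ``(sx, sy, sz)`` in millimetres.
    unit
        One of ``"Bq_per_mL"``, ``"SUV_g_per_mL"``, ``"difference"``.
    """

    values: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    unit: str = UNIT_BQ_ML

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValidationError(f"expected a 3D array, got ndim={self.values.ndim}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("volume contains non-finite values")
        if np.isscalar(self.voxel_size_mm) or np.ndim(self.voxel_size_mm) == 0:
            s = float(self.voxel_size_mm)  # isotropic shorthand
            self.voxel_size_mm = (s, s, s)
        self.voxel_size_mm = tuple(float(s) for s in self.voxel_size_mm)
        if len(self.voxel_size_mm) != 3 or any(s <= 0 for s in self.voxel_size_mm):
            raise ValidationError(f"voxel spacing must be a positive triple, got {self.voxel_size_mm}")
        if self.unit not in VALID_UNITS:
            raise UnitError(f"unknown unit tag {self.unit!r}; expected one of {VALID_UNITS}")
        if self.unit != UNIT_DIFFERENCE and np.any(self.values < 0):
            raise ValidationError(f"negative voxel values are invalid in a {self.unit} volume")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mL(self) -> float:
        """Volume of one voxel in millilitres (1 mL = 1000 mm^3)."""
        return float(np.prod(self.voxel_size_mm)) / 1000.0

    def congruent_with(self, other: "VolumeGrid | VoiMask") -> bool:
        return self.shape == other.shape and np.allclose(
            self.voxel_size_mm, other.voxel_size_mm
        )

    def require_congruent(self, other: "VolumeGrid | VoiMask", what: str = "volume") -> None:
        if not self.congruent_with(other):
            raise GeometryError(
                f"{what} grids are not congruent: "
                f"{self.shape}@{self.voxel_size_mm} vs {other.shape}@{other.voxel_size_mm}"
            )


@dataclass
class VoiMask:
    """Binary volume-of-interest mask congruent with a :class:`VolumeGrid`.

    Stands in for manual voxel-by-voxel delineation of the LV myocardium or
    whole brain: segmentation arrives as a mask file, never interactively.
    """

    values: np.ndarray
    voxel_size_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 3:
            raise ValidationError(f"expected a 3D mask, got ndim={arr.ndim}")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValidationError("mask must be binary (0/1)")
        self.values = arr.astype(bool)
        if np.isscalar(self.voxel_size_mm) or np.ndim(self.voxel_size_mm) == 0:
            s = float(self.voxel_size_mm)
            self.voxel_size_mm = (s, s, s)
        self.voxel_size_mm = tuple(float(s) for s in self.voxel_size_mm)
        if any(s <= 0 for s in self.voxel_size_mm):
            raise ValidationError("voxel spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())

    def require_nonempty(self) -> None:
        if self.voxel_count == 0:
            raise ValidationError("mask is empty; quantification over it is undefined")


@dataclass
class AcquisitionMeta:
    """Injection/scan metadata feeding the SUV formula.

    SUV (g/mL) = voxel value x (C x weight(kg) / dose(Bq)) x 1000 (g/kg),
    with C the fluorine-18 decay-correction factor 2^(delay / half-life).
    """

    dose_bq: float
    weight_kg: float
    delay_min: float = 0.0
    half_life_min: float = F18_HALF_LIFE_MIN

    def __post_init__(self) -> None:
        if self.dose_bq <= 0:
            raise ValidationError(f"injected dose must be positive, got {self.dose_bq}")
        if self.weight_kg <= 0:
            raise ValidationError(f"body weight must be positive, got {self.weight_kg}")
        if self.delay_min < 0:
            raise ValidationError(f"injection-to-scan delay must be >= 0, got {self.delay_min}")
        if self.half_life_min <= 0:
            raise ValidationError(f"half-life must be positive, got {self.half_life_min}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "AcquisitionMeta":
        return cls(**json.loads(Path(path).read_text()))


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for ext in (".nii.gz", ".nii"):
        if name.endswith(ext):
            return path.with_name(name[: -len(ext)] + ".json")
    return path.with_suffix(".json")


def write_volume(volume: VolumeGrid, path: str | Path) -> None:
    """Write a volume as NIfTI-1 with spacing in the affine plus a unit sidecar."""
    path = Path(path)
    affine = np.diag(list(volume.voxel_size_mm) + [1.0])
    nib.save(nib.Nifti1Image(volume.values.astype(np.float32), affine), str(path))
    _sidecar_path(path).write_text(json.dumps({"unit": volume.unit}))


def read_volume(path: str | Path, unit: str | None = None) -> VolumeGrid:
    """Read a NIfTI-1 volume.

    The unit tag comes from the JSON sidecar written by :func:`write_volume`;
    an explicit ``unit`` argument overrides it, and Bq/mL is assumed when
    neither is available.
    """
    path = Path(path)
    img = nib.load(str(path))
    spacing = tuple(float(s) for s in img.header.get_zooms()[:3])
    if unit is None:
        sidecar = _sidecar_path(path)
        unit = (
            json.loads(sidecar.read_text()).get("unit", UNIT_BQ_ML)
            if sidecar.exists()
            else UNIT_BQ_ML
        )
    return VolumeGrid(np.asarray(img.dataobj, dtype=float), spacing, unit)


def write_mask(mask: VoiMask, path: str | Path) -> None:
    affine = np.diag(list(mask.voxel_size_mm) + [1.0])
    nib.save(nib.Nifti1Image(mask.values.astype(np.uint8), affine), str(path))


def read_mask(path: str | Path, reference: VolumeGrid) -> VoiMask:
    """Read a binary mask and check congruence against a reference volume."""
    img = nib.load(str(path))
    spacing = tuple(float(s) for s in img.header.get_zooms()[:3])
    mask = VoiMask(np.asarray(img.dataobj) > 0.5, spacing)
    reference.require_congruent(mask, what="mask/reference")
    return mask
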