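"""Synthetic gated blood-pool PET phantoms and TTC stain images.

The generator emulates what the quantification pipeline actually consumes:
already-reconstructed voxel volumes of a blood-pool tracer.  An LV phantom
is an axis-aligned ellipsoidal myocardial shell (grid axis 2 = long axis)
around a blood-filled chamber; a brain phantom is a filled ellipsoid.
Tissue signal is purely intravascular: ``vascular_fraction x blood_activity``,
multiplied by ``1 + vasodilation_delta`` under pharmacological stress (the
chamber blood itself does not change).  An infarct is an angular wedge of
the shell with its vascular signal scaled down.  Cardiac gating is emulated
by a small prescribed wall-thickness modulation across gates — systole
thickest wall, diastole (gate 0) thinnest wall / largest cavity — without
simulating an ECG.

Degradation is applied in physical order: isotropic Gaussian PSF blur in mm
(partial-volume effect), then per-voxel Poisson noise on
``counts = activity x dwell_scale`` rescaled back to Bq/mL.  All randomness
derives from the spec's single integer seed; outputs are bit-reproducible.

Noise-free, blur-free phantoms are exactly piecewise constant, so every
downstream statistic has a closed-form ground truth.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ValidationError
from .image_io import UNIT_BQ_ML, VoiMask, VolumeGrid, write_mask, write_volume

#: Fractional inner-radius reduction at systole (gate-wise wall thickening).
WALL_MODULATION = 0.15


@dataclass(frozen=True)
class InfarctSpec:
    """An infarct wedge: angular sector of the shell with scaled-down signal."""

    extent_deg: float
    activity_scale: float
    start_deg: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.extent_deg <= 360:
            raise ValidationError(
                f"wedge extent must be in (0, 360] degrees, got {self.extent_deg}"
            )
        if not 0 <= self.activity_scale <= 1:
            raise ValidationError(
                f"infarct activity scale must be in [0, 1], got {self.activity_scale}"
            )


@dataclass(frozen=True)
class PhantomSpec:
    """Full parameterisation of a synthetic acquisition.

    ``blood_activity`` is the chamber/blood Bq/mL; tissue (shell or brain)
    carries ``vascular_fraction`` of it.  ``dwell_scale`` converts Bq/mL to
    expected counts per voxel for the Poisson model (counts = activity x
    dwell_scale), so larger values mean longer effective dwell and lower
    relative noise.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: float = 1.4
    blood_activity: float = 10000.0
    vascular_fraction: float = 0.1
    vasodilation_delta: float = 0.0
    infarct: InfarctSpec | None = None
    psf_sigma_mm: float = 0.0
    noise: str = "none"  # "none" | "poisson"
    dwell_scale: float = 1.0
    n_gates: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(int(s) <= 0 for s in self.grid_shape):
            raise ValidationError(f"grid shape must be a positive triple, got {self.grid_shape}")
        if self.voxel_size_mm <= 0:
            raise ValidationError("voxel size must be positive")
        if self.blood_activity < 0:
            raise ValidationError("blood activity must be >= 0")
        if not 0 <= self.vascular_fraction <= 1:
            raise ValidationError(
                f"vascular fraction must be in [0, 1], got {self.vascular_fraction}"
            )
        if self.vasodilation_delta < 0:
            raise ValidationError("vasodilation delta must be >= 0")
        if self.psf_sigma_mm < 0:
            raise ValidationError("PSF sigma must be >= 0")
        if self.noise not in ("none", "poisson"):
            raise ValidationError(f"unknown noise model {self.noise!r}")
        if self.noise == "poisson" and self.dwell_scale <= 0:
            raise ValidationError("Poisson noise needs a positive dwell scale")
        if self.n_gates < 1:
            raise ValidationError("need at least one gate")

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PhantomSpec":
        d = json.loads(Path(path).read_text())
        if d.get("infarct") is not None:
            d["infarct"] = InfarctSpec(**d["infarct"])
        d["grid_shape"] = tuple(d["grid_shape"])
        return cls(**d)


@dataclass(frozen=True)
class GatedPhantom:
    """One synthetic gated acquisition with its ground truth attached."""

    gates: tuple[VolumeGrid, ...]
    myocardium_mask: VoiMask
    chamber_mask: VoiMask
    diastolic_gate_index: int
    truth: PhantomSpec

    @property
    def diastolic_gate(self) -> VolumeGrid:
        return self.gates[self.diastolic_gate_index]


def _coords_mm(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    axes = [
        (np.arange(n) - (n - 1) / 2.0) * spec.voxel_size_mm
        for n in spec.grid_shape
    ]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid(x, y, z, semi_axes) -> np.ndarray:
    a, b, c = semi_axes
    return (x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2 <= 1.0


def _lv_semi_axes(spec: PhantomSpec) -> tuple[tuple, tuple]:
    """Outer and diastolic-inner semi-axes (mm), scaled to the grid extent."""
    half = min(n * spec.voxel_size_mm for n in spec.grid_shape) / 2.0
    outer = (0.50 * half, 0.50 * half, 0.70 * half)
    inner = tuple(0.60 * s for s in outer)
    return outer, inner


def _gate_inner_scale(gate: int, n_gates: int) -> float:
    # gate 0 = diastole (largest cavity); mid-cycle = systole (thickest wall)
    if n_gates == 1:
        return 1.0
    return 1.0 - WALL_MODULATION * np.sin(np.pi * gate / n_gates) ** 2


def _wedge_mask(x, y, infarct: InfarctSpec) -> np.ndarray:
    theta = np.degrees(np.arctan2(y, x)) % 360.0
    rel = (theta - infarct.start_deg) % 360.0
    return rel < infarct.extent_deg


def _degrade(values: np.ndarray, spec: PhantomSpec, rng_key: tuple) -> np.ndarray:
    if spec.psf_sigma_mm > 0:
        values = gaussian_filter(
            values, sigma=spec.psf_sigma_mm / spec.voxel_size_mm, mode="constant"
        )
    if spec.noise == "poisson":
        rng = np.random.default_rng(np.random.SeedSequence(list(rng_key)))
        counts = rng.poisson(np.maximum(values, 0.0) * spec.dwell_scale)
        values = counts / spec.dwell_scale
    return values


_MODE_CODE = {"rest": 0, "stress": 1}


def _tissue_value(spec: PhantomSpec, mode: str) -> float:
    v = spec.vascular_fraction * spec.blood_activity
    if mode == "stress":
        v *= 1.0 + spec.vasodilation_delta
    return v


def make_lv_phantom(spec: PhantomSpec, mode: str = "rest") -> GatedPhantom:
    """Gated left-ventricle phantom: blood-pool chamber inside a myocardial shell.

    Stress multiplies the *shell* vascular signal by ``1 + delta``; chamber
    blood activity is unchanged.  Masks are defined on the diastolic
    geometry (gate 0), which is also what the analysis consumes.
    """
    if mode not in _MODE_CODE:
        raise ValidationError(f"mode must be 'rest' or 'stress', got {mode!r}")
    x, y, z = _coords_mm(spec)
    outer_ax, inner_ax0 = _lv_semi_axes(spec)
    outer = _ellipsoid(x, y, z, outer_ax)

    tissue = _tissue_value(spec, mode)
    wedge = None
    if spec.infarct is not None:
        wedge = _wedge_mask(x, y, spec.infarct)

    gates = []
    inner_dia = _ellipsoid(x, y, z, inner_ax0)
    for g in range(spec.n_gates):
        scale = _gate_inner_scale(g, spec.n_gates)
        inner = _ellipsoid(x, y, z, tuple(scale * s for s in inner_ax0))
        shell = outer & ~inner
        vol = np.zeros(spec.grid_shape, dtype=float)
        vol[inner] = spec.blood_activity
        vol[shell] = tissue
        if wedge is not None:
            vol[shell & wedge] = tissue * spec.infarct.activity_scale
        vol = _degrade(vol, spec, (spec.seed, _MODE_CODE[mode], g))
        gates.append(VolumeGrid(vol, spec.voxel_size_mm, UNIT_BQ_ML))

    shell_dia = outer & ~inner_dia
    if wedge is not None and not (shell_dia & wedge).any():
        raise ValidationError("infarct wedge does not intersect the myocardial shell")
    return GatedPhantom(
        gates=tuple(gates),
        myocardium_mask=VoiMask(shell_dia, spec.voxel_size_mm),
        chamber_mask=VoiMask(inner_dia, spec.voxel_size_mm),
        diastolic_gate_index=0,
        truth=spec,
    )


def make_brain_phantom(spec: PhantomSpec, mode: str = "rest") -> tuple[VolumeGrid, VoiMask]:
    """Whole-brain phantom: a filled ellipsoid of uniform vascular signal."""
    if mode not in _MODE_CODE:
        raise ValidationError(f"mode must be 'rest' or 'stress', got {mode!r}")
    x, y, z = _coords_mm(spec)
    half = min(n * spec.voxel_size_mm for n in spec.grid_shape) / 2.0
    brain = _ellipsoid(x, y, z, (0.55 * half, 0.50 * half, 0.45 * half))
    vol = np.zeros(spec.grid_shape, dtype=float)
    vol[brain] = _tissue_value(spec, mode)
    vol = _degrade(vol, spec, (spec.seed, _MODE_CODE[mode], 0))
    return VolumeGrid(vol, spec.voxel_size_mm, UNIT_BQ_ML), VoiMask(brain, spec.voxel_size_mm)


# -- TTC stain image -------------------------------------------------------

VIABLE_RGB = (150, 30, 40)     # dark red, strongly saturated
INFARCT_RGB = (210, 180, 140)  # tan, weakly saturated
LABEL_BACKGROUND, LABEL_VIABLE, LABEL_INFARCT = 0, 1, 2


def make_ttc_image(
    wedge_fraction: float,
    image_size: int = 256,
    viable_color: tuple = VIABLE_RGB,
    infarct_color: tuple = INFARCT_RGB,
    r_outer_frac: float = 0.42,
    r_inner_frac: float = 0.18,
    jitter: float = 5.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic TTC-stained short-axis slice photograph.

    An annular tissue "slice" on a white background; a contiguous angular
    wedge covering ``wedge_fraction`` of the annulus is rendered in the
    infarct (tan) color, the remainder in the viable (dark red) color, with
    seeded Gaussian color jitter of standard deviation ``jitter`` intensity
    levels on tissue pixels.  Returns ``(rgb_uint8, label_mask)`` with
    labels 0 = background, 1 = viable, 2 = infarct.
    """
    if not 0 <= wedge_fraction <= 1:
        raise ValidationError(f"wedge fraction must be in [0, 1], got {wedge_fraction}")
    if not 0 <= r_inner_frac < r_outer_frac <= 0.5:
        raise ValidationError(
            f"degenerate annulus: inner {r_inner_frac}, outer {r_outer_frac}"
        )
    n = int(image_size)
    if n < 8:
        raise ValidationError("image size too small for an annulus")
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    cx = cy = (n - 1) / 2.0
    r = np.hypot(xx - cx, yy - cy)
    annulus = (r >= r_inner_frac * n) & (r <= r_outer_frac * n)
    if not annulus.any():
        raise ValidationError("degenerate annulus: no tissue pixels")
    theta = np.degrees(np.arctan2(yy - cy, xx - cx)) % 360.0
    wedge = annulus & (theta < 360.0 * wedge_fraction)

    labels = np.zeros((n, n), dtype=np.uint8)
    labels[annulus] = LABEL_VIABLE
    labels[wedge] = LABEL_INFARCT

    img = np.full((n, n, 3), 255.0)
    img[labels == LABEL_VIABLE] = viable_color
    img[labels == LABEL_INFARCT] = infarct_color
    if jitter > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, jitter, size=img.shape)
        tissue = labels > 0
        img[tissue] = img[tissue] + noise[tissue]
    return np.clip(np.rint(img), 0, 255).astype(np.uint8), labels


def save_gated_phantom(phantom: GatedPhantom, out_dir: str | Path, prefix: str = "phantom") -> None:
    """Persist all gates, masks, and the generating spec for provenance."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for g, vol in enumerate(phantom.gates):
        write_volume(vol, out / f"{prefix}_gate{g}.nii.gz")
    write_mask(phantom.myocardium_mask, out / f"{prefix}_myocardium.nii.gz")
    write_mask(phantom.chamber_mask, out / f"{prefix}_chamber.nii.gz")
    phantom.truth.to_json(out / f"{prefix}_spec.json")
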