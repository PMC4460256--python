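"""Synthetic two-shell head volumes and voxel-level preprocessing.

The generator builds an ellipsoidal "head" on an 8-bit voxel grid: background
below the skin threshold, a soft-tissue shell at or above it, and a bony shell
at or above the skull threshold.  Landmarks are placed at fixed parametric
directions on the skin surface so the generated annotation plays the role of a
manual one, with analytically known coordinates.

Axis convention (stack frame): array index ``[i, j, k]`` with
``i``/x = left-right (subject's left negative in the model frame),
``j``/y = posterior-anterior, ``k``/z = inferior-superior.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .landmarks import Landmark, LandmarkSet

SKIN_THRESHOLD = 10
SKULL_THRESHOLD = 110

_SKIN_FILL = 40
_SKULL_FILL = 180

# 6-neighbourhood for boundary/erosion, full 26-neighbourhood for deciding
# whether a background pocket is an enclosed cavity.
_STRUCT_6 = ndimage.generate_binary_structure(3, 1)
_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class VoxelVolume:
    """3D grid of 8-bit intensities with per-axis spacing in mm."""

    intensities: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a 3D array")
        if self.intensities.dtype != np.uint8:
            if self.intensities.min() < 0 or self.intensities.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            self.intensities = self.intensities.astype(np.uint8)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be strictly positive")
        if any(d <= 0 for d in self.intensities.shape):
            raise ValueError("dims must be strictly positive")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.intensities.shape


@dataclass
class BinaryVolume:
    """Boolean mask derived from a :class:`VoxelVolume` by thresholding."""

    mask: np.ndarray
    threshold_used: int
    label: str = "skin"
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.mask.shape


@dataclass
class PhantomSpec:
    """Parameters of the synthetic head.

    ``asymmetry`` perturbs the skin radius with low-order harmonics in the
    y/z direction components (mirror symmetry in x is preserved so bilateral
    checks stay meaningful).  ``feature_bumps`` adds Gaussian protuberances:
    tuples ``(name, direction, amplitude_mm)`` with ``direction`` a 3-vector.
    """

    grid_shape: tuple[int, int, int] = (128, 128, 128)
    skin_semiaxes_mm: tuple[float, float, float] = (58.0, 58.0, 58.0)
    skull_semiaxes_mm: tuple[float, float, float] = (48.0, 48.0, 48.0)
    skull_thickness_mm: float = 8.0
    center_voxel: tuple[float, float, float] | None = None
    asymmetry: tuple[float, float] = (0.0, 0.0)
    feature_bumps: list = field(default_factory=list)
    noise_sd: float = 0.0
    seed: int = 0
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        for axis, (a, b) in enumerate(
            zip(self.skull_semiaxes_mm, self.skin_semiaxes_mm)
        ):
            if a <= 0 or b <= 0:
                raise ValueError(f"degenerate semiaxis on axis {axis}")
            if a >= b:
                raise ValueError(
                    f"skull semiaxis must be smaller than skin semiaxis "
                    f"on axis {axis}"
                )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.center_voxel is None:
            self.center_voxel = tuple((n - 1) / 2.0 for n in self.grid_shape)


# Parametric directions for the phantom's "manual" annotation.  Azimuth is
# measured from anterior (+y) toward the subject's right (+x); elevation from
# the horizontal plane through the head centre.  Bilateral entries list the
# right-side azimuth; the left side mirrors it.  TE20 sits exactly lateral at
# elevation 0 so that the midpoint of the two sides is the head centre.
PHANTOM_DIRECTIONS: dict[str, tuple[str, float, float]] = {
    # name: (laterality, azimuth_deg, elevation_deg)
    "Yintang": ("midline", 0.0, 15.0),
    "TOP": ("midline", 0.0, 90.0),
    "Pupil": ("bilateral", 8.0, 5.0),
    "GV15": ("midline", 180.0, -30.0),
    "GV16": ("midline", 180.0, -20.0),
    "GV17": ("midline", 180.0, 15.0),
    "GV25": ("midline", 0.0, -10.0),
    "GV26": ("midline", 0.0, -20.0),
    "GV27": ("midline", 0.0, -25.0),
    "CV23": ("midline", 0.0, -50.0),
    "CV24": ("midline", 0.0, -32.0),
    "GB1": ("bilateral", 30.0, 4.0),
    "GB2": ("bilateral", 75.0, -12.0),
    "GB3": ("bilateral", 55.0, 5.0),
    "GB7": ("bilateral", 95.0, 12.0),
    "GB8": ("bilateral", 90.0, 28.0),
    "GB9": ("bilateral", 110.0, 25.0),
    "GB12": ("bilateral", 115.0, -15.0),
    "GB20": ("bilateral", 150.0, -22.0),
    "ST1": ("bilateral", 9.0, 1.0),
    "ST2": ("bilateral", 10.0, -4.0),
    "ST3": ("bilateral", 11.0, -10.0),
    "ST4": ("bilateral", 12.0, -20.0),
    "ST5": ("bilateral", 45.0, -30.0),
    "ST6": ("bilateral", 55.0, -28.0),
    "ST7": ("bilateral", 65.0, -5.0),
    "TE17": ("bilateral", 100.0, -14.0),
    "TE20": ("bilateral", 90.0, 0.0),
    "TE21": ("bilateral", 80.0, -2.0),
    "TE22": ("bilateral", 78.0, 2.0),
    "TE23": ("bilateral", 28.0, 10.0),
    "BL1": ("bilateral", 5.0, 6.0),
    "BL2": ("bilateral", 6.0, 12.0),
    "LI19": ("bilateral", 6.0, -19.0),
    "LI20": ("bilateral", 8.0, -15.0),
    "SI17": ("bilateral", 70.0, -32.0),
    "SI18": ("bilateral", 30.0, -8.0),
}


def _direction(az_deg: float, el_deg: float) -> np.ndarray:
    az = np.deg2rad(az_deg)
    el = np.deg2rad(el_deg)
    return np.array(
        [np.sin(az) * np.cos(el), np.cos(az) * np.cos(el), np.sin(el)]
    )


def _radius_factor(spec: PhantomSpec, d: np.ndarray) -> np.ndarray:
    """Direction-dependent multiplier on the skin radius (asymmetry/bumps).

    ``d`` is (..., 3) of unit directions; x enters only through |x| so the
    phantom stays mirror symmetric.
    """
    dy, dz = d[..., 1], d[..., 2]
    ay, az = spec.asymmetry
    factor = 1.0 + ay * dy**3 + az * dz**3
    for _name, bump_dir, amp in spec.feature_bumps:
        b = np.asarray(bump_dir, dtype=float)
        b = b / np.linalg.norm(b)
        cosang = np.clip(d @ b, -1.0, 1.0)
        ang = np.arccos(cosang)
        factor = factor + (amp / np.mean(spec.skin_semiaxes_mm)) * np.exp(
            -((ang / 0.25) ** 2)
        )
    return factor


def surface_point(spec: PhantomSpec, az_deg: float, el_deg: float) -> np.ndarray:
    """Stack-frame coordinates of the skin-surface point in direction
    (azimuth, elevation), by radial projection onto the deformed ellipsoid."""
    d = _direction(az_deg, el_deg)
    a = np.asarray(spec.skin_semiaxes_mm) * _radius_factor(spec, d)
    scale = 1.0 / np.sqrt(np.sum((d / a) ** 2))
    spacing = np.asarray(spec.spacing_mm)
    return np.asarray(spec.center_voxel) + d * scale / spacing


def phantom_landmarks(spec: PhantomSpec) -> LandmarkSet:
    """Ground-truth annotation for the phantom (34 anatomical + 3 auxiliary
    names, bilateral entries expanded to both sides), stack frame."""
    out = LandmarkSet()
    for name, (laterality, az, el) in PHANTOM_DIRECTIONS.items():
        if laterality == "midline":
            out.add(Landmark(name, "midline", tuple(surface_point(spec, az, el))))
        else:
            out.add(Landmark(name, "right", tuple(surface_point(spec, az, el))))
            out.add(Landmark(name, "left", tuple(surface_point(spec, -az, el))))
    return out


def generate_head_phantom(spec: PhantomSpec) -> tuple[VoxelVolume, LandmarkSet]:
    """Build the two-shell voxel head and its ground-truth landmark set.

    Skin-shell voxels get intensity >= 10 and < 110, skull-shell voxels
    >= 110, background < 10.
    """
    ni, nj, nk = spec.grid_shape
    spacing = np.asarray(spec.spacing_mm)
    ci, cj, ck = spec.center_voxel
    xs = ((np.arange(ni) - ci) * spacing[0]).astype(np.float32)
    ys = ((np.arange(nj) - cj) * spacing[1]).astype(np.float32)
    zs = ((np.arange(nk) - ck) * spacing[2]).astype(np.float32)

    deformed = any(spec.asymmetry) or spec.feature_bumps
    if deformed:
        pts = np.stack(
            np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1
        )
        rad = np.sqrt(np.sum(pts**2, axis=-1))
        with np.errstate(invalid="ignore", divide="ignore"):
            dirs = pts / np.where(rad[..., None] == 0, 1.0, rad[..., None])
        factor = _radius_factor(spec, dirs)

        def _inside(semiaxes) -> np.ndarray:
            a = np.asarray(semiaxes) * factor[..., None]
            return np.sum((pts / a) ** 2, axis=-1) <= 1.0

    else:
        # undeformed ellipsoids are separable: broadcast three 1D profiles
        def _inside(semiaxes) -> np.ndarray:
            a, b, c = semiaxes
            return (
                (xs[:, None, None] / a) ** 2
                + (ys[None, :, None] / b) ** 2
                + (zs[None, None, :] / c) ** 2
            ) <= 1.0

    skin = _inside(spec.skin_semiaxes_mm)
    skull_outer = _inside(spec.skull_semiaxes_mm)
    inner_axes = np.maximum(
        np.asarray(spec.skull_semiaxes_mm) - spec.skull_thickness_mm, 1.0
    )
    skull_inner = _inside(inner_axes)

    vol = np.zeros(spec.grid_shape, dtype=np.int16)
    vol[skin] = _SKIN_FILL
    vol[skull_outer & ~skull_inner] = _SKULL_FILL

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        vol = vol + rng.normal(0.0, spec.noise_sd, size=vol.shape)
    vol = np.clip(np.rint(vol), 0, 255).astype(np.uint8)

    return (
        VoxelVolume(vol, spacing_mm=tuple(spec.spacing_mm)),
        phantom_landmarks(spec),
    )


# ------------------------------------------------------------------ voxel ops

def binarize(vol: VoxelVolume, threshold: int) -> BinaryVolume:
    """Mask of voxels with intensity >= ``threshold`` (inclusive)."""
    if not 0 <= threshold <= 255:
        raise ValueError("threshold must be in [0, 255]")
    label = "skull" if threshold >= SKULL_THRESHOLD else "skin"
    return BinaryVolume(
        vol.intensities >= threshold, threshold, label, vol.spacing_mm
    )


def fill_holes(bin_vol: BinaryVolume, iterations: int = 1) -> BinaryVolume:
    """Seal holes: morphological closing (``iterations`` dilation/erosion
    steps) followed by filling of enclosed cavities.

    Cavities are background pockets with no 26-connected path to the array
    border.  The output is always a superset of the input mask.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    mask = bin_vol.mask
    if iterations > 0:
        closed = ndimage.binary_closing(
            mask, structure=_STRUCT_6, iterations=iterations
        )
        mask = mask | closed
    labels, _ = ndimage.label(~mask, structure=_STRUCT_26)
    border = np.zeros_like(mask)
    border[0, :, :] = border[-1, :, :] = True
    border[:, 0, :] = border[:, -1, :] = True
    border[:, :, 0] = border[:, :, -1] = True
    outside = np.unique(labels[border & ~mask])
    cavity = (labels > 0) & ~np.isin(labels, outside)
    return BinaryVolume(
        mask | cavity, bin_vol.threshold_used, bin_vol.label, bin_vol.spacing_mm
    )


def extract_boundary(bin_vol: BinaryVolume) -> BinaryVolume:
    """Mask voxels with at least one 6-neighbour outside the mask (array
    edges count as outside)."""
    if not bin_vol.mask.any():
        raise ValueError("cannot extract boundary of an empty mask")
    interior = ndimage.binary_erosion(
        bin_vol.mask, structure=_STRUCT_6, border_value=0
    )
    return BinaryVolume(
        bin_vol.mask & ~interior,
        bin_vol.threshold_used,
        bin_vol.label,
        bin_vol.spacing_mm,
    )


# ------------------------------------------------------------------ stack I/O

def write_bmp_stack(vol: VoxelVolume, directory: str | Path) -> None:
    """One 8-bit BMP per k slice (rows = j, columns = i) plus a JSON sidecar
    with dims and spacing."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ni, nj, nk = vol.dims
    for k in range(nk):
        img = Image.fromarray(vol.intensities[:, :, k].T, mode="L")
        img.save(directory / f"slice_{k:04d}.bmp")
    sidecar = {"dims": [ni, nj, nk], "spacing_mm": list(vol.spacing_mm)}
    (directory / "stack.json").write_text(json.dumps(sidecar, indent=1) + "\n")


def read_bmp_stack(directory: str | Path) -> VoxelVolume:
    directory = Path(directory)
    paths = sorted(directory.glob("*.bmp"))
    if not paths:
        raise FileNotFoundError(f"no BMP slices in {directory}")
    slices = []
    for p in paths:
        arr = np.asarray(Image.open(p).convert("L"))
        slices.append(arr.T)
    vol = np.stack(slices, axis=-1)
    spacing = (1.0, 1.0, 1.0)
    sidecar = directory / "stack.json"
    if sidecar.exists():
        spacing = tuple(json.loads(sidecar.read_text())["spacing_mm"])
    return VoxelVolume(vol, spacing_mm=spacing)


def read_dicom_series(directory: str | Path) -> VoxelVolume:
    """Optional DICOM reader; requires ``pydicom`` to be installed."""
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - optional path
        raise ImportError(
            "reading DICOM series requires the optional dependency 'pydicom'"
        ) from exc
    directory = Path(directory)
    files = sorted(directory.glob("*.dcm"))
    if not files:
        raise FileNotFoundError(f"no DICOM files in {directory}")
    datasets = [pydicom.dcmread(str(f)) for f in files]
    datasets.sort(key=lambda d: float(getattr(d, "SliceLocation", 0.0)))
    slices = []
    for ds in datasets:
        arr = ds.pixel_array.astype(float)
        lo, hi = arr.min(), arr.max()
        scaled = (arr - lo) / (hi - lo) * 255 if hi > lo else arr * 0
        slices.append(scaled.astype(np.uint8).T)
    vol = np.stack(slices, axis=-1)
    spc = datasets[0].PixelSpacing if hasattr(datasets[0], "PixelSpacing") else [1, 1]
    dz = float(getattr(datasets[0], "SliceThickness", 1.0))
    return VoxelVolume(vol, spacing_mm=(float(spc[0]), float(spc[1]), dz))
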