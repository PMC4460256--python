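"""Stack-to-model coordinate transform and anatomical reference planes."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import BinaryVolume

DEFAULT_ALPHA = 4.0 / 512.0

_COLLINEAR_TOL = 1e-12


@dataclass(frozen=True)
class ModelFrame:
    """Centred, scaled frame: p' = alpha * (p - center_of_mass)."""

    center_of_mass: tuple[float, float, float]
    alpha: float = DEFAULT_ALPHA

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")

    @property
    def cm(self) -> np.ndarray:
        return np.asarray(self.center_of_mass, dtype=float)

    def to_model(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return self.alpha * (pts - self.cm)

    def to_stack(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts / self.alpha + self.cm

    @property
    def voxel_pitch(self) -> float:
        """Model-frame size of one voxel step (unit spacing)."""
        return self.alpha


@dataclass(frozen=True)
class Plane:
    """Oriented plane; points p with dot(normal, p - anchor) = 0."""

    anchor: tuple[float, float, float]
    normal: tuple[float, float, float]
    kind: str = "generic"

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=float)
        length = np.linalg.norm(n)
        if length < _COLLINEAR_TOL:
            raise ValueError("degenerate plane normal")
        object.__setattr__(self, "normal", tuple(n / length))
        object.__setattr__(
            self, "anchor", tuple(float(v) for v in self.anchor)
        )

    @property
    def n(self) -> np.ndarray:
        return np.asarray(self.normal)

    @property
    def a(self) -> np.ndarray:
        return np.asarray(self.anchor)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return (pts - self.a) @ self.n


def center_of_mass(bin_vol: BinaryVolume) -> np.ndarray:
    """Mean index triple of the mask's true voxels.

    The raw moment sums are normalized by the voxel count so that the result
    is a centering translation.
    """
    if not bin_vol.mask.any():
        raise ValueError("center of mass of an empty mask is undefined")
    idx = np.argwhere(bin_vol.mask)
    return idx.mean(axis=0)


def to_model_frame(points: np.ndarray, frame: ModelFrame) -> np.ndarray:
    return frame.to_model(points)


def from_model_frame(points: np.ndarray, frame: ModelFrame) -> np.ndarray:
    return frame.to_stack(points)


def _plane_from_triple(anchor, span_a, span_b, kind: str) -> Plane:
    anchor = np.asarray(anchor, dtype=float)
    u = np.asarray(span_a, dtype=float) - anchor
    v = np.asarray(span_b, dtype=float) - anchor
    n = np.cross(u, v)
    scale = max(np.linalg.norm(u) * np.linalg.norm(v), _COLLINEAR_TOL)
    if np.linalg.norm(n) / scale < 1e-9:
        raise ValueError(f"collinear points cannot define the {kind} plane")
    return Plane(tuple(anchor), tuple(n), kind)


def sagittal_plane(yintang, top, gv17) -> Plane:
    """Midsagittal plane through Yintang, TOP and GV17.

    Normal is proportional to (GV17 - Yintang) x (TOP - Yintang), anchored at
    Yintang.
    """
    return _plane_from_triple(yintang, gv17, top, "sagittal")


def coronal_plane(te20_left, te20_right, top) -> Plane:
    """Coronal plane through the two TE20 points and TOP, anchored at TOP."""
    return _plane_from_triple(top, te20_left, te20_right, "coronal")


def transverse_plane(sagittal: Plane, coronal: Plane, level_point) -> Plane:
    """Plane perpendicular to the axis common to the sagittal and coronal
    planes, through ``level_point``."""
    axis = np.cross(sagittal.n, coronal.n)
    if np.linalg.norm(axis) < 1e-9:
        raise ValueError("sagittal and coronal planes are parallel")
    return Plane(tuple(np.asarray(level_point, dtype=float)), tuple(axis), "transverse")
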